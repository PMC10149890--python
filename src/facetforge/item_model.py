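"""Item pools, Likert response matrices and factor-structure maps.

The central objects here describe a multi-facet questionnaire: every item
belongs to exactly one narrow facet, and each facet is assigned to a broad
factor under one or more scoring schemes.  For the FFNI the package ships a
schematic 60-item pool with 15 facets, a three-factor map (agentic /
antagonistic / neurotic narcissism with a 4/8/3 facet split) and a
two-factor map (grandiose / vulnerable with an 11/4 split).

Responses are 1-5 Likert ratings with no missing values; reverse-keyed
items are recoded to ``6 - x`` at load time so every downstream statistic
operates on a consistently keyed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

LIKERT_MIN = 1
LIKERT_MAX = 5


class PoolError(ValueError):
    """Structural problem in an item pool or factor map."""


class DataError(ValueError):
    """Invalid response or criterion data (missing cell, out-of-range rating...)."""


@dataclass(frozen=True)
class Item:
    item_id: str
    facet: str
    text: str | None = None
    reverse_keyed: bool = False
    content_redundant: bool = False


@dataclass(frozen=True)
class FactorMap:
    """Facet -> factor assignment with a per-facet scoring sign.

    ``signs[facet]`` is +1 or -1; a -1 means the facet's items are
    reverse-scored when aggregated into its factor (e.g. indifference
    within neurotic narcissism).
    """

    factors: tuple[str, ...]
    assignment: Mapping[str, str]
    signs: Mapping[str, int]

    def facets_of(self, factor: str) -> list[str]:
        return [f for f, g in self.assignment.items() if g == factor]


@dataclass(frozen=True)
class ItemPool:
    items: tuple[Item, ...]
    facets: tuple[str, ...]
    map_three: FactorMap
    map_two: FactorMap

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for it in self.items:
            if it.item_id in seen:
                raise PoolError(f"duplicate item_id {it.item_id!r}")
            seen.add(it.item_id)
            if it.facet not in self.facets:
                raise PoolError(
                    f"item {it.item_id!r} references unknown facet {it.facet!r}"
                )
        for name, fmap in (("three", self.map_three), ("two", self.map_two)):
            for facet in self.facets:
                if facet not in fmap.assignment:
                    raise PoolError(
                        f"facet {facet!r} missing from the {name}-factor map"
                    )

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def items_of_facet(self, facet: str) -> list[Item]:
        return [it for it in self.items if it.facet == facet]

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise PoolError(f"unknown item {item_id!r}")

    def factor_map(self, model_kind: str) -> FactorMap:
        if model_kind == "three":
            return self.map_three
        if model_kind == "two":
            return self.map_two
        raise PoolError(f"model_kind must be 'two' or 'three', got {model_kind!r}")


@dataclass
class ResponseMatrix:
    """Persons x items integer Likert ratings aligned to an ItemPool subset.

    Values are stored after reverse-keying (6 - x for reverse-keyed items),
    so column means and correlations are directly interpretable.
    """

    values: np.ndarray
    person_ids: list[str]
    item_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if n != len(self.person_ids) or p != len(self.item_ids):
            raise DataError("response matrix shape does not match id lists")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise DataError("ratings must be integers")
        if self.values.min() < LIKERT_MIN or self.values.max() > LIKERT_MAX:
            raise DataError("ratings outside the 1-5 Likert range")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    def column(self, item_id: str) -> np.ndarray:
        return self.values[:, self.item_ids.index(item_id)]

    def subset(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(self.values[:, idx], self.person_ids, list(item_ids))

    def degenerate_items(self) -> list[str]:
        """Items whose column holds fewer than 2 distinct ratings."""
        out = []
        for j, iid in enumerate(self.item_ids):
            if np.unique(self.values[:, j]).size < 2:
                out.append(iid)
        return out


@dataclass
class CriterionTable:
    """Persons x external criterion scores, person-aligned with a ResponseMatrix."""

    values: np.ndarray
    person_ids: list[str]
    criterion_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise DataError("criterion table contains missing values")
        n, c = self.values.shape
        if n != len(self.person_ids) or c != len(self.criterion_ids):
            raise DataError("criterion table shape does not match id lists")

    def column(self, criterion_id: str) -> np.ndarray:
        return self.values[:, self.criterion_ids.index(criterion_id)]

    def check_alignment(self, responses: ResponseMatrix) -> None:
        if self.person_ids != responses.person_ids:
            raise DataError("criterion table persons are not aligned with responses")


# ---------------------------------------------------------------------------
# loading / writing


def _build_factor_map(raw: Mapping, facets: Sequence[str], name: str) -> FactorMap:
    assignment: dict[str, str] = {}
    signs: dict[str, int] = {}
    factors = tuple(raw.keys())
    for factor, facet_list in raw.items():
        for entry in facet_list:
            if isinstance(entry, str):
                facet, sign = entry, 1
            else:  # {"facet": ..., "sign": -1}
                facet, sign = entry["facet"], int(entry.get("sign", 1))
            if facet in assignment:
                raise PoolError(
                    f"facet {facet!r} assigned twice in the {name}-factor map"
                )
            assignment[facet] = factor
            signs[facet] = sign
    for facet in facets:
        if facet not in assignment:
            raise PoolError(f"facet {facet!r} missing from the {name}-factor map")
    return FactorMap(factors=factors, assignment=assignment, signs=signs)


def load_item_pool(pool_file: str | Path) -> ItemPool:
    """Read a pool spec (YAML/JSON) and return a validated :class:`ItemPool`."""
    with open(pool_file, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    facets = tuple(raw["facets"])
    items = tuple(
        Item(
            item_id=str(d["id"]),
            facet=d["facet"],
            text=d.get("text"),
            reverse_keyed=bool(d.get("reverse_keyed", False)),
            content_redundant=bool(d.get("content_redundant", False)),
        )
        for d in raw["items"]
    )
    maps = raw["factor_maps"]
    return ItemPool(
        items=items,
        facets=facets,
        map_three=_build_factor_map(maps["three"], facets, "three"),
        map_two=_build_factor_map(maps["two"], facets, "two"),
    )


def bundled_pool_path() -> Path:
    """Path of the packaged schematic FFNI short-form pool spec."""
    return Path(__file__).parent / "data" / "ffni_sf_pool.yaml"


def load_bundled_pool() -> ItemPool:
    return load_item_pool(bundled_pool_path())


def apply_pool_filters(
    pool: ItemPool, drop_redundant: bool = True, drop_reverse: bool = True
) -> ItemPool:
    """Remove flagged items, keeping the facet list intact.

    Raises :class:`PoolError` if any facet would retain fewer than 2
    candidates, since a 2-items-per-facet selection would then be infeasible.
    """
    kept = tuple(
        it
        for it in pool.items
        if not (drop_redundant and it.content_redundant)
        and not (drop_reverse and it.reverse_keyed)
    )
    filtered = replace(pool, items=kept)
    for facet in filtered.facets:
        k = len(filtered.items_of_facet(facet))
        if k < 2:
            raise PoolError(
                f"facet {facet!r} retains only {k} candidate item(s) after filtering"
            )
    return filtered


def load_responses(table_file: str | Path, pool: ItemPool) -> ResponseMatrix:
    """Read a delimited persons x items table and validate against *pool*.

    The first column holds person ids.  Reverse-keyed items are recoded as
    ``6 - x``.  Missing cells, unknown columns and out-of-range ratings are
    hard errors.
    """
    df = pd.read_csv(table_file, sep=None, engine="python", index_col=0)
    unknown = [c for c in df.columns if c not in pool.item_ids]
    if unknown:
        raise DataError(f"unknown item column(s): {unknown}")
    # align to pool order, keeping only columns present in the file
    ordered = [i for i in pool.item_ids if i in df.columns]
    df = df[ordered]
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise DataError(f"missing ratings for person(s) {rows}; complete data required")
    values = df.to_numpy()
    bad = (values < LIKERT_MIN) | (values > LIKERT_MAX) | (values != np.floor(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"invalid rating {values[i, j]!r} at person {df.index[i]!r}, "
            f"item {ordered[j]!r}"
        )
    values = values.astype(np.int64)
    for j, iid in enumerate(ordered):
        if pool.item(iid).reverse_keyed:
            values[:, j] = LIKERT_MAX + LIKERT_MIN - values[:, j]
    return ResponseMatrix(values, [str(x) for x in df.index], ordered)


def write_responses(responses: ResponseMatrix, path: str | Path, pool: ItemPool | None = None) -> None:
    """Write a response matrix as CSV (inverse of :func:`load_responses`).

    Reverse-keying is undone on output so the round-trip is the identity.
    """
    values = responses.values.copy()
    if pool is not None:
        for j, iid in enumerate(responses.item_ids):
            if pool.item(iid).reverse_keyed:
                values[:, j] = LIKERT_MAX + LIKERT_MIN - values[:, j]
    df = pd.DataFrame(values, index=responses.person_ids, columns=responses.item_ids)
    df.index.name = "person"
    df.to_csv(path)


def load_criteria(table_file: str | Path) -> CriterionTable:
    df = pd.read_csv(table_file, sep=None, engine="python", index_col=0)
    if df.isna().any().any():
        raise DataError("criterion table contains missing values")
    return CriterionTable(
        df.to_numpy(dtype=float), [str(x) for x in df.index], list(df.columns)
    )


def write_criteria(criteria: CriterionTable, path: str | Path) -> None:
    df = pd.DataFrame(
        criteria.values, index=criteria.person_ids, columns=criteria.criterion_ids
    )
    df.index.name = "person"
    df.to_csv(path)


def scale_memberships(
    pool: ItemPool,
    selection: Sequence[str] | None = None,
    model_kind: str = "three",
) -> dict[str, list[tuple[str, int]]]:
    """Map each factor to its ordered ``(item_id, sign)`` list.

    *selection* restricts the membership to a subset of the pool (the brief
    form); by default all pool items are used.  Signs come from the factor
    map: a facet scored negatively (indifference under neurotic narcissism)
    contributes its items with sign -1, i.e. reverse-scored within the scale.
    """
    fmap = pool.factor_map(model_kind)
    if selection is None:
        selected = list(pool.item_ids)
    else:
        unknown = [i for i in selection if i not in pool.item_ids]
        if unknown:
            raise PoolError(f"selection contains unknown item(s): {unknown}")
        selected = list(selection)
    out: dict[str, list[tuple[str, int]]] = {f: [] for f in fmap.factors}
    for iid in selected:
        facet = pool.item(iid).facet
        factor = fmap.assignment[facet]
        out[factor].append((iid, fmap.signs[facet]))
    return out
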