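{
  "type": "object",
  "required": ["version", "pool", "selection", "selection_sample", "config"],
  "properties": {
    "version": {"type": "string"},
    "pool": {
      "type": "object",
      "required": ["n_items_full", "n_items_filtered", "facets"],
      "properties": {
        "n_items_full": {"type": "integer"},
        "n_items_filtered": {"type": "integer"},
        "facets": {"type": "array"}
      }
    },
    "selection": {
      "type": "object",
      "required": ["items", "by_facet", "n_items"],
      "properties": {
        "items": {"type": "array"},
        "by_facet": {"type": "object"},
        "n_items": {"type": "integer"}
      }
    },
    "selection_sample": {
      "type": "object",
      "required": ["selection", "objective"],
      "properties": {
        "selection": {"type": "array"},
        "objective": {
          "type": "object",
          "required": ["composite"],
          "properties": {"composite": {"type": "number"}}
        }
      }
    },
    "validation_sample": {"type": "object", "nullable": true},
    "validation_degraded": {"type": "boolean", "nullable": true},
    "alpha": {"type": "object"},
    "brief_vs_full_pool_r": {"type": "object"},
    "config": {
      "type": "object",
      "required": ["aco", "objective"],
      "properties": {
        "aco": {"type": "object"},
        "objective": {"type": "object"}
      }
    },
    "run_best_composites": {"type": "array"},
    "trace": {"type": "array"}
  }
}
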