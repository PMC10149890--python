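# Schematic FFNI short-form pool: 60 items, 15 facets (4 items per facet),
# with the published three-factor (agentic 4 / antagonistic 8 / neurotic 3
# facets) and two-factor (grandiose 11 / vulnerable 4 facets) maps.
#
# SYNTHETIC ITEM IDENTITIES: item ids are schematic ("<facet>_<k>"); the
# German item texts and the identities of the six content-redundant and two
# reverse-coded items excluded from the selection pool are published in the
# instrument's published supplementary materials and are not reproduced
# here.  The flags below mark placeholder items chosen so that the filtered
# pool has the documented size (52) and every facet keeps >= 2 candidates.
facets:
  - acclaim_seeking
  - authoritativeness
  - grandiose_fantasies
  - exhibitionism
  - manipulativeness
  - exploitativeness
  - entitlement
  - lack_of_empathy
  - arrogance
  - reactive_anger
  - distrust
  - thrill_seeking
  - shame
  - indifference
  - need_for_admiration

factor_maps:
  three:
    agentic:
      - acclaim_seeking
      - authoritativeness
      - grandiose_fantasies
      - exhibitionism
    antagonistic:
      - manipulativeness
      - exploitativeness
      - entitlement
      - lack_of_empathy
      - arrogance
      - reactive_anger
      - distrust
      - thrill_seeking
    neurotic:
      - shame
      - {facet: indifference, sign: -1}
      - need_for_admiration
  two:
    grandiose:
      - indifference
      - exhibitionism
      - authoritativeness
      - grandiose_fantasies
      - manipulativeness
      - exploitativeness
      - entitlement
      - lack_of_empathy
      - arrogance
      - acclaim_seeking
      - thrill_seeking
    vulnerable:
      - reactive_anger
      - shame
      - need_for_admiration
      - distrust

items:
  - {id: acclaim_seeking_1, facet: acclaim_seeking}
  - {id: acclaim_seeking_2, facet: acclaim_seeking}
  - {id: acclaim_seeking_3, facet: acclaim_seeking}
  - {id: acclaim_seeking_4, facet: acclaim_seeking, content_redundant: true}
  - {id: authoritativeness_1, facet: authoritativeness}
  - {id: authoritativeness_2, facet: authoritativeness}
  - {id: authoritativeness_3, facet: authoritativeness}
  - {id: authoritativeness_4, facet: authoritativeness}
  - {id: grandiose_fantasies_1, facet: grandiose_fantasies}
  - {id: grandiose_fantasies_2, facet: grandiose_fantasies}
  - {id: grandiose_fantasies_3, facet: grandiose_fantasies}
  - {id: grandiose_fantasies_4, facet: grandiose_fantasies, content_redundant: true}
  - {id: exhibitionism_1, facet: exhibitionism}
  - {id: exhibitionism_2, facet: exhibitionism}
  - {id: exhibitionism_3, facet: exhibitionism}
  - {id: exhibitionism_4, facet: exhibitionism}
  - {id: manipulativeness_1, facet: manipulativeness}
  - {id: manipulativeness_2, facet: manipulativeness}
  - {id: manipulativeness_3, facet: manipulativeness}
  - {id: manipulativeness_4, facet: manipulativeness, content_redundant: true}
  - {id: exploitativeness_1, facet: exploitativeness}
  - {id: exploitativeness_2, facet: exploitativeness}
  - {id: exploitativeness_3, facet: exploitativeness}
  - {id: exploitativeness_4, facet: exploitativeness}
  - {id: entitlement_1, facet: entitlement}
  - {id: entitlement_2, facet: entitlement}
  - {id: entitlement_3, facet: entitlement}
  - {id: entitlement_4, facet: entitlement, content_redundant: true}
  - {id: lack_of_empathy_1, facet: lack_of_empathy}
  - {id: lack_of_empathy_2, facet: lack_of_empathy}
  - {id: lack_of_empathy_3, facet: lack_of_empathy}
  - {id: lack_of_empathy_4, facet: lack_of_empathy}
  - {id: arrogance_1, facet: arrogance}
  - {id: arrogance_2, facet: arrogance}
  - {id: arrogance_3, facet: arrogance}
  - {id: arrogance_4, facet: arrogance, content_redundant: true}
  - {id: reactive_anger_1, facet: reactive_anger}
  - {id: reactive_anger_2, facet: reactive_anger}
  - {id: reactive_anger_3, facet: reactive_anger}
  - {id: reactive_anger_4, facet: reactive_anger}
  - {id: distrust_1, facet: distrust}
  - {id: distrust_2, facet: distrust}
  - {id: distrust_3, facet: distrust}
  - {id: distrust_4, facet: distrust}
  - {id: thrill_seeking_1, facet: thrill_seeking}
  - {id: thrill_seeking_2, facet: thrill_seeking}
  - {id: thrill_seeking_3, facet: thrill_seeking}
  - {id: thrill_seeking_4, facet: thrill_seeking, content_redundant: true}
  - {id: shame_1, facet: shame}
  - {id: shame_2, facet: shame}
  - {id: shame_3, facet: shame}
  - {id: shame_4, facet: shame}
  - {id: indifference_1, facet: indifference}
  - {id: indifference_2, facet: indifference}
  - {id: indifference_3, facet: indifference, reverse_keyed: true}
  - {id: indifference_4, facet: indifference, reverse_keyed: true}
  - {id: need_for_admiration_1, facet: need_for_admiration}
  - {id: need_for_admiration_2, facet: need_for_admiration}
  - {id: need_for_admiration_3, facet: need_for_admiration}
  - {id: need_for_admiration_4, facet: need_for_admiration}
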