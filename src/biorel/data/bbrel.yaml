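# Bacteria-Biotope relation extraction task configuration.
#
# Two relation categories: Lives_In holds between a microorganism and a
# location (habitat or geographical) entity; Exhibits holds between a
# microorganism and a phenotype entity.  No relation is legal between,
# e.g., a geographical and a phenotype entity, so such pairs are never
# candidates.  Relations are undirected; the dependency path and the
# role-named output are always oriented microorganism-first.
name: bbrel
categories: [none, Lives_In, Exhibits]
entity_types: [Microorganism, Habitat, Geographical, Phenotype]
legal_triples:
  - [Microorganism, Habitat, Lives_In]
  - [Microorganism, Geographical, Lives_In]
  - [Microorganism, Phenotype, Exhibits]
orientation_priority: [Microorganism]
roles:
  Lives_In: [Microorganism, Location]
  Exhibits: [Microorganism, Property]
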