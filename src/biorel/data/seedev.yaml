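# Seed-development (Arabidopsis thaliana) binary relation extraction task
# configuration — EDITABLE SKELETON.
#
# The 22 relation categories are listed below.  The full legal
# (type, type, category) constraint table and the cluster membership map
# are defined by the task's own documentation, not bundled here:
# `legal_triples: null` means unconstrained (every intra-sentence type
# pair becomes a candidate) until you fill the table in, and the cluster
# lists must be completed before `biorel evaluate --clusters` is used.
name: seedev
categories:
  - none
  - Exists_In_Genotype
  - Occurs_In_Genotype
  - Exists_At_Stage
  - Occurs_During
  - Is_Localized_In
  - Is_Involved_In_Process
  - Transcribes_Or_Translates_To
  - Is_Functionally_Equivalent_To
  - Regulates_Accumulation
  - Regulates_Development_Phase
  - Regulates_Expression
  - Regulates_Molecule_Activity
  - Regulates_Process
  - Regulates_Tissue_Development
  - Composes_Primary_Structure
  - Composes_Protein_Complex
  - Is_Protein_Domain_Of
  - Is_Member_Of_Family
  - Has_Sequence_Identical_To
  - Interacts_With
  - Binds_To
  - Is_Linked_To
entity_types:
  - Gene
  - Gene_Family
  - Box
  - Promoter
  - RNA
  - Protein
  - Protein_Family
  - Protein_Complex
  - Protein_Domain
  - Hormone
  - Regulatory_Network
  - Pathway
  - Genotype
  - Tissue
  - Development_Phase
  - Environmental_Factor
legal_triples: null
orientation_priority: []
clusters:
  Comparison: []
  Function: []
  Regulation: []
  Genic_regulation: []
  Composition_membership: []
  Interaction: []
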