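# Tiered metadata reporting checklist, human gut flavour.
#
# Derived from the MIxS v6.0 core checklist plus the MIMARKS and human-gut
# environmental package fields. Tiers are cumulative: Silver requires every
# Bronze field, Gold requires every Silver field. Alternative environment
# packages can be dropped in as sibling YAML files with the same schema.

name: human-gut
tiers:
  bronze:
    - sample name
    - project name
    - taxonomy id
    - collection date
    - lat lon
    - geo loc name
    - broad-scale environmental context
    - local-scale environmental context
    - environmental medium
  silver_additional:
    - sequencing method
    - negative control type
    - target gene
    - pcr primers
    - host subject id
    - host disease status
    - host total mass
    - host sex
  gold_additional:
    - sample material processing
    - nucleic acid extraction
    - host height
    - host diet
    - host occupation
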