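# Default attribute-synonym map and missing-value vocabulary.
#
# Synonym matching is case- and separator-insensitive (spaces, underscores
# and hyphens are equivalent), so each entry below stands for the whole
# family of casing/separator variants. Only "Sample Name" and
# "User_sample_ID" are documented submitter variants from published INSDC
# records; the remaining entries are implementation-supplied common INSDC
# variants (non-normative, freely editable).

synonyms:
  # sample name family
  sample name: sample name
  user sample id: sample name
  sample title: sample name
  sample id: sample name
  sample alias: sample name
  isolate name: sample name
  library name: sample name
  # project
  project name: project name
  bioproject: project name
  study name: project name
  # taxonomy
  taxonomy id: taxonomy id
  taxid: taxonomy id
  ncbi taxonomy id: taxonomy id
  organism taxid: taxonomy id
  # collection date
  collection date: collection date
  date of collection: collection date
  sampling date: collection date
  # geography
  lat lon: lat lon
  latitude and longitude: lat lon
  geographic location latitude longitude: lat lon
  geo loc name: geo loc name
  geographic location: geo loc name
  geographic location country and or sea: geo loc name
  country: geo loc name
  # environmental context
  broad-scale environmental context: broad-scale environmental context
  env broad scale: broad-scale environmental context
  broad scale environmental context: broad-scale environmental context
  local-scale environmental context: local-scale environmental context
  env local scale: local-scale environmental context
  local scale environmental context: local-scale environmental context
  environmental medium: environmental medium
  env medium: environmental medium
  env material: environmental medium
  # sample processing
  sequencing method: sequencing method
  seq meth: sequencing method
  sequencing technology: sequencing method
  negative control type: negative control type
  neg cont type: negative control type
  target gene: target gene
  target subfragment: target gene
  pcr primers: pcr primers
  primer sequences: pcr primers
  # host
  host subject id: host subject id
  subject id: host subject id
  participant id: host subject id
  host disease status: host disease status
  host disease: host disease status
  disease status: host disease status
  host total mass: host total mass
  host weight: host total mass
  host body mass: host total mass
  host sex: host sex
  sex: host sex
  gender: host sex
  host height: host height
  height: host height
  host diet: host diet
  diet: host diet
  host occupation: host occupation
  occupation: host occupation
  sample material processing: sample material processing
  samp mat process: sample material processing
  nucleic acid extraction: nucleic acid extraction
  dna extraction method: nucleic acid extraction

# Values treated as missing after trimming and case-folding (mirrors the
# INSDC missing-value reporting vocabulary).
missing_tokens:
  - ""
  - "na"
  - "n/a"
  - "nan"
  - "missing"
  - "not applicable"
  - "not collected"
  - "not provided"
  - "unknown"
  - "-"
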