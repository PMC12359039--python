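# Pattern catalogue for sequence-data evidence extraction.
#
# Human-editable. Accession patterns follow the public INSDC / partner-archive
# prefix conventions; minimum digit counts guard against gene-symbol
# collisions (e.g. the protein "SRP54" must never match the SRP study
# prefix). All accession patterns are matched case-sensitively with
# alphanumeric word boundaries applied by the extractor.

accessions:
  - {registry: SRA,        record_type: bioproject,     pattern: 'PRJNA\d{4,}'}
  - {registry: ENA,        record_type: bioproject,     pattern: 'PRJEB\d{4,}'}
  - {registry: DDBJ,       record_type: bioproject,     pattern: 'PRJDB\d{4,}'}
  - {registry: SRA,        record_type: study,          pattern: 'SRP\d{4,}'}
  - {registry: ENA,        record_type: study,          pattern: 'ERP\d{4,}'}
  - {registry: DDBJ,       record_type: study,          pattern: 'DRP\d{4,}'}
  - {registry: SRA,        record_type: sample,         pattern: 'SAMN\d{4,}'}
  - {registry: ENA,        record_type: sample,         pattern: 'SAMEA?\d{4,}'}
  - {registry: DDBJ,       record_type: sample,         pattern: 'SAMD\d{4,}'}
  - {registry: SRA,        record_type: sample,         pattern: 'SRS\d{4,}'}
  - {registry: ENA,        record_type: sample,         pattern: 'ERS\d{4,}'}
  - {registry: DDBJ,       record_type: sample,         pattern: 'DRS\d{4,}'}
  - {registry: SRA,        record_type: experiment,     pattern: 'SRX\d{4,}'}
  - {registry: ENA,        record_type: experiment,     pattern: 'ERX\d{4,}'}
  - {registry: DDBJ,       record_type: experiment,     pattern: 'DRX\d{4,}'}
  - {registry: SRA,        record_type: run,            pattern: 'SRR\d{5,}'}
  - {registry: ENA,        record_type: run,            pattern: 'ERR\d{5,}'}
  - {registry: DDBJ,       record_type: run,            pattern: 'DRR\d{5,}'}
  - {registry: CNCB-NGDC,  record_type: bioproject,     pattern: 'PRJCA\d{4,}'}
  - {registry: CNCB-NGDC,  record_type: study,          pattern: 'CRA\d{4,}'}
  - {registry: CNCB-NGDC,  record_type: run,            pattern: 'CRR\d{5,}'}
  - {registry: CNGB,       record_type: bioproject,     pattern: 'CNP\d{4,}'}
  - {registry: MG-RAST,    record_type: analysis,       pattern: 'mgm\d{4,}\.\d+'}
  - {registry: EGA,        record_type: study,          pattern: 'EGAS\d{11}'}
  - {registry: EGA,        record_type: analysis,       pattern: 'EGAD\d{11}'}
  - {registry: Zenodo,     record_type: repository_doi, pattern: '10\.5281/zenodo\.\d+'}
  - {registry: Figshare,   record_type: repository_doi, pattern: '10\.6084/m9\.figshare\.\d+'}

# Explicit database-name mentions (used to populate databases_mentioned even
# when no accession from that archive is cited). case_sensitive applies to
# short ambiguous initialisms.
database_names:
  - {registry: SRA,       pattern: 'SRA',                               case_sensitive: true}
  - {registry: SRA,       pattern: 'Sequence Read Archive',             case_sensitive: false}
  - {registry: ENA,       pattern: 'ENA',                               case_sensitive: true}
  - {registry: ENA,       pattern: 'European Nucleotide Archive',       case_sensitive: false}
  - {registry: DDBJ,      pattern: 'DDBJ',                              case_sensitive: true}
  - {registry: DDBJ,      pattern: 'DNA Data Bank of Japan',            case_sensitive: false}
  - {registry: CNCB-NGDC, pattern: 'CNCB|NGDC',                         case_sensitive: true}
  - {registry: CNCB-NGDC, pattern: 'National Genomics Data Center|Genome Sequence Archive', case_sensitive: false}
  - {registry: MG-RAST,   pattern: 'MG-RAST',                           case_sensitive: false}
  - {registry: Figshare,  pattern: 'figshare',                          case_sensitive: false}
  - {registry: Zenodo,    pattern: 'zenodo',                            case_sensitive: false}
  - {registry: EGA,       pattern: 'EGA',                               case_sensitive: true}
  - {registry: EGA,       pattern: 'European Genome[- ]Phenome Archive', case_sensitive: false}
  - {registry: CNGB,      pattern: 'CNGB|China National GeneBank',      case_sensitive: true}

# Archives where data retrieval requires no login or institutional
# affiliation. EGA is controlled-access and deliberately excluded.
open_registries: [SRA, ENA, DDBJ, Figshare, Zenodo, MG-RAST, CNCB-NGDC, CNGB]

primers:
  min_length: 12
  context_window: 200
  # case-insensitive context keywords
  keywords:
    - 'primers?'
    - 'forward'
    - 'reverse'
    - 'amplif\w*'
    - 'amplicon'
    - '16S'
    - '18S'
  # case-sensitive context keywords ("its" is an English word; V4 etc. and
  # 515F-style labels are only meaningful uppercase)
  keywords_case_sensitive:
    - 'ITS[12]?'
    - 'V[1-9]'
    - '\d{1,4}[FR]'

sequencing_method:
  marker_gene:
    - {pattern: '16S', case_sensitive: false}
    - {pattern: '18S', case_sensitive: false}
    - {pattern: 'ITS[12]?', case_sensitive: true}
    - {pattern: 'rRNA gene', case_sensitive: false}
    - {pattern: 'amplicon', case_sensitive: false}
    - {pattern: 'metabarcoding', case_sensitive: false}
    - {pattern: 'marker[- ]gene', case_sensitive: false}
  metagenome:
    - {pattern: 'shotgun', case_sensitive: false}
    - {pattern: 'metagenom\w*', case_sensitive: false}
    - {pattern: 'WGS', case_sensitive: true}
    - {pattern: 'whole[- ]genome sequencing', case_sensitive: false}

code_links:
  hosts: [github.com, gitlab.com, bitbucket.org, zenodo.org, osf.io, codeocean.com]
  context_window: 200
  keywords:
    - 'code'
    - 'scripts?'
    - 'software'
    - 'pipeline'
    - 'notebooks?'
    - 'workflows?'

# Data-availability-statement trigger phrases, matched case-insensitively as
# substrings. Classification precedence:
#   public_deposit > restricted_with_procedure > upon_request > in_paper_only
das_phrases:
  public_deposit:
    - 'deposited in'
    - 'deposited at'
    - 'deposited to'
    - 'uploaded to'
    - 'submitted to'
    - 'are available in'
    - 'are available at'
    - 'available in the'
    - 'can be found in'
    - 'under accession'
    - 'under bioproject'
  restricted_with_procedure:
    - 'controlled access'
    - 'managed access'
    - 'data access committee'
    - 'upon application'
    - 'by application'
    - 'access application'
    - 'authorized researchers'
  upon_request:
    - 'upon request'
    - 'on request'
    - 'upon reasonable request'
    - 'on reasonable request'
    - 'from the corresponding author'
  in_paper_only:
    - 'within the article'
    - 'within the paper'
    - 'in this published article'
    - 'within the supplementary'
    - 'in the supplementary material'
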