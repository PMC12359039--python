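# fairbadge

Tiered open-data badge assessment for microbiome publications.

Microbiome studies routinely promise raw sequence data that cannot actually
be retrieved — accessions are missing, data sit behind "available upon
reasonable request" statements, or the deposited records lack the metadata
needed for reuse. `fairbadge` turns two tiered reporting standards into an
automated, testable evaluation tool:

* a **sequence-data availability badge** (None / Bronze / Silver / Gold /
  Cannot-be-determined) assigned from machine-extracted evidence in the
  article full text plus repository resolution, and
* a **metadata reporting tier** for INSDC sample records, evaluated against
  cumulative MIxS-derived checklists after harmonizing submitter-specific
  attribute spellings, together with cross-study sparsity analytics.

It is aimed at meta-analysts screening for reusable datasets, at journals
and funders auditing compliance, and at authors self-assessing before
submission.

## The badge rules

A badge is the highest cumulative tier whose requirements are all satisfied
or not applicable:

| Tier | Requirements (cumulative) |
|------|---------------------------|
| Bronze | data downloadable and not paywalled; accession numbers provided; raw sequences as BCL or FASTQ |
| Silver | + sequencing method stated (marker gene vs metagenomics); PCR primer sequences (amplicon studies only; *n/a* for pure metagenomes) |
| Gold | + access requirements clear (public data, or a stated procedure otherwise); repository open without login/affiliation (e.g. SRA, figshare; EGA is controlled-access); analysis code provided |

Articles below Bronze are *None*; unretrievable full text is
*Cannot be determined*. A binary *None-versus-Badged* collapse supports
"is there minimally available data?" screening.

Predicted badges are scored against manual labels with overall accuracy,
per-class precision/recall/F1 with support, macro-average F1 (unweighted
mean over classes present in the truth labels) and truth-support-weighted
F1.

## Worked example

```bash
# write a seeded 200-article fixture corpus (JATS XML + manifest + truth)
fairbadge make-fixtures --output-dir fixtures --seed 1

# assign badges offline (ids as arguments, or a file via --ids-file)
fairbadge assess-sequences --offline --fixtures-dir fixtures \
    PMC9000000 PMC9000001 --output badges.csv
```

`badges.csv` holds one row per article with the badge and every evidence
component (explicitly marked `not_detected` when absent), e.g.:

```
article_id,badge,database,accessions,n_runs,primers,code_links,das_class,missing_criteria,retrieval_status
PMC9000001,silver,SRA,PRJNA302995;SRR1219930;SRR1219933,4,GTGYCAGCMGCCGCGGTAA;GGACTACNVGGGTWTCTAAT,not_detected,public_deposit,code_provided,ok
PMC9000000,none,not_detected,not_detected,0,not_detected,not_detected,upon_request,data_downloadable_not_paywalled;accession_numbers_provided;raw_sequences_bcl_or_fastq,ok
```

The first article deposited FASTQ runs under a BioProject with primers and
method stated, but published no code — Silver, one criterion short of Gold.
The second promises data "upon reasonable request" and fails every Bronze
requirement. Scoring a labels file
(`fairbadge evaluate labels.csv -o report.csv`) on the three-item reference
set prints `accuracy=0.667` in both the four-category and binary views.

Sample metadata is assessed per accession:

```bash
fairbadge assess-metadata --fixtures-dir fixtures PRJNA800000 \
    --output metadata.csv --assess-tier
```

which emits the full long-format attribute table plus the awarded metadata
tier and its blocking fields.

## Layout

* `src/fairbadge/extraction.py` — accession/primer/method/code/DAS detectors
  (pattern catalogues in `src/fairbadge/data/*.yaml`, human-editable)
* `src/fairbadge/badge_engine.py` — evidence bundle and badge rules
* `src/fairbadge/metadata_engine.py` — harmonization, tier checklists,
  population/sparsity analytics
* `src/fairbadge/repo_clients.py` — offline fixture client (hermetic) and a
  polite live client for NCBI/EBI endpoints
* `src/fairbadge/evaluation.py` — accuracy/F1 scoring of predictions
* `src/fairbadge/synthetic_fixtures.py` — seeded article and metadata
  generators with known ground truth
* `src/fairbadge/cli.py` — `assess-sequences`, `assess-metadata`,
  `evaluate`, `make-fixtures`

See `docs/methods.md` for the model, defaults, and known limitations.
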