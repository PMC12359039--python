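# Methods

## The badge model

The sequence-data availability badge is an ordinal standard over eight
boolean requirements, grouped into cumulative tiers. The engine operates on
an explicit `EvidenceBundle` in which every requirement is a set boolean —
unknown evidence is recorded as `False` with the reason kept in a
provenance map — so the rules are a total function and can be verified by
exhaustive enumeration (2^9 bundles minus the combinations excluded by the
invariant that downloadability presupposes an accession; 384 valid cases).

Two modelling choices deserve note:

* **Downloadability is required at every tier.** Prose descriptions of the
  Silver tier sometimes allow data that are "not necessarily openly
  accessible"; the machine-readable requirement table lists "downloadable
  and not paywalled" in every column, and the table is normative here. The
  non-public alternative survives only in Gold's access-clarity
  requirement, which is satisfied either by public data or by a stated
  access procedure in the data-availability statement (DAS).
* **Raw-format evidence comes from repository listings, never prose.** The
  BCL/FASTQ requirement is established from resolved run file listings
  (live) or the fixture manifest (offline); articles' own claims about
  formats are unreliable.
* **Primer reporting is scoped to amplicon studies.** For a pure
  metagenome study the primer criterion is *not applicable* rather than
  satisfied, which keeps the criterion ledger honest.

**Monotonicity** (more evidence never lowers the badge) holds for every
evidence boolean except `is_amplicon`, which is study context rather than
openness evidence: declaring a study amplicon-based activates the primer
requirement and can legitimately drop Silver to Bronze. Tests and the
acceptance script therefore check monotonicity over the other eight
booleans, exhaustively.

`cannot_be_determined` (full text unretrievable or unparseable) maps to
`not_badged` in the binary collapse but is excluded from accuracy
computations by default; a flag includes it.

## Evidence extraction

Extraction is pattern-driven and deterministic; all catalogues are packaged
YAML (`src/fairbadge/data/sequence_catalogue.yaml`) and editable without
code changes.

* **Accessions** — the public INSDC prefix grammar (BioProject
  `PRJ(NA|EB|DB)`, studies `(SRP|ERP|DRP)`, samples `SAM(N|EA?|D)` /
  `(SRS|ERS|DRS)`, experiments, runs `(SRR|ERR|DRR)`) plus partner archives
  (CNCB-NGDC `PRJCA`/`CRA`/`CRR`, CNGB `CNP`, MG-RAST `mgm…`, EGA
  `EGAS`/`EGAD`, Zenodo and figshare DOIs). Guards: alphanumeric word
  boundaries, minimum digit counts (≥5 for runs, ≥4 elsewhere) so gene
  symbols like *SRP54* never match, dedup on token, first-occurrence
  order. `A to B` / `A–B` spans are flagged as range endpoints and not
  expanded (expansion would require a registry lookup).
* **Primers** — runs of ≥12 IUPAC nucleotide letters (case-insensitive,
  reported upper-case) accepted only when a primer-context keyword
  (primer/forward/reverse/amplif\*/16S/18S/ITS/V-region/515F-style label)
  occurs within 200 characters. Real primers are ≥15 nt; 12 with the
  context guard balances recall against accidental matches.
* **Sequencing method** — marker-gene vs metagenome lexicons mirroring the
  "marker gene or metagenomics" dichotomy; `ITS` and `WGS` are matched
  case-sensitively because their lower-case forms are English words.
* **Code links** — URLs on known code hosts (github, gitlab, bitbucket,
  zenodo, osf, codeocean), or any URL/DOI within 200 characters of code
  wording.
* **DAS class** — phrase tables per class, precedence `public_deposit >
  restricted_with_procedure > upon_request > in_paper_only > absent`; an
  accession inside a dedicated DAS also counts as a deposit trigger. A
  present but unclassifiable statement falls back to `absent` (the enum
  carries no "unknown" value).

Which accession record types count as "accession provided" is deliberately
permissive: any catalogued type qualifies and the type is recorded, since
the standard itself does not restrict the type.

## Metadata tiers and analytics

Sample records are attribute→value maps. Harmonization renames submitter
variants onto canonical names, matching case- and separator-insensitively;
only the "Sample Name" / "User_sample_ID" pair is documented from real
INSDC submissions, the rest of the packaged map is implementation-supplied
and non-normative. Collisions keep the first non-missing value and are
logged.

The default checklist is the human-gut flavour: 9 Bronze fields (MIxS core
mandatory), +8 Silver (method, controls, target gene, primers, host
fields through host sex), +5 Gold. A field counts as satisfied when the
fraction of samples with a non-missing value reaches the completeness
threshold — **1.0 by default** (strict, transparent) and configurable,
since the standard states presence, not a tolerance. Missing values are
the INSDC vocabulary ("na", "not collected", "not provided", …). The tier
is awarded per study; value-format validation (ISO dates, decimal
degrees) is out of scope for the tier and would be warning-only.

Cross-study analytics: an attribute is *populated* for a study iff ≥1
sample has a non-missing value; the population matrix covers the attribute
union; the sparsity histogram uses right-closed bins (first bin includes
0) so counts conserve the attribute total; the median population uses the
even-count mean rule.

## Synthetic fixtures

The article generator emits templated JATS XML whose evidence exactly
realizes a target badge, plus manifest entries that make offline accession
resolution consistent with the text; the ground-truth badge is computed by
running the rule engine on the profile's implied evidence (not by running
the extractor, which keeps round-trip tests non-circular). The default
200-article corpus uses the badge mix observed in large open-field surveys
of gut-microbiome literature (45% None / 20% Bronze / 27% Silver / 8%
Gold), registry weights dominated by SRA then ENA, and upon-request
statements for most None articles. Noise options are restricted to
transformations the extractor contracts to tolerate — word-case jitter,
spacing jitter around punctuation, section reordering — applied so that
digit-bearing tokens (accessions, labels) and URLs are never altered.

The metadata generator plants per-attribute population rates and returns
the *realized* outcomes, so recovery comparisons are exact rather than
statistical. Defaults emulate a 42-study survey with a 220-attribute
union: 16 attributes fully populated, 167 rare attributes at rate 1/42
(median attribute ≈ 2.4% population), the remainder uniform on
[0.15, 0.85]; synonym noise renames 25% of renameable attributes to styled
submitter variants, and 10% of values in populated attributes are missing
tokens (at least one real value is always kept). Every attribute is
guaranteed to appear in at least one study so the observed union equals
the vocabulary.

What passing these fixtures does **not** show: real articles interleave
evidence with heterogeneous prose, split tokens across markup or lines,
and cite accessions of other studies; the corpus does not emulate those,
so round-trip accuracy here is an upper bound on real-world recall, not an
estimate of it.

## Numerical and design choices

* Text offsets are 0-based half-open; extraction is deterministic by
  construction (no randomness, stable ordering).
* Evaluation metrics use plain counting; F1 = 0 when precision + recall
  = 0; macro-F1 averages over classes present in the truth labels
  (predicted-only classes enter only if explicitly declared); weighted F1
  weights by truth support, the standard convention. The implementation is
  cross-checked in tests against both a literal TP/FP/FN counter
  (exhaustively over all multisets of (truth, prediction) pairs with
  n ≤ 6 — sufficient because reports are permutation invariant) and
  scikit-learn on random label sets.
* Offline mode is hermetic (asserted with a suite-wide socket guard); the
  live client exists for interactive surveys, is rate-limited with a
  contact header, and is never exercised by the tests.
* Problem sizes in tests and the acceptance script (200-article corpus,
  600 noisy articles, 1000 random label sets, 42×220 metadata corpus)
  match the study conditions the fixtures emulate while keeping a full run
  in the tens of seconds.

## Known limitations

* No PDF/OCR or supplementary-file parsing; JATS XML and plain text only.
* Accession ranges report endpoints only; run counts rely on repository
  resolution.
* The live client covers NCBI efetch and the ENA portal; other registries
  resolve only through fixtures.
* No ontology resolution (ENVO/UBERON) and no numeric FAIRness score
  beyond the ordinal badge; metadata tiers are not part of the default
  article assessment command and are exposed separately.
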