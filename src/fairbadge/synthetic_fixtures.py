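"""Seeded synthetic corpora with known ground truth.

Generates (i) templated full-text articles whose embedded evidence —
accession tokens, primer strings, method wording, DAS sentence, code link —
realizes a chosen target badge exactly, together with the fixture manifest
entries that make offline accession resolution consistent with the article;
and (ii) multi-study sample-metadata tables with planted per-attribute
population rates, submitter-style synonym noise and missing-value tokens.

Every generator is driven by an explicit integer seed and is byte-stable:
the same profile always produces the identical article or study set. Noise
options are limited to transformations the extraction module contracts to
tolerate (case folding, punctuation spacing, section reordering); the
default corpus is noise-free.

The default 200-article corpus mirrors the badge mix observed in large
open-field surveys of gut-microbiome literature (45% None, 20% Bronze,
27% Silver, 8% Gold) with registries weighted by their reported usage
shares (SRA dominant, then ENA).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from lxml import etree
from lxml.builder import E

from .badge_engine import Badge, EvidenceBundle, assign_sequence_badge
from .config import metadata_checklist
from .extraction import ArticleDocument, DasClass, open_registries
from .metadata_engine import (PopulationMatrix, SampleRecord, StudyMetadata,
                              default_synonym_map, is_missing)
from .repo_clients import FixtureManifest


class InconsistentProfileError(ValueError):
    """The profile's settings cannot realize its target badge."""


# ---------------------------------------------------------------------------
# article profiles
# ---------------------------------------------------------------------------

_PROJECT_TOKENS = {
    "SRA": ("PRJNA", 6), "ENA": ("PRJEB", 6), "DDBJ": ("PRJDB", 6),
    "CNCB-NGDC": ("PRJCA", 6),
}
_RUN_TOKENS = {
    "SRA": ("SRR", 7), "ENA": ("ERR", 7), "DDBJ": ("DRR", 7),
    "CNCB-NGDC": ("CRR", 7),
}
_DB_DISPLAY = {
    "SRA": "NCBI Sequence Read Archive (SRA)",
    "ENA": "European Nucleotide Archive (ENA)",
    "DDBJ": "DNA Data Bank of Japan (DDBJ)",
    "CNCB-NGDC": "Genome Sequence Archive of the CNCB-NGDC",
    "MG-RAST": "MG-RAST server",
    "Figshare": "figshare repository",
    "Zenodo": "zenodo archive",
}

_BADGED = (Badge.BRONZE, Badge.SILVER, Badge.GOLD)

_PRIMER_PAIRS = [
    ("515F", "GTGYCAGCMGCCGCGGTAA", "806R", "GGACTACNVGGGTWTCTAAT"),
    ("341F", "CCTACGGGNGGCWGCAG", "805R", "GACTACHVGGGTATCTAATCC"),
]

# filler prose; deliberately free of method-lexicon terms, accession-like
# tokens, DAS trigger phrases and long IUPAC-alphabet words
_INTRO_POOL = [
    "The gut microbial community of healthy adult volunteers was profiled "
    "across a six month longitudinal cohort.",
    "Stool specimens were obtained at two clinic visits and stored frozen "
    "until nucleic acid processing.",
    "Dietary intake was recorded with a validated questionnaire at enrolment.",
    "Participants gave written informed consent under the institutional "
    "review protocol.",
]
_RESULTS_POOL = [
    "Community composition differed significantly between the intervention "
    "and control groups.",
    "Taxon abundances were broadly consistent across both clinic visits.",
    "Several low abundance genera tracked the dietary intervention.",
    "Inter-individual variation exceeded the longitudinal signal in most "
    "participants.",
]
_PLAIN_METHODS = (
    "Genomic DNA was extracted from stool aliquots with a bead beating "
    "protocol and libraries were prepared for paired end runs on an "
    "Illumina instrument.")

_DAS_TEMPLATES = {
    DasClass.UPON_REQUEST:
        "The datasets generated during the current study are available from "
        "the corresponding author upon reasonable request.",
    DasClass.IN_PAPER_ONLY:
        "All data generated or analysed during this study are included "
        "within the article and its supplementary information files.",
    DasClass.RESTRICTED_WITH_PROCEDURE:
        "Sequence data are accessible through a managed access procedure; "
        "requests are reviewed by the institutional data access committee.",
}


@dataclass
class ArticleProfile:
    """Self-consistent recipe for one synthetic article."""

    article_id: str
    target_badge: Badge
    is_amplicon: bool = True
    registry: str = "SRA"
    n_runs: int = 2
    das_style: DasClass | None = None  # default derived from target_badge
    case_jitter: bool = False
    punct_jitter: bool = False
    section_shuffle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.target_badge = Badge(self.target_badge)
        if self.das_style is None:
            self.das_style = (DasClass.PUBLIC_DEPOSIT
                              if self.target_badge in _BADGED
                              else DasClass.UPON_REQUEST)
        self.das_style = DasClass(self.das_style)
        self.validate()

    def validate(self) -> None:
        t = self.target_badge
        if t in _BADGED:
            if self.das_style is not DasClass.PUBLIC_DEPOSIT:
                raise InconsistentProfileError(
                    f"{t.value} badge requires a public-deposit DAS")
            if self.n_runs < 1:
                raise InconsistentProfileError("badged article needs >= 1 run")
            if self.registry not in _PROJECT_TOKENS and \
                    self.registry not in ("MG-RAST", "Figshare", "Zenodo"):
                raise InconsistentProfileError(
                    f"no token template for registry {self.registry}")
            if t is Badge.GOLD and self.registry not in open_registries():
                raise InconsistentProfileError(
                    f"gold badge impossible with closed registry {self.registry}")
        elif t is Badge.NONE:
            if self.das_style is DasClass.PUBLIC_DEPOSIT:
                raise InconsistentProfileError(
                    "a public-deposit DAS with resolvable data contradicts "
                    "target badge none")


def _accession_tokens(profile: ArticleProfile, rng: random.Random
                      ) -> tuple[str, list[str]]:
    """Project accession plus shown run accessions for the profile."""
    reg = profile.registry
    if reg == "MG-RAST":
        base = rng.randrange(10**6, 10**7)
        return f"mgm{base}.3", [f"mgm{base + i + 1}.3"
                                for i in range(min(profile.n_runs, 3))]
    if reg == "Figshare":
        return f"10.6084/m9.figshare.{rng.randrange(10**6, 10**7)}", []
    if reg == "Zenodo":
        return f"10.5281/zenodo.{rng.randrange(10**6, 10**7)}", []
    pp, pd_ = _PROJECT_TOKENS[reg]
    rp, rd = _RUN_TOKENS[reg]
    project = pp + str(rng.randrange(10**(pd_ - 1), 10**pd_))
    base = rng.randrange(10**(rd - 1), 10**rd - profile.n_runs)
    runs = [rp + str(base + i) for i in range(profile.n_runs)]
    return project, runs


def _run_clause(runs: list[str]) -> str:
    if not runs:
        return ""
    if len(runs) == 1:
        return f" (run {runs[0]})"
    if len(runs) >= 4:
        return f" (runs {runs[0]} to {runs[-1]})"
    return f" (runs {', '.join(runs)})"


def _expected_bundle(profile: ArticleProfile) -> EvidenceBundle:
    badged = profile.target_badge in _BADGED
    rich = profile.target_badge in (Badge.SILVER, Badge.GOLD)
    return EvidenceBundle(
        determinable=True,
        has_accession=badged,
        data_public_downloadable=badged,
        raw_format_ok=badged,
        sequencing_method_known=rich,
        is_amplicon=rich and profile.is_amplicon,
        primers_found=rich and profile.is_amplicon,
        das_clarifies_access=(
            profile.das_style is DasClass.RESTRICTED_WITH_PROCEDURE),
        repository_open_access=(
            profile.registry in open_registries() if badged else True),
        code_available=profile.target_badge is Badge.GOLD,
    )


# --- tolerated-noise transforms -------------------------------------------

def _case_jitter(text: str, rng: random.Random) -> str:
    words = text.split(" ")
    out = []
    for w in words:
        if w.isalpha() and len(w) > 2 and rng.random() < 0.2:
            w = w.upper() if rng.random() < 0.5 else w.lower()
        out.append(w)
    return " ".join(out)


def _punct_jitter(text: str, rng: random.Random) -> str:
    for src, dst in ((", ", " , "), (". ", " . "), (" (", " ( "), (") ", " ) ")):
        parts = text.split(src)
        text = parts[0]
        for part in parts[1:]:
            text += (dst if rng.random() < 0.5 else src) + part
    return text


def generate_article(profile: ArticleProfile
                     ) -> tuple[ArticleDocument, dict[str, dict], Badge]:
    """Emit one article plus the manifest resolutions that make its
    accessions resolve consistently.

    Returns ``(document, resolution_fragment, true_badge)`` where
    ``true_badge`` is computed by running the badge engine on the evidence
    implied by the profile (and checked against ``target_badge``).
    """
    rng = random.Random(profile.seed)
    target = profile.target_badge

    if target is Badge.CANNOT_BE_DETERMINED:
        doc = ArticleDocument(profile.article_id, title="Unretrievable article")
        return doc, {}, target

    true_badge = assign_sequence_badge(_expected_bundle(profile)).badge
    if true_badge is not target:
        raise InconsistentProfileError(
            f"profile realizes {true_badge.value}, not {target.value}")

    badged = target in _BADGED
    rich = target in (Badge.SILVER, Badge.GOLD)

    resolutions: dict[str, dict] = {}
    das_parts: list[str] = []
    if badged:
        project, runs = _accession_tokens(profile, rng)
        entry = {"registry": profile.registry, "public": True,
                 "n_runs": profile.n_runs, "file_formats": ["FASTQ"]}
        resolutions[project] = entry
        for r in runs:
            resolutions[r] = {"registry": profile.registry, "public": True,
                              "n_runs": 1, "file_formats": ["FASTQ"]}
        das_parts.append(
            f"Raw reads were deposited in the "
            f"{_DB_DISPLAY[profile.registry]} under {project}"
            f"{_run_clause(runs)}.")
    elif profile.das_style in _DAS_TEMPLATES:
        das_parts.append(_DAS_TEMPLATES[profile.das_style])

    if target is Badge.GOLD:
        slug = f"lab{rng.randrange(100, 999)}"
        das_parts.append(
            f"Analysis code and workflow scripts are provided at "
            f"https://github.com/{slug}/stool-profiling.")

    if rich:
        if profile.is_amplicon:
            fl, fseq, rl, rseq = _PRIMER_PAIRS[rng.randrange(len(_PRIMER_PAIRS))]
            if profile.case_jitter and rng.random() < 0.5:
                fseq, rseq = fseq.lower(), rseq.lower()
            methods = (
                f"The V4 region of the 16S rRNA gene was amplified with "
                f"primers {fl} ({fseq}) and {rl} ({rseq}), and amplicon "
                f"libraries were sequenced on an Illumina instrument.")
        else:
            methods = (
                "Shotgun metagenomic sequencing libraries were prepared from "
                "extracted DNA and sequenced to an average depth of "
                f"{rng.randrange(5, 40)} million read pairs.")
    else:
        methods = _PLAIN_METHODS

    das_text = " ".join(das_parts) if das_parts else None
    sections = [
        ("Introduction", " ".join(rng.sample(_INTRO_POOL, 2))),
        ("Methods", methods),
        ("Results", " ".join(rng.sample(_RESULTS_POOL, 2))),
    ]
    if das_text:
        sections.append(("Data Availability", das_text))

    if profile.case_jitter or profile.punct_jitter:
        noisy = []
        for label, body in sections:
            if profile.punct_jitter:
                body = _punct_jitter(body, rng)
            if profile.case_jitter:
                body = _case_jitter(body, rng)
            noisy.append((label, body))
        sections = noisy
        if das_text:
            das_text = sections[-1][1]
    if profile.section_shuffle:
        rng.shuffle(sections)

    doc = ArticleDocument(
        article_id=profile.article_id,
        title=f"Gut microbial community dynamics in cohort {profile.seed % 997}",
        publication_year=rng.randrange(2013, 2025),
        journal="Journal of Synthetic Microbiome Fixtures",
        sections=sections,
        das_text=das_text,
    )
    return doc, resolutions, true_badge


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

#: badge mix of the default corpus (open-field survey proportions)
DEFAULT_BADGE_MIX = {Badge.NONE: 0.45, Badge.BRONZE: 0.20,
                     Badge.SILVER: 0.27, Badge.GOLD: 0.08}
#: registry usage weights among badged articles
DEFAULT_REGISTRY_WEIGHTS = [
    ("SRA", 0.62), ("ENA", 0.18), ("DDBJ", 0.05), ("CNCB-NGDC", 0.05),
    ("MG-RAST", 0.04), ("Figshare", 0.03), ("Zenodo", 0.03),
]
_NONE_DAS_STYLES = [
    (DasClass.UPON_REQUEST, 0.6), (DasClass.ABSENT, 0.2),
    (DasClass.IN_PAPER_ONLY, 0.1), (DasClass.RESTRICTED_WITH_PROCEDURE, 0.1),
]


def default_corpus_profiles(seed: int = 0, n: int = 200,
                            case_jitter: bool = False,
                            punct_jitter: bool = False,
                            section_shuffle: bool = False
                            ) -> list[ArticleProfile]:
    """The packaged seeded corpus: ``n`` article profiles with the default
    badge mix and registry weights. Deterministic in ``seed``."""
    rng = random.Random(seed)
    badges: list[Badge] = []
    for badge, frac in DEFAULT_BADGE_MIX.items():
        badges.extend([badge] * round(n * frac))
    while len(badges) < n:
        badges.append(Badge.NONE)
    badges = badges[:n]
    rng.shuffle(badges)

    registries, reg_weights = zip(*DEFAULT_REGISTRY_WEIGHTS)
    das_styles, das_weights = zip(*_NONE_DAS_STYLES)

    profiles = []
    for i, badge in enumerate(badges):
        badged = badge in _BADGED
        registry = rng.choices(registries, reg_weights)[0] if badged else "SRA"
        if badge is Badge.GOLD and registry not in open_registries():
            registry = "SRA"
        profiles.append(ArticleProfile(
            article_id=f"PMC{9_000_000 + i}",
            target_badge=badge,
            is_amplicon=rng.random() < 0.7,
            registry=registry,
            n_runs=rng.randint(1, 6) if badged else 0,
            das_style=(DasClass.PUBLIC_DEPOSIT if badged
                       else rng.choices(das_styles, das_weights)[0]),
            case_jitter=case_jitter,
            punct_jitter=punct_jitter,
            section_shuffle=section_shuffle,
            seed=rng.randrange(2**31),
        ))
    return profiles


def jats_bytes(doc: ArticleDocument) -> bytes:
    """Serialize an ArticleDocument as minimal JATS (PMC dialect) XML."""
    secs = []
    for label, body in doc.sections:
        attrs = {}
        if label.lower().startswith("data availability"):
            attrs["sec-type"] = "data-availability"
        secs.append(E.sec(attrs, E.title(label), E.p(body)))
    article = E.article(
        E.front(
            E("journal-meta", E("journal-title", doc.journal or "")),
            E("article-meta",
              E("title-group", E("article-title", doc.title)),
              E("pub-date", E.year(str(doc.publication_year or ""))))),
        E.body(*secs),
    )
    return etree.tostring(article, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def write_corpus(out_dir: str | Path, profiles: list[ArticleProfile],
                 metadata_profile: "MetadataProfile | None" = None
                 ) -> dict[str, Badge]:
    """Write a fixture corpus (JATS articles + manifest + truth table, and
    optionally metadata CSVs) consumable by the offline client.

    Articles targeting ``cannot_be_determined`` are left out of the
    manifest, so offline retrieval reports them not found. Returns the
    ground-truth badge per article id (also written to ``truth.csv``).
    """
    root = Path(out_dir)
    (root / "articles").mkdir(parents=True, exist_ok=True)
    manifest = FixtureManifest(root=root)
    truth: dict[str, Badge] = {}
    for profile in profiles:
        doc, resolutions, badge = generate_article(profile)
        truth[profile.article_id] = badge
        if badge is Badge.CANNOT_BE_DETERMINED:
            continue
        rel = f"articles/{profile.article_id}.xml"
        (root / rel).write_bytes(jats_bytes(doc))
        manifest.articles[profile.article_id] = rel
        manifest.resolutions.update(resolutions)

    if metadata_profile is not None:
        studies, _ = generate_metadata_studies(metadata_profile)
        write_metadata_csvs(root, studies, manifest)

    manifest.save()
    pd.DataFrame(
        [{"article_id": aid, "badge": b.value} for aid, b in truth.items()]
    ).to_csv(root / "truth.csv", index=False)
    return truth


# ---------------------------------------------------------------------------
# metadata studies
# ---------------------------------------------------------------------------

@dataclass
class MetadataProfile:
    """Recipe for a multi-study sample-metadata corpus.

    Defaults emulate the survey conditions of a cross-study metadata audit:
    42 studies whose attribute union totals 220 names, 16 attributes
    populated by every study, 167 rare attributes populated at a planted
    rate of 1/42 (so the median attribute draws on a single study), and the
    remainder at intermediate rates.
    """

    n_studies: int = 42
    attribute_vocabulary: list[str] | None = None
    planted_population_rate: dict[str, float] | None = None
    synonym_noise_rate: float = 0.25
    missing_token_rate: float = 0.1
    samples_per_study: tuple[int, int] = (3, 8)
    n_attributes: int = 220
    n_full: int = 16
    n_rare: int = 167
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.synonym_noise_rate, self.missing_token_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.planted_population_rate is not None:
            bad = [a for a, r in self.planted_population_rate.items()
                   if not 0 <= r <= 1]
            if bad:
                raise ValueError(f"population rates outside [0, 1]: {bad}")


def _default_vocabulary(n_attributes: int) -> list[str]:
    tiers = metadata_checklist()["tiers"]
    named = (list(tiers["bronze"]) + ["organism"] + list(tiers["silver_additional"])
             + list(tiers["gold_additional"]))
    fillers = [f"study specific attribute {i:03d}"
               for i in range(n_attributes - len(named))]
    return (named + fillers)[:n_attributes]


_MISSING_CHOICES = ["not collected", "missing", "NA", "not provided", ""]


def _plausible_value(attr: str, rng: random.Random) -> str:
    if attr == "collection date":
        return f"{rng.randrange(2015, 2024)}-{rng.randrange(1, 13):02d}-" \
               f"{rng.randrange(1, 29):02d}"
    if attr == "lat lon":
        return f"{rng.uniform(-60, 60):.4f} N {rng.uniform(-150, 150):.4f} E"
    if attr == "taxonomy id":
        return "408170"
    if attr == "host sex":
        return rng.choice(["male", "female"])
    return f"{attr} value {rng.randrange(1, 100)}"


def _styled_variant(name: str, rng: random.Random) -> str:
    sep = rng.choice(["_", " ", "-"])
    words = name.split(" ")
    style = rng.randrange(3)
    if style == 0:
        words = [w.capitalize() for w in words]
    elif style == 1:
        words = [w.upper() for w in words]
    return sep.join(words)


def generate_metadata_studies(profile: MetadataProfile
                              ) -> tuple[list[StudyMetadata], PopulationMatrix]:
    """Generate studies plus the *realized* planted population matrix.

    Each attribute is populated in each study with its planted probability;
    the matrix records the realized outcomes, so recovery comparisons are
    exact. Populated attributes always carry at least one non-missing value
    per study; unpopulated attributes are either absent or present with only
    missing tokens. Synonym noise renames canonical attributes to styled
    submitter variants that the default synonym map can invert. Every
    attribute appears in at least one study, so the observed attribute union
    equals the vocabulary.
    """
    rng = random.Random(profile.seed)
    vocab = (profile.attribute_vocabulary
             if profile.attribute_vocabulary is not None
             else _default_vocabulary(profile.n_attributes))

    if profile.planted_population_rate is not None:
        rates = {a: profile.planted_population_rate.get(a, 0.5) for a in vocab}
    else:
        rates = {}
        for i, attr in enumerate(vocab):
            if i < profile.n_full:
                rates[attr] = 1.0
            elif i >= len(vocab) - profile.n_rare:
                rates[attr] = 1.0 / profile.n_studies
            else:
                rates[attr] = rng.uniform(0.15, 0.85)

    inverse_synonyms: dict[str, list[str]] = {}
    for raw, canon in default_synonym_map().items():
        if raw != canon:
            inverse_synonyms.setdefault(canon, []).append(raw)

    studies: list[StudyMetadata] = []
    planted: dict[str, dict[str, bool]] = {a: {} for a in vocab}
    appearances: dict[str, int] = {a: 0 for a in vocab}

    for s in range(profile.n_studies):
        study_id = f"STUDY{s:03d}"
        n_samples = rng.randint(*profile.samples_per_study)
        samples = [SampleRecord(f"{study_id}.S{j}", {}) for j in range(n_samples)]
        for attr in vocab:
            populated = rng.random() < rates[attr]
            planted[attr][study_id] = populated
            present = populated or rng.random() < 0.5
            if not present:
                continue
            appearances[attr] += 1
            name = attr
            if attr in inverse_synonyms and rng.random() < profile.synonym_noise_rate:
                name = _styled_variant(rng.choice(inverse_synonyms[attr]), rng)
            if populated:
                values = [
                    rng.choice(_MISSING_CHOICES)
                    if rng.random() < profile.missing_token_rate
                    else _plausible_value(attr, rng)
                    for _ in samples
                ]
                if all(is_missing(v) for v in values):
                    values[0] = _plausible_value(attr, rng)
            else:
                values = [rng.choice(_MISSING_CHOICES) for _ in samples]
            for rec, value in zip(samples, values):
                rec.attributes[name] = value
        checklist_name = ("MIMS.me.human-gut.6.0" if rng.random() < 0.5 else None)
        studies.append(StudyMetadata(study_id, accession=f"PRJNA{800000 + s}",
                                     checklist_name=checklist_name,
                                     records=samples))

    # guarantee every attribute appears somewhere (all-missing if needed)
    for attr, count in appearances.items():
        if count == 0:
            study = studies[rng.randrange(len(studies))]
            for rec in study.records:
                rec.attributes[attr] = rng.choice(_MISSING_CHOICES)

    attrs = sorted(vocab)
    matrix = pd.DataFrame(
        {st.study_id: [planted[a][st.study_id] for a in attrs] for st in studies},
        index=attrs, dtype=bool)
    return studies, PopulationMatrix(matrix)


def write_metadata_csvs(out_dir: str | Path, studies: list[StudyMetadata],
                        manifest: FixtureManifest | None = None) -> None:
    """Write one wide CSV per study and register it in the manifest."""
    root = Path(out_dir)
    (root / "metadata").mkdir(parents=True, exist_ok=True)
    for study in studies:
        columns = list(dict.fromkeys(
            name for rec in study.records for name in rec.attributes))
        df = pd.DataFrame([
            {"sample_id": rec.sample_id,
             **{c: rec.attributes.get(c, "") for c in columns}}
            for rec in study.records
        ])
        rel = f"metadata/{study.study_id}.csv"
        df.to_csv(root / rel, index=False)
        if manifest is not None:
            key = study.accession or study.study_id
            manifest.metadata[key] = {
                "path": rel, "study_id": study.study_id,
                "checklist_name": study.checklist_name}
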