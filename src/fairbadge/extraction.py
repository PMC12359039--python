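"""Evidence extraction from microbiome article full text.

Turns the plain text of a publication into the machine-readable evidence
that the sequence-data badge rules consume:

* accession numbers, tagged with their registry (SRA, ENA, DDBJ, partner
  archives) and record type (BioProject, study, sample, experiment, run, ...);
* PCR primer sequences over the IUPAC nucleotide alphabet, with their
  conventional labels (515F, 806R, ...) when stated;
* the sequencing method (marker-gene amplicon vs shotgun metagenome);
* code-availability links (GitHub, Zenodo, ... or DOI/URL near code wording);
* the class of the data-availability statement (DAS).

All pattern catalogues live in a packaged YAML file
(``fairbadge/data/sequence_catalogue.yaml``) and can be extended without
touching code. Extraction is deterministic: identical text always yields an
identical :class:`ExtractionResult`. Text offsets are 0-based, half-open.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence
from urllib.parse import urlparse

from .config import sequence_catalogue


class RetrievalStatus(str, enum.Enum):
    OK = "ok"
    NOT_FOUND = "not_found"
    NO_FULLTEXT = "no_fulltext"
    PARSE_ERROR = "parse_error"


class SequencingMethod(str, enum.Enum):
    MARKER_GENE = "marker_gene"
    METAGENOME = "metagenome"
    BOTH = "both"
    UNKNOWN = "unknown"


class DasClass(str, enum.Enum):
    PUBLIC_DEPOSIT = "public_deposit"
    RESTRICTED_WITH_PROCEDURE = "restricted_with_procedure"
    UPON_REQUEST = "upon_request"
    IN_PAPER_ONLY = "in_paper_only"
    ABSENT = "absent"


#: classification precedence for :func:`classify_das`
DAS_PRECEDENCE = (
    DasClass.PUBLIC_DEPOSIT,
    DasClass.RESTRICTED_WITH_PROCEDURE,
    DasClass.UPON_REQUEST,
    DasClass.IN_PAPER_ONLY,
)


class NotDeterminableError(RuntimeError):
    """Raised when an article's full text could not be retrieved or parsed."""


@dataclass
class ArticleDocument:
    """A retrieved full-text article decomposed into labeled sections."""

    article_id: str
    title: str = ""
    publication_year: int | None = None
    journal: str | None = None
    publisher: str | None = None
    sections: list[tuple[str, str]] = field(default_factory=list)
    das_text: str | None = None
    retrieval_status: RetrievalStatus = RetrievalStatus.OK

    @property
    def full_text(self) -> str:
        """Concatenated section bodies, with the DAS appended if it is not
        already part of a section."""
        text = "\n\n".join(body for _, body in self.sections)
        if self.das_text and self.das_text not in text:
            text = f"{text}\n\n{self.das_text}" if text else self.das_text
        return text


@dataclass(frozen=True)
class AccessionHit:
    token: str
    registry: str
    record_type: str
    span: tuple[int, int]
    is_range_endpoint: bool = False


@dataclass(frozen=True)
class PrimerHit:
    sequence: str  # upper-case IUPAC nucleotide string
    label: str | None
    span: tuple[int, int]


@dataclass
class ExtractionResult:
    """All machine-detected evidence for one article."""

    article_id: str
    accessions: list[AccessionHit] = field(default_factory=list)
    primers: list[PrimerHit] = field(default_factory=list)
    code_links: list[str] = field(default_factory=list)
    sequencing_method: SequencingMethod = SequencingMethod.UNKNOWN
    das_class: DasClass = DasClass.ABSENT
    databases_mentioned: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# compiled catalogue
# ---------------------------------------------------------------------------

_BOUND_L = r"(?<![A-Za-z0-9])"
_BOUND_R = r"(?![A-Za-z0-9])"
_IUPAC = "ACGTURYSWKMBDHVN"
_RANGE_GAP = re.compile(r"\s*(?:-|–|—|−|to|through)\s*", re.IGNORECASE)


def _bounded(pattern: str, flags: int = 0) -> re.Pattern:
    return re.compile(_BOUND_L + "(?:" + pattern + ")" + _BOUND_R, flags)


@lru_cache(maxsize=1)
def _compiled():
    cat = sequence_catalogue()
    accession_patterns = [
        (_bounded(e["pattern"]), e["registry"], e["record_type"])
        for e in cat["accessions"]
    ]
    db_names = [
        (_bounded(e["pattern"], 0 if e.get("case_sensitive") else re.IGNORECASE),
         e["registry"])
        for e in cat["database_names"]
    ]
    pc = cat["primers"]
    primer_candidate = _bounded(rf"[{_IUPAC}]{{{pc['min_length']},}}", re.IGNORECASE)
    primer_keywords = [
        _bounded("|".join(pc["keywords"]), re.IGNORECASE),
        _bounded("|".join(pc["keywords_case_sensitive"])),
    ]
    method = {
        name: [
            _bounded(e["pattern"], 0 if e.get("case_sensitive") else re.IGNORECASE)
            for e in entries
        ]
        for name, entries in cat["sequencing_method"].items()
    }
    cl = cat["code_links"]
    code_keywords = _bounded("|".join(cl["keywords"]), re.IGNORECASE)
    das_phrases = {
        DasClass(name): [p.lower() for p in phrases]
        for name, phrases in cat["das_phrases"].items()
    }
    return {
        "accessions": accession_patterns,
        "db_names": db_names,
        "primer_candidate": primer_candidate,
        "primer_keywords": primer_keywords,
        "primer_window": pc["context_window"],
        "method": method,
        "code_hosts": set(cl["hosts"]),
        "code_keywords": code_keywords,
        "code_window": cl["context_window"],
        "das_phrases": das_phrases,
        "open_registries": set(cat["open_registries"]),
    }


def open_registries() -> set[str]:
    """Registries retrievable without login or institutional affiliation."""
    return set(_compiled()["open_registries"])


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_accessions(text: str) -> list[AccessionHit]:
    """Find all catalogued accession tokens in ``text``.

    Matches are non-overlapping (longest-first at each position),
    deduplicated on token, and returned in order of first occurrence.
    Consecutive same-type accessions joined by a dash or "to" are flagged as
    range endpoints; the range is not expanded.
    """
    if not text:
        return []
    raw: list[tuple[int, int, str, str, str]] = []
    for pattern, registry, record_type in _compiled()["accessions"]:
        for m in pattern.finditer(text):
            raw.append((m.start(), m.end(), m.group(0), registry, record_type))
    raw.sort(key=lambda t: (t[0], -(t[1] - t[0])))

    kept: list[tuple[int, int, str, str, str]] = []
    last_end = -1
    for start, end, token, registry, record_type in raw:
        if start < last_end:
            continue
        kept.append((start, end, token, registry, record_type))
        last_end = end

    # flag A–B style ranges between adjacent same-type hits
    range_idx: set[int] = set()
    for i in range(len(kept) - 1):
        s1, e1, _, reg1, rt1 = kept[i]
        s2, e2, _, reg2, rt2 = kept[i + 1]
        if (reg1, rt1) == (reg2, rt2) and _RANGE_GAP.fullmatch(text[e1:s2]):
            range_idx.update((i, i + 1))

    hits: list[AccessionHit] = []
    seen: set[str] = set()
    for i, (start, end, token, registry, record_type) in enumerate(kept):
        if token in seen:
            continue
        seen.add(token)
        hits.append(AccessionHit(token, registry, record_type, (start, end),
                                 is_range_endpoint=i in range_idx))
    return hits


def _keyword_spans(text: str, patterns: Iterable[re.Pattern]) -> list[tuple[int, int]]:
    spans = []
    for pat in patterns:
        spans.extend(m.span() for m in pat.finditer(text))
    return spans


def _near(span: tuple[int, int], spans: Sequence[tuple[int, int]], window: int) -> bool:
    s, e = span
    return any(ks - window <= e and ke + window >= s for ks, ke in spans)


_LABEL_RE = re.compile(r"(\d{1,4}[FfRr])\s*[\(\[:]?\s*$")


def detect_primers(text: str) -> list[PrimerHit]:
    """Find primer sequences: IUPAC-alphabet runs near primer context words.

    Detection is case-insensitive in the sequence string (returned
    upper-cased); a candidate is only accepted when a primer-context keyword
    occurs within the configured character window, which rejects e.g.
    homopolymer accession-like strings cited without primer wording.
    """
    if not text:
        return []
    comp = _compiled()
    keyword_spans = _keyword_spans(text, comp["primer_keywords"])
    if not keyword_spans:
        return []
    hits = []
    for m in comp["primer_candidate"].finditer(text):
        if not _near(m.span(), keyword_spans, comp["primer_window"]):
            continue
        label_m = _LABEL_RE.search(text[max(0, m.start() - 15):m.start()])
        hits.append(PrimerHit(m.group(0).upper(),
                              label_m.group(1).upper() if label_m else None,
                              m.span()))
    return hits


def classify_sequencing_method(text: str) -> SequencingMethod:
    """Classify the study as marker-gene (amplicon), metagenome, both, or
    unknown from lexicon matches in the text."""
    if not text:
        return SequencingMethod.UNKNOWN
    lex = _compiled()["method"]
    marker = any(p.search(text) for p in lex["marker_gene"])
    shotgun = any(p.search(text) for p in lex["metagenome"])
    if marker and shotgun:
        return SequencingMethod.BOTH
    if marker:
        return SequencingMethod.MARKER_GENE
    if shotgun:
        return SequencingMethod.METAGENOME
    return SequencingMethod.UNKNOWN


_URL_RE = re.compile(r"https?://[^\s<>()\[\]\"']+")
_DOI_RE = re.compile(r"\b10\.\d{4,9}/[^\s<>()\[\]\"']+")
_TRAILING_PUNCT = ".,;:]}>\"'"


def detect_code_links(text: str) -> list[str]:
    """Find code-availability links.

    A URL counts when its host is in the code-hosting catalogue, or when any
    URL/DOI co-occurs with code wording (code, scripts, software, ...) within
    the configured window. Deduplicated, order of first occurrence.
    """
    if not text:
        return []
    comp = _compiled()
    keyword_spans = [m.span() for m in comp["code_keywords"].finditer(text)]
    links: list[str] = []
    seen: set[str] = set()

    candidates: list[tuple[int, str, bool]] = []
    for m in _URL_RE.finditer(text):
        url = m.group(0).rstrip(_TRAILING_PUNCT)
        host = (urlparse(url).hostname or "").removeprefix("www.")
        in_catalogue = any(host == h or host.endswith("." + h)
                           for h in comp["code_hosts"])
        candidates.append((m.start(), url, in_catalogue or
                           _near(m.span(), keyword_spans, comp["code_window"])))
    for m in _DOI_RE.finditer(text):
        doi = m.group(0).rstrip(_TRAILING_PUNCT)
        candidates.append((m.start(), doi,
                           _near(m.span(), keyword_spans, comp["code_window"])))

    for _, link, ok in sorted(candidates, key=lambda t: t[0]):
        if ok and link not in seen and not any(link in kept for kept in seen):
            seen.add(link)
            links.append(link)
    return links


def classify_das(das_text: str | None, fallback_text: str = "") -> DasClass:
    """Classify the data-availability statement.

    Scans ``das_text`` when present, otherwise ``fallback_text``, for the
    packaged trigger phrases and returns the first matching class in the
    precedence order public_deposit > restricted_with_procedure >
    upon_request > in_paper_only; ``absent`` when nothing matches. When a
    dedicated DAS is present, an accession token inside it also counts as a
    public-deposit trigger.
    """
    target = das_text if das_text else fallback_text
    if not target:
        return DasClass.ABSENT
    lowered = target.lower()
    phrases = _compiled()["das_phrases"]
    for cls in DAS_PRECEDENCE:
        if any(p in lowered for p in phrases[cls]):
            return cls
        if cls is DasClass.PUBLIC_DEPOSIT and das_text and detect_accessions(das_text):
            return DasClass.PUBLIC_DEPOSIT
    return DasClass.ABSENT


def detect_database_mentions(text: str) -> set[str]:
    """Registries explicitly named in the text (SRA, ENA, figshare, ...)."""
    if not text:
        return set()
    return {registry for pattern, registry in _compiled()["db_names"]
            if pattern.search(text)}


def extract_all(document: ArticleDocument) -> ExtractionResult:
    """Run every detector over a retrieved article.

    Raises :class:`NotDeterminableError` when the document's full text was
    not retrieved (``retrieval_status`` != ok).
    """
    if document.retrieval_status is not RetrievalStatus.OK:
        raise NotDeterminableError(
            f"article {document.article_id}: full text not available "
            f"({document.retrieval_status.value})")
    text = document.full_text
    accessions = detect_accessions(text)
    result = ExtractionResult(
        article_id=document.article_id,
        accessions=accessions,
        primers=detect_primers(text),
        code_links=detect_code_links(text),
        sequencing_method=classify_sequencing_method(text),
        das_class=classify_das(document.das_text, text),
        databases_mentioned=(
            detect_database_mentions(text) | {h.registry for h in accessions}),
    )
    return result


def aggregate_database_usage(extractions: Iterable[ExtractionResult]) -> dict[str, float]:
    """Share of articles per sequence database, among articles whose
    accessions point to exactly one registry.

    Articles citing no accession, or accessions in several registries, are
    excluded from the denominator (multi-database articles are a small
    minority and have no single home archive). Returns registry -> percent.
    """
    counts: dict[str, int] = {}
    for ex in extractions:
        registries = {h.registry for h in ex.accessions}
        if len(registries) != 1:
            continue
        reg = registries.pop()
        counts[reg] = counts.get(reg, 0) + 1
    total = sum(counts.values())
    return {reg: 100.0 * n / total for reg, n in sorted(counts.items())} if total else {}
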