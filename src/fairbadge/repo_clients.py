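"""Article and repository access behind narrow, replayable contracts.

Two client implementations share one interface:

* :class:`OfflineClient` serves everything from a fixture directory — JATS
  XML article files, accession resolution records, and sample-metadata CSV
  tables, all indexed by a ``manifest.json``. It never opens a network
  connection, so the whole pipeline is testable hermetically.
* :class:`LiveClient` talks to the public NCBI/EBI endpoints with polite
  rate limiting and a contact identifier. Live responses can be written
  back to the fixture format, so a recorded session replays identically.

Expected misses (unknown article, truncated XML) are reported through
``retrieval_status`` / ``failed`` flags rather than exceptions, so a batch
survey never aborts on a single bad item.
"""

from __future__ import annotations

import io
import json
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from .extraction import ArticleDocument, RetrievalStatus
from .metadata_engine import SampleRecord, StudyMetadata, UnevaluableError


@dataclass
class ResolutionRecord:
    """Outcome of resolving one accession in a repository."""

    accession: str
    registry: str = "other"
    public: bool = False
    n_runs: int = 0
    file_formats: set[str] = field(default_factory=set)
    resolved_at: str = "fixture"
    failed: bool = False


@dataclass
class FixtureManifest:
    """Index of a fixture directory.

    ``manifest.json`` schema::

        {
          "resolutions": {accession: {registry, public, n_runs, file_formats}},
          "articles":    {article_id: relative path to JATS XML},
          "metadata":    {accession: {path, study_id, checklist_name}}
        }
    """

    root: Path
    resolutions: dict[str, dict] = field(default_factory=dict)
    articles: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def load(cls, fixtures_dir: str | Path) -> "FixtureManifest":
        root = Path(fixtures_dir)
        raw = json.loads((root / "manifest.json").read_text(encoding="utf-8"))
        return cls(root=root,
                   resolutions=raw.get("resolutions", {}),
                   articles=raw.get("articles", {}),
                   metadata=raw.get("metadata", {}))

    def save(self) -> None:
        payload = {"resolutions": self.resolutions, "articles": self.articles,
                   "metadata": self.metadata}
        (self.root / "manifest.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# JATS parsing
# ---------------------------------------------------------------------------

_DAS_TITLE_HINTS = ("data availability", "availability of data")


def parse_jats(data: bytes | str, article_id: str) -> ArticleDocument:
    """Parse a JATS (PMC dialect) XML document into an ArticleDocument.

    Section labels come from ``<sec><title>`` elements; the data-availability
    statement is taken from a ``sec-type="data-availability"`` section or a
    section whose title names data availability. Malformed XML yields
    ``retrieval_status = parse_error`` instead of raising.
    """
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        tree = etree.parse(io.BytesIO(data))
    except etree.XMLSyntaxError:
        return ArticleDocument(article_id, retrieval_status=RetrievalStatus.PARSE_ERROR)

    def text_of(node) -> str:
        return " ".join("".join(node.itertext()).split()) if node is not None else ""

    root = tree.getroot()
    title = text_of(root.find(".//article-meta/title-group/article-title"))
    journal = text_of(root.find(".//journal-meta//journal-title")) or None
    publisher = text_of(root.find(".//journal-meta//publisher-name")) or None
    year_node = root.find(".//article-meta/pub-date/year")
    year = int(year_node.text) if year_node is not None and year_node.text and \
        year_node.text.isdigit() else None

    sections: list[tuple[str, str]] = []
    das_text: str | None = None
    for sec in root.iter("sec"):
        label = text_of(sec.find("title"))
        body = " ".join(text_of(p) for p in sec.findall("p"))
        if not body:
            continue
        sections.append((label, body))
        sec_type = (sec.get("sec-type") or "").lower()
        if "data-availability" in sec_type or \
                any(h in label.lower() for h in _DAS_TITLE_HINTS):
            das_text = body

    status = RetrievalStatus.OK if sections else RetrievalStatus.NO_FULLTEXT
    return ArticleDocument(article_id, title=title, publication_year=year,
                           journal=journal, publisher=publisher,
                           sections=sections, das_text=das_text,
                           retrieval_status=status)


# ---------------------------------------------------------------------------
# offline client
# ---------------------------------------------------------------------------

class OfflineClient:
    """Hermetic client: everything is served from a fixture directory."""

    def __init__(self, fixtures_dir: str | Path):
        self.manifest = FixtureManifest.load(fixtures_dir)

    def fetch_fulltext(self, article_id: str) -> ArticleDocument:
        rel = self.manifest.articles.get(article_id)
        if rel is None:
            return ArticleDocument(article_id,
                                   retrieval_status=RetrievalStatus.NOT_FOUND)
        path = self.manifest.root / rel
        if not path.exists():
            return ArticleDocument(article_id,
                                   retrieval_status=RetrievalStatus.NOT_FOUND)
        return parse_jats(path.read_bytes(), article_id)

    def resolve_accession(self, accession: str) -> ResolutionRecord:
        entry = self.manifest.resolutions.get(accession)
        if entry is None:
            return ResolutionRecord(accession, failed=True)
        return ResolutionRecord(
            accession=accession,
            registry=entry.get("registry", "other"),
            public=bool(entry.get("public", False)),
            n_runs=int(entry.get("n_runs", 0)),
            file_formats=set(entry.get("file_formats", [])),
            resolved_at="fixture",
        )

    def fetch_sample_metadata(self, accession: str) -> StudyMetadata:
        entry = self.manifest.metadata.get(accession)
        if entry is None:
            raise UnevaluableError(f"no metadata fixture for {accession}")
        df = pd.read_csv(self.manifest.root / entry["path"], dtype=str,
                         keep_default_na=False)
        records = [
            SampleRecord(str(row["sample_id"]),
                         {c: row[c] for c in df.columns if c != "sample_id"})
            for _, row in df.iterrows()
        ]
        if not records:
            raise UnevaluableError(f"metadata fixture for {accession} is empty")
        return StudyMetadata(study_id=entry.get("study_id", accession),
                             accession=accession,
                             checklist_name=entry.get("checklist_name"),
                             records=records)


# ---------------------------------------------------------------------------
# live client
# ---------------------------------------------------------------------------

class LiveClient:
    """Minimal polite client for the public NCBI/EBI endpoints.

    Fetches PMC full text through NCBI efetch and resolves accessions /
    sample metadata through the ENA portal API. Requests are rate limited
    and carry a contact identifier in the User-Agent. Intended for
    interactive surveys; all automated tests run against
    :class:`OfflineClient`.
    """

    EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    ENA_FILEREPORT = "https://www.ebi.ac.uk/ena/portal/api/filereport"

    def __init__(self, contact: str | None = None, min_interval: float = 0.4,
                 timeout: float = 30.0):
        self.contact = contact
        self.min_interval = min_interval
        self.timeout = timeout
        self._last_request = 0.0

    def _get(self, url: str, params: dict[str, str]) -> bytes:
        wait = self.min_interval - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        query = urllib.parse.urlencode(params)
        req = urllib.request.Request(
            f"{url}?{query}",
            headers={"User-Agent": f"fairbadge/0.1 ({self.contact or 'no-contact'})"})
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            data = resp.read()
        self._last_request = time.monotonic()
        return data

    def fetch_fulltext(self, article_id: str) -> ArticleDocument:
        try:
            data = self._get(self.EFETCH, {"db": "pmc", "id": article_id,
                                           "rettype": "xml"})
        except OSError:
            return ArticleDocument(article_id,
                                   retrieval_status=RetrievalStatus.NOT_FOUND)
        return parse_jats(data, article_id)

    def resolve_accession(self, accession: str) -> ResolutionRecord:
        try:
            data = self._get(self.ENA_FILEREPORT, {
                "accession": accession, "result": "read_run",
                "fields": "run_accession,fastq_ftp", "format": "tsv"})
        except OSError:
            return ResolutionRecord(accession, failed=True)
        lines = [ln for ln in data.decode("utf-8", "replace").splitlines()[1:] if ln]
        has_fastq = any(len(ln.split("\t")) > 1 and ln.split("\t")[1] for ln in lines)
        return ResolutionRecord(
            accession=accession, registry="ENA", public=bool(lines),
            n_runs=len(lines),
            file_formats={"FASTQ"} if has_fastq else set(),
            resolved_at=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()))

    def fetch_sample_metadata(self, accession: str) -> StudyMetadata:
        try:
            data = self._get(self.ENA_FILEREPORT, {
                "accession": accession, "result": "read_run",
                "fields": "sample_accession,sample_title,checklist",
                "format": "tsv"})
        except OSError as exc:
            raise UnevaluableError(f"could not resolve {accession}") from exc
        df = pd.read_csv(io.BytesIO(data), sep="\t", dtype=str,
                         keep_default_na=False)
        if df.empty:
            raise UnevaluableError(f"{accession} lists no samples")
        records = [
            SampleRecord(row.get("sample_accession", f"sample{i}"),
                         dict(row))
            for i, (_, row) in enumerate(df.iterrows())
        ]
        checklist = next((v for v in df.get("checklist", pd.Series(dtype=str))
                          if v), None)
        return StudyMetadata(study_id=accession, accession=accession,
                             checklist_name=checklist, records=records)


def make_client(mode: str, fixtures_dir: str | Path | None = None,
                contact: str | None = None):
    """Construct an offline or live client from CLI-style options."""
    if mode == "offline":
        if fixtures_dir is None:
            raise ValueError("offline mode requires a fixtures directory")
        return OfflineClient(fixtures_dir)
    if mode == "live":
        return LiveClient(contact=contact)
    raise ValueError(f"unknown mode {mode!r}")
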