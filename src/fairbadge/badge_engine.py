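"""Sequence-data availability badge assignment.

Implements the tiered open-data standard for nucleotide sequence reporting
as a transparent rule engine over an explicit evidence bundle:

* **Bronze** — findable raw data: sequence data downloadable and not
  paywalled, accession numbers provided, raw sequences given as BCL/FASTQ.
* **Silver** — adds sample-processing context: the sequencing method is
  stated (marker gene vs metagenomics) and, for amplicon studies, the PCR
  primer sequences (not applicable to pure metagenome studies).
* **Gold** — open *and* FAIR: access requirements are clear (public data,
  or a stated access procedure otherwise), the repository needs no login or
  institutional affiliation, and analysis code is provided.

Tiers are cumulative; the badge is the highest tier whose requirements —
and those of every tier below it — are all satisfied or not applicable.
``None`` marks articles below Bronze, and ``cannot_be_determined`` articles
whose full text could not be retrieved or parsed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .extraction import DasClass, ExtractionResult, SequencingMethod, open_registries


class Badge(str, enum.Enum):
    NONE = "none"
    BRONZE = "bronze"
    SILVER = "silver"
    GOLD = "gold"
    CANNOT_BE_DETERMINED = "cannot_be_determined"


class BinaryBadge(str, enum.Enum):
    BADGED = "badged"
    NOT_BADGED = "not_badged"


class CriterionState(str, enum.Enum):
    SATISFIED = "satisfied"
    UNSATISFIED = "unsatisfied"
    NOT_APPLICABLE = "not_applicable"


#: criterion names (snake-cased requirement row labels), by tier
BRONZE_CRITERIA = (
    "data_downloadable_not_paywalled",
    "accession_numbers_provided",
    "raw_sequences_bcl_or_fastq",
)
SILVER_CRITERIA = (
    "sequencing_method_provided",
    "pcr_primer_sequences",
)
GOLD_CRITERIA = (
    "das_clarifies_access_requirements",
    "database_publicly_accessible",
    "code_provided",
)
TIER_CRITERIA: dict[Badge, tuple[str, ...]] = {
    Badge.BRONZE: BRONZE_CRITERIA,
    Badge.SILVER: SILVER_CRITERIA,
    Badge.GOLD: GOLD_CRITERIA,
}
_TIER_ORDER = (Badge.BRONZE, Badge.SILVER, Badge.GOLD)


@dataclass
class EvidenceBundle:
    """All booleans the badge rules consume, explicitly set.

    Unknown evidence is recorded as ``False`` (with the reason noted in
    ``provenance``); the rules never see a tri-state value.
    """

    determinable: bool = True
    has_accession: bool = False
    data_public_downloadable: bool = False
    raw_format_ok: bool = False
    sequencing_method_known: bool = False
    is_amplicon: bool = False
    primers_found: bool = False
    das_clarifies_access: bool = False
    repository_open_access: bool = False
    code_available: bool = False
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data_public_downloadable and not self.has_accession:
            raise ValueError(
                "data_public_downloadable requires has_accession "
                "(downloadability is established by resolving an accession)")


@dataclass
class BadgeReport:
    badge: Badge
    criteria: dict[str, CriterionState]
    missing: list[str]


def _evaluate_criteria(ev: EvidenceBundle) -> dict[str, CriterionState]:
    sat = CriterionState.SATISFIED
    unsat = CriterionState.UNSATISFIED

    def b(flag: bool) -> CriterionState:
        return sat if flag else unsat

    criteria = {
        "data_downloadable_not_paywalled": b(ev.data_public_downloadable),
        "accession_numbers_provided": b(ev.has_accession),
        "raw_sequences_bcl_or_fastq": b(ev.raw_format_ok),
        "sequencing_method_provided": b(ev.sequencing_method_known),
        "pcr_primer_sequences": (
            CriterionState.NOT_APPLICABLE if not ev.is_amplicon
            else b(ev.primers_found)),
        "das_clarifies_access_requirements": b(
            ev.data_public_downloadable or ev.das_clarifies_access),
        "database_publicly_accessible": b(ev.repository_open_access),
        "code_provided": b(ev.code_available),
    }
    return criteria


def assign_sequence_badge(evidence: EvidenceBundle) -> BadgeReport:
    """Assign the badge: the highest cumulative tier whose requirements are
    all satisfied or not applicable.

    ``determinable = False`` forces ``cannot_be_determined`` regardless of
    the other fields; its ``missing`` entry names the blocking condition so
    the report invariant (missing empty iff Gold) holds.
    """
    if not evidence.determinable:
        return BadgeReport(Badge.CANNOT_BE_DETERMINED, {},
                           missing=["full_text_available"])

    criteria = _evaluate_criteria(evidence)

    def tier_ok(tier: Badge) -> bool:
        return all(criteria[name] is not CriterionState.UNSATISFIED
                   for name in TIER_CRITERIA[tier])

    badge = Badge.NONE
    for tier in _TIER_ORDER:
        if tier_ok(tier):
            badge = tier
        else:
            break

    if badge is Badge.GOLD:
        missing: list[str] = []
    else:
        next_tier = _TIER_ORDER[_TIER_ORDER.index(badge) + 1] \
            if badge is not Badge.NONE else Badge.BRONZE
        missing = [name for name in TIER_CRITERIA[next_tier]
                   if criteria[name] is CriterionState.UNSATISFIED]
    return BadgeReport(badge, criteria, missing)


def collapse_binary(badge: Badge | str) -> BinaryBadge:
    """Collapse the four-category badge to the None-versus-Badged view.

    Bronze/Silver/Gold are Badged; None is not. ``cannot_be_determined``
    also maps to not-badged (callers wanting to exclude undetermined items
    from accuracy statistics do so before collapsing).
    """
    badge = Badge(badge)
    if badge in (Badge.BRONZE, Badge.SILVER, Badge.GOLD):
        return BinaryBadge.BADGED
    return BinaryBadge.NOT_BADGED


def evidence_from_extraction(extraction: ExtractionResult,
                             resolutions: list | None = None,
                             determinable: bool = True) -> EvidenceBundle:
    """Derive the evidence bundle from extracted text evidence plus
    repository resolution records.

    ``resolutions`` are :class:`~fairbadge.repo_clients.ResolutionRecord`-like
    objects for the extracted accessions (may be empty in offline mode
    without a manifest — the corresponding booleans then stay ``False`` and
    the reason is recorded in the bundle's provenance map).
    """
    resolutions = resolutions or []
    resolved = [r for r in resolutions if not getattr(r, "failed", False)]
    raw_formats = {"FASTQ", "BCL"}

    provenance: dict[str, str] = {}
    if extraction.accessions and not resolutions:
        provenance["data_public_downloadable"] = "no resolution records supplied"
        provenance["raw_format_ok"] = "no resolution records supplied"

    has_accession = bool(extraction.accessions)
    data_public = has_accession and any(
        r.public and r.file_formats for r in resolved)
    return EvidenceBundle(
        determinable=determinable,
        has_accession=has_accession,
        data_public_downloadable=data_public,
        raw_format_ok=any(set(r.file_formats) & raw_formats for r in resolved),
        sequencing_method_known=(
            extraction.sequencing_method is not SequencingMethod.UNKNOWN),
        is_amplicon=extraction.sequencing_method in (
            SequencingMethod.MARKER_GENE, SequencingMethod.BOTH),
        primers_found=bool(extraction.primers),
        das_clarifies_access=(
            extraction.das_class is DasClass.RESTRICTED_WITH_PROCEDURE),
        repository_open_access=all(
            h.registry in open_registries() for h in extraction.accessions),
        code_available=bool(extraction.code_links),
        provenance=provenance,
    )
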