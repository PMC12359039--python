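"""Tiered evaluation and cross-study analytics of sample metadata.

Evaluates INSDC-style sample metadata (attribute -> value maps per sample)
against a cumulative Bronze/Silver/Gold checklist derived from the MIxS
v6.0 core fields plus the MIMARKS and human-gut package fields, after
harmonizing submitter-specific attribute spellings ("Sample Name",
"User_sample_ID", ...) onto canonical names.

Also computes cross-study sparsity analytics: which attributes are
populated in which studies, the per-attribute population proportion, its
median, and a comprehensiveness histogram.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import metadata_checklist, metadata_vocabulary

logger = logging.getLogger(__name__)


class MetadataTier(str, enum.Enum):
    NONE = "none"
    BRONZE = "bronze"
    SILVER = "silver"
    GOLD = "gold"


@dataclass
class SampleRecord:
    sample_id: str
    attributes: dict[str, str] = field(default_factory=dict)


@dataclass
class StudyMetadata:
    study_id: str
    accession: str | None = None
    checklist_name: str | None = None
    records: list[SampleRecord] = field(default_factory=list)


@dataclass
class ChecklistTier:
    tier: MetadataTier
    required_fields: list[str]  # cumulative: includes all lower-tier fields


@dataclass
class MetadataAssessment:
    study_id: str
    tier_awarded: MetadataTier
    field_completeness: dict[str, float]
    blocking_fields: list[str]


@dataclass
class PopulationMatrix:
    """Boolean attribute x study matrix: attribute populated in that study
    (at least one sample with a non-missing value)."""

    matrix: pd.DataFrame  # bool, index = attributes, columns = study ids

    @property
    def proportions(self) -> pd.Series:
        """Per-attribute fraction of studies in which it is populated."""
        return self.matrix.mean(axis=1)


class UnevaluableError(ValueError):
    """Raised when an operation receives no evaluable records/studies."""


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

_SEP_RE = re.compile(r"[\s_\-]+")


def normalize_attribute(name: str) -> str:
    """Case- and separator-insensitive canonical form of an attribute name
    (lower case, single spaces)."""
    return _SEP_RE.sub(" ", name.strip().lower()).strip()


@lru_cache(maxsize=1)
def default_synonym_map() -> dict[str, str]:
    return dict(metadata_vocabulary()["synonyms"])


@lru_cache(maxsize=1)
def _missing_tokens() -> frozenset[str]:
    return frozenset(metadata_vocabulary()["missing_tokens"])


def is_missing(value: str | None) -> bool:
    """True when a metadata value is empty or a recognized missing token
    ("na", "not collected", ...) after trimming and case-folding."""
    if value is None:
        return True
    return value.strip().lower() in _missing_tokens()


def harmonize_attributes(records: Iterable[SampleRecord],
                         synonym_map: dict[str, str] | None = None,
                         ) -> list[SampleRecord]:
    """Rename synonym attributes to their canonical names.

    Matching against the map is case- and separator-insensitive; unmapped
    attribute names pass through verbatim. When two raw names collapse onto
    one canonical within a record, the first non-missing value wins and the
    collision is logged. Idempotent. Non-mutating.
    """
    raw_map = default_synonym_map() if synonym_map is None else synonym_map
    norm_map = {normalize_attribute(k): v for k, v in raw_map.items()}

    out: list[SampleRecord] = []
    for rec in records:
        attrs: dict[str, str] = {}
        for raw_name, value in rec.attributes.items():
            name = norm_map.get(normalize_attribute(raw_name), raw_name)
            if name in attrs:
                logger.warning(
                    "sample %s: attributes collide on %r; keeping first "
                    "non-missing value", rec.sample_id, name)
                if is_missing(attrs[name]) and not is_missing(value):
                    attrs[name] = value
            else:
                attrs[name] = value
        out.append(SampleRecord(rec.sample_id, attrs))
    return out


def harmonize_study(study: StudyMetadata,
                    synonym_map: dict[str, str] | None = None) -> StudyMetadata:
    return StudyMetadata(study.study_id, study.accession, study.checklist_name,
                         harmonize_attributes(study.records, synonym_map))


# ---------------------------------------------------------------------------
# tier evaluation
# ---------------------------------------------------------------------------

def default_checklist() -> list[ChecklistTier]:
    """The packaged human-gut checklist as cumulative tiers."""
    cfg = metadata_checklist()["tiers"]
    bronze = list(cfg["bronze"])
    silver = bronze + list(cfg["silver_additional"])
    gold = silver + list(cfg["gold_additional"])
    return [
        ChecklistTier(MetadataTier.BRONZE, bronze),
        ChecklistTier(MetadataTier.SILVER, silver),
        ChecklistTier(MetadataTier.GOLD, gold),
    ]


def evaluate_metadata_tier(study: StudyMetadata,
                           checklist: Sequence[ChecklistTier] | None = None,
                           completeness_threshold: float = 1.0,
                           ) -> MetadataAssessment:
    """Award the highest cumulative tier whose fields all reach the
    completeness threshold.

    A field's completeness is the fraction of the study's samples with a
    non-missing value; by default every sample must be populated (strict
    threshold of 1.0). ``blocking_fields`` lists the unsatisfied fields of
    the next tier up, in checklist order. Attributes are expected to be
    harmonized beforehand (see :func:`harmonize_study`).
    """
    if not study.records:
        raise UnevaluableError(f"study {study.study_id} has no sample records")
    checklist = list(default_checklist() if checklist is None else checklist)
    checklist.sort(key=lambda t: list(MetadataTier).index(t.tier))

    n = len(study.records)
    all_fields = list(dict.fromkeys(
        f for tier in checklist for f in tier.required_fields))
    completeness = {
        f: sum(not is_missing(rec.attributes.get(f)) for rec in study.records) / n
        for f in all_fields
    }

    def satisfied(field_name: str) -> bool:
        return completeness[field_name] >= completeness_threshold

    awarded = MetadataTier.NONE
    blocking = [f for f in checklist[0].required_fields if not satisfied(f)]
    for tier in checklist:
        if all(satisfied(f) for f in tier.required_fields):
            awarded = tier.tier
        else:
            blocking = [f for f in tier.required_fields if not satisfied(f)]
            break
    else:
        blocking = []
    return MetadataAssessment(study.study_id, awarded, completeness, blocking)


# ---------------------------------------------------------------------------
# cross-study analytics
# ---------------------------------------------------------------------------

def population_matrix(studies: Sequence[StudyMetadata]) -> PopulationMatrix:
    """Boolean attribute x study population matrix over the union of
    attribute names.

    An attribute is populated for a study iff at least one sample carries a
    non-missing value. Whether attributes were harmonized first is the
    caller's choice. Attributes are sorted; study column order follows the
    input.
    """
    if not studies:
        raise UnevaluableError("no studies supplied")
    columns: dict[str, dict[str, bool]] = {}
    for study in studies:
        populated: dict[str, bool] = {}
        for rec in study.records:
            for name, value in rec.attributes.items():
                populated[name] = populated.get(name, False) or not is_missing(value)
        columns[study.study_id] = populated
    attrs = sorted({a for col in columns.values() for a in col})
    df = pd.DataFrame(
        {sid: [col.get(a, False) for a in attrs] for sid, col in columns.items()},
        index=attrs, dtype=bool)
    return PopulationMatrix(df)


def sparsity_histogram(matrix: PopulationMatrix,
                       bin_edges: Sequence[float]) -> list[int]:
    """Histogram of per-attribute population proportions.

    Bins are left-open/right-closed, except the first which includes 0, so
    each attribute falls in exactly one bin and the counts sum to the number
    of attributes. ``bin_edges`` must be strictly increasing and span [0, 1].
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    if edges[0] != 0 or edges[-1] != 1:
        raise ValueError("bin_edges must span [0, 1]")
    counts = [0] * (len(edges) - 1)
    props = matrix.proportions.to_numpy()
    idx = np.searchsorted(edges, props, side="left") - 1
    for i in np.clip(idx, 0, len(counts) - 1):
        counts[i] += 1
    return counts


def median_population(matrix: PopulationMatrix) -> float:
    """Median per-attribute population proportion (mean of the middle two
    for an even attribute count)."""
    props = matrix.proportions
    if props.empty:
        raise UnevaluableError("empty population matrix")
    return float(np.median(props.to_numpy()))


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def study_from_wide_table(df: pd.DataFrame, study_id: str,
                          sample_id_column: str = "sample_id",
                          accession: str | None = None,
                          checklist_name: str | None = None) -> StudyMetadata:
    """Build a study from a wide table (one row per sample, one column per
    attribute)."""
    records = [
        SampleRecord(str(row[sample_id_column]),
                     {c: ("" if pd.isna(row[c]) else str(row[c]))
                      for c in df.columns if c != sample_id_column})
        for _, row in df.iterrows()
    ]
    return StudyMetadata(study_id, accession, checklist_name, records)


def study_from_long_table(df: pd.DataFrame, study_id: str,
                          accession: str | None = None,
                          checklist_name: str | None = None) -> StudyMetadata:
    """Build a study from a long table with columns
    sample_id / attribute / value."""
    records: dict[str, SampleRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        rec = records.setdefault(sid, SampleRecord(sid, {}))
        rec.attributes[str(row["attribute"])] = (
            "" if pd.isna(row["value"]) else str(row["value"]))
    return StudyMetadata(study_id, accession, checklist_name, list(records.values()))


def assessment_to_frame(assessments: Iterable[MetadataAssessment]) -> pd.DataFrame:
    return pd.DataFrame([
        {"study_id": a.study_id, "tier_awarded": a.tier_awarded.value,
         "blocking_fields": ";".join(a.blocking_fields)}
        for a in assessments
    ])
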