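"""Loading of packaged, human-editable pattern and checklist catalogues."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml


@lru_cache(maxsize=None)
def _load_packaged(name: str) -> dict:
    ref = resources.files("fairbadge.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_yaml(path: str | Path) -> dict:
    """Load a user-supplied YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def sequence_catalogue() -> dict:
    """Accession/lexicon/phrase catalogue driving the extraction module."""
    return _load_packaged("sequence_catalogue.yaml")


def metadata_checklist() -> dict:
    """Default tiered metadata checklist (human gut flavour)."""
    return _load_packaged("metadata_checklist_human_gut.yaml")


def metadata_vocabulary() -> dict:
    """Default attribute synonym map and missing-value token list."""
    return _load_packaged("metadata_synonyms.yaml")
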