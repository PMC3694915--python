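"""Packaged reference tables.

Small plain-text fixtures shipped with the package: the genus-level trait
table (extant + fossil body mass and generation time), the published
node-age/rate interval table used as an audit surface, the fossil
calibration priors, and the human per-generation rate configuration with
the node generation times that reproduce the published per-year rates.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .priors import CalibrationPrior, load_priors
from .rates import PerGenerationRateInterval
from .traits import load_traits

__all__ = [
    "trait_table",
    "node_age_intervals",
    "calibration_priors",
    "rate_config",
    "human_rate_interval",
    "fixtures",
    "checksums",
]

_DATA = resources.files("platydate") / "data"


def _path(name: str):
    return _DATA / name


def trait_table() -> pd.DataFrame:
    """Extant and fossil genus traits: mass (g), generation time (yr)."""
    with resources.as_file(_path("trait_table.csv")) as p:
        return load_traits(p)


def node_age_intervals() -> pd.DataFrame:
    """Published per-node rate and age intervals (rates /site/yr, ages Ma)."""
    with resources.as_file(_path("node_age_intervals.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def calibration_priors() -> list[CalibrationPrior]:
    with resources.as_file(_path("calibration_priors.csv")) as p:
        return load_priors(p)


def rate_config() -> dict:
    with resources.as_file(_path("rate_config.json")) as p:
        return json.loads(p.read_text())


def human_rate_interval() -> PerGenerationRateInterval:
    lo, hi = rate_config()["pergen"]
    return PerGenerationRateInterval(lo, hi)


def checksums() -> dict[str, str]:
    """SHA-256 of each packaged data file (provenance for run logs)."""
    out = {}
    for entry in sorted(_DATA.iterdir(), key=lambda e: e.name):
        out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()
    return out


def fixtures() -> dict:
    """All packaged fixtures keyed by role."""
    return {
        "trait_table": trait_table(),
        "node_age_intervals": node_age_intervals(),
        "calibration_priors": calibration_priors(),
        "human_rate_interval": human_rate_interval(),
        "rate_config": rate_config(),
        "checksums": checksums(),
    }
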