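"""Per-generation → per-year substitution-rate conversion.

The only direct (pedigree-based) substitution-rate estimate among primates
is for humans, expressed per site per *generation*.  Under the hypothesis
that most germ-line mutations arise at DNA replication, the per-year rate
of a lineage is the per-generation rate divided by that lineage's mean
generation time: r = μ_gen / ḡ.  Carrying the full published human interval
through the division propagates rate uncertainty into divergence-time
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "HUMAN_PEDIGREE_INTERVAL",
    "PerGenerationRateInterval",
    "PerYearRateInterval",
    "clade_generation_time",
    "per_year_interval",
]


@dataclass(frozen=True)
class PerGenerationRateInterval:
    """Substitutions/site/generation, low ≤ high."""

    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low <= self.high):
            raise ValueError(f"need 0 < low <= high, got ({self.low}, {self.high})")


#: Broadest published human pedigree interval, subs/site/generation.
HUMAN_PEDIGREE_INTERVAL = PerGenerationRateInterval(9.70e-9, 1.36e-8)


@dataclass(frozen=True)
class PerYearRateInterval:
    """Substitutions/site/year for a lineage with mean generation time gbar.

    ``slow`` comes from the low per-generation bound, ``fast`` from the
    high one; fast/slow always equals the per-generation ratio.
    """

    slow: float
    fast: float
    gbar: float

    def __post_init__(self):
        if not (0 < self.slow <= self.fast):
            raise ValueError(f"need 0 < slow <= fast, got ({self.slow}, {self.fast})")


def clade_generation_time(
    table: pd.DataFrame,
    members: list[str],
    policy: str = "mean_extant",
    value: float | None = None,
) -> float:
    """Mean generation time (years) for a clade.

    policy ``mean_extant`` averages extant members only, ``mean_all``
    averages every listed member (fossils included, post-imputation),
    ``explicit`` passes ``value`` through unchanged.
    """
    if policy == "explicit":
        if value is None or value <= 0:
            raise ValueError("explicit policy needs a positive value")
        return float(value)
    if not members:
        raise ValueError("empty member list")
    sub = table[table["genus"].isin(members)]
    unknown = set(members) - set(sub["genus"])
    if unknown:
        raise KeyError(f"genera not in trait table: {sorted(unknown)}")
    if policy == "mean_extant":
        sub = sub[~sub["is_fossil"]]
        if sub.empty:
            raise ValueError("no extant members under mean_extant policy")
    elif policy != "mean_all":
        raise ValueError(f"unknown policy {policy!r}")
    g = sub["generation_time_yr"]
    if g.isna().any():
        raise ValueError(
            f"missing generation times for: {sub.loc[g.isna(), 'genus'].tolist()}"
        )
    return float(g.mean())


def per_year_interval(
    pergen: PerGenerationRateInterval, gbar: float
) -> PerYearRateInterval:
    """Divide the per-generation interval by a mean generation time."""
    if gbar <= 0:
        raise ValueError(f"generation time must be positive, got {gbar}")
    return PerYearRateInterval(slow=pergen.low / gbar, fast=pergen.high / gbar, gbar=gbar)
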