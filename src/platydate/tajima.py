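"""Tajima's one-degree-of-freedom relative rate test.

Given two ingroup sequences A, B and an outgroup C, sites where A differs
from B while B agrees with C are uniquely derived on the A lineage (count
m_A), and symmetrically for m_B.  Under a molecular clock E[m_A] = E[m_B],
and (m_A − m_B)²/(m_A + m_B) is asymptotically χ² with 1 df.  The screen
runs the test over taxon pairs and flags taxa involved in significant
comparisons so they can be excluded from clock dating (in the original
platyrrhine analysis only *Aotus* was flagged).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from scipy.stats import chi2 as _chi2

__all__ = ["TajimaResult", "tajima_counts", "tajima_1d", "tajima_test", "relative_rate_screen"]

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class TajimaResult:
    taxon_a: str
    taxon_b: str
    mA: int
    mB: int
    n_sites_used: int
    chi2: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def tajima_counts(seqA: str, seqB: str, outgroup: str) -> tuple[int, int, int]:
    """Counts of uniquely derived sites for A and B relative to the outgroup.

    Columns containing a gap or any non-ACGT character in any of the three
    sequences are excluded entirely (complete deletion over the triplet).
    """
    if not (len(seqA) == len(seqB) == len(outgroup)):
        raise ValueError("sequences must be aligned to equal length")
    mA = mB = used = 0
    for a, b, c in zip(seqA.upper(), seqB.upper(), outgroup.upper()):
        if a not in _VALID or b not in _VALID or c not in _VALID:
            continue
        used += 1
        if a != b:
            if b == c:
                mA += 1
            elif a == c:
                mB += 1
    return mA, mB, used


def tajima_1d(mA: int, mB: int) -> tuple[float, float]:
    """χ² statistic and upper-tail p for the 1D relative rate test.

    (0, 0) is defined as a perfect clock: chi2 = 0, p = 1.
    """
    if mA < 0 or mB < 0:
        raise ValueError("counts must be nonnegative")
    if mA + mB == 0:
        return 0.0, 1.0
    stat = (mA - mB) ** 2 / (mA + mB)
    return float(stat), float(_chi2.sf(stat, df=1))


def tajima_test(alignment: dict, a: str, b: str, outgroup: str) -> TajimaResult:
    """Run the relative rate test for one ingroup pair."""
    mA, mB, used = tajima_counts(alignment[a], alignment[b], alignment[outgroup])
    stat, p = tajima_1d(mA, mB)
    return TajimaResult(a, b, mA, mB, used, stat, p)


def relative_rate_screen(
    alignment: dict,
    outgroup_label: str,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> tuple[list[str], list[TajimaResult]]:
    """Screen ingroup taxa for clock violations.

    ``alignment`` maps labels to aligned sequences.  By default every
    unordered ingroup pair is tested against the designated outgroup; a
    taxon is flagged if any comparison involving it is significant at
    ``alpha``.  Returns (flagged taxa, all test results).
    """
    if outgroup_label not in alignment:
        raise KeyError(f"outgroup {outgroup_label!r} not in alignment")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ingroup = [t for t in alignment if t != outgroup_label]
    if pairs is None:
        pairs = list(combinations(ingroup, 2))
    results = [tajima_test(alignment, a, b, outgroup_label) for a, b in pairs]
    flagged = sorted(
        {t for r in results if r.p < alpha for t in (r.taxon_a, r.taxon_b)}
    )
    return flagged, results
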