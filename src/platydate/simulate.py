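"""Synthetic trait tables and clocklike sequence alignments.

The generator mirrors the statistical structure the dating method assumes:
generation time is an allometric function of body mass plus noise, and a
branch's substitution rate per year is a single per-generation rate
divided by that branch's generation time.  Sequences evolve under HKY
along a chronogram, giving every branch an expected length (subs/site) of

    duration_Ma × 10⁶ × μ_gen / g_branch.

Site evolution uses exact exponential waiting times per site (vectorized
per branch, branches visited in preorder), so output is byte-reproducible
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .datasets import fixtures  # noqa: F401  (re-export: packaged fixtures)
from .traits import AllometricFit

__all__ = [
    "simulate_traits",
    "expected_branch_length",
    "SyntheticTruth",
    "build_truth",
    "default_study_truth",
    "simulate_alignment",
    "write_fasta",
    "fixtures",
]

#: Geometric midpoint of the published human per-generation interval,
#: subs/site/generation; the generator's single "true" rate.
DEFAULT_PERGEN_RATE = float(np.sqrt(9.70e-9 * 1.36e-8))

_BASES = np.array(list("ACGT"))


def simulate_traits(
    n: int,
    fit: AllometricFit,
    noise_sd: float,
    mass_range: tuple[float, float] = (300.0, 10_000.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic extant trait table from an allometric fit.

    Masses are uniform on ``mass_range``; generation times are the fit
    prediction plus Gaussian noise, floored at 1 yr.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = mass_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid mass range {mass_range}")
    rng = np.random.default_rng(seed)
    mass = rng.uniform(lo, hi, size=n)
    g = np.maximum(fit.predict(mass) + rng.normal(0.0, noise_sd, size=n), 1.0)
    return pd.DataFrame(
        {
            "genus": [f"sim_{i:04d}" for i in range(n)],
            "clade": "Synthetic",
            "body_mass_g": mass,
            "generation_time_yr": g,
            "is_fossil": False,
        }
    )


def expected_branch_length(
    duration_ma: float, pergen_rate: float, generation_time: float
) -> float:
    """Expected substitutions/site on a branch of the given duration."""
    if duration_ma <= 0 or pergen_rate <= 0 or generation_time <= 0:
        raise ValueError("duration, rate and generation time must be positive")
    return duration_ma * 1e6 * pergen_rate / generation_time


@dataclass
class SyntheticTruth:
    """A chronogram with known ages and generation-time-driven branch rates.

    ``tree`` node ``.age`` attributes are in Ma (tips at 0);
    ``generation_times`` maps a node/tip label to the generation time of
    the *edge above it* (unlabelled edges take ``default_generation_time``).
    """

    tree: dendropy.Tree
    pergen_rate: float = DEFAULT_PERGEN_RATE
    generation_times: dict = field(default_factory=dict)
    default_generation_time: float = 16.0
    seed: int | None = None

    def edge_generation_time(self, node) -> float:
        label = node.taxon.label if node.is_leaf() else node.label
        return float(self.generation_times.get(label, self.default_generation_time))

    def branch_lengths(self) -> dict:
        """Expected subs/site per edge, keyed by child node."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            dur = node.parent_node.age - node.age
            out[node] = expected_branch_length(
                dur, self.pergen_rate, self.edge_generation_time(node)
            ) if dur > 0 else 0.0
        return out

    def node_ages(self) -> dict[frozenset, float]:
        """True age (Ma) per internal node, keyed by its tip-label set."""
        ages = {}
        tipsets = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[node] = frozenset([node.taxon.label])
            else:
                tipsets[node] = frozenset().union(
                    *(tipsets[k] for k in node.child_nodes())
                )
                ages[tipsets[node]] = float(node.age)
        return ages

    def expected_depths(self) -> dict[frozenset, float]:
        """Expected least-squares molecular depth (subs/site) per node.

        Matches the clock estimator: mean over tip pairs with this LCA of
        half the expected tip-to-tip path length.
        """
        bl = self.branch_lengths()
        tipsets = {}
        depth_to = {}  # tip label -> subs/site from each ancestor
        out = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[node] = frozenset([node.taxon.label])
                depth_to[node] = {node.taxon.label: 0.0}
                continue
            kids = node.child_nodes()
            tipsets[node] = frozenset().union(*(tipsets[k] for k in kids))
            merged = {}
            for k in kids:
                for tip, d in depth_to[k].items():
                    merged[tip] = d + bl[k]
            depth_to[node] = merged
            tot = npairs = 0
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for ti in tipsets[kids[a]]:
                        for tj in tipsets[kids[b]]:
                            tot += merged[ti] + merged[tj]
                            npairs += 1
            out[tipsets[node]] = tot / (2 * npairs)
        return out

    def effective_generation_times(self) -> dict[frozenset, float]:
        """Per-node ḡ such that age = depth / (pergen_rate / ḡ) exactly.

        When generation time varies along root-to-tip paths no single ḡ is
        "the" clade value; this is the path-averaged one consistent with
        the least-squares depth.
        """
        ages = self.node_ages()
        depths = self.expected_depths()
        return {
            k: ages[k] * 1e6 * self.pergen_rate / depths[k]
            for k in ages
            if depths[k] > 0
        }


def build_truth(
    ages_newick: str,
    generation_times: dict | None = None,
    pergen_rate: float = DEFAULT_PERGEN_RATE,
    default_generation_time: float = 16.0,
) -> SyntheticTruth:
    """Truth object from a newick whose branch lengths are durations in Ma.

    Internal node labels in the newick can be referenced in
    ``generation_times`` to set the generation time of the edge above them.
    """
    tree = dendropy.Tree.get(data=ages_newick, schema="newick")
    tree.calc_node_ages(ultrametricity_precision=1e-6)
    return SyntheticTruth(
        tree=tree,
        pergen_rate=pergen_rate,
        generation_times=generation_times or {},
        default_generation_time=default_generation_time,
    )


#: Study-like chronogram: New World monkey crown at 24.4 Ma, catarrhine
#: crown at 29.2 Ma, anthropoid root at 44.3 Ma (interval midpoints of the
#: packaged node table); platyrrhine edges at ḡ=16 yr, catarrhine at 24 yr.
_STUDY_NEWICK = (
    "((((Saimiri:18.7,Callithrix:18.7)Cebidae:4.2,"
    "(Ateles:12.0,Alouatta:12.0)Atelidae:10.9)AtelidCebid:1.5,"
    "Callicebus:24.4)Platyrrhini:19.9,"
    "((Homo:8.8,Pan:8.8)HomoPan:20.4,Macaca:29.2)Catarrhini:15.1)Anthropoidea;"
)

_STUDY_GENTIMES = {
    "Homo": 27.0, "Pan": 27.0, "HomoPan": 24.0, "Macaca": 24.0,
    "Catarrhini": 19.5,
}


def default_study_truth(pergen_rate: float = DEFAULT_PERGEN_RATE) -> SyntheticTruth:
    return build_truth(
        _STUDY_NEWICK,
        generation_times=dict(_STUDY_GENTIMES),
        pergen_rate=pergen_rate,
        default_generation_time=16.0,
    )


def _hky_q(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY rate matrix (order ACGT) scaled to one expected sub/site/unit."""
    A, C, G, T = range(4)
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            ts = (i, j) in ((A, G), (G, A), (C, T), (T, C))
            q[i, j] = (kappa if ts else 1.0) * freqs[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(freqs * np.diag(q)).sum()
    return q / scale


def _evolve(states: np.ndarray, blen: float, q: np.ndarray, rng) -> np.ndarray:
    """Exact waiting-time evolution of site states along one branch."""
    if blen <= 0:
        return states.copy()
    leave = -np.diag(q)
    jump = q / leave[:, None]
    np.fill_diagonal(jump, 0.0)
    jump_cdf = np.cumsum(jump, axis=1)
    states = states.copy()
    t = rng.exponential(1.0 / leave[states])
    active = t < blen
    while active.any():
        idx = np.flatnonzero(active)
        u = rng.random(idx.size)
        states[idx] = (u[:, None] < jump_cdf[states[idx]]).argmax(axis=1)
        t[idx] += rng.exponential(1.0 / leave[states[idx]])
        active[idx] = t[idx] < blen
    return states


def simulate_alignment(
    truth: SyntheticTruth,
    length: int,
    kappa: float = 2.0,
    base_freqs=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> dict[str, str]:
    """Simulate an HKY alignment along the truth chronogram.

    Returns {tip label: sequence}.  The root sequence is drawn from the
    base frequencies; each branch then evolves its parent's states with
    expected ``rate × duration`` substitutions per site.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or (freqs <= 0).any() or abs(freqs.sum() - 1) > 1e-9:
        raise ValueError("base_freqs must be 4 positive values summing to 1")
    rng = np.random.default_rng(seed)
    q = _hky_q(kappa, freqs)
    bl = truth.branch_lengths()

    states = {truth.tree.seed_node: rng.choice(4, size=length, p=freqs)}
    seqs = {}
    for node in truth.tree.preorder_node_iter():
        if node.parent_node is not None:
            states[node] = _evolve(states[node.parent_node], bl[node], q, rng)
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(_BASES[states[node]])
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
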