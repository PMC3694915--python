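"""Clock-constrained node heights and node-age intervals.

The dating arithmetic is deliberately simple and transparent:

1. model-corrected pairwise distances (JC69, K2P or TN93 closed forms,
   substitutions/site) from an alignment;
2. least-squares node heights on a fixed rooted topology under a strict
   clock ("linearized tree"): the unconstrained optimum of
   Σ_{i<j} (d_ij − 2·h_lca(i,j))² is, per internal node, half the mean
   distance over the tip pairs whose LCA it is; ultrametric monotonicity
   (child height ≤ parent height) is then restored by weighted
   pair-count pooling, i.e. isotonic regression in the tree order;
3. ages: a node of molecular depth h (subs/site) dated with a per-year
   rate interval (slow, fast) has age interval [h/fast, h/slow],
   reported in Ma.

Because the fast rate bound gives the young age and the slow bound the
old age, t_fast·rate_fast = t_slow·rate_slow = h is an exact identity
and is used to audit published interval tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .rates import PerYearRateInterval

__all__ = [
    "SaturationError",
    "pairwise_distances",
    "ols_clock_heights",
    "ClockHeights",
    "date_nodes",
    "reproduce_interval_table",
]

_VALID = frozenset("ACGT")
_PURINES = frozenset("AG")


class SaturationError(ValueError):
    """Distance correction undefined: sequences too diverged for the model."""


def _pair_counts(s1: str, s2: str):
    """Mismatch classification over jointly valid (ACGT) sites."""
    n = p1 = p2 = q = 0
    counts = {b: 0 for b in "ACGT"}
    for a, b in zip(s1, s2):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        counts[a] += 1
        counts[b] += 1
        if a != b:
            if (a in _PURINES) == (b in _PURINES):
                if a in _PURINES:
                    p1 += 1  # A<->G transition
                else:
                    p2 += 1  # C<->T transition
            else:
                q += 1
    return n, p1, p2, q, counts


def _jc69(p: float, pair: str) -> float:
    if p >= 0.75:
        raise SaturationError(f"JC69 undefined at p={p:.3f} for pair {pair}")
    return -0.75 * math.log(1 - 4 * p / 3)


def _k2p(P: float, Q: float, pair: str) -> float:
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined for pair {pair} (P={P:.3f}, Q={Q:.3f})")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _tn93(P1: float, P2: float, Q: float, freqs: dict, pair: str) -> float:
    gA, gC, gG, gT = (freqs[b] for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0:
        raise SaturationError(f"TN93 undefined: missing base in pair {pair}")
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError(f"TN93 undefined for pair {pair}")
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def pairwise_distances(
    alignment: dict, model: str = "TN93", complete_deletion: bool = False
) -> pd.DataFrame:
    """Model-corrected pairwise distances (subs/site) as a labelled matrix.

    Gap/ambiguous sites are deleted pairwise by default; with
    ``complete_deletion`` any column invalid in *any* sequence is dropped
    for every pair.
    """
    model = model.upper()
    if model not in {"JC69", "K2P", "TN93"}:
        raise ValueError(f"unknown model {model!r}")
    labels = list(alignment)
    seqs = {t: alignment[t].upper() for t in labels}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    if complete_deletion:
        keep = [
            i
            for i in range(lengths.pop())
            if all(s[i] in _VALID for s in seqs.values())
        ]
        seqs = {t: "".join(s[i] for i in keep) for t, s in seqs.items()}

    d = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            n, p1, p2, q, counts = _pair_counts(seqs[a], seqs[b])
            if n == 0:
                raise ValueError(f"no comparable sites for pair {a}/{b}")
            pair = f"{a}/{b}"
            if model == "JC69":
                dist = _jc69((p1 + p2 + q) / n, pair)
            elif model == "K2P":
                dist = _k2p((p1 + p2) / n, q / n, pair)
            else:
                freqs = {k: v / (2 * n) for k, v in counts.items()}
                dist = _tn93(p1 / n, p2 / n, q / n, freqs, pair)
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass
class ClockHeights:
    """Ultrametric node heights (subs/site) on a rooted topology.

    ``heights`` maps each internal node's tip-label frozenset to its
    height; tips are at height 0 by construction.
    """

    tree: dendropy.Tree
    heights: dict

    def height_of(self, members) -> float:
        """Height of the LCA of ``members`` (any subset of its clade)."""
        members = set(members)
        best = None
        for tips, h in self.heights.items():
            if members <= tips and (best is None or len(tips) < len(best[0])):
                best = (tips, h)
        if best is None:
            raise KeyError(f"no node contains {sorted(members)}")
        return best[1]


def _node_pair_stats(tree: dendropy.Tree, d: pd.DataFrame):
    """Per internal node: tipset, mean d/2 over pairs with that LCA, #pairs."""
    stats = []
    tipsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = frozenset([node.taxon.label])
            continue
        kids = node.child_nodes()
        tipsets[node] = frozenset().union(*(tipsets[k] for k in kids))
        tot = 0.0
        npairs = 0
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for ti in tipsets[kids[a]]:
                    for tj in tipsets[kids[b]]:
                        tot += d.at[ti, tj]
                        npairs += 1
        stats.append((node, tipsets[node], tot / (2 * npairs), npairs))
    return stats, tipsets


def ols_clock_heights(tree: dendropy.Tree, d: pd.DataFrame) -> ClockHeights:
    """Least-squares ultrametric node heights on a fixed rooted topology.

    Minimizes Σ_{i<j} (d_ij − 2 h_lca(i,j))² subject to child ≤ parent.
    The unconstrained solution is separable per node (half the mean
    distance over its LCA pairs); violations of monotonicity are resolved
    by pooling a violating child block into its parent block with
    pair-count weights (exact isotonic regression: the constraint graph
    is an in-tree, where adjacent-violator pooling attains the optimum).
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(d.index):
        raise ValueError(
            f"topology tips and distance-matrix taxa differ: "
            f"{sorted(tips ^ set(d.index))}"
        )
    stats, tipsets = _node_pair_stats(tree, d)

    # isotonic pooling on the in-tree order (heights nondecreasing rootward)
    block = {}  # node -> block id
    blocks = {}  # id -> [value, weight, nodes]
    parent_of = {}
    for i, (node, _, h, w) in enumerate(stats):
        block[node] = i
        blocks[i] = [h, float(w), [node]]
        if node.parent_node is not None:
            parent_of[node] = node.parent_node

    def merge(ci, pi):
        v = (blocks[ci][0] * blocks[ci][1] + blocks[pi][0] * blocks[pi][1]) / (
            blocks[ci][1] + blocks[pi][1]
        )
        blocks[pi] = [v, blocks[ci][1] + blocks[pi][1], blocks[pi][2] + blocks[ci][2]]
        for nd in blocks[ci][2]:
            block[nd] = pi
        del blocks[ci]

    # Always resolve the violation whose child block is highest: that block
    # can only move down, so its merge with the parent block is forced in
    # the optimum (PAVA argument); arbitrary merge order is not exact here.
    while True:
        worst = None
        for node, _, _, _ in stats:
            par = parent_of.get(node)
            if par is None:
                continue
            ci, pi = block[node], block[par]
            if ci != pi and blocks[ci][0] > blocks[pi][0] + 1e-15:
                if worst is None or blocks[ci][0] > blocks[worst[0]][0]:
                    worst = (ci, pi)
        if worst is None:
            break
        merge(*worst)

    heights = {}
    for node, tipset, _, _ in stats:
        heights[tipset] = max(blocks[block[node]][0], 0.0)
        node.height = heights[tipset]
    return ClockHeights(tree=tree, heights=heights)


def date_nodes(
    heights: ClockHeights,
    rates: dict[str, PerYearRateInterval],
    nodes: dict[str, list[str]],
) -> pd.DataFrame:
    """Convert node heights to age intervals in Ma.

    ``nodes`` maps a display name to member tip labels (the node is their
    LCA); ``rates`` maps the same names to per-year rate intervals (a
    ``"default"`` entry applies to unlisted nodes).  Ages: t_fast = h/fast,
    t_slow = h/slow, in Ma.
    """
    rows = []
    for name, members in nodes.items():
        r = rates.get(name, rates.get("default"))
        if r is None:
            raise KeyError(f"no rate interval for node {name!r} and no default")
        if r.fast <= 0 or r.slow <= 0:
            raise ValueError(f"zero rate for node {name!r}")
        h = heights.height_of(members)
        rows.append(
            {
                "node": name,
                "h_subs_per_site": h,
                "gbar": r.gbar,
                "rate_fast": r.fast,
                "rate_slow": r.slow,
                "t_fast": h / r.fast / 1e6,
                "t_slow": h / r.slow / 1e6,
            }
        )
    df = pd.DataFrame(rows)
    return df


def reproduce_interval_table(table: pd.DataFrame) -> pd.DataFrame:
    """Audit a printed rate/age interval table via t·r conservation.

    For each row the upper age endpoint is recomputed from the lower one
    and the two rates (t_slow = t_fast · rate_fast / rate_slow), and the
    relative discrepancy of the conservation identity
    t_fast·rate_fast = t_slow·rate_slow is reported.
    """
    out = table.copy()
    out["t_slow_recomputed"] = out["t_fast"] * out["rate_fast"] / out["rate_slow"]
    out["conservation_rel_err"] = (
        out["t_fast"] * out["rate_fast"] - out["t_slow"] * out["rate_slow"]
    ).abs() / (out["t_fast"] * out["rate_fast"])
    out["agrees_2dp"] = (out["t_slow_recomputed"].round(2) - out["t_slow"]).abs() < 5e-3
    return out
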