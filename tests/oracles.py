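"""Independent oracles used by the test suite.

Kept deliberately separate from the package: brute-force or enumeration
implementations that the fast code paths are checked against.
"""

from __future__ import annotations

import numpy as np
import dendropy


def random_rooted_tree(rng, ntips: int) -> tuple[dendropy.Tree, list[str]]:
    """Random rooted binary topology over ntips labelled tips."""
    labels = [f"t{i}" for i in range(ntips)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[max(i, j)], nodes[min(i, j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for n in nodes if n not in (a, b)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    return tree, labels


def _tree_problem(tree, d):
    """Targets (mean d/2 per LCA), pair weights, constraint edges."""
    internals = list(tree.postorder_internal_node_iter())
    idx = {nd: k for k, nd in enumerate(internals)}
    tipsets = {}
    pairs, target, weight = [], {}, {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            tipsets[nd] = {nd.taxon.label}
            continue
        kids = nd.child_nodes()
        tipsets[nd] = set().union(*(tipsets[k] for k in kids))
        tot, cnt = 0.0, 0
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for ti in tipsets[kids[a]]:
                    for tj in tipsets[kids[b]]:
                        pairs.append((idx[nd], d.at[ti, tj]))
                        tot += d.at[ti, tj]
                        cnt += 1
        target[idx[nd]] = tot / (2 * cnt)
        weight[idx[nd]] = cnt
    edges = [
        (idx[nd], idx[nd.parent_node])
        for nd in internals
        if nd.parent_node is not None
    ]
    return internals, idx, tipsets, pairs, edges, target, weight


def exact_clock_heights(tree, d) -> dict:
    """Exact constrained least-squares node heights by active-set enumeration.

    The optimum merges nodes into blocks (active child=parent constraints)
    with blockwise weighted-mean values, possibly clamped at zero; every
    candidate active set is enumerated (feasible for <= ~7 tips) and the
    feasible candidate with least squared error is returned, keyed by the
    node's tip-label frozenset.
    """
    internals, idx, tipsets, pairs, edges, target, weight = _tree_problem(tree, d)
    n = len(internals)

    def sse(h):
        return sum((dij - 2 * h[k]) ** 2 for k, dij in pairs)

    best = None
    for mask in range(1 << len(edges)):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e, (c, p) in enumerate(edges):
            if mask >> e & 1:
                parent[find(c)] = find(p)
        groups = {}
        for k in range(n):
            groups.setdefault(find(k), []).append(k)
        glist = list(groups.values())
        for zmask in range(1 << len(glist)):
            h = np.zeros(n)
            for gi, members in enumerate(glist):
                if zmask >> gi & 1:
                    val = 0.0
                else:
                    wsum = sum(weight[m] for m in members)
                    val = sum(weight[m] * target[m] for m in members) / wsum
                for m in members:
                    h[m] = val
            feasible = all(h[p] >= h[c] - 1e-12 for c, p in edges) and (
                h >= -1e-12
            ).all()
            if feasible:
                val = sse(h)
                if best is None or val < best[0]:
                    best = (val, h.copy())
    return {frozenset(tipsets[nd]): best[1][idx[nd]] for nd in internals}


def normal_equations_quadratic(m, g):
    """Direct solve of the 3x3 normal equations for g = a + b m + c m²."""
    m = np.asarray(m, float)
    g = np.asarray(g, float)
    X = np.column_stack([np.ones_like(m), m, m**2])
    return np.linalg.solve(X.T @ X, X.T @ g)
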