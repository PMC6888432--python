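"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the likelihood oracle
enumerates ancestral states explicitly instead of pruning, and the Ward
oracle recomputes every cluster-pair distance from scratch via the
error-sum-of-squares closed form instead of the incremental Lance-Williams
update.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from evoscape._jtt import AA_ORDER
from evoscape.formats_io import PhyloTree
from evoscape.site_rates import SubstitutionModel


def enumeration_likelihood(tree: PhyloTree, model: SubstitutionModel,
                           rate: float, leaf_chars: dict[str, str]) -> float:
    """Column likelihood by explicit summation over ancestral-state
    assignments: sum over all joint states of pi(root) * prod P(parent,child).

    Leaves with gap/'X' are marginalized like internal nodes.
    """
    free = [n for n in range(tree.n_nodes) if tree.children[n]]
    fixed: dict[int, int] = {}
    for leaf in tree.leaves:
        ch = leaf_chars[tree.labels[leaf]]
        i = AA_ORDER.find(ch)
        if i < 0:  # gap or X: marginalize
            free.append(leaf)
        else:
            fixed[leaf] = i
    m = len(free)
    # all 20^m joint assignments of the free nodes
    grids = np.meshgrid(*([np.arange(20)] * m), indexing="ij")
    assign = np.stack([g.ravel() for g in grids], axis=1)  # (20^m, m)
    pos = {n: k for k, n in enumerate(free)}

    def state_of(node: int) -> np.ndarray:
        if node in fixed:
            return np.full(len(assign), fixed[node])
        return assign[:, pos[node]]

    prob = model.pi[state_of(tree.root)].astype(float).copy()
    for node in range(tree.n_nodes):
        if node == tree.root:
            continue
        P = model.transition_matrix(tree.lengths[node] * rate)
        prob *= P[state_of(tree.parent[node]), state_of(node)]
    return float(prob.sum())


def ward_oracle_linkage(D0: np.ndarray) -> np.ndarray:
    """Greedy Ward agglomeration with from-scratch cluster distances.

    The distance between clusters A and B is the error-sum-of-squares merge
    cost evaluated directly on the original dissimilarities (scaled so that
    singleton pairs equal d), with the same lowest-index tie-break as the
    implementation. Returns a (n-1, 4) linkage matrix.
    """
    n = len(D0)
    clusters = {i: frozenset([i]) for i in range(n)}
    next_id = n
    Z = []

    def dist(A: frozenset, B: frozenset) -> float:
        SA = sum(D0[a, a2] for a in A for a2 in A)
        SB = sum(D0[b, b2] for b in B for b2 in B)
        SAB = sum(D0[a, b] for a in A for b in B)
        na, nb = len(A), len(B)
        return na * nb / (na + nb) * (
            2 * SAB / (na * nb) - SA / na ** 2 - SB / nb ** 2)

    while len(clusters) > 1:
        best = None
        for i, j in combinations(sorted(clusters), 2):
            d = dist(clusters[i], clusters[j])
            if best is None or (d, i, j) < best:
                best = (d, i, j)
        d, i, j = best
        Z.append((i, j, d, len(clusters[i]) + len(clusters[j])))
        clusters[next_id] = clusters.pop(i) | clusters.pop(j)
        next_id += 1
    return np.array(Z)
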