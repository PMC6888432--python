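"""Order/disorder track integration with the alignment and rate comparison.

Per-residue disorder scores (IUPred-style, 0 = ordered, 1 = disordered, cutoff
0.5) are spread over the alignment's non-gap cells and ordered by the tree's
ladderized leaf order, giving the heat-map matrix that shows how the
order-disorder architecture tracks the phylogeny. Per-column consensus calls
and the per-residue rate Z scores then split residues into ordered,
constrained-disorder (disordered, slower than average) and flexible-disorder
(disordered, faster than average) categories, and the ordered vs disordered
rate distributions are compared with a Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import GAP, AnnotationTrack, ConsistencyError, MultipleAlignment, PhyloTree

__all__ = [
    "DISORDER_CUTOFF",
    "DisorderMatrix",
    "ResidueClassification",
    "build_disorder_matrix",
    "call_disorder",
    "consensus_structure",
    "classify_residues",
    "mann_whitney",
    "compare_rate_distributions",
]

#: Score at or above which a residue counts as disordered.
DISORDER_CUTOFF = 0.5


@dataclass
class DisorderMatrix:
    """(n_taxa, L) disorder scores in tree leaf order; gap cells are masked."""

    taxa: list[str]  # ladderized tree leaf order
    scores: np.ma.MaskedArray

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores.filled(np.nan), index=self.taxa,
                          columns=range(1, self.scores.shape[1] + 1))
        df.index.name = "taxon"
        return df


def build_disorder_matrix(aln: MultipleAlignment,
                          tracks: dict[str, AnnotationTrack],
                          tree: PhyloTree) -> DisorderMatrix:
    """Spread each taxon's per-residue scores across its alignment row.

    Rows follow the tree's ladderized leaf order so the matrix reads as a
    phylogeny-ordered heat map; cells where the alignment has a gap are
    masked. Tracks are keyed by id, so their input order is irrelevant.
    """
    order = tree.ladderized_leaf_order()
    if set(order) != set(aln.taxa):
        raise ConsistencyError("tree leaves and alignment taxa differ")
    missing = [t for t in order if t not in tracks]
    if missing:
        raise ConsistencyError(f"no disorder track for taxa: {missing}")
    L = aln.length
    data = np.zeros((len(order), L))
    mask = np.ones((len(order), L), dtype=bool)
    for i, taxon in enumerate(order):
        row = aln.row(taxon)
        track = tracks[taxon]
        if len(track) != len(row) - row.count(GAP):
            raise ConsistencyError(
                f"track length {len(track)} != ungapped length of {taxon!r}")
        j = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                data[i, c] = track.scores[j]
                mask[i, c] = False
                j += 1
    return DisorderMatrix(taxa=order, scores=np.ma.MaskedArray(data, mask=mask))


def call_disorder(scores: np.ndarray, cutoff: float = DISORDER_CUTOFF) -> np.ndarray:
    """Binary disorder call per residue: disordered iff score >= cutoff.

    The boundary value counts as disordered (inclusive convention).
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("disorder scores must lie in [0, 1]")
    return scores >= cutoff


def consensus_structure(matrix: DisorderMatrix, column: int,
                        cutoff: float = DISORDER_CUTOFF,
                        majority: float = 0.5) -> str:
    """Per-column consensus call over non-masked cells.

    'disordered' iff at least ``majority`` of the taxa with a residue in the
    column score >= cutoff (boundary inclusive); 'no_data' if the column is
    entirely gaps.
    """
    col = matrix.scores[:, column - 1]
    vals = col.compressed()
    if len(vals) == 0:
        return "no_data"
    frac = float(np.mean(vals >= cutoff))
    return "disordered" if frac >= majority else "ordered"


@dataclass
class ResidueClassification:
    """Per-reference-residue structure/evolution categories.

    category is 'ordered' for ordered residues and, for disordered ones,
    'constrained_disorder' (Z < 0, slower than average) or
    'flexible_disorder' (Z >= 0).
    """

    table: pd.DataFrame  # pos, structure, z, category

    def category_of(self, pos: int) -> str:
        sel = self.table.loc[self.table["pos"] == pos, "category"]
        if sel.empty:
            raise KeyError(f"no classification for residue {pos}")
        return sel.iloc[0]


def classify_residues(structure: pd.Series | dict[int, str],
                      z: pd.Series | dict[int, float]) -> ResidueClassification:
    """Combine per-residue consensus structure with rate Z scores.

    Both inputs are keyed by 1-based reference position. Slow means Z < 0.
    Residues whose structure is 'no_data' or whose Z is NaN keep category
    'no_data'.
    """
    s = pd.Series(structure)
    zz = pd.Series(z, dtype=float)
    if not s.index.equals(zz.index):
        if set(s.index) != set(zz.index):
            raise ConsistencyError("structure and Z tables cover different residues")
        zz = zz.reindex(s.index)
    rows = []
    for pos in s.index:
        struct, zv = s[pos], zz[pos]
        evo = "no_data" if np.isnan(zv) else ("slow" if zv < 0 else "fast")
        if struct == "no_data" or np.isnan(zv):
            cat = "no_data"
        elif struct == "ordered":
            cat = "ordered"
        else:
            cat = "constrained_disorder" if zv < 0 else "flexible_disorder"
        rows.append((int(pos), struct, zv, evo, cat))
    return ResidueClassification(
        pd.DataFrame(rows, columns=["pos", "structure", "z", "evolution", "category"]))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all label assignments.

    Handles ties (U computed from midranks). The two-sided p-value is the
    probability, over all C(n+m, n) assignments, that min(U, nm-U) is at most
    the observed min.
    """
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    stat_obs = min(u_obs, n * m - u_obs)
    hits = 0
    total = comb(n + m, n)
    idx = np.arange(n + m)
    for group in combinations(idx, n):
        u = float(ranks[list(group)].sum() - n * (n + 1) / 2)
        if min(u, n * m - u) <= stat_obs + 1e-9:
            hits += 1
    return u_obs, hits / total


def mann_whitney(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Uses exact enumeration when both samples have at most ``exact_max_n``
    observations, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        return _exact_mannwhitney(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_rate_distributions(z: np.ndarray, structure: np.ndarray) -> dict:
    """Compare rate Z scores between ordered and disordered residues.

    ``structure`` holds 'ordered'/'disordered' labels aligned with ``z``;
    other labels (no_data) are dropped. Returns the U statistic of the
    disordered group, the two-sided p-value and the group medians.
    """
    z = np.asarray(z, dtype=float)
    structure = np.asarray(structure)
    dis = z[(structure == "disordered") & ~np.isnan(z)]
    orde = z[(structure == "ordered") & ~np.isnan(z)]
    if len(dis) == 0 or len(orde) == 0:
        raise ValueError("need both ordered and disordered residues to compare")
    u, p = mann_whitney(dis, orde)
    return {
        "U": u,
        "p_value": p,
        "n_disordered": int(len(dis)),
        "n_ordered": int(len(orde)),
        "median_disordered": float(np.median(dis)),
        "median_ordered": float(np.median(orde)),
    }
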