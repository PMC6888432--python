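"""Phosphosite calling and majority-rule conservation across an alignment.

Phosphorylation-propensity tracks (NetPhos-style, one score in [0,1] per
residue) are thresholded at 0.75 on S/T/Y residues to give per-sequence site
calls; an alignment column is a conserved site when at least half of the
sequences in the alignment carry a positive call there (gapped sequences
count in the denominator by default, taken literally from the "amount of
sequence in the alignment" rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import GAP, AnnotationTrack, ConsistencyError, MultipleAlignment, build_column_map

__all__ = [
    "PTM_CUTOFF",
    "MAJORITY_THRESHOLD",
    "PHOSPHO_RESIDUES",
    "PtmCallSet",
    "call_sites",
    "conserved_columns",
]

PTM_CUTOFF = 0.75
MAJORITY_THRESHOLD = 0.5
PHOSPHO_RESIDUES = frozenset("STY")


def call_sites(track: AnnotationTrack, sequence: str,
               cutoff: float = PTM_CUTOFF) -> set[int]:
    """Positive phosphosite positions (1-based, ungapped) for one sequence.

    A residue is positive when its score is at or above the cutoff and the
    residue is phospho-acceptor S, T or Y.
    """
    seq = sequence.replace(GAP, "")
    if len(track) != len(seq):
        raise ConsistencyError(
            f"track length {len(track)} != sequence length {len(seq)}")
    return {
        i + 1
        for i, (s, ch) in enumerate(zip(track.scores, seq))
        if s >= cutoff and ch in PHOSPHO_RESIDUES
    }


@dataclass
class PtmCallSet:
    """Per-sequence calls, per-column conservation flags and the reference-
    coordinate summary table."""

    calls: dict[str, set[int]]          # taxon -> positive ungapped positions
    conserved_cols: list[int]           # 1-based alignment columns
    table: pd.DataFrame                 # ref_pos, residue, human_score, fraction_positive, conserved
    conserved_ref_positions: list[int]
    conserved_nonref_cols: list[int]    # conserved columns gapped in the reference


def conserved_columns(aln: MultipleAlignment,
                      tracks: dict[str, AnnotationTrack],
                      cutoff: float = PTM_CUTOFF,
                      majority: float = MAJORITY_THRESHOLD,
                      denominator: str = "all",
                      require_reference_positive: bool = True) -> PtmCallSet:
    """Majority-rule conserved phosphosites over the alignment.

    A column is conserved when the fraction of positive sequences reaches
    ``majority`` (inclusive). With ``denominator="all"`` every sequence in the
    alignment counts (a gap is a negative); ``denominator="non_gap"`` divides
    by the sequences that actually have a residue in the column. With
    ``require_reference_positive`` the reference-coordinate report keeps only
    conserved columns where the reference itself is positive (the "conserved
    human sites" framing); columns gapped in the reference are reported
    separately either way.
    """
    if denominator not in {"all", "non_gap"}:
        raise ValueError("denominator must be 'all' or 'non_gap'")
    missing = [t for t in aln.taxa if t not in tracks]
    if missing:
        raise ConsistencyError(f"no phospho track for taxa: {missing}")

    calls = {t: call_sites(tracks[t], aln.row(t), cutoff) for t in aln.taxa}

    # per-taxon map from alignment column to ungapped position
    L = aln.length
    positive = np.zeros((aln.n_taxa, L), dtype=bool)
    non_gap = np.zeros((aln.n_taxa, L), dtype=bool)
    for i, t in enumerate(aln.taxa):
        row = aln.row(t)
        pos = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                pos += 1
                non_gap[i, c] = True
                if pos in calls[t]:
                    positive[i, c] = True

    n_pos = positive.sum(axis=0)
    denom = np.full(L, aln.n_taxa) if denominator == "all" else non_gap.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, n_pos / np.maximum(denom, 1), 0.0)
    conserved = frac >= majority

    cmap = build_column_map(aln)
    refseq = aln.ungapped(aln.reference_id)
    ref_calls = calls[aln.reference_id]

    rows = []
    conserved_ref, conserved_nonref = [], []
    ref_track = tracks[aln.reference_id]
    for c in range(1, L + 1):
        if not conserved[c - 1]:
            continue
        res = cmap.residue_of(c)
        if res is None:
            conserved_nonref.append(c)
        elif not require_reference_positive or res in ref_calls:
            conserved_ref.append(res)
    for res in sorted(set(ref_calls) | set(conserved_ref)):
        c = cmap.column_of(res)
        rows.append((res, refseq[res - 1], float(ref_track.scores[res - 1]),
                     float(frac[c - 1]), bool(conserved[c - 1])))
    table = pd.DataFrame(
        rows, columns=["ref_pos", "residue", "human_score",
                       "fraction_positive", "conserved"])
    return PtmCallSet(
        calls=calls,
        conserved_cols=[c for c in range(1, L + 1) if conserved[c - 1]],
        table=table,
        conserved_ref_positions=conserved_ref,
        conserved_nonref_cols=conserved_nonref,
    )
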