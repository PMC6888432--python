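"""Readers, writers and coordinate bookkeeping for the pipeline's file formats.

All residue and alignment-column coordinates are 1-based throughout the
package, matching protein mutation nomenclature (e.g. Ser346Arg). Every TSV
writer emits a leading ``#`` comment line recording the package version and
the parameters used; readers skip ``#`` lines.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "FormatError",
    "ConsistencyError",
    "MultipleAlignment",
    "PhyloTree",
    "AnnotationTrack",
    "ColumnMap",
    "VariantRecord",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "build_column_map",
    "read_track",
    "write_track",
    "read_variants",
    "write_variants",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = set(AMINO_ACIDS) | {"X", "-"}

GAP = "-"


class FormatError(ValueError):
    """Malformed input file."""


class ConsistencyError(ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


def _comment_header(**params) -> str:
    from evoscape import __version__

    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# evoscape v{__version__}" + (f" {kv}" if kv else "")


# ---------------------------------------------------------------------------
# Multiple sequence alignment
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    """A gapped amino-acid alignment with a designated reference sequence.

    Rows are equal-length strings over the 20 amino acids, ``X`` (unknown
    residue, treated as missing data) and ``-`` (gap). ``reference_id`` names
    the row onto which per-residue results are projected (the human sequence
    in the study design this package supports).
    """

    taxa: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.taxa:
            raise FormatError("alignment has no sequences")
        if len(self.taxa) != len(set(self.taxa)):
            raise FormatError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows (lengths {sorted(lengths)})")
        if self.length < 1:
            raise FormatError("alignment of length 0")
        if self.reference_id not in self.taxa:
            raise KeyError(f"reference sequence {self.reference_id!r} not in alignment")
        for t, r in zip(self.taxa, self.rows):
            bad = set(r) - _VALID_CHARS
            if bad:
                raise FormatError(f"invalid characters {sorted(bad)} in sequence {t!r}")
            if set(r) == {GAP}:
                raise FormatError(f"sequence {t!r} is all gaps")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    @property
    def reference_row(self) -> str:
        return self.row(self.reference_id)

    def ungapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    def observed_frequencies(self) -> np.ndarray:
        """Amino-acid frequencies over all rows; gaps and X excluded.

        Used by the ``jtt+f`` model variant. Zero counts get a small
        pseudo-count so the stationary distribution stays strictly positive.
        """
        counts = np.zeros(20)
        idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
        for r in self.rows:
            for ch in r:
                if ch in idx:
                    counts[idx[ch]] += 1
        counts = np.maximum(counts, 0.5)
        return counts / counts.sum()


def read_alignment(path: str | Path, reference_id: str) -> MultipleAlignment:
    """Read an aligned FASTA file; uppercases residues and normalizes '.' to '-'."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no sequences found in {path}")
    taxa = [r.id for r in records]
    rows = [str(r.seq).upper().replace(".", GAP) for r in records]
    return MultipleAlignment(taxa=taxa, rows=rows, reference_id=reference_id)


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{r}\n")


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted tree with branch lengths, stored as flat parent/child arrays.

    Node ids are 0..n_nodes-1 with the root last in ``postorder``. Leaves
    carry labels; internal nodes have ``label`` None. Branch lengths are in
    expected substitutions per site. A basal multifurcation (unrooted-style
    Newick) is accepted as-is: under reversible models the likelihood does
    not depend on root placement.
    """

    def __init__(self, parent: Sequence[int], lengths: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.lengths) == len(self.labels) == n):
            raise ValueError("parent/lengths/labels length mismatch")
        if np.any(~np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise FormatError("branch lengths must be finite and non-negative")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise FormatError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        leaf_labels = [l for i, l in enumerate(self.labels) if not self.children[i]]
        if any(l is None for l in leaf_labels):
            raise FormatError("every leaf must be labeled")
        if len(leaf_labels) != len(set(leaf_labels)):
            raise FormatError("duplicate leaf labels in tree")
        self.postorder = self._postorder()

    def _postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    def ladderized_leaf_order(self) -> list[str]:
        """Leaf labels in ladderized order (small subtrees first).

        Deterministic for a fixed input: ties between equal-size subtrees are
        broken by the lexicographically smallest leaf label they contain.
        """
        n_desc: dict[int, int] = {}
        min_label: dict[int, str] = {}
        for node in self.postorder:
            kids = self.children[node]
            if not kids:
                n_desc[node] = 1
                min_label[node] = self.labels[node]
            else:
                n_desc[node] = sum(n_desc[k] for k in kids)
                min_label[node] = min(min_label[k] for k in kids)

        out: list[str] = []

        def visit(node: int) -> None:
            kids = self.children[node]
            if not kids:
                out.append(self.labels[node])
                return
            for k in sorted(kids, key=lambda c: (n_desc[c], min_label[c])):
                visit(k)

        visit(self.root)
        return out

    # -- Newick I/O (via dendropy) ------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        missing_lengths = 0
        for nd in nodes:
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            if nd.edge.length is None:
                missing_lengths += int(nd.parent_node is not None)
                lengths.append(0.0)
            else:
                lengths.append(float(nd.edge.length))
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon else nd.label
                labels.append(lab)
            else:
                labels.append(None)
        if missing_lengths:
            warnings.warn(
                f"{missing_lengths} branch length(s) missing in Newick input; "
                "defaulting to 0", stacklevel=3)
        return cls(parent, lengths, labels)

    @classmethod
    def from_newick_string(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True)
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"could not parse Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if not self.children[node]:
                body = self.labels[node]
            else:
                body = "(" + ",".join(fmt(k) for k in self.children[node]) + ")"
            if node == self.root:
                return body
            return f"{body}:{self.lengths[node]:.10g}"

        return fmt(self.root) + ";"


def read_newick(path: str | Path) -> PhyloTree:
    """Read a single-tree Newick file.

    Missing branch lengths default to 0 with a warning. An unrooted
    (trifurcating-root) tree is accepted without rerooting.
    """
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"empty Newick file: {path}")
    return PhyloTree.from_newick_string(text)


# ---------------------------------------------------------------------------
# Alignment-column <-> reference-residue coordinate map
# ---------------------------------------------------------------------------

@dataclass
class ColumnMap:
    """Bijection between non-gap reference columns and reference residues.

    ``column_to_residue[c]`` (1-based column) is the 1-based residue index in
    the reference sequence, or None where the reference row has a gap.
    """

    column_to_residue: list[int | None]
    residue_to_column: dict[int, int]

    def residue_of(self, column: int) -> int | None:
        return self.column_to_residue[column - 1]

    def column_of(self, residue: int) -> int:
        return self.residue_to_column[residue]

    @property
    def n_residues(self) -> int:
        return len(self.residue_to_column)


def build_column_map(aln: MultipleAlignment) -> ColumnMap:
    col_to_res: list[int | None] = []
    res_to_col: dict[int, int] = {}
    res = 0
    for c, ch in enumerate(aln.reference_row, start=1):
        if ch == GAP:
            col_to_res.append(None)
        else:
            res += 1
            col_to_res.append(res)
            res_to_col[res] = c
    return ColumnMap(col_to_res, res_to_col)


# ---------------------------------------------------------------------------
# Per-residue score tracks (disorder / phospho propensity)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTrack:
    """Per-residue scores in [0,1] for one ungapped sequence."""

    sequence_id: str
    kind: str  # "disorder" or "phospho"
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("track scores must be a 1-D vector")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError(
                f"track scores for {self.sequence_id!r} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


def read_track(path: str | Path, aln: MultipleAlignment,
               kind: str = "disorder") -> dict[str, AnnotationTrack]:
    """Read a TSV score track (``seq_id<TAB>pos<TAB>score``) into dense tracks.

    Positions are 1-based over each sequence's ungapped residues; every
    residue must appear exactly once and scores must lie in [0,1].
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["seq_id", "pos", "score"]
    if list(df.columns[:3]) != expected:
        raise FormatError(
            f"track file must have columns {expected}, got {list(df.columns)}")
    tracks: dict[str, AnnotationTrack] = {}
    for seq_id, grp in df.groupby("seq_id", sort=False):
        if seq_id not in aln.taxa:
            raise ConsistencyError(f"track sequence {seq_id!r} not in alignment")
        n = len(aln.ungapped(seq_id))
        pos = grp["pos"].to_numpy()
        if len(pos) != n or sorted(pos) != list(range(1, n + 1)):
            raise FormatError(
                f"track for {seq_id!r} must cover positions 1..{n} exactly once")
        scores = np.empty(n)
        scores[pos - 1] = grp["score"].to_numpy()
        if np.any(scores < 0) or np.any(scores > 1):
            raise ValueError(f"track score outside [0, 1] for {seq_id!r}")
        tracks[seq_id] = AnnotationTrack(seq_id, kind, scores)
    return tracks


def write_track(tracks: Iterable[AnnotationTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        tracks = list(tracks)
        kinds = ",".join(sorted({t.kind for t in tracks}))
        fh.write(_comment_header(kind=kinds, coords="1-based") + "\n")
        fh.write("seq_id\tpos\tscore\n")
        for t in tracks:
            for i, s in enumerate(t.scores, start=1):
                fh.write(f"{t.sequence_id}\t{i}\t{s:.6g}\n")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One missense variant on reference coordinates."""

    protein: str
    position: int  # 1-based residue index in the reference sequence
    ref_aa: str
    alt_aa: str
    n_cases: int
    pathogenicity: str


@dataclass
class VariantReadReport:
    """Accepted records plus per-row rejection reasons."""

    records: list[VariantRecord]
    rejected: list[str] = field(default_factory=list)


DEFAULT_PATHOGENIC_LABELS = frozenset({"pathogenic"})


def read_variants(path: str | Path, aln: MultipleAlignment,
                  allowed_labels: frozenset[str] | set[str] = DEFAULT_PATHOGENIC_LABELS,
                  ) -> VariantReadReport:
    """Read a variant TSV, keeping rows with an allowed pathogenicity label
    whose reference amino acid matches the alignment's reference sequence.

    Rows failing validation (position out of range, ref mismatch) are not
    fatal: they are collected in the report's ``rejected`` list.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"protein": str, "ref": str, "alt": str, "label": str})
    expected = ["protein", "pos", "ref", "alt", "n_cases", "label"]
    if list(df.columns) != expected:
        raise FormatError(
            f"variant file must have columns {expected}, got {list(df.columns)}")
    refseq = aln.ungapped(aln.reference_id)
    report = VariantReadReport(records=[])
    for row in df.itertuples(index=False):
        if row.label not in allowed_labels:
            continue
        pos = int(row.pos)
        if not (1 <= pos <= len(refseq)):
            report.rejected.append(
                f"{row.protein} pos {pos}: outside reference length {len(refseq)}")
            continue
        if refseq[pos - 1] != row.ref:
            report.rejected.append(
                f"{row.protein} pos {pos}: ref {row.ref!r} != reference "
                f"residue {refseq[pos - 1]!r}")
            continue
        report.records.append(VariantRecord(
            protein=row.protein, position=pos, ref_aa=row.ref, alt_aa=row.alt,
            n_cases=int(row.n_cases), pathogenicity=row.label))
    return report


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(coords="1-based") + "\n")
        fh.write("protein\tpos\tref\talt\tn_cases\tlabel\n")
        for v in records:
            fh.write(f"{v.protein}\t{v.position}\t{v.ref_aa}\t{v.alt_aa}\t"
                     f"{v.n_cases}\t{v.pathogenicity}\n")
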