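"""Synthetic input bundles with known ground truth for every pipeline stage.

The generator emulates the study conditions the pipeline was designed for: a
few dozen chordate orthologs of a human reference protein evolving under
JTT + discrete gamma on a Yule tree, an ordered/disordered block architecture
whose disordered blocks evolve faster, NetPhos-style phospho tracks with
planted conserved sites, RettBASE-style pathogenic missense variants enriched
in domains, KEGG-OC-style presence/absence profiles with four planted
taxonomic-depth classes, and an HPA-style TPM table over 37 tissues with
spiked tissue-specific proteins. Every stage draws from its own substream of
one global seed, so outputs are bit-reproducible and stages can be
regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._jtt import AA_ORDER
from .formats_io import (
    AnnotationTrack,
    MultipleAlignment,
    PhyloTree,
    write_alignment,
    write_track,
    write_variants,
    VariantRecord,
)
from .phyloprofiling import DEFAULT_TAXONOMY_ORDER, PhyloProfileMatrix
from .site_rates import GammaCategories, SubstitutionModel, jtt_model

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_alignment",
    "simulate_disorder_tracks",
    "simulate_ptm",
    "simulate_profiles",
    "simulate_expression",
    "simulate_variants",
    "simulate_bundle",
]

_STAGES = ("tree", "alignment", "disorder", "ptm", "profiles",
           "expression", "variants")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle (one stage per field group)."""

    seed: int = 0
    reference_id: str = "human"

    # tree + alignment
    n_taxa: int = 24
    n_sites: int = 300
    alpha: float = 0.5
    K: int = 16
    branch_length_mean: float = 0.1  # substitutions/site, exponential
    gap_fraction: float = 0.0

    # disorder architecture; blocks must sum to n_sites
    disorder_blocks: list[tuple[int, str]] = field(default_factory=list)
    disorder_rate_multiplier: float = 3.0  # disordered blocks evolve faster
    ordered_beta: tuple[float, float] = (2.0, 8.0)
    disordered_beta: tuple[float, float] = (8.0, 2.0)

    # phosphosites
    n_ptm_conserved: int = 6
    n_ptm_nonconserved: int = 4
    f_conserved: float = 0.9
    f_nonconserved: float = 0.3

    # phylogenetic profiles
    # species counts per narrowest group: chordates, other metazoans, other
    # multicellular, unicellular eukaryotes. Each nesting level is well under
    # half of the next broader one, as in real eukaryote samplings, so the
    # depth-labeling rule can discriminate the four classes.
    profile_class_sizes: tuple[int, ...] = (15, 15, 15, 15)
    species_per_group: tuple[int, ...] = (12, 18, 40, 90)
    flip_noise: float = 0.05

    # expression
    n_expr_proteins: int = 200
    n_tissues: int = 37
    n_spiked: int = 9
    spike_fold: float = 50.0
    spike_tissue: str = "cerebral_cortex"

    # variants
    n_variants: int = 18
    n_benign: int = 10
    domain_enrichment: float = 4.0

    def __post_init__(self) -> None:
        if not self.disorder_blocks:
            # one-fifth granularity: ordered/disordered/ordered/disordered
            n = self.n_sites
            a, b, c = n // 5, (3 * n) // 10, n // 4
            self.disorder_blocks = [
                (a, "ordered"), (b, "disordered"),
                (c, "ordered"), (n - a - b - c, "disordered"),
            ]
        if sum(l for l, _ in self.disorder_blocks) != self.n_sites:
            raise ValueError("disorder block lengths must sum to n_sites")
        if self.n_taxa < 2:
            raise ValueError("need at least two taxa")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent substream per stage, all derived from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(_STAGES.index(stage),)))

    @property
    def taxa(self) -> list[str]:
        width = len(str(self.n_taxa))
        return [self.reference_id] + [
            f"sp{i:0{width}d}" for i in range(2, self.n_taxa + 1)]


# ---------------------------------------------------------------------------
# Tree and alignment
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, branch_length_mean: float,
                  rng: np.random.Generator,
                  labels: list[str] | None = None) -> PhyloTree:
    """Yule-process topology with i.i.d. exponential branch lengths.

    Starting from a cherry, a uniformly chosen leaf is split until ``n_taxa``
    leaves exist; every edge then gets an independent Exponential draw with
    the stated mean.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    if labels is None:
        labels = [f"t{i}" for i in range(1, n_taxa + 1)]
    # children-list representation; node 0 is the root
    children: list[list[int]] = [[1, 2], [], []]
    leaves = [1, 2]
    while len(leaves) < n_taxa:
        pick = int(rng.integers(len(leaves)))
        node = leaves.pop(pick)
        a, b = len(children), len(children) + 1
        children[node] = [a, b]
        children.append([])
        children.append([])
        leaves.extend([a, b])
    parent = [-1] * len(children)
    for p, kids in enumerate(children):
        for k in kids:
            parent[k] = p
    lengths = rng.exponential(branch_length_mean, size=len(children))
    lengths[0] = 0.0
    node_labels: list[str | None] = [None] * len(children)
    for lab, leaf in zip(labels, leaves):
        node_labels[leaf] = lab
    return PhyloTree(parent, lengths, node_labels)


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel,
                       gamma: GammaCategories, n_sites: int,
                       rng: np.random.Generator,
                       reference_id: str | None = None,
                       rate_multipliers: np.ndarray | None = None,
                       gap_fraction: float = 0.0,
                       ) -> tuple[MultipleAlignment, np.ndarray]:
    """Evolve ``n_sites`` independent columns down the tree.

    Each site draws a uniform gamma category; its rate is the category rate
    times an optional per-site multiplier (used to make disordered blocks
    evolve faster). Returns the alignment and the true per-site rates.
    With ``gap_fraction`` > 0, non-reference cells are masked to '-' i.i.d.
    at that rate (keeping at least one residue per row and per column).
    """
    if rate_multipliers is None:
        rate_multipliers = np.ones(n_sites)
    if len(rate_multipliers) != n_sites:
        raise ValueError("rate_multipliers length must equal n_sites")
    cats = rng.integers(gamma.K, size=n_sites)
    true_rates = gamma.rates[cats] * rate_multipliers

    states = np.empty((tree.n_nodes, n_sites), dtype=int)
    states[tree.root] = rng.choice(20, size=n_sites, p=model.pi)
    # preorder = reversed postorder
    for node in reversed(tree.postorder):
        if node == tree.root:
            continue
        t = tree.lengths[node]
        parent_states = states[tree.parent[node]]
        child = np.empty(n_sites, dtype=int)
        for k in np.unique(true_rates):
            sel = true_rates == k
            P = model.transition_matrix(t * float(k))
            cum = np.cumsum(P, axis=1)
            u = rng.random(int(sel.sum()))
            rowcum = cum[parent_states[sel]]
            child[sel] = np.minimum((u[:, None] > rowcum).sum(axis=1), 19)
        states[node] = child

    leaves = tree.leaves
    taxa = [tree.labels[i] for i in leaves]
    rows = ["".join(AA_ORDER[s] for s in states[i]) for i in leaves]
    ref = reference_id if reference_id is not None else taxa[0]
    if gap_fraction > 0:
        grid = rng.random((len(taxa), n_sites)) < gap_fraction
        grid[taxa.index(ref)] = False      # keep reference ungapped
        grid[:, grid.all(axis=0)] = False  # no all-gap columns
        rows = ["".join("-" if g else ch for g, ch in zip(gr, row))
                for gr, row in zip(grid, rows)]
    aln = MultipleAlignment(taxa=taxa, rows=rows, reference_id=ref)
    return aln, true_rates


# ---------------------------------------------------------------------------
# Disorder tracks
# ---------------------------------------------------------------------------

def simulate_disorder_tracks(aln: MultipleAlignment,
                             blocks: list[tuple[int, str]],
                             rng: np.random.Generator,
                             ordered_beta: tuple[float, float] = (2.0, 8.0),
                             disordered_beta: tuple[float, float] = (8.0, 2.0),
                             ) -> tuple[dict[str, AnnotationTrack], list[str]]:
    """Per-taxon IUPred-style tracks following a block architecture.

    Blocks are (length, regime) over the *reference* residues and must sum to
    the reference's ungapped length; ordered blocks draw Beta(2,8) scores
    (mean 0.2), disordered blocks Beta(8,2) (mean 0.8), independently per
    taxon and residue (the per-taxon jitter). Columns gapped in the reference
    inherit the regime of the nearest preceding reference residue. Returns
    the tracks and the true regime per reference residue.
    """
    ref_len = len(aln.ungapped(aln.reference_id))
    if sum(l for l, _ in blocks) != ref_len:
        raise ValueError("block lengths must sum to the reference length")
    regime_by_residue: list[str] = []
    for length, regime in blocks:
        if regime not in {"ordered", "disordered"}:
            raise ValueError(f"unknown regime {regime!r}")
        regime_by_residue.extend([regime] * length)

    # regime per alignment column (reference-gap columns borrow a neighbor)
    regime_by_col: list[str] = []
    res = 0
    for ch in aln.reference_row:
        if ch != "-":
            res += 1
        regime_by_col.append(regime_by_residue[max(res - 1, 0)])

    params = {"ordered": ordered_beta, "disordered": disordered_beta}
    tracks: dict[str, AnnotationTrack] = {}
    for taxon in aln.taxa:
        row = aln.row(taxon)
        scores = []
        for c, ch in enumerate(row):
            if ch == "-":
                continue
            a, b = params[regime_by_col[c]]
            scores.append(rng.beta(a, b))
        tracks[taxon] = AnnotationTrack(taxon, "disorder", np.array(scores))
    return tracks, regime_by_residue


def rate_multipliers_from_blocks(blocks: list[tuple[int, str]],
                                 disordered_multiplier: float) -> np.ndarray:
    """Per-site rate multipliers: 1 for ordered, the multiplier for disordered."""
    out: list[float] = []
    for length, regime in blocks:
        out.extend([disordered_multiplier if regime == "disordered" else 1.0]
                   * length)
    return np.array(out)


# ---------------------------------------------------------------------------
# Phosphosites
# ---------------------------------------------------------------------------

def simulate_ptm(aln: MultipleAlignment, sites: list[tuple[int, float]],
                 rng: np.random.Generator,
                 ) -> tuple[MultipleAlignment, dict[str, AnnotationTrack], dict[int, float]]:
    """Plant phosphosites at reference positions with given conservation.

    For each (reference position, conservation fraction f): a Binomial
    (n_taxa, f) subset of taxa — always including the reference — has its
    residue at that column set to 'S' with a phospho score drawn in
    [0.8, 1.0]; remaining taxa score low there. Background scores are
    Beta(2,6) (rarely above the 0.75 cutoff, and only counted on S/T/Y).
    Returns the (edited) alignment, the phospho tracks and the realized
    positive fraction per planted position.

    Editing the planted columns overrides the substitution process there;
    rate ground truth at those few columns is therefore not preserved.
    """
    from .formats_io import build_column_map

    cmap = build_column_map(aln)
    rows = [list(r) for r in aln.rows]
    n = aln.n_taxa
    ref_i = aln.taxa.index(aln.reference_id)
    high = {pos: set() for pos, _ in sites}
    realized: dict[int, float] = {}
    for pos, f in sites:
        col = cmap.column_of(pos) - 1
        chosen = {i for i in range(n) if rng.random() < f} | {ref_i}
        for i in chosen:
            rows[i][col] = "S"
        high[pos] = chosen
        realized[pos] = len(chosen) / n
    edited = MultipleAlignment(
        taxa=list(aln.taxa), rows=["".join(r) for r in rows],
        reference_id=aln.reference_id)

    site_cols = {cmap.column_of(pos) - 1: pos for pos, _ in sites}
    tracks: dict[str, AnnotationTrack] = {}
    for i, taxon in enumerate(edited.taxa):
        row = edited.row(taxon)
        scores = []
        for c, ch in enumerate(row):
            if ch == "-":
                continue
            if c in site_cols and i in high[site_cols[c]]:
                scores.append(0.8 + 0.2 * rng.random())
            else:
                scores.append(rng.beta(2, 6))
        tracks[taxon] = AnnotationTrack(taxon, "phospho", np.array(scores))
    return edited, tracks, realized


# ---------------------------------------------------------------------------
# Phylogenetic profiles
# ---------------------------------------------------------------------------

def simulate_profiles(class_sizes: tuple[int, ...],
                      species_per_group: tuple[int, ...],
                      flip_noise: float,
                      rng: np.random.Generator,
                      ) -> tuple[PhyloProfileMatrix, list[str]]:
    """Planted-class presence/absence profiles.

    ``species_per_group`` counts species whose narrowest group is, in order:
    chordates, other metazoans, other multicellular, unicellular eukaryotes.
    Class g's pattern is presence exactly inside nesting level g (Class 1 =
    chordates only ... Class 4 = all eukaryotes); each cell then flips i.i.d.
    with probability ``flip_noise``. Returns the matrix (with taxonomy
    groups) and the true class label per protein.
    """
    if len(class_sizes) != 4 or len(species_per_group) != 4:
        raise ValueError("expected four classes and four species groups")
    level_names = ["chordates", "metazoans", "multicellular", "eukaryotes"]
    species: list[str] = []
    level_of: list[int] = []
    for lvl, count in enumerate(species_per_group):
        for i in range(count):
            species.append(f"{level_names[lvl][:4]}_{i + 1:02d}")
            level_of.append(lvl)
    level_of_arr = np.array(level_of)

    groups: dict[str, set[str]] = {}
    for lvl, name in enumerate(level_names):
        groups[name] = {s for s, l in zip(species, level_of) if l <= lvl}

    proteins: list[str] = []
    truth: list[str] = []
    patterns = []
    for cls, size in enumerate(class_sizes, start=1):
        pattern = (level_of_arr <= cls - 1).astype(int)
        for i in range(size):
            proteins.append(f"prot_c{cls}_{i + 1:02d}")
            truth.append(f"Class{cls}")
            patterns.append(pattern)
    matrix = np.array(patterns)
    flips = rng.random(matrix.shape) < flip_noise
    matrix = np.where(flips, 1 - matrix, matrix)
    return PhyloProfileMatrix(proteins, species, matrix,
                              taxonomy_groups=groups), truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(n_proteins: int, n_tissues: int, n_spiked: int,
                        spike_fold: float, spike_tissue: str,
                        rng: np.random.Generator,
                        ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Log-normal baseline TPM with spiked tissue-specific proteins.

    Baseline TPM is exp(N(1, 1)) per cell; the first ``n_spiked`` proteins
    have their ``spike_tissue`` cell multiplied by ``spike_fold``. Returns
    the table and the list of spiked (protein, tissue) pairs.
    """
    tissues = [spike_tissue, "testis"] + [
        f"tissue{i:02d}" for i in range(3, n_tissues + 1)]
    tissues = tissues[:n_tissues]
    proteins = [f"gene{i + 1:03d}" for i in range(n_proteins)]
    X = np.exp(rng.normal(1.0, 1.0, size=(n_proteins, n_tissues)))
    spikes = []
    for i in range(min(n_spiked, n_proteins)):
        X[i, 0] *= spike_fold
        spikes.append((proteins[i], tissues[0]))
    return pd.DataFrame(X, index=proteins, columns=tissues), spikes


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def simulate_variants(refseq: str, domains: dict[str, tuple[int, int]],
                      n_pathogenic: int, n_benign: int,
                      enrichment: float, rng: np.random.Generator,
                      protein: str = "refprot") -> list[VariantRecord]:
    """Missense variants enriched in domain regions.

    Positions are drawn without replacement with weight ``enrichment`` inside
    any domain interval and 1 outside; alt alleles are uniform over the other
    19 residues; pathogenic case counts are 1 + Poisson(2). ``n_benign``
    decoys labeled 'benign' are added the same way without enrichment.
    """
    L = len(refseq)
    in_domain = np.zeros(L, dtype=bool)
    for start, end in domains.values():
        in_domain[start - 1:end] = True
    weights = np.where(in_domain, enrichment, 1.0)
    weights = weights / weights.sum()
    k = min(n_pathogenic, L)
    positions = rng.choice(L, size=k, replace=False, p=weights) + 1
    records = []
    for pos in sorted(positions.tolist()):
        ref = refseq[pos - 1]
        alt = rng.choice([a for a in AA_ORDER if a != ref])
        records.append(VariantRecord(protein, int(pos), ref, str(alt),
                                     int(1 + rng.poisson(2)), "pathogenic"))
    benign_pos = rng.choice(L, size=min(n_benign, L), replace=False) + 1
    for pos in sorted(benign_pos.tolist()):
        ref = refseq[pos - 1]
        alt = rng.choice([a for a in AA_ORDER if a != ref])
        records.append(VariantRecord(protein, int(pos), ref, str(alt),
                                     int(1 + rng.poisson(1)), "benign"))
    return records


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete input bundle plus ground-truth JSON; returns the truth.

    Files: alignment.fasta, tree.nwk, disorder.tsv, phospho.tsv,
    variants.tsv, domains.tsv, orthologs.tsv, taxonomy.tsv, expression.tsv,
    truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tree = simulate_tree(config.n_taxa, config.branch_length_mean,
                         config.rng("tree"), labels=config.taxa)
    model = jtt_model()
    gamma = GammaCategories.discretize(config.alpha, config.K)
    mult = rate_multipliers_from_blocks(config.disorder_blocks,
                                        config.disorder_rate_multiplier)
    aln, true_rates = simulate_alignment(
        tree, model, gamma, config.n_sites, config.rng("alignment"),
        reference_id=config.reference_id, rate_multipliers=mult,
        gap_fraction=config.gap_fraction)

    dis_tracks, regimes = simulate_disorder_tracks(
        aln, config.disorder_blocks, config.rng("disorder"),
        config.ordered_beta, config.disordered_beta)

    rng_ptm = config.rng("ptm")
    sty_pool = list(range(1, len(aln.ungapped(config.reference_id)) + 1))
    n_sites_ptm = config.n_ptm_conserved + config.n_ptm_nonconserved
    chosen = rng_ptm.choice(len(sty_pool), size=n_sites_ptm, replace=False)
    sites = [(sty_pool[int(i)], config.f_conserved) for i in chosen[:config.n_ptm_conserved]]
    sites += [(sty_pool[int(i)], config.f_nonconserved) for i in chosen[config.n_ptm_conserved:]]
    aln, ptm_tracks, realized_f = simulate_ptm(aln, sites, rng_ptm)

    profiles, class_truth = simulate_profiles(
        config.profile_class_sizes, config.species_per_group,
        config.flip_noise, config.rng("profiles"))

    expr, spikes = simulate_expression(
        config.n_expr_proteins, config.n_tissues, config.n_spiked,
        config.spike_fold, config.spike_tissue, config.rng("expression"))

    domains: dict[str, tuple[int, int]] = {}
    pos = 1
    for i, (length, regime) in enumerate(config.disorder_blocks):
        if regime == "ordered":
            domains[f"DOM{len(domains) + 1}"] = (pos, pos + length - 1)
        pos += length
    refseq = aln.ungapped(config.reference_id)
    variants = simulate_variants(refseq, domains, config.n_variants,
                                 config.n_benign, config.domain_enrichment,
                                 config.rng("variants"))

    # -- write everything ----------------------------------------------------
    write_alignment(aln, outdir / "alignment.fasta")
    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    write_track(dis_tracks.values(), outdir / "disorder.tsv")
    write_track(ptm_tracks.values(), outdir / "phospho.tsv")
    write_variants(variants, outdir / "variants.tsv")
    with open(outdir / "domains.tsv", "w") as fh:
        fh.write("# synthetic domain intervals (the generator's ordered "
                 "blocks); not authoritative for any real protein\n")
        fh.write("name\tstart\tend\n")
        for name, (s, e) in domains.items():
            fh.write(f"{name}\t{s}\t{e}\n")
    with open(outdir / "orthologs.tsv", "w") as fh:
        fh.write("protein\tspecies\tmember\n")
        for p, row in zip(profiles.proteins, profiles.matrix):
            for s, v in zip(profiles.species, row):
                if v:
                    fh.write(f"{p}\t{s}\t1\n")
    with open(outdir / "taxonomy.tsv", "w") as fh:
        fh.write("species\tgroup\n")
        narrow = {}
        for name in DEFAULT_TAXONOMY_ORDER:          # broadest first
            for s in profiles.taxonomy_groups.get(name, ()):
                narrow[s] = name                     # narrower names overwrite
        for s in profiles.species:
            fh.write(f"{s}\t{narrow[s]}\n")
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="protein")

    truth = {
        "seed": config.seed,
        "true_site_rates": true_rates.tolist(),
        "alpha": config.alpha,
        "disorder_regimes": regimes,
        "ptm_sites": {str(p): f for p, f in sites},
        "ptm_realized_fraction": {str(p): f for p, f in realized_f.items()},
        "profile_classes": dict(zip(profiles.proteins, class_truth)),
        "expression_spikes": spikes,
        "domains": {k: list(v) for k, v in domains.items()},
        "pathogenic_positions": [v.position for v in variants
                                 if v.pathogenicity == "pathogenic"],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
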