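import numpy as np
import pytest

from evoscape._jtt import AA_ORDER
from evoscape.formats_io import MultipleAlignment
from evoscape.site_rates import GammaCategories, jtt_model
from evoscape.synthetic_data import (
    SimulationConfig,
    rate_multipliers_from_blocks,
    simulate_alignment,
    simulate_bundle,
    simulate_disorder_tracks,
    simulate_expression,
    simulate_profiles,
    simulate_ptm,
    simulate_tree,
    simulate_variants,
)


@pytest.fixture(scope="module")
def model():
    return jtt_model()


class TestTree:
    def test_two_taxa_is_single_cherry(self):
        tree = simulate_tree(2, 0.1, np.random.default_rng(0))
        assert sorted(tree.leaf_labels) == ["t1", "t2"]
        assert len(tree.children[tree.root]) == 2

    @pytest.mark.parametrize("n", [2, 5, 24])
    def test_leaf_count(self, n):
        tree = simulate_tree(n, 0.1, np.random.default_rng(1))
        assert len(tree.leaves) == n

    def test_same_seed_same_newick(self):
        t1 = simulate_tree(10, 0.1, np.random.default_rng(7))
        t2 = simulate_tree(10, 0.1, np.random.default_rng(7))
        assert t1.to_newick() == t2.to_newick()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, 0.1, np.random.default_rng(0))


class TestAlignment:
    def test_zero_rate_gives_constant_columns(self, model):
        rng = np.random.default_rng(3)
        tree = simulate_tree(6, 0.2, rng)
        gamma = GammaCategories.discretize(0.5, 8)
        aln, _ = simulate_alignment(tree, model, gamma, 20, rng,
                                    rate_multipliers=np.zeros(20))
        for c in range(20):
            assert len({r[c] for r in aln.rows}) == 1

    def test_observed_frequencies_approach_stationary(self, model):
        rng = np.random.default_rng(4)
        tree = simulate_tree(4, 0.05, rng)
        gamma = GammaCategories.discretize(1.0, 4)
        aln, _ = simulate_alignment(tree, model, gamma, 10_000, rng)
        counts = np.zeros(20)
        for row in aln.rows:
            for ch in row:
                counts[AA_ORDER.index(ch)] += 1
        freqs = counts / counts.sum()
        tv = 0.5 * np.abs(freqs - model.pi).sum()
        assert tv < 0.03

    def test_fast_sites_more_variable_than_slow(self, model):
        rng = np.random.default_rng(5)
        tree = simulate_tree(16, 0.15, rng)
        gamma = GammaCategories.discretize(0.4, 8)
        aln, rates = simulate_alignment(tree, model, gamma, 400, rng)
        nuniq = np.array([len({r[c] for r in aln.rows}) for c in range(400)])
        lo, hi = rates <= np.quantile(rates, 0.2), rates >= np.quantile(rates, 0.8)
        assert np.median(nuniq[hi]) > np.median(nuniq[lo])

    def test_gap_masking_respects_reference(self, model):
        rng = np.random.default_rng(6)
        tree = simulate_tree(8, 0.1, rng)
        gamma = GammaCategories.discretize(1.0, 4)
        aln, _ = simulate_alignment(tree, model, gamma, 100, rng,
                                    gap_fraction=0.1)
        assert "-" not in aln.row(aln.reference_id)
        assert any("-" in r for r in aln.rows)


class TestDisorderTracks:
    def _aln(self, model, rng, n_taxa=10, n_sites=120):
        tree = simulate_tree(n_taxa, 0.1, rng)
        gamma = GammaCategories.discretize(0.5, 8)
        aln, _ = simulate_alignment(tree, model, gamma, n_sites, rng)
        return aln

    def test_scores_in_unit_interval(self, model):
        rng = np.random.default_rng(7)
        aln = self._aln(model, rng)
        tracks, regimes = simulate_disorder_tracks(
            aln, [(60, "ordered"), (60, "disordered")], rng)
        for t in tracks.values():
            assert np.all((t.scores >= 0) & (t.scores <= 1))
        assert regimes == ["ordered"] * 60 + ["disordered"] * 60

    def test_ordered_block_rarely_crosses_cutoff(self, model):
        # Beta(2,8): P(score >= 0.5) ~ 0.0196 per residue
        rng = np.random.default_rng(8)
        aln = self._aln(model, rng)
        tracks, _ = simulate_disorder_tracks(aln, [(120, "ordered")], rng)
        frac = np.mean(tracks[aln.reference_id].scores >= 0.5)
        assert frac < 0.1

    def test_regimes_recovered_by_consensus_calls(self, model):
        from evoscape.structure_disorder import build_disorder_matrix, consensus_structure
        from evoscape.formats_io import build_column_map

        hits, total = 0, 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            tree = simulate_tree(10, 0.1, rng)
            gamma = GammaCategories.discretize(0.5, 8)
            aln, _ = simulate_alignment(tree, model, gamma, 120, rng)
            blocks = [(40, "ordered"), (40, "disordered"), (40, "ordered")]
            tracks, regimes = simulate_disorder_tracks(aln, blocks, rng)
            dmat = build_disorder_matrix(aln, tracks, tree)
            cmap = build_column_map(aln)
            for pos, regime in enumerate(regimes, start=1):
                call = consensus_structure(dmat, cmap.column_of(pos))
                hits += (call == regime)
                total += 1
        assert hits / total >= 0.95

    def test_block_length_mismatch_rejected(self, model):
        rng = np.random.default_rng(9)
        aln = self._aln(model, rng)
        with pytest.raises(ValueError):
            simulate_disorder_tracks(aln, [(50, "ordered")], rng)


class TestPtm:
    def test_full_conservation_marks_every_taxon(self, model):
        rng = np.random.default_rng(10)
        tree = simulate_tree(8, 0.1, rng)
        gamma = GammaCategories.discretize(0.5, 8)
        aln, _ = simulate_alignment(tree, model, gamma, 50, rng)
        edited, tracks, realized = simulate_ptm(aln, [(10, 1.0)], rng)
        assert realized[10] == 1.0
        col = 9  # ungapped == aligned here
        assert all(r[col] == "S" for r in edited.rows)
        for t in edited.taxa:
            assert tracks[t].scores[col] >= 0.75

    def test_zero_conservation_keeps_only_reference(self, model):
        rng = np.random.default_rng(11)
        tree = simulate_tree(12, 0.1, rng)
        gamma = GammaCategories.discretize(0.5, 8)
        aln, _ = simulate_alignment(tree, model, gamma, 50, rng)
        edited, tracks, realized = simulate_ptm(aln, [(5, 0.0)], rng)
        assert realized[5] == 1 / 12  # reference is always positive


class TestProfiles:
    def test_zero_noise_gives_exact_patterns(self):
        rng = np.random.default_rng(12)
        mat, truth = simulate_profiles((3, 3, 3, 3), (4, 8, 16, 36), 0.0, rng)
        # all proteins of a class share an identical row
        for cls in set(truth):
            rows = mat.matrix[[i for i, t in enumerate(truth) if t == cls]]
            assert (rows == rows[0]).all()
        # class 4 pattern is presence everywhere
        c4 = mat.matrix[[i for i, t in enumerate(truth) if t == "Class4"]]
        assert c4.all()

    def test_groups_are_nested(self):
        rng = np.random.default_rng(13)
        mat, _ = simulate_profiles((2, 2, 2, 2), (4, 8, 16, 36), 0.05, rng)
        g = mat.taxonomy_groups
        assert g["chordates"] <= g["metazoans"] <= g["multicellular"] <= g["eukaryotes"]


class TestExpression:
    def test_spiked_cells_recorded(self):
        rng = np.random.default_rng(14)
        table, spikes = simulate_expression(50, 37, 5, 50.0, "cortex", rng)
        assert len(spikes) == 5 and all(t == "cortex" for _, t in spikes)
        assert table.shape == (50, 37)

    def test_spiked_cells_flagged_by_specificity_statistic(self):
        from evoscape.expression_specificity import specificity_calls

        hits, total = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            table, spikes = simulate_expression(20, 37, 3, 50.0, "cortex", rng)
            calls = {(c.protein, c.tissue): c.flag
                     for c in specificity_calls(table)}
            for pair in spikes:
                hits += calls[pair]
                total += 1
        assert hits / total >= 0.95


class TestVariants:
    def test_ref_alleles_match_sequence(self):
        rng = np.random.default_rng(15)
        refseq = "".join(rng.choice(list(AA_ORDER), 80))
        recs = simulate_variants(refseq, {"D": (10, 30)}, 10, 5, 4.0, rng)
        for v in recs:
            assert refseq[v.position - 1] == v.ref_aa and v.ref_aa != v.alt_aa


class TestBundle:
    def test_bundle_bit_reproducible(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        cfg = SimulationConfig(seed=5, n_taxa=8, n_sites=60,
                               n_expr_proteins=20,
                               profile_class_sizes=(3, 3, 3, 3))
        simulate_bundle(cfg, a)
        simulate_bundle(SimulationConfig(**vars(cfg)), b)
        for f in sorted(p.name for p in a.iterdir()):
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_bundle_roundtrips_through_readers(self, bundle):
        from evoscape.formats_io import (read_alignment, read_newick,
                                         read_track, read_variants)

        outdir, truth = bundle
        aln = read_alignment(outdir / "alignment.fasta", "human")
        tree = read_newick(outdir / "tree.nwk")
        assert set(tree.leaf_labels) == set(aln.taxa)
        tracks = read_track(outdir / "disorder.tsv", aln)
        assert set(tracks) == set(aln.taxa)
        report = read_variants(outdir / "variants.tsv", aln)
        assert [v.position for v in report.records] == sorted(
            truth["pathogenic_positions"])
        assert report.rejected == []

    def test_rate_multipliers_follow_blocks(self):
        mult = rate_multipliers_from_blocks(
            [(2, "ordered"), (3, "disordered")], 3.0)
        assert mult.tolist() == [1.0, 1.0, 3.0, 3.0, 3.0]
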