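import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from oracles import ward_oracle_linkage

from evoscape.formats_io import FormatError
from evoscape.phyloprofiling import (
    PhyloProfileMatrix,
    assign_class_labels,
    build_profile,
    linkage_to_newick,
    manhattan_distance,
    read_taxonomy_groups,
    ward_cluster,
    ward_linkage,
)
from evoscape.synthetic_data import simulate_profiles


class TestBuildProfile:
    def test_score_threshold_boundary(self):
        table = pd.DataFrame({
            "protein": ["p", "p"], "species": ["s1", "s2"],
            "score": [150.0, 149.0]})
        m = build_profile(table)
        assert m.matrix.tolist() == [[1, 0]]

    def test_absent_pairs_default_zero(self):
        table = pd.DataFrame({"protein": ["p1", "p2"],
                              "species": ["s1", "s2"], "member": [1, 1]})
        m = build_profile(table)
        assert m.to_frame().loc["p1", "s2"] == 0

    def test_all_zero_row_flagged(self):
        table = pd.DataFrame({"protein": ["p1", "p2"],
                              "species": ["s1", "s1"], "member": [1, 0]})
        m = build_profile(table)
        assert m.all_zero_proteins == ["p2"]

    def test_conflicting_duplicates_rejected(self):
        table = pd.DataFrame({"protein": ["p", "p"],
                              "species": ["s1", "s1"], "member": [1, 0]})
        with pytest.raises(FormatError, match="conflict"):
            build_profile(table)

    def test_taxonomy_groups_roundtrip(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("species\tgroup\nhsa\tchordates\ndme\tmetazoans\n"
                     "ath\tmulticellular\nsce\teukaryotes\n")
        groups = read_taxonomy_groups(p)
        assert groups["chordates"] == {"hsa"}
        assert groups["metazoans"] == {"hsa", "dme"}
        assert groups["eukaryotes"] == {"hsa", "dme", "ath", "sce"}


class TestManhattan:
    def test_hand_count(self):
        assert manhattan_distance([1, 0, 1], [0, 0, 1]) == 1

    def test_identity(self):
        assert manhattan_distance([1, 1, 0], [1, 1, 0]) == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            manhattan_distance([1, 0], [1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1),
                              st.integers(0, 1)), min_size=3, max_size=3))
    def test_metric_axioms_on_binary_triples(self, rows):
        a, b, c = (np.array(r) for r in rows)
        dab = manhattan_distance(a, b)
        assert dab == manhattan_distance(b, a)
        assert dab <= manhattan_distance(a, c) + manhattan_distance(c, b)
        assert (dab == 0) == bool((a == b).all())


class TestWard:
    def test_first_merge_is_nearest_pair(self):
        m = PhyloProfileMatrix(["a", "b", "c"], [f"s{i}" for i in range(10)],
                               np.array([[0] * 10,
                                         [1] + [0] * 9,
                                         [1] * 10]))
        res = ward_cluster(m, k=1)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_merge_sequence_matches_scratch_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = rng.integers(0, 2, size=(6, 12))
            D = np.abs(X[:, None, :] - X[None, :, :]).sum(2).astype(float)
            Z = ward_linkage(D)
            Zo = ward_oracle_linkage(D)
            assert np.allclose(Z, Zo, atol=1e-9)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(12, 20))
        D = np.abs(X[:, None, :] - X[None, :, :]).sum(2).astype(float)
        Z = ward_linkage(D)
        assert np.all(np.diff(Z[:, 2]) >= -1e-9)

    def test_matches_r_hclust_ward_d(self, tmp_path):
        rng = np.random.default_rng(7)
        X = rng.random((9, 5))
        D = np.abs(X[:, None, :] - X[None, :, :]).sum(2)
        Z = ward_linkage(D)
        np.savetxt(tmp_path / "D.txt", D)
        r = subprocess.run(
            ["Rscript", "-e",
             f'D <- as.matrix(read.table("{tmp_path}/D.txt"));'
             'h <- hclust(as.dist(D), method="ward.D");'
             'cat(sprintf("%.12g", sort(h$height)), sep="\\n")'],
            capture_output=True, text=True, check=True)
        heights = np.array([float(x) for x in r.stdout.split()])
        assert np.allclose(np.sort(Z[:, 2]), heights, rtol=1e-9)

    def test_assignment_invariant_to_row_permutation(self):
        rng = np.random.default_rng(11)
        mat, truth = simulate_profiles((5, 5, 5, 5), (6, 9, 20, 45), 0.02, rng)
        res = ward_cluster(mat, k=4)
        perm = rng.permutation(len(mat.proteins))
        mat2 = PhyloProfileMatrix([mat.proteins[i] for i in perm],
                                  mat.species, mat.matrix[perm],
                                  taxonomy_groups=mat.taxonomy_groups)
        res2 = ward_cluster(mat2, k=4)
        back = {mat2.proteins[i]: res2.assignments[i]
                for i in range(len(perm))}
        ari = adjusted_rand_score(res.assignments,
                                  [back[p] for p in mat.proteins])
        assert ari == 1.0

    def test_k_larger_than_n_rejected(self):
        m = PhyloProfileMatrix(["a", "b"], ["s1"], np.array([[1], [0]]))
        with pytest.raises(ValueError):
            ward_cluster(m, k=4)

    def test_ward_d2_variant_differs_only_in_heights_on_scaled_data(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(8, 10))
        D = np.abs(X[:, None, :] - X[None, :, :]).sum(2).astype(float)
        Z2 = ward_linkage(D, variant="ward_d2")
        assert np.all(np.diff(Z2[:, 2]) >= -1e-9)


class TestClassLabels:
    def _matrix(self, presence_by_level, n_species=(4, 8, 16, 36)):
        """One protein whose presence probability depends on nesting level."""
        rng = np.random.default_rng(0)
        species, level = [], []
        names = ["chordates", "metazoans", "multicellular", "eukaryotes"]
        for lvl, n in enumerate(n_species):
            for i in range(n):
                species.append(f"{names[lvl][:4]}{i}")
                level.append(lvl)
        groups = {names[lvl]: {s for s, l in zip(species, level) if l <= lvl}
                  for lvl in range(4)}
        row = [1 if rng.random() < presence_by_level[l] else 0 for l in level]
        m = PhyloProfileMatrix(["p", "q", "r", "s"], species,
                               np.array([row, row, row, row]),
                               taxonomy_groups=groups)
        res = ward_cluster(m, k=4)
        return assign_class_labels(res, m)

    def test_present_everywhere_is_eukaryote_class(self):
        res = self._matrix([0.95, 0.95, 0.95, 0.95])
        assert set(res.class_labels.values()) == {"Class4_eukaryote"}

    def test_chordate_only_is_class1(self):
        res = self._matrix([0.9, 0.03, 0.03, 0.03])
        assert set(res.class_labels.values()) == {"Class1_chordate"}

    def test_sparse_everywhere_is_unresolved(self):
        res = self._matrix([0.4, 0.4, 0.4, 0.4])
        assert set(res.class_labels.values()) == {"unresolved"}

    def test_invariant_to_duplicating_species_column(self):
        rng = np.random.default_rng(8)
        mat, _ = simulate_profiles((4, 4, 4, 4), (6, 9, 20, 45), 0.0, rng)
        res = assign_class_labels(ward_cluster(mat, k=4), mat)
        labels1 = [res.label_of(i) for i in range(len(mat.proteins))]
        # duplicate one chordate species column inside its group
        dup = mat.species.index(sorted(mat.taxonomy_groups["chordates"])[0])
        species2 = mat.species + [mat.species[dup] + "_dup"]
        matrix2 = np.hstack([mat.matrix, mat.matrix[:, [dup]]])
        groups2 = {g: set(s) | ({species2[-1]} if mat.species[dup] in s else set())
                   for g, s in mat.taxonomy_groups.items()}
        mat2 = PhyloProfileMatrix(mat.proteins, species2, matrix2,
                                  taxonomy_groups=groups2)
        res2 = assign_class_labels(ward_cluster(mat2, k=4), mat2)
        labels2 = [res2.label_of(i) for i in range(len(mat.proteins))]
        assert labels1 == labels2

    def test_missing_groups_rejected(self):
        m = PhyloProfileMatrix(["a"], ["s1"], np.array([[1]]))
        res = ward_cluster(m, k=1)
        with pytest.raises(ValueError):
            assign_class_labels(res, m)


def test_linkage_newick_export_parses():
    from evoscape.formats_io import PhyloTree

    rng = np.random.default_rng(5)
    X = rng.integers(0, 2, size=(6, 8))
    D = np.abs(X[:, None, :] - X[None, :, :]).sum(2).astype(float)
    Z = ward_linkage(D)
    nwk = linkage_to_newick(Z, [f"p{i}" for i in range(6)])
    tree = PhyloTree.from_newick_string(nwk)
    assert sorted(tree.leaf_labels) == [f"p{i}" for i in range(6)]
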