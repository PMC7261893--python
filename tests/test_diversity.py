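import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pollenscan as ps
from pollenscan import datasets
from tests.conftest import haploid_matrix


def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """Leaf-to-leaf path lengths of a random binary tree with positive
    branch lengths (the independent oracle: distances are additive by
    construction)."""
    nodes = {i: {i: 0.0} for i in range(n_leaves)}  # node -> leaf distances
    next_id = n_leaves
    active = list(range(n_leaves))
    dist = np.zeros((n_leaves, n_leaves))
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[min(i, j)], active[max(i, j)]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        for leaf_a, da in nodes[a].items():
            for leaf_b, db in nodes[b].items():
                d = da + la + db + lb
                dist[leaf_a, leaf_b] = dist[leaf_b, leaf_a] = d
        merged = {leaf: d + la for leaf, d in nodes[a].items()}
        merged.update({leaf: d + lb for leaf, d in nodes[b].items()})
        nodes[next_id] = merged
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return dist


class TestSimpleMatching:
    def test_identical_profiles(self, lemon_map):
        gm = haploid_matrix(
            {"g1": ["218"] * 12, "g2": ["218"] * 12}, lemon_map.loci
        )
        dm = ps.simple_matching(gm)
        assert dm.d[0, 1] == 0.0

    def test_fully_different_profiles(self, lemon_map):
        gm = haploid_matrix(
            {"g1": ["1"] * 12, "g2": ["2"] * 12}, lemon_map.loci
        )
        dm = ps.simple_matching(gm)
        assert dm.d[0, 1] == 1.0

    def test_half_matching(self):
        loci = [f"m{i}" for i in range(30)]
        gm = haploid_matrix(
            {"g1": ["A"] * 30, "g2": ["A"] * 15 + ["B"] * 15}, loci
        )
        dm = ps.simple_matching(gm)
        assert dm.d[0, 1] == pytest.approx(0.5)

    def test_pairwise_deletion_denominator(self):
        loci = ["m1", "m2", "m3", "m4"]
        gm = haploid_matrix(
            {"g1": ["A", "B", None, "C"], "g2": ["A", "X", "Y", None]}, loci
        )
        dm = ps.simple_matching(gm)
        # jointly scored: m1 (match), m2 (mismatch) -> d = 1/2
        assert dm.loci_used[0, 1] == 2
        assert dm.d[0, 1] == pytest.approx(0.5)

    def test_no_overlap_raises_unless_nan_allowed(self):
        loci = ["m1", "m2"]
        gm = haploid_matrix({"g1": ["A", None], "g2": [None, "B"]}, loci)
        with pytest.raises(ValueError, match="no.*scored locus"):
            ps.simple_matching(gm)
        dm = ps.simple_matching(gm, on_no_overlap="nan")
        assert np.isnan(dm.d[0, 1])

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_equals_normalized_hamming_without_missing(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(5, 8)).astype(str)
        loci = [f"m{i}" for i in range(8)]
        gm = haploid_matrix(
            {f"g{i}": list(calls[i]) for i in range(5)}, loci
        )
        dm = ps.simple_matching(gm)
        hamming = (calls[:, None, :] != calls[None, :, :]).mean(axis=2)
        assert np.allclose(dm.d, hamming)


class TestNJTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        dm = ps.DissimilarityMatrix(["a", "b", "c"], d, np.full((3, 3), 1))
        tree = ps.nj_tree(dm)
        pl = tree.leaf_path_lengths()
        assert pl.loc["a", "b"] == pytest.approx(3.0)
        assert pl.loc["a", "c"] == pytest.approx(4.0)
        assert pl.loc["b", "c"] == pytest.approx(5.0)

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0, 1], [1, 0]], float)
        dm = ps.DissimilarityMatrix(["a", "b"], d, np.full((2, 2), 1))
        with pytest.raises(ValueError):
            ps.nj_tree(dm)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8, 12])
    def test_additive_matrix_recovered_exactly(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        d = random_additive_matrix(n_leaves, rng)
        ids = [f"t{i}" for i in range(n_leaves)]
        dm = ps.DissimilarityMatrix(ids, d, np.full_like(d, 1, dtype=int))
        tree = ps.nj_tree(dm)
        pl = tree.leaf_path_lengths().loc[ids, ids].to_numpy()
        assert np.abs(pl - d).max() < 1e-9

    def test_ultrametric_cherries_paired(self):
        # ((a,b),(c,d)): within-cherry distance 2, across 6
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        dm = ps.DissimilarityMatrix(list("abcd"), d, np.full((4, 4), 1))
        tree = ps.nj_tree(dm)
        pl = tree.leaf_path_lengths()
        assert pl.loc["a", "b"] < pl.loc["a", "c"]
        assert pl.loc["c", "d"] < pl.loc["b", "c"]

    def test_row_order_invariance(self, lemon_map):
        cfg = datasets.lemon_pollen_config(seed=41, n_gametes=12, dropout_rate=0.0)
        gm, _ = ps.simulate_gametes(cfg)
        dm = ps.simple_matching(gm)
        perm = np.random.default_rng(0).permutation(gm.n_units)
        shuffled = ps.GenotypeMatrix(calls=gm.calls.iloc[perm], ploidy=1)
        dm2 = ps.simple_matching(shuffled)
        t1 = ps.nj_tree(dm).canonical_newick()
        t2 = ps.nj_tree(dm2).canonical_newick()
        assert t1 == t2

    def test_weighted_variant_warns_and_matches_classic(self):
        d = random_additive_matrix(5, np.random.default_rng(7))
        ids = [f"t{i}" for i in range(5)]
        dm = ps.DissimilarityMatrix(ids, d, np.full_like(d, 1, dtype=int))
        with pytest.warns(UserWarning, match="classic"):
            tw = ps.nj_tree(dm, variant="weighted")
        assert tw.canonical_newick() == ps.nj_tree(dm).canonical_newick()

    def test_agrees_with_scikit_bio_reference(self):
        """Independent cross-check: near-additive matrices must give the
        same patristic distances as scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        base = random_additive_matrix(7, rng)
        noise = rng.uniform(-0.01, 0.01, size=base.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        d = base + noise
        ids = [f"t{i}" for i in range(7)]
        ours = ps.nj_tree(
            ps.DissimilarityMatrix(ids, d, np.full_like(d, 1, dtype=int))
        ).leaf_path_lengths()
        ref_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        ref = ref_tree.tip_tip_distances(ids)
        ref_frame = pd.DataFrame(ref.data, index=ref.ids, columns=ref.ids)
        assert np.allclose(
            ours.loc[ids, ids].to_numpy(), ref_frame.loc[ids, ids].to_numpy(),
            atol=1e-8,
        )

    def test_newick_parses_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        d = random_additive_matrix(6, np.random.default_rng(3))
        ids = [f"unit {i}" for i in range(6)]  # spaces force quoting
        tree = ps.nj_tree(
            ps.DissimilarityMatrix(ids, d, np.full_like(d, 1, dtype=int))
        )
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(ids)


class TestPopulationTreeReport:
    def test_excluded_haplotype_forms_pollen_only_cluster(self, tangor_map):
        """Zygotic exclusion of one male haplotype class removes those
        haplotypes from the progeny-derived gametes, so the joint tree
        shows pollen-only clades."""
        sim = ps.simulate_progeny(datasets.tangor_cross_config(seed=42, n_gametes=80))
        haplos = ps.male_haplotype_matrix(sim.progeny, tangor_map)
        pollen, _ = ps.simulate_gametes(
            datasets.tangor_pollen_config(seed=43, n_gametes=40, dropout_rate=0.0)
        )
        report = ps.population_tree_report(
            pollen, haplos, label_a="pollen", label_b="progeny_male"
        )
        assert report.exclusivity_count("pollen") >= 1

    def test_same_population_twice_mixes(self, lemon_map):
        cfg = datasets.lemon_pollen_config(seed=44, n_gametes=10, dropout_rate=0.0)
        gm, _ = ps.simulate_gametes(cfg)
        report = ps.population_tree_report(gm, gm, label_a="x", label_b="y")
        # identical profiles pair x with y: no large single-source clade
        assert len(report.tree.leaf_names) == 20
        labels = set(report.labels.values())
        assert labels == {"x", "y"}

    def test_panel_mismatch_rejected(self, lemon_map, tangor_map):
        cfg = datasets.lemon_pollen_config(seed=45, n_gametes=5)
        gm, _ = ps.simulate_gametes(cfg)
        other, _ = ps.simulate_gametes(
            datasets.tangor_pollen_config(seed=46, n_gametes=5)
        )
        with pytest.raises(ValueError, match="panel"):
            ps.population_tree_report(gm, other)
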