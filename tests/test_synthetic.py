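"""Ground-truth properties of the synthetic study-system generator."""

import numpy as np
import pytest

from nicheweave import climate, phylo, synthetic
from nicheweave.synthetic import VirtualTaxon


class TestMakeClimateGrid:
    def test_zero_noise_equals_generating_harmonic(self):
        bands = ({"tmax": (15.0, -5.0, 2.0), "tmin": (5.0, -4.0, 1.0), "vpd": (0.8, -0.3, 0.1)},)
        grid = synthetic.make_climate_grid(3, 3, seed=0, regional_harmonics=bands, noise_sd=0.0)
        m = np.arange(1, 13)
        expected = 15.0 - 5.0 * np.cos(2 * np.pi * m / 12) + 2.0 * np.sin(2 * np.pi * m / 12)
        assert np.allclose(grid.values["tmax"][:, 1, 1], expected, atol=1e-12)

    def test_same_seed_bit_identical(self):
        a = synthetic.make_climate_grid(6, 6, seed=9)
        b = synthetic.make_climate_grid(6, 6, seed=9)
        for var in ("tmax", "tmin", "vpd"):
            assert np.array_equal(a.values[var], b.values[var])

    def test_band_mean_difference_matches_configuration(self):
        south = {"tmax": (20.0, -8.0, -3.0), "tmin": (10.0, -6.0, -2.0), "vpd": (1.0, -0.4, -0.2)}
        north = {"tmax": (4.0, -8.0, -3.0), "tmin": (-4.0, -6.0, -2.0), "vpd": (0.3, -0.4, -0.2)}
        sd = 0.5
        grid = synthetic.make_climate_grid(
            50, 50, seed=2, regional_harmonics=(south, north), smooth=False, noise_sd=sd
        )
        a0 = grid.values["tmax"].mean(axis=0)  # annual mean per cell
        diff = a0[25:].mean() - a0[:25].mean()
        se = sd / np.sqrt(12 * 25 * 50) * np.sqrt(2)
        assert abs(diff - (4.0 - 20.0)) <= 3 * se

    def test_tmax_not_below_tmin(self, small_grid):
        small_grid.validate_physical()

    def test_nonfinite_parameters_rejected(self):
        bad = ({"tmax": (np.inf, 0, 0), "tmin": (0, 0, 0), "vpd": (0, 0, 0)},)
        with pytest.raises(ValueError):
            synthetic.make_climate_grid(4, 4, seed=0, regional_harmonics=bad)


class TestMakeEcosystemMap:
    def test_k1_rejected(self, small_grid):
        with pytest.raises(ValueError):
            synthetic.make_ecosystem_map(small_grid, k=1)

    def test_two_bands_on_4x4(self):
        grid = synthetic.make_climate_grid(4, 4, seed=0)
        eco = synthetic.make_ecosystem_map(grid, k=2, scheme="latitudinal_bands")
        counts = np.bincount(eco.labels.reshape(-1))
        assert list(counts) == [8, 8]

    def test_labels_partition_grid(self, small_grid):
        eco = synthetic.make_ecosystem_map(small_grid, k=4)
        assert np.bincount(eco.labels.reshape(-1)).sum() == small_grid.geometry.n_cells
        assert np.all(np.bincount(eco.labels.reshape(-1)) > 0)

    def test_kmeans_agrees_with_separated_bands(self):
        south = {"tmax": (25.0, -8.0, -3.0), "tmin": (15.0, -6.0, -2.0), "vpd": (1.2, -0.4, -0.2)}
        north = {"tmax": (-5.0, -8.0, -3.0), "tmin": (-15.0, -6.0, -2.0), "vpd": (0.2, -0.4, -0.2)}
        grid = synthetic.make_climate_grid(
            20, 10, seed=5, regional_harmonics=(south, north), smooth=False, noise_sd=0.3
        )
        bands = synthetic.make_ecosystem_map(grid, k=2, scheme="latitudinal_bands")
        km = synthetic.make_ecosystem_map(grid, k=2, scheme="kmeans_on_climate", seed=1)
        agreement = max(
            np.mean(km.labels == bands.labels), np.mean(km.labels == 1 - bands.labels)
        )
        assert agreement >= 0.95

    def test_k_exceeding_cells_rejected(self, small_grid):
        with pytest.raises(ValueError):
            synthetic.make_ecosystem_map(small_grid, k=10_000)


class TestVirtualTaxaAndTruth:
    def test_suitabilities_within_unit_interval(self, community):
        _, truth = community
        for surf in truth.true_suitability.values():
            assert np.all((surf >= 0) & (surf <= 1))

    def test_identical_niches_overlap_exactly_100(self, predictors):
        _, X = predictors.as_table()
        center = X[X.shape[0] // 2]
        breadth = 0.5 * X.var(axis=0)
        pair = [
            VirtualTaxon("tick_0", "tick", center, breadth),
            VirtualTaxon("host_0", "host", center, breadth),
        ]
        truth = synthetic.build_truth(pair, predictors)
        assert truth.true_pairwise_overlap.loc["tick_0", "host_0"] == 100.0

    def test_overlap_decreases_with_separation(self, predictors):
        # separate the second niche along the realized climate gradient
        # (interpolating between occupied cells keeps centers on-manifold)
        _, X = predictors.as_table()
        order = np.argsort(X[:, 0])
        c_near = X[order[len(order) // 4]]
        c_far = X[order[3 * len(order) // 4]]
        # breadth wide relative to the background so the sweep stays in the
        # informative overlap range on this small grid
        breadth = 8.0 * X.var(axis=0)
        values = []
        for f in np.linspace(0, 0.6, 5):
            pair = [
                VirtualTaxon("tick_0", "tick", c_near, breadth),
                VirtualTaxon("host_0", "host", (1 - f) * c_near + f * c_far, breadth),
            ]
            truth = synthetic.build_truth(pair, predictors)
            values.append(float(truth.true_pairwise_overlap.iloc[0, 0]))
        assert values[0] == pytest.approx(100.0)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_breadth_rejected(self):
        with pytest.raises(ValueError):
            VirtualTaxon("t", "tick", np.zeros(9), -np.ones(9))

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            VirtualTaxon("t", "tick", np.zeros(9), np.ones(9), max_prevalence=1.5)


class TestSampleOccurrences:
    def test_degenerate_support_puts_all_records_on_one_cell(self, community, predictors):
        taxa, truth = community
        import copy

        t = taxa[0]
        truth2 = copy.copy(truth)
        surf = np.zeros_like(truth.true_suitability[t.taxon_id])
        surf[3, 4] = 0.7
        truth2.true_suitability = dict(truth.true_suitability)
        truth2.true_suitability[t.taxon_id] = surf
        occ = synthetic.sample_occurrences(t, truth2, 25, seed=1)
        geom = predictors.geometry
        assert len(occ) == 25
        assert np.allclose(occ["lon"], geom.x_origin + 4.5 * geom.cell_size)
        assert np.allclose(occ["lat"], geom.y_origin + 3.5 * geom.cell_size)

    def test_sample_mean_near_niche_center(self, predictors):
        _, X = predictors.as_table()
        sd = np.sqrt(X.var(axis=0))
        taxon = VirtualTaxon("t", "tick", X[X.shape[0] // 2], (0.6 * sd) ** 2)
        truth = synthetic.build_truth([taxon], predictors)
        occ = synthetic.sample_occurrences(taxon, truth, 500, seed=3)
        geom = predictors.geometry
        vecs = []
        for lon, lat in zip(occ["lon"], occ["lat"]):
            r, c = geom.cell_index(lon, lat)
            vecs.append(predictors.cell_vector(r, c))
        vecs = np.stack(vecs)
        se = vecs.std(axis=0, ddof=1) / np.sqrt(len(vecs))
        # sampling is suitability-weighted over a finite grid, so allow a
        # small systematic offset on top of the 3 SE Monte-Carlo band
        assert np.all(np.abs(vecs.mean(axis=0) - taxon.niche_center) <= 3 * se + 0.25 * sd)

    def test_all_zero_suitability_rejected(self, community):
        taxa, truth = community
        import copy

        truth2 = copy.copy(truth)
        truth2.true_suitability = dict(truth.true_suitability)
        truth2.true_suitability[taxa[0].taxon_id] = np.zeros_like(
            truth.true_suitability[taxa[0].taxon_id]
        )
        with pytest.raises(ValueError):
            synthetic.sample_occurrences(taxa[0], truth2, 10, seed=0)

    def test_same_seed_identical_records(self, community):
        taxa, truth = community
        a = synthetic.sample_occurrences(taxa[0], truth, 50, seed=5)
        b = synthetic.sample_occurrences(taxa[0], truth, 50, seed=5)
        assert a.equals(b)

    def test_records_inside_grid_extent(self, community, predictors):
        taxa, truth = community
        occ = synthetic.sample_occurrences(taxa[1], truth, 100, seed=2)
        geom = predictors.geometry
        assert occ["lon"].between(geom.x_origin, geom.x_origin + geom.n_cols).all()
        assert occ["lat"].between(geom.y_origin, geom.y_origin + geom.n_rows).all()


class TestMakePhylogeny:
    def test_two_taxa_single_cherry(self):
        tree = synthetic.make_phylogeny(["A", "B"], seed=0)
        assert sorted(phylo.tip_labels(tree)) == ["A", "B"]
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 1

    @pytest.mark.parametrize("n", [3, 7, 12])
    def test_binary_rooted_tree_has_n_minus_1_internal_nodes(self, n):
        tree = synthetic.make_phylogeny([f"t{i}" for i in range(n)], seed=n)
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        assert len(internal) == n - 1
        assert all(
            nd.edge.length > 0 for nd in tree.preorder_node_iter() if nd.parent_node
        )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_phylogeny(["A", "A", "B"], seed=0)

    def test_newick_round_trip_preserves_lengths(self):
        for seed in range(10):
            tree = synthetic.make_phylogeny([f"t{i}" for i in range(6)], seed=seed)
            text = phylo.to_newick(tree)
            back = phylo.parse_newick(text)
            orig = {lf.taxon.label: lf.root_distance for lf in _with_depths(tree)}
            again = {lf.taxon.label: lf.root_distance for lf in _with_depths(back)}
            for k in orig:
                assert again[k] == pytest.approx(orig[k], abs=1e-9)


def _with_depths(tree):
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return tree.leaf_node_iter()


class TestSimulateBMTrait:
    def test_lambda_zero_gives_uncorrelated_tips(self, host_tree):
        reps = np.stack(
            [
                synthetic.simulate_bm_trait(host_tree, 0.0, 1.0, seed=s).to_numpy()
                for s in range(300)
            ]
        )
        cov = np.cov(reps.T)
        off = cov[~np.eye(cov.shape[0], dtype=bool)]
        labels, V = phylo.phylo_vcv(host_tree)
        # off-diagonal covariance should be near zero relative to tip variance
        assert np.max(np.abs(off)) < 0.35 * np.max(np.diag(V))

    def test_sigma2_zero_rejected(self, host_tree):
        with pytest.raises(ValueError):
            synthetic.simulate_bm_trait(host_tree, 0.5, 0.0, seed=0)

    def test_lambda_out_of_range_rejected(self, host_tree):
        with pytest.raises(ValueError):
            synthetic.simulate_bm_trait(host_tree, 1.2, 1.0, seed=0)

    def test_same_seed_identical(self, host_tree):
        a = synthetic.simulate_bm_trait(host_tree, 0.7, 2.0, seed=4)
        b = synthetic.simulate_bm_trait(host_tree, 0.7, 2.0, seed=4)
        assert a.equals(b)


def test_child_seed_is_stable_and_stage_dependent():
    assert synthetic.child_seed(1, "climate") == synthetic.child_seed(1, "climate")
    assert synthetic.child_seed(1, "climate") != synthetic.child_seed(1, "taxa")
    assert 0 <= synthetic.child_seed(123, "x") < 2**31
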