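"""Ensemble distribution modelling: sampling design, learners, metrics."""

import numpy as np
import pandas as pd
import pytest

from nicheweave import sdm, synthetic
from nicheweave.grids import PREDICTOR_LAYERS
from nicheweave.sdm import (
    LEARNER_NAMES,
    abiotic_suitability,
    binarize,
    combine_member_scores,
    confusion_metrics,
    ensemble,
    fit_learner,
    generate_pseudo_absences,
    split_records,
    threshold_max_tss,
    train_sdm,
)


@pytest.fixture(scope="module")
def presences(predictors_module, community_module):
    taxa, truth = community_module
    return synthetic.sample_occurrences(taxa[0], truth, 60, seed=3)


@pytest.fixture(scope="module")
def predictors_module(request):
    from nicheweave import climate

    grid = synthetic.make_climate_grid(12, 10, seed=42)
    return climate.build_predictors(grid)


@pytest.fixture(scope="module")
def community_module(predictors_module):
    taxa = synthetic.make_taxa(predictors_module, 2, 4, seed=7, breadth_scale=0.8)
    truth = synthetic.build_truth(taxa, predictors_module)
    return taxa, truth


def _separable_points(n=120, seed=0):
    """Labelled points perfectly separated by the first predictor."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 9))
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    X[: n // 2, 0] += 6.0
    df = pd.DataFrame(X, columns=list(PREDICTOR_LAYERS))
    df.insert(0, "cell_id", np.arange(n))
    df["label"] = y
    df["partition"] = np.where(rng.random(n) < 0.7, "train", "test")
    return df


class TestPseudoAbsences:
    def test_one_to_one_correspondence(self, presences, predictors_module):
        points = generate_pseudo_absences(presences, predictors_module, seed=0)
        assert (points["label"] == 1).sum() == len(presences)
        assert (points["label"] == 0).sum() == len(presences)

    def test_absences_never_coincide_with_presence_cells(self, presences, predictors_module):
        for seed in range(5):
            points = generate_pseudo_absences(presences, predictors_module, seed=seed)
            pres = set(points.loc[points["label"] == 1, "cell_id"])
            abs_ = set(points.loc[points["label"] == 0, "cell_id"])
            assert pres.isdisjoint(abs_)

    def test_insufficient_candidate_cells_rejected(self, predictors_module):
        geom = predictors_module.geometry
        lon, lat = geom.cell_centers()
        full = pd.DataFrame(
            {"taxon_id": "t", "role": "tick", "lon": lon.reshape(-1), "lat": lat.reshape(-1)}
        )
        with pytest.raises(ValueError):
            generate_pseudo_absences(full, predictors_module, seed=0)

    def test_deterministic_given_seed(self, presences, predictors_module):
        a = generate_pseudo_absences(presences, predictors_module, seed=9)
        b = generate_pseudo_absences(presences, predictors_module, seed=9)
        assert a.equals(b)


class TestSplitRecords:
    def test_70_30_split_per_label(self, presences, predictors_module):
        points = generate_pseudo_absences(presences, predictors_module, seed=0)
        out = split_records(points, 0.7, seed=1)
        for label in (0, 1):
            grp = out[out["label"] == label]
            assert (grp["partition"] == "train").sum() == round(0.7 * len(grp))

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 1.3])
    def test_degenerate_fraction_rejected(self, presences, predictors_module, fraction):
        points = generate_pseudo_absences(presences, predictors_module, seed=0)
        with pytest.raises(ValueError):
            split_records(points, fraction, seed=0)

    def test_partitions_form_exact_partition(self, presences, predictors_module):
        points = generate_pseudo_absences(presences, predictors_module, seed=0)
        out = split_records(points, 0.7, seed=2)
        assert set(out["partition"]) == {"train", "test"}
        assert len(out) == len(points)
        assert out.drop(columns="partition").equals(points.drop(columns="partition"))


class TestLearners:
    @pytest.mark.parametrize("name", LEARNER_NAMES)
    def test_separable_fixture_recovered(self, name):
        points = _separable_points()
        fitted = fit_learner(points[points["partition"] == "train"], name)
        test = points[points["partition"] == "test"]
        scores = fitted.predict(test[list(PREDICTOR_LAYERS)].to_numpy())
        t, _ = threshold_max_tss(scores, test["label"].to_numpy())
        m = confusion_metrics(scores, test["label"].to_numpy(), t)
        assert m.sensitivity >= 0.95
        assert m.specificity >= 0.95

    @pytest.mark.parametrize("name", LEARNER_NAMES)
    def test_constant_label_rejected(self, name):
        points = _separable_points()
        points["label"] = 1
        with pytest.raises(ValueError):
            fit_learner(points, name)

    @pytest.mark.parametrize("name", LEARNER_NAMES)
    def test_scores_clamped_to_unit_interval(self, name, rng):
        points = _separable_points()
        fitted = fit_learner(points[points["partition"] == "train"], name)
        q = rng.normal(scale=20, size=(1000, 9))
        scores = fitted.predict(q)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            fit_learner(_separable_points(), "random_forest")


class TestConfusionMetrics:
    def test_perfect_classification(self):
        scores = np.array([0.9, 0.9, 0.1, 0.1])
        labels = np.array([1, 1, 0, 0])
        m = confusion_metrics(scores, labels, 0.5)
        assert (m.sensitivity, m.specificity, m.kappa) == (1.0, 1.0, 1.0)

    def test_worked_confusion_table(self):
        # TP=40, FN=10, FP=5, TN=45
        scores = np.concatenate([np.ones(40), np.zeros(10), np.ones(5), np.zeros(45)])
        labels = np.concatenate([np.ones(50), np.zeros(50)]).astype(int)
        m = confusion_metrics(scores, labels, 0.5)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.9)
        assert m.omission_rate == pytest.approx(0.2)
        assert m.proportion_correct == pytest.approx(0.85)
        assert m.kappa == pytest.approx(0.7)

    def test_label_independent_scores_give_near_zero_kappa(self, rng):
        kappas = []
        for _ in range(200):
            scores = rng.random(200)
            labels = np.repeat([0, 1], 100)
            kappas.append(confusion_metrics(scores, labels, 0.5).kappa)
        assert abs(np.mean(kappas)) < 0.02

    def test_agrees_with_brute_force_counts(self, rng):
        for _ in range(100):
            n = rng.integers(10, 60)
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            t = rng.random()
            m = confusion_metrics(scores, labels, t)
            tp = sum(s >= t and l == 1 for s, l in zip(scores, labels))
            fn = sum(s < t and l == 1 for s, l in zip(scores, labels))
            tn = sum(s < t and l == 0 for s, l in zip(scores, labels))
            fp = sum(s >= t and l == 0 for s, l in zip(scores, labels))
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))
            assert m.proportion_correct == pytest.approx((tp + tn) / n)


class TestEnsemble:
    def test_weighted_mean_arithmetic(self):
        out = combine_member_scores(np.array([[0.8], [0.4]]), np.array([0.6, 0.2]))
        assert out[0] == pytest.approx((0.8 * 0.6 + 0.4 * 0.2) / 0.8)

    def test_single_member_identity(self, predictors_module):
        points = _separable_points()
        fitted = fit_learner(points[points["partition"] == "train"], "smooth_additive")
        metrics = confusion_metrics(
            np.array([0.9, 0.1]), np.array([1, 0]), 0.5
        )
        smap = ensemble([(fitted, metrics)], predictors_module, taxon_id="t")
        _, X = predictors_module.as_table()
        direct = fitted.predict(X)
        got = smap.values.reshape(-1)[~np.isnan(smap.values.reshape(-1))]
        assert np.allclose(got, direct)

    def test_ensemble_within_member_envelope(self, predictors_module):
        points = _separable_points()
        members = []
        for name in LEARNER_NAMES:
            fitted = fit_learner(points[points["partition"] == "train"], name)
            metrics = confusion_metrics(np.array([0.9, 0.1]), np.array([1, 0]), 0.5)
            members.append((fitted, metrics))
        smap = ensemble(members, predictors_module)
        _, X = predictors_module.as_table()
        scores = np.stack([f.predict(X) for f, _ in members])
        vals = smap.values.reshape(-1)
        vals = vals[~np.isnan(vals)]
        assert np.all(vals >= scores.min(axis=0) - 1e-12)
        assert np.all(vals <= scores.max(axis=0) + 1e-12)

    def test_no_member_retained_names_rule(self, predictors_module):
        points = _separable_points()
        fitted = fit_learner(points[points["partition"] == "train"], "smooth_additive")
        bad = confusion_metrics(np.array([0.1, 0.9]), np.array([1, 0]), 0.5)
        with pytest.raises(ValueError, match="kappa >= 0.4"):
            ensemble([(fitted, bad)], predictors_module)


class TestBinarize:
    def test_worked_max_tss_threshold(self):
        scores = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.6])
        labels = np.array([1, 1, 1, 0, 0, 0])
        t, tss = threshold_max_tss(scores, labels)
        assert t == pytest.approx(0.65)
        assert tss == pytest.approx(1.0)

    def test_constant_shift_moves_threshold(self):
        scores = np.array([0.5, 0.45, 0.4, 0.2, 0.1, 0.3])
        labels = np.array([1, 1, 1, 0, 0, 0])
        t0, tss0 = threshold_max_tss(scores, labels)
        t1, tss1 = threshold_max_tss(scores + 0.2, labels)
        assert t1 == pytest.approx(t0 + 0.2)
        assert tss1 == pytest.approx(tss0)

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValueError):
            threshold_max_tss(np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 0]))

    def test_shuffled_labels_give_near_zero_expected_tss(self, rng):
        tss_values = []
        for _ in range(200):
            scores = rng.random(60)
            labels = rng.permutation(np.repeat([0, 1], 30))
            _, tss = threshold_max_tss(scores, labels)
            tss_values.append(tss)
        # max-TSS is biased upward under the null; the mean stays modest
        assert 0 < np.mean(tss_values) < 0.35


class TestAbioticSuitability:
    def test_two_cell_mean(self, predictors_module):
        from nicheweave.grids import EcosystemMap
        from nicheweave.sdm import SuitabilityMap

        geom = predictors_module.geometry
        values = np.zeros((geom.n_rows, geom.n_cols))
        values[0, 0], values[0, 1] = 0.1, 0.3
        labels = np.ones((geom.n_rows, geom.n_cols), dtype=int)
        labels[0, 0] = labels[0, 1] = 0
        eco = EcosystemMap(geometry=geom, labels=labels)
        smap = SuitabilityMap("t", geom, values)
        assert abiotic_suitability(smap, eco, 0) == pytest.approx(20.0)
        assert abiotic_suitability(
            SuitabilityMap("t", geom, np.zeros_like(values)), eco, 1
        ) == pytest.approx(0.0)
        assert abiotic_suitability(
            SuitabilityMap("t", geom, np.ones_like(values)), eco, 1
        ) == pytest.approx(100.0)


class TestEndToEnd:
    def test_recovery_and_determinism(self):
        from nicheweave import climate

        grid = synthetic.make_climate_grid(20, 20, seed=13)
        predictors = climate.build_predictors(grid)
        taxa = synthetic.make_taxa(predictors, 1, 0, seed=7, breadth_scale=0.8)
        truth = synthetic.build_truth(taxa, predictors)
        occ = synthetic.sample_occurrences(taxa[0], truth, 150, seed=8)
        res1 = train_sdm(occ, predictors, seed=5)
        res2 = train_sdm(occ, predictors, seed=5)
        assert np.array_equal(res1.binary.values, res2.binary.values)
        assert np.allclose(
            res1.suitability.values, res2.suitability.values, equal_nan=True
        )
        assert res1.ensemble_metrics.kappa >= 0.5
        est = res1.suitability.values.reshape(-1)
        tru = truth.true_suitability[taxa[0].taxon_id].reshape(-1)
        ok = ~np.isnan(est)
        assert np.corrcoef(est[ok], tru[ok])[0, 1] >= 0.7
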