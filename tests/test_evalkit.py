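"""Accuracy metrics, CV plans, bootstrap, and the experiment harnesses."""

import numpy as np
import pytest

import gscross as g


class TestPearsonAccuracy:
    def test_affine_transform_gives_unity(self):
        y = np.array([0.3, 1.2, -0.5, 2.0])
        assert g.pearson_accuracy(y, 2 * y + 5) == pytest.approx(1.0)
        assert g.pearson_accuracy(y, -y) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert g.pearson_accuracy([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(g.pearson_accuracy([1, 1, 1], [1, 2, 3]))

    def test_length_checks(self):
        with pytest.raises(ValueError):
            g.pearson_accuracy([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            g.pearson_accuracy([1, 2], [1, 2])


class TestCVPlan:
    def test_fold_sizes_and_partition(self):
        plan = g.make_cv_plan(10, k=5, n_reps=3, seed=0)
        for rep in range(3):
            folds = plan.folds[rep]
            assert all(len(f) == 2 for f in folds)
            combined = np.sort(np.concatenate(folds))
            np.testing.assert_array_equal(combined, np.arange(10))

    def test_near_equal_sizes_with_remainder(self):
        plan = g.make_cv_plan(11, k=5, n_reps=1, seed=1)
        sizes = sorted(len(f) for f in plan.folds[0])
        assert max(sizes) - min(sizes) <= 1

    def test_defaults_match_study_protocol(self):
        plan = g.make_cv_plan(50, seed=2)
        assert plan.k == 5 and plan.n_reps == 10

    def test_n_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            g.make_cv_plan(3, k=5, seed=0)


class TestBootstrap:
    def test_perfect_prediction_all_ones(self):
        y = np.random.default_rng(0).normal(size=30)
        rs, n_undef = g.bootstrap_accuracy(y, y, n_boot=50, seed=1)
        assert n_undef == 0
        np.testing.assert_allclose(rs, 1.0)

    def test_bootstrap_mean_consistent_with_full_sample(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=100)
        gv = 0.5 * y + rng.normal(size=100)
        rs, _ = g.bootstrap_accuracy(y, gv, n_boot=1000, seed=3)
        full = g.pearson_accuracy(y, gv)
        assert abs(np.mean(rs) - full) < 2 * np.std(rs, ddof=1)

    def test_default_resample_protocol(self):
        import inspect

        assert inspect.signature(g.bootstrap_accuracy).parameters["n_boot"].default == 1000

    def test_invalid_n_boot(self):
        with pytest.raises(ValueError):
            g.bootstrap_accuracy([1.0, 2.0], [1.0, 2.0], n_boot=0)


@pytest.fixture(scope="module")
def small_world():
    gmap = g.simulate_map(120, 5, 120, seed=31)
    panel_a, panel_b = g.simulate_species_pair(60, 60, gmap, 3, 0.25, 0.3, seed=32)
    fams = g.sample_parents_and_families(panel_a, panel_b, gmap,
                                         n_families=3, n_f1=10, n_f2=60, seed=33)
    return gmap, panel_a, panel_b, fams


class TestWithinPanel:
    def test_run_count_per_method(self, small_world):
        _, panel, _, _ = small_world
        suite = g.simulate_trait_suite(panel, panel, [], "S.QTN", seed=34)
        plan = g.make_cv_plan(60, k=5, n_reps=2, seed=35)
        df = g.within_panel_experiment(panel, suite["panel_a"].phenotypes, plan,
                                       cdmean_iters=10, seed=36)
        counts = df.groupby("configuration").size()
        assert set(counts.index) == {"RRBLUP.Whole", "RRBLUP.Random", "RRBLUP.CDmean", "PC.only"}
        assert (counts == 10).all()  # n_reps * k runs per method

    def test_null_trait_accuracy_near_zero(self):
        # a weakly structured panel and many independent noise traits: the
        # per-trait fold accuracies are correlated, so averaging over traits
        # (not folds) is what drives the mean to zero
        gmap = g.simulate_map(80, 4, 120, seed=60)
        panel = g.simulate_panel(60, gmap, 2, 0.05, seed=61)
        rng = np.random.default_rng(37)
        means = []
        for t in range(15):
            y = rng.normal(size=60)
            plan = g.make_cv_plan(60, k=5, n_reps=1, seed=100 + t)
            df = g.within_panel_experiment(panel, y, plan, cdmean_iters=2,
                                           seed=200 + t)
            means.append(df["r"].mean())
        assert abs(np.mean(means)) < 0.1

    def test_structure_trait_pc_model_competitive(self, small_world):
        """A trait equal to subpopulation means is structure-confounded: the
        PC-only model tracks RR-BLUP closely on it."""
        _, panel, _, _ = small_world
        rng = np.random.default_rng(40)
        means = {k: rng.normal() for k in np.unique(panel.subpop_label)}
        gv = np.array([means[k] for k in panel.subpop_label])
        y = g.add_noise_to_target_h2(gv, 0.8, seed=41).phenotypes
        plan = g.make_cv_plan(60, k=5, n_reps=2, seed=42)
        df = g.within_panel_experiment(panel, y, plan, cdmean_iters=5, seed=43)
        mean_r = df.groupby("configuration")["r"].mean()
        spread = df.groupby("configuration")["r"].std().max()
        assert abs(mean_r["PC.only"] - mean_r["RRBLUP.Whole"]) < 2 * spread

    def test_subset_size_guard(self, small_world):
        _, panel, _, _ = small_world
        plan = g.make_cv_plan(60, k=5, n_reps=1, seed=44)
        with pytest.raises(ValueError):
            g.within_panel_experiment(panel, np.zeros(60) + np.arange(60), plan,
                                      subset_size=55, cdmean_iters=1, seed=45)

    def test_no_leakage_of_validation_phenotypes(self, small_world):
        """Perturbing held-out phenotypes must not change any training output."""
        _, panel, _, _ = small_world
        X = g.code_markers(panel.genotypes)
        rng = np.random.default_rng(46)
        y = rng.normal(size=60)
        train, valid = np.arange(45), np.arange(45, 60)
        gebv1 = g.RRBLUP().fit(X[train], y[train]).gebv(X[valid])
        y2 = y.copy()
        y2[valid] = rng.normal(size=15)
        gebv2 = g.RRBLUP().fit(X[train], y2[train]).gebv(X[valid])
        np.testing.assert_array_equal(gebv1, gebv2)


class TestCrossPanel:
    def test_sum_configuration_is_sum_of_wholes(self, small_world):
        _, pa, pb, fams = small_world
        suite = g.simulate_trait_suite(pa, pb, fams, "S.QTN", seed=47)
        X_t = g.code_markers(fams[0].f2)
        y_a, y_b = suite["panel_a"].phenotypes, suite["panel_b"].phenotypes
        gebv_a = g.RRBLUP().fit(g.code_markers(pa.genotypes), y_a).gebv(X_t)
        gebv_b = g.RRBLUP().fit(g.code_markers(pb.genotypes), y_b).gebv(X_t)
        df = g.cross_panel_experiment(
            pa, pb, y_a, y_b, fams[0].f2, suite["families"][0].phenotypes,
            configs=("Whole.MsiMsa",), seed=48,
        )
        expected = g.pearson_accuracy(suite["families"][0].phenotypes,
                                      g.sum_gebv(gebv_a, gebv_b))
        assert df["r"].iloc[0] == pytest.approx(expected)

    def test_random_with_full_subset_reduces_to_whole(self, small_world):
        _, pa, pb, fams = small_world
        suite = g.simulate_trait_suite(pa, pb, fams, "S.QTN", seed=49)
        y_a, y_b = suite["panel_a"].phenotypes, suite["panel_b"].phenotypes
        y_t = suite["families"][0].phenotypes
        df = g.cross_panel_experiment(
            pa, pb, y_a, y_b, fams[0].f2, y_t,
            configs=("Msi.Random", "Msi.Whole"), subset_size=60, seed=50,
        )
        r = df.set_index("configuration")["r"]
        assert r["Msi.Random"] == pytest.approx(r["Msi.Whole"])

    def test_config_labels_round_trip(self, small_world):
        _, pa, pb, fams = small_world
        suite = g.simulate_trait_suite(pa, pb, fams, "S.QTN", seed=51)
        df = g.cross_panel_experiment(
            pa, pb, suite["panel_a"].phenotypes, suite["panel_b"].phenotypes,
            fams[0].f2, suite["families"][0].phenotypes,
            configs=("Msi.Whole", "Msa.Whole"), n_boot=20, seed=52,
        )
        assert set(df["configuration"]) == {"Msi.Whole", "Msa.Whole"}
        assert (df.groupby("configuration").size() == 21).all()  # 1 point + 20 boot

    def test_unknown_configuration_rejected(self, small_world):
        _, pa, pb, fams = small_world
        with pytest.raises(ValueError):
            g.cross_panel_experiment(
                pa, pb, np.zeros(60), np.zeros(60), fams[0].f2,
                np.zeros(60), configs=("Whole.Nonsense",), seed=0,
            )


class TestSimulationExperiment:
    def test_grid_shape_and_metadata(self, small_world):
        _, pa, pb, fams = small_world
        df = g.simulation_experiment(
            pa, pb, fams, scenarios=("S.QTN", "D.QTN"),
            architectures=("A20D0E0", "A20D4E0"),
            configs=("Msi.Whole", "Msa.Whole"), seed=53,
        )
        assert len(df) == 2 * 2 * 2 * len(fams)
        assert set(df["scenario"]) == {"S.QTN", "D.QTN"}
        assert set(df["architecture"]) == {"A20D0E0", "A20D4E0"}
        assert df["r_genetic"].notna().all()

    def test_deterministic_given_seed(self, small_world):
        _, pa, pb, fams = small_world
        kwargs = dict(scenarios=("S.QTN",), architectures=("A20D0E0",),
                      configs=("Msi.Whole",), seed=54)
        df1 = g.simulation_experiment(pa, pb, fams, **kwargs)
        df2 = g.simulation_experiment(pa, pb, fams, **kwargs)
        np.testing.assert_array_equal(df1["r"].to_numpy(), df2["r"].to_numpy())
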