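import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline
from sklearn.metrics import adjusted_rand_score

from plasmadrift import (
    ArchetypeSpec,
    DriftConfig,
    DriftProfile,
    SimulationConfig,
    cluster_profiles,
    compute_profiles,
    filter_irreproducible,
    fit_drift_fn,
    fit_drift_model,
    simulate,
)
from plasmadrift.drift_model import DriftModelError

from conftest import meta_at, small_sim_config

TIMES = [1.0, 3.0, 8.0, 24.0, 36.0]


def _tiny_study(fc_by_subject: dict[str, list[float]], times=(1.0, 3.0, 8.0)):
    """Build table+meta where one feature follows given per-subject fold-changes."""
    rows, meta = [], []
    for subj, fcs in fc_by_subject.items():
        base = 100.0
        for t, fc in zip(times, fcs):
            sid = f"{subj}_{t:g}"
            rows.append((sid, base * fc))
            meta.append({"sample_id": sid, "subject_id": subj,
                         "time_h": t, "temperature_c": 22.0})
    from plasmadrift import FeatureTable
    table = FeatureTable(
        pd.DataFrame({"f": [r[1] for r in rows]}, index=[r[0] for r in rows])
    )
    return table, pd.DataFrame(meta)


class TestComputeProfiles:
    def test_hand_computed_fold_changes_and_correlation(self):
        # subject A fold-changes (1, 2, 3); subject B (1, 3, 4):
        # Pearson correlation of the log profiles is 0.98460 (hand-checked)
        table, meta = _tiny_study({"A": [1, 2, 3], "B": [1, 3, 4]})
        profiles, excluded = compute_profiles(table, meta, t_ref=1.0)
        assert excluded == []
        (p,) = profiles
        np.testing.assert_allclose(
            p.per_subject_profile.loc["A"], [1, 2, 3], rtol=1e-12
        )
        np.testing.assert_allclose(p.mean_profile, [1.0, 2.5, 3.5], rtol=1e-12)
        expected_r = np.corrcoef(np.log([1, 2, 3]), np.log([1, 3, 4]))[0, 1]
        assert p.reproducibility == pytest.approx(expected_r, abs=1e-12)
        assert p.reproducibility == pytest.approx(0.98460, abs=5e-5)

    def test_constant_feature_is_flat_with_zero_reproducibility(self):
        table, meta = _tiny_study({"A": [1, 1, 1], "B": [1, 1, 1]})
        (p,), _ = compute_profiles(table, meta)
        np.testing.assert_allclose(p.mean_profile, 1.0)
        assert p.reproducibility == 0.0

    def test_identical_kinetics_give_reproducibility_one(self):
        table, meta = _tiny_study({"A": [1, 2, 4], "B": [1, 2, 4], "C": [1, 2, 4]})
        (p,), _ = compute_profiles(table, meta)
        assert p.reproducibility == pytest.approx(1.0)

    def test_missing_reference_sample_is_error(self):
        table, meta = _tiny_study({"A": [1, 2, 3]})
        meta = meta[meta["time_h"] != 1.0]
        with pytest.raises(DriftModelError, match="reference time"):
            compute_profiles(table.subset(samples=list(meta["sample_id"])), meta)

    def test_mixed_temperature_rejected(self):
        table, meta = _tiny_study({"A": [1, 2, 3], "B": [1, 2, 3]})
        meta.loc[meta["subject_id"] == "B", "temperature_c"] = 4.0
        with pytest.raises(DriftModelError, match="single temperature"):
            compute_profiles(table, meta)

    def test_zero_reference_intensity_flags_feature(self):
        table, meta = _tiny_study({"A": [1, 2, 3], "B": [1, 2, 3]})
        data = table.data.copy()
        data.loc["A_1", "f"] = 0.0
        from plasmadrift import FeatureTable
        profiles, excluded = compute_profiles(FeatureTable(data), meta)
        assert profiles == []
        assert excluded == [("f", "unassigned")]


class TestFilterIrreproducible:
    def _profile(self, fid, mean, repro):
        mp = pd.Series(mean, index=TIMES)
        return DriftProfile(fid, pd.DataFrame(), mp, repro)

    def test_vacuous_threshold_excludes_nothing(self):
        profiles = [self._profile("a", [1, 2, 3, 4, 5], -0.9)]
        kept, excluded = filter_irreproducible(profiles, threshold=-1.0)
        assert len(kept) == 1 and excluded == []

    def test_flat_but_noisy_features_kept_as_stable(self):
        profiles = [self._profile("flat", [1.0, 1.01, 0.99, 1.02, 1.0], 0.0)]
        kept, excluded = filter_irreproducible(profiles, threshold=0.5, flat_tol=0.05)
        assert [p.feature_id for p in kept] == ["flat"]

    def test_drifting_low_reproducibility_excluded(self):
        profiles = [
            self._profile("bad", [1.0, 1.3, 1.6, 2.0, 2.2], 0.1),
            self._profile("good", [1.0, 1.3, 1.6, 2.0, 2.2], 0.95),
        ]
        kept, excluded = filter_irreproducible(profiles, threshold=0.5)
        assert [p.feature_id for p in kept] == ["good"]
        assert excluded == [("bad", "irreproducible")]

    def test_planted_random_sign_drift_is_excluded(self):
        # subjects drift with random kinetics: reproducibility ~ 0
        rng = np.random.default_rng(5)
        table_rows, meta_rows = [], []
        for s in range(8):
            kin = np.concatenate([[0.0], rng.uniform(-1, 1, 4)])
            for t, k in zip(TIMES, kin):
                sid = f"P{s}_{t:g}"
                table_rows.append((sid, 100.0 * 2.0 ** k))
                meta_rows.append({"sample_id": sid, "subject_id": f"P{s}",
                                  "time_h": t, "temperature_c": 22.0})
        from plasmadrift import FeatureTable
        table = FeatureTable(pd.DataFrame(
            {"f": [r[1] for r in table_rows]}, index=[r[0] for r in table_rows]
        ))
        profiles, _ = compute_profiles(table, pd.DataFrame(meta_rows))
        kept, excluded = filter_irreproducible(profiles, threshold=0.5)
        assert excluded == [("f", "irreproducible")]


class TestClusterProfiles:
    def _profiles_from_curves(self, curves, n_each, noise_sd, seed):
        rng = np.random.default_rng(seed)
        profiles, truth = [], []
        for ci, curve in enumerate(curves):
            for j in range(n_each):
                mp = np.asarray(curve) * np.exp(rng.normal(0, noise_sd, len(curve)))
                mp[0] = 1.0
                profiles.append(DriftProfile(
                    f"c{ci}_f{j}", pd.DataFrame(), pd.Series(mp, index=TIMES), 1.0
                ))
                truth.append(ci)
        return profiles, truth

    def test_two_planted_archetypes_recovered_exactly(self):
        up = [1.0, 1.2, 1.5, 1.9, 2.1]
        down = [1.0, 0.9, 0.75, 0.6, 0.55]
        profiles, truth = self._profiles_from_curves([up, down], 20, 0.01, seed=1)
        assignments = cluster_profiles(profiles, k_range=(2, 10))
        labels = {f: cid for cid, members in assignments for f in members}
        pred = [labels[p.feature_id] for p in profiles]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_four_archetypes_recovered(self):
        curves = [
            [1.0, 1.2, 1.5, 1.9, 2.1],           # monotone up
            [1.0, 0.9, 0.75, 0.6, 0.55],          # monotone down
            [1.0, 1.0, 1.0, 1.0, 1.0],            # flat
            [1.0, 1.5, 1.05, 1.0, 1.0],           # 3 h excursion
        ]
        profiles, truth = self._profiles_from_curves(curves, 15, 0.02, seed=2)
        assignments = cluster_profiles(profiles, k_range=(2, 12))
        labels = {f: cid for cid, members in assignments for f in members}
        pred = [labels[p.feature_id] for p in profiles]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_identical_profiles_collapse_to_one_cluster(self):
        profiles, _ = self._profiles_from_curves([[1, 1.2, 1.4, 1.6, 1.8]], 10, 0.0, 3)
        assignments = cluster_profiles(profiles, k_range=(2, 5))
        assert len(assignments) == 1
        assert len(assignments[0][1]) == 10

    def test_too_few_profiles_is_error(self):
        profiles, _ = self._profiles_from_curves([[1, 1.2, 1.4, 1.6, 1.8]], 1, 0.0, 3)
        with pytest.raises(DriftModelError, match=">= 2 profiles"):
            cluster_profiles(profiles)


class TestFitDriftFn:
    def test_flat_profile_gives_unit_function(self):
        fn = fit_drift_fn([1.0] * 5, TIMES, t_ref=1.0)
        np.testing.assert_allclose(fn(np.linspace(1, 36, 50)), 1.0, atol=1e-12)

    def test_interpolates_anchored_values_at_knots(self):
        vals = [1.0, 1.1, 1.4, 1.8, 1.95]
        fn = fit_drift_fn(vals, TIMES, t_ref=1.0)
        np.testing.assert_allclose(fn(TIMES), vals, atol=1e-10)

    def test_linear_profile_reproduced_between_knots(self):
        # natural cubic splines reproduce affine data exactly: g(t)=1+0.05(t-1)
        vals = [1 + 0.05 * (t - 1) for t in TIMES]
        fn = fit_drift_fn(vals, TIMES, t_ref=1.0)
        assert fn(20.0) == pytest.approx(1.95, rel=0.02)
        # independent oracle: scipy natural spline on the same knots
        oracle = CubicSpline(TIMES, vals, bc_type="natural")
        grid = np.linspace(1, 36, 200)
        np.testing.assert_allclose(fn(grid), oracle(grid), rtol=1e-10)

    def test_anchoring_normalizes_at_t_ref(self):
        vals = [2.0, 2.2, 2.8, 3.6, 3.9]  # not anchored
        fn = fit_drift_fn(vals, TIMES, t_ref=1.0)
        assert fn(1.0) == pytest.approx(1.0, abs=1e-10)

    def test_out_of_range_clamps_to_boundary(self):
        vals = [1.0, 1.1, 1.4, 1.8, 1.95]
        fn = fit_drift_fn(vals, TIMES, t_ref=1.0)
        assert fn(0.2) == pytest.approx(fn(1.0))
        assert fn(100.0) == pytest.approx(fn(36.0))

    def test_positivity_guard_falls_back_to_linear(self):
        # sharp dip forces the cubic to undershoot zero between knots
        vals = [1.0, 1.0, 0.01, 1.0, 1.0]
        with pytest.warns(UserWarning, match="piecewise-linear"):
            fn = fit_drift_fn(vals, TIMES, t_ref=1.0)
        assert fn.kind == "linear"
        assert np.min(fn(np.linspace(1, 36, 300))) > 0

    @pytest.mark.parametrize(
        "vals, times, match",
        [
            ([1, 1.1, 1.2], [1, 3, 8], "insufficient time points"),
            ([1, 1.1, -0.2, 1.3, 1.1], TIMES, "positive"),
            ([1, 1.1, 1.2, 1.3, 1.4], [1, 3, 3, 24, 36], "increasing"),
        ],
    )
    def test_invalid_inputs(self, vals, times, match):
        with pytest.raises(DriftModelError, match=match):
            fit_drift_fn(vals, times, t_ref=1.0)


class TestFitDriftModel:
    def test_noiseless_simulation_recovers_truth_at_knots(self):
        cfg = small_sim_config(
            seed=5, noise_sd=0.0, dilution_sd=0.0,
            n_features=36,
            cluster_spec=(
                ArchetypeSpec("increase", 12, 1.8, attenuation=2.5, tau_h=20.0),
                ArchetypeSpec("decrease", 12, 0.8, attenuation=3.5, tau_h=16.0),
                ArchetypeSpec("stable", 12, 0.0),
            ),
        )
        table, meta, truth = simulate(cfg)
        m22 = meta_at(meta, 22.0)
        model = fit_drift_model(table.subset(samples=list(m22["sample_id"])), m22)
        assert len(model.clusters) == 3
        assert model.excluded_features == []
        times = np.asarray(TIMES)
        for cluster in model.clusters:
            label = truth.feature_cluster[cluster.member_features[0]]
            expected = truth.g_true_anchored(label, 22.0, times)
            np.testing.assert_allclose(cluster.drift_fn(times), expected, atol=1e-10)
            # every member comes from the same planted cluster
            assert set(truth.feature_cluster[cluster.member_features]) == {label}

    def test_partition_property(self, small_sim):
        table, meta, _ = small_sim
        m22 = meta_at(meta, 22.0)
        model = fit_drift_model(table.subset(samples=list(m22["sample_id"])), m22)
        assigned = [f for c in model.clusters for f in c.member_features]
        excluded = [f for f, _ in model.excluded_features]
        assert sorted(assigned + excluded) == sorted(table.feature_ids)
        assert len(set(assigned)) == len(assigned)

    def test_anchor_invariant(self, small_sim):
        table, meta, _ = small_sim
        m4 = meta_at(meta, 4.0)
        model = fit_drift_model(table.subset(samples=list(m4["sample_id"])), m4)
        for cluster in model.clusters:
            assert abs(cluster.drift_fn(model.t_ref) - 1.0) <= 1e-10

    def test_scale_invariance_of_feature_columns(self, small_sim):
        table, meta, _ = small_sim
        m22 = meta_at(meta, 22.0)
        sub = table.subset(samples=list(m22["sample_id"]))
        base = fit_drift_model(sub, m22)
        scaled_data = sub.data.copy()
        scaled_data.iloc[:, 0] *= 137.0
        from plasmadrift import FeatureTable
        scaled = fit_drift_model(FeatureTable(scaled_data), m22)
        assert [c.member_features for c in base.clusters] == [
            c.member_features for c in scaled.clusters
        ]
        grid = np.linspace(1, 36, 40)
        for c0, c1 in zip(base.clusters, scaled.clusters):
            np.testing.assert_allclose(c0.drift_fn(grid), c1.drift_fn(grid), rtol=1e-10)

    def test_single_time_point_is_error(self):
        table, meta = _tiny_study({"A": [1.0], "B": [1.0]}, times=(1.0,))
        with pytest.raises(DriftModelError, match="insufficient time points"):
            fit_drift_model(table, meta)

    def test_mixed_temperature_is_error(self, small_sim):
        table, meta, _ = small_sim
        with pytest.raises(DriftModelError, match="single temperature"):
            fit_drift_model(table, meta)
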