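import numpy as np
import pytest

from wristnms.emg_baseline import train_ann
from wristnms.musculoskeletal import MUSCLE_NAMES, ExcitationTrajectory
from wristnms.neural_mapping import (
    AssignmentMap,
    LinearUnitModel,
    NeuralModel,
    RankDeficiencyError,
    assign_units,
    fit_unit_regressor,
    irls_bisquare,
    predict_excitations,
    train_neural_model,
)
from wristnms.spike_features import DSCMatrix, SpikeTrainSet, build_window_grid, extract_dsc


def _excitation_with(muscle_values: dict, n_windows=10, step=0.1):
    times = np.arange(n_windows) * step
    values = np.zeros((n_windows, 6))
    for name, vals in muscle_values.items():
        values[:, MUSCLE_NAMES.index(name)] = vals
    return ExcitationTrajectory(times, values)


class TestAssignUnits:
    def test_eight_of_ten_assigned(self):
        # FCR excitation positive in windows 0..7 only; 10 spikes, one per window
        vals = np.zeros(10)
        vals[:8] = 0.5
        exc = _excitation_with({"FCR": vals})
        spikes = SpikeTrainSet({"u": np.arange(10) * 0.1 + 0.05}, 1.0)
        amap = assign_units(spikes, exc)
        assert amap.muscles_of("u") == {"FCR"}

    def test_seven_of_ten_not_assigned(self):
        vals = np.zeros(10)
        vals[:7] = 0.5
        exc = _excitation_with({"FCR": vals})
        spikes = SpikeTrainSet({"u": np.arange(10) * 0.1 + 0.05}, 1.0)
        amap = assign_units(spikes, exc)
        assert "u" in amap.unassigned

    def test_multiple_qualifying_muscles_all_assigned(self):
        exc = _excitation_with({"FCR": np.full(10, 0.4), "FCU": np.full(10, 0.3)})
        spikes = SpikeTrainSet({"u": np.arange(10) * 0.1 + 0.05}, 1.0)
        amap = assign_units(spikes, exc)
        assert amap.muscles_of("u") == {"FCR", "FCU"}

    def test_zero_spike_unit_flagged(self):
        exc = _excitation_with({"FCR": np.full(10, 0.4)})
        spikes = SpikeTrainSet({"u": np.array([])}, 1.0)
        amap = assign_units(spikes, exc)
        assert "u" in amap.unassigned
        assert "u" in amap.zero_spike_units

    def test_pooled_across_trials(self):
        # 4/5 coincident in each of two trials -> pooled 8/10 assigned
        vals = np.array([0.5, 0.5, 0.5, 0.5, 0.0])
        exc = _excitation_with({"FCU": vals}, n_windows=5)
        spikes = SpikeTrainSet({"u": np.arange(5) * 0.1 + 0.05}, 0.5)
        amap = assign_units([spikes, spikes], [exc, exc])
        assert amap.muscles_of("u") == {"FCU"}

    def test_true_muscle_recovered_on_synthetic_data(self, clean_dataset):
        ds = clean_dataset
        pairs = [(t.spikes, t.true_excitations) for t in ds.trials]
        amap = assign_units([p[0] for p in pairs], [p[1] for p in pairs])
        fired = [u for u, st in pairs[0][0].trains.items()]
        total, ok = 0, 0
        for uid, muscles in amap.assignments.items():
            total += 1
            ok += uid.split("_")[0] in muscles
        assert total > 0
        assert ok / total >= 0.9


class TestIRLS:
    def test_exact_recovery_on_clean_linear_data(self, rng):
        x = rng.integers(0, 6, 100).astype(float)
        y = 0.1 + 0.02 * x
        X = np.column_stack([np.ones_like(x), x])
        beta, _, _ = irls_bisquare(X, y)
        np.testing.assert_allclose(beta, [0.1, 0.02], atol=1e-10)

    def test_outlier_resistance_beats_ols(self, rng):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.integers(0, 8, 120).astype(float)
            y = 0.1 + 0.02 * x + r.normal(0, 0.002, x.size)
            out = r.choice(x.size, size=12, replace=False)
            y[out] = 1.0
            X = np.column_stack([np.ones_like(x), x])
            beta_r, _, _ = irls_bisquare(X, y)
            beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            err_r = np.abs(beta_r - [0.1, 0.02]).max()
            err_ols = np.abs(beta_ols - [0.1, 0.02]).max()
            wins += err_r < err_ols
        assert wins >= 19

    def test_matches_statsmodels_rlm(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.uniform(0, 5, 200)
        y = 0.3 - 0.1 * x + rng.normal(0, 0.05, 200)
        y[rng.choice(200, 20, replace=False)] += 2.0
        X = np.column_stack([np.ones_like(x), x])
        beta, _, _ = irls_bisquare(X, y)
        fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
        np.testing.assert_allclose(beta, fit.params, atol=5e-3)


class TestFitUnitRegressor:
    def test_exact_linear_fit(self):
        x = np.array([1, 2, 3, 4, 5, 1, 2, 3], float)
        y = 0.1 + 0.02 * x
        m = fit_unit_regressor(x, y)
        assert m.intercept == pytest.approx(0.1, abs=1e-10)
        assert m.slope == pytest.approx(0.02, abs=1e-10)

    def test_fit_restricted_to_spiking_windows(self):
        x = np.array([0, 0, 1, 2, 3, 0, 4], float)
        y = 0.05 + 0.03 * x
        y[x == 0] = 99.0  # garbage in non-spiking windows must not matter
        m = fit_unit_regressor(x, y)
        assert m.intercept == pytest.approx(0.05, abs=1e-8)
        assert m.slope == pytest.approx(0.03, abs=1e-8)

    def test_constant_dsc_rank_deficiency(self):
        with pytest.raises(RankDeficiencyError):
            fit_unit_regressor(np.full(10, 2.0), np.linspace(0, 1, 10))


def _toy_neural_model(unit_models, fallback_value=0.11):
    """NeuralModel with a stub constant-output fallback per muscle."""
    X = np.linspace(0, 1, 20)[:, None]
    y = np.full(20, fallback_value)
    ann = train_ann(X, y, restarts=1, seed=0, max_iter=10)
    assignments = {}
    for (muscle, unit) in unit_models:
        assignments.setdefault(unit, set()).add(muscle)
    return NeuralModel(
        assignment=AssignmentMap(assignments, set()),
        unit_models=unit_models,
        fallback={m: ann for m in MUSCLE_NAMES},
    )


class TestPredictExcitations:
    def _dsc(self, counts, unit_ids):
        counts = np.asarray(counts)
        grid = build_window_grid(counts.shape[0] * 0.1, 0.1, 0.1)
        return DSCMatrix(counts, grid, unit_ids)

    def test_median_of_active_unit_estimates(self):
        units = ["a", "b", "c"]
        models = {
            ("FCR", u): LinearUnitModel("FCR", u, v, 0.0)
            for u, v in zip(units, [0.2, 0.4, 0.9])
        }
        nm = _toy_neural_model(models)
        dsc = self._dsc([[1, 1, 1]], units)
        exc = predict_excitations(nm, dsc, td_features=np.zeros((1, 1)))
        assert exc.values[0, MUSCLE_NAMES.index("FCR")] == pytest.approx(0.4, abs=1e-6)

    def test_fallback_used_when_no_unit_active(self):
        models = {("FCR", "a"): LinearUnitModel("FCR", "a", 0.5, 0.0)}
        nm = _toy_neural_model(models, fallback_value=0.11)
        dsc = self._dsc([[0]], ["a"])
        exc = predict_excitations(nm, dsc, td_features=np.zeros((1, 1)))
        assert exc.values[0, MUSCLE_NAMES.index("FCR")] == pytest.approx(0.11, abs=1e-3)

    def test_negative_estimate_clamped_to_zero(self):
        models = {("FCR", "a"): LinearUnitModel("FCR", "a", -0.05, 0.0)}
        nm = _toy_neural_model(models)
        dsc = self._dsc([[1]], ["a"])
        exc = predict_excitations(nm, dsc, td_features=np.zeros((1, 1)))
        assert exc.values[0, MUSCLE_NAMES.index("FCR")] == 0.0

    def test_missing_td_features_for_fallback_rejected(self):
        nm = _toy_neural_model({})
        dsc = self._dsc([[0]], ["a"])
        with pytest.raises(ValueError):
            predict_excitations(nm, dsc, td_features=None)

    def test_median_insensitive_to_single_unit_spike_deletion(self, rng):
        # deleting 20% of one unit's spikes moves the ensemble less than that
        # unit's own estimate
        units = [f"u{i}" for i in range(5)]
        models = {
            ("FCU", u): LinearUnitModel("FCU", u, 0.05, 0.04 + 0.01 * i)
            for i, u in enumerate(units)
        }
        nm = _toy_neural_model(models)
        counts = rng.integers(1, 6, size=(40, 5))
        dsc = self._dsc(counts, units)
        base = predict_excitations(nm, dsc, np.zeros((40, 1)))
        counts2 = counts.copy()
        drop = rng.random(40) < 0.2
        counts2[drop, 0] = np.maximum(counts2[drop, 0] - 1, 1)
        dsc2 = self._dsc(counts2, units)
        pred2 = predict_excitations(nm, dsc2, np.zeros((40, 1)))
        m = MUSCLE_NAMES.index("FCU")
        ens_change = np.abs(pred2.values[:, m] - base.values[:, m]).mean()
        unit_change = np.abs(
            models[("FCU", "u0")].predict(counts2[:, 0])
            - models[("FCU", "u0")].predict(counts[:, 0])
        ).mean()
        assert ens_change < unit_change


class TestTrainNeuralModel:
    def _training_setup(self, rng):
        n_w = 60
        grid = build_window_grid(n_w * 0.1, 0.1, 0.1)
        e = np.abs(np.sin(np.linspace(0, 3, n_w))) * 0.6
        exc = _excitation_with({"FCU": e, "FCR": e * 0.8}, n_windows=n_w)
        units = ["FCU_a", "FCU_b", "FCU_c", "FCR_x"]
        counts = np.zeros((n_w, 4), dtype=int)
        for j, u in enumerate(units):
            lam = 10 * e + rng.normal(0, 0.3, n_w)
            counts[:, j] = np.clip(np.round(lam), 0, None)
        dsc = DSCMatrix(counts, grid, units)
        assignment = AssignmentMap(
            {"FCU_a": {"FCU"}, "FCU_b": {"FCU"}, "FCU_c": {"FCU"},
             "FCR_x": {"FCR", "FCU"}},
            set(),
        )
        td = rng.normal(size=(n_w, 3))
        return dsc, exc, td, assignment

    def test_one_model_per_assigned_pair(self, rng):
        dsc, exc, td, assignment = self._training_setup(rng)
        nm = train_neural_model([dsc], [exc], [td], assignment,
                                ann_restarts=1, ann_seed=0, ann_max_iter=5)
        fcu_models = [k for k in nm.unit_models if k[0] == "FCU"]
        assert len(fcu_models) == 4  # 3 own units + cross-assigned FCR_x

    def test_six_fallback_networks(self, rng):
        dsc, exc, td, assignment = self._training_setup(rng)
        nm = train_neural_model([dsc], [exc], [td], assignment,
                                ann_restarts=1, ann_seed=0, ann_max_iter=5)
        assert set(nm.fallback) == set(MUSCLE_NAMES)

    def test_dual_assignment_gives_independent_models(self, rng):
        dsc, exc, td, assignment = self._training_setup(rng)
        nm = train_neural_model([dsc], [exc], [td], assignment,
                                ann_restarts=1, ann_seed=0, ann_max_iter=5)
        assert ("FCU", "FCR_x") in nm.unit_models
        assert ("FCR", "FCR_x") in nm.unit_models
        a = nm.unit_models[("FCU", "FCR_x")]
        b = nm.unit_models[("FCR", "FCR_x")]
        assert (a.intercept, a.slope) != (b.intercept, b.slope)

    def test_muscle_without_units_flagged_fallback_only(self, rng):
        dsc, exc, td, assignment = self._training_setup(rng)
        nm = train_neural_model([dsc], [exc], [td], assignment,
                                ann_restarts=1, ann_seed=0, ann_max_iter=5)
        assert "PT" in nm.fallback_only_muscles
        assert "FCU" not in nm.fallback_only_muscles


class TestParameterRecovery:
    def test_held_out_excitation_r2(self, clean_dataset):
        """Slopes positive and held-out excitation prediction R^2 >= 0.8 for
        muscles with linearly generated spike rates."""
        ds = clean_dataset
        train = [t for t in ds.trials if t.repetition_index in (1, 2)]
        test = [t for t in ds.trials if t.repetition_index == 3]
        amap = assign_units([t.spikes for t in train],
                            [t.true_excitations for t in train])
        dsc_train = [extract_dsc(t.spikes, ds.grid) for t in train]
        td_train = [np.zeros((ds.grid.n_windows, 1)) for t in train]
        nm = train_neural_model(dsc_train, [t.true_excitations for t in train],
                                td_train, amap, ann_restarts=1, ann_seed=0,
                                ann_max_iter=5)
        own = [m for (mus, u), m in nm.unit_models.items()
               if u.startswith(mus)]
        assert np.mean([m.slope > 0 for m in own]) > 0.9
        y_all, yhat_all = [], []
        for tr in test:
            dsc = extract_dsc(tr.spikes, ds.grid)
            pred = predict_excitations(nm, dsc, np.zeros((ds.grid.n_windows, 1)))
            # compare only unit-driven windows of muscles with assigned units
            for m, mus in enumerate(MUSCLE_NAMES):
                cols = [dsc.unit_ids.index(u) for u in amap.units_of(mus)
                        if u in dsc.unit_ids and (mus, u) in nm.unit_models]
                if not cols:
                    continue
                active = (dsc.counts[:, cols] >= 1).any(axis=1)
                y_all.append(tr.true_excitations.values[active, m])
                yhat_all.append(pred.values[active, m])
        y = np.concatenate(y_all)
        yhat = np.concatenate(yhat_all)
        from wristnms.pipeline_eval import r2

        assert r2(y, yhat) >= 0.8
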