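"""PSTH analysis and penalized Poisson tuning-curve model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.special import gammaln

from socialtrack3d.behavior_features import FeatureMatrix
from socialtrack3d.neural_tuning import (BinnedDesign, SpikeTrain,
                                         TuningConfig, co_encoding,
                                         delta_loglik_bits_per_spike,
                                         fit_tuning, forward_select,
                                         modulation_index,
                                         poisson_penalized_loglik, psth,
                                         simulate_spikes)

DT = 1.0 / 60.0


def _features(rng, T, n_noise=4, smooth=30):
    cols = {}
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(0, 1, T)
    v = gaussian_filter1d(rng.normal(0, 1, T), smooth)
    cols["drive"] = v / v.std()
    a = gaussian_filter1d(rng.normal(0, 1, T), smooth)
    cols["angle"] = np.mod(2 * a / a.std(), 2 * np.pi) - np.pi
    return FeatureMatrix(pd.DataFrame(cols), circular=("angle",))


def _design(fm, spikes=None, T=None):
    if spikes is None:
        T = T or len(fm.data)
        spikes = SpikeTrain("u", np.array([]), 0.0, T * DT)
    return BinnedDesign.from_features(fm, spikes, DT)


class TestPSTH:
    def _poisson_train(self, rng, rate, duration):
        n = rng.poisson(rate * duration)
        return SpikeTrain("u", np.sort(rng.uniform(0, duration, n)), 0, duration)

    def test_rate_doubling_detected(self, rng):
        duration = 600.0
        events = np.sort(rng.uniform(20, duration - 20, 40))
        base = self._poisson_train(rng, 5.0, duration).times
        extra = np.concatenate([ev + rng.uniform(-0.5, 0.5, rng.poisson(5.0))
                                for ev in events])
        spikes = SpikeTrain("u", np.sort(np.concatenate([base, extra])),
                            0, duration)
        res = psth(spikes, events, "naive")
        assert res["r_post"] / res["r_pre"] == pytest.approx(2.0, rel=0.25)
        assert res["p"] < 0.001

    def test_cleaned_mode_drops_events_with_busy_baseline(self, rng):
        spikes = self._poisson_train(rng, 5.0, 200.0)
        events = np.array([50.0, 52.0, 100.0, 150.0])
        res = psth(spikes, events, "cleaned", min_events=1)
        # 52 s has an event 2 s before it and is dropped.
        assert res["n_events"] == 3

    def test_type_i_error_calibrated(self, rng):
        # Homogeneous Poisson spiking, random events: p < 0.05 in ~5% of runs.
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            spikes = self._poisson_train(rng, 8.0, 300.0)
            events = np.sort(rng.uniform(10, 290, 25))
            res = psth(spikes, events, "naive")
            if res["p"] == res["p"] and res["p"] < 0.05:
                hits += 1
        # Binomial 95% band around 0.05 with n = 200: roughly [0.02, 0.09].
        assert 0.01 <= hits / n_runs <= 0.10

    def test_zero_spikes_skips_test(self):
        spikes = SpikeTrain("u", np.array([]), 0, 100.0)
        res = psth(spikes, np.array([20.0, 50.0, 70.0, 80.0, 90.0]), "naive")
        assert res["r_pre"] == 0 and res["r_post"] == 0
        assert np.isnan(res["p"])

    def test_under_powered_flagged(self, rng):
        spikes = self._poisson_train(rng, 5.0, 100.0)
        res = psth(spikes, np.array([50.0, 60.0]), "naive")
        assert res["under_powered"]

    def test_modulation_index(self):
        assert modulation_index(1.0, 1.0) == 0
        assert modulation_index(0.0, 5.0) == 1
        assert modulation_index(2.0, 1.0) == pytest.approx(-1 / 3)
        with pytest.raises(ValueError):
            modulation_index(0.0, 0.0)


class TestPenalizedLikelihood:
    def test_zero_curves_equal_constant_rate_likelihood(self, rng):
        fm = _features(rng, 2000)
        spikes = SpikeTrain("u", np.sort(rng.uniform(0, 2000 * DT, 500)),
                            0, 2000 * DT)
        design = _design(fm, spikes)
        c = {"drive": np.zeros(10)}
        obj, _, _ = poisson_penalized_loglik(c, design, 20.0)
        n = design.counts
        # exp(0) = 1 expected count per bin; no penalty for flat curves.
        expected = float(np.sum(n * 0.0 - 1.0))
        assert obj == pytest.approx(expected)

    def test_gradient_matches_finite_differences(self, rng):
        fm = _features(rng, 500)
        spikes = SpikeTrain("u", np.sort(rng.uniform(0, 500 * DT, 150)),
                            0, 500 * DT)
        design = _design(fm, spikes)
        c = {"drive": rng.normal(0, 0.2, 10), "angle": rng.normal(0, 0.2, 10)}
        _, grad, hessp = poisson_penalized_loglik(c, design, 20.0)
        eps = 1e-6
        for name in c:
            num = np.zeros(10)
            for i in range(10):
                cp = {k: v.copy() for k, v in c.items()}
                cm = {k: v.copy() for k, v in c.items()}
                cp[name][i] += eps
                cm[name][i] -= eps
                op, _, _ = poisson_penalized_loglik(cp, design, 20.0)
                om, _, _ = poisson_penalized_loglik(cm, design, 20.0)
                num[i] = (op - om) / (2 * eps)
            assert np.max(np.abs(grad[name] - num)) < 1e-6
        # Hessian-vector product vs finite-difference of the gradient.
        v = {k: rng.normal(0, 0.1, 10) for k in c}
        hv = hessp(v)
        cp = {k: c[k] + eps * v[k] for k in c}
        cm = {k: c[k] - eps * v[k] for k in c}
        _, gp, _ = poisson_penalized_loglik(cp, design, 20.0)
        _, gm, _ = poisson_penalized_loglik(cm, design, 20.0)
        for name in c:
            num = (gp[name] - gm[name]) / (2 * eps)
            assert np.max(np.abs(hv[name] - num)) < 1e-4

    def test_large_beta_flattens_curves(self, rng):
        fm = _features(rng, 4000)
        true = {"drive": np.linspace(-1, 1, 10)}
        design0 = _design(fm)
        spikes = simulate_spikes(design0.A, true, DT, rng)
        design = _design(fm, spikes)
        fit = fit_tuning(design, ["drive"], beta=1e7)
        curve = fit["curves"]["drive"]
        assert np.ptp(curve) < 0.01

    def test_curve_recovery_on_simulated_spikes(self, rng):
        T = 30000
        fm = _features(rng, T)
        centers = np.arange(10)
        true = {"drive": 0.8 * np.exp(-0.5 * ((centers - 6) / 1.5) ** 2) - 0.6}
        design0 = _design(fm, T=T)
        spikes = simulate_spikes(design0.A, true, DT, rng)
        design = _design(fm, spikes)
        fit = fit_tuning(design, ["drive"], beta=20.0)
        # The smoothness penalty biases sparsely occupied edge bins; assert
        # pointwise recovery where the data actually constrain the curve.
        occupied = design.A["drive"].sum(0) > 500
        assert occupied.sum() >= 7
        err = np.abs(fit["curves"]["drive"] - true["drive"])[occupied]
        assert np.max(err) < 0.1

    def test_empty_spike_train_flagged(self, rng):
        fm = _features(rng, 1000)
        design = _design(fm)
        fit = fit_tuning(design, ["drive"], beta=20.0)
        assert not fit["converged"]
        assert np.all(fit["curves"]["drive"] <= -10)


class TestDeltaLoglik:
    def test_constant_model_gives_zero(self, rng):
        n = rng.poisson(2.0, 500)
        lam = np.full(500, n.mean())
        assert delta_loglik_bits_per_spike(lam, n) == pytest.approx(0.0)

    def test_three_bin_toy_hand_computed(self):
        n = np.array([0.0, 1.0, 2.0])
        lam = np.array([0.5, 1.0, 1.5])
        # Hand evaluation: L = sum(lam - n log lam + log n!)/sum(n), per spike,
        # for the model and for the constant rate <n> = 1.
        l_model = (np.sum(lam - n * np.log(lam) + gammaln(n + 1))) / 3
        l_const = (np.sum(1.0 - n * np.log(1.0) + gammaln(n + 1))) / 3
        expected = (l_const - l_model) / np.log(2)
        assert delta_loglik_bits_per_spike(lam, n) == pytest.approx(expected)
        assert expected > 0  # the graded rates fit better than the mean

    def test_per_spike_normalization_scale_invariance(self, rng):
        n = rng.poisson(3.0, 400).astype(float)
        lam = np.maximum(n + rng.normal(0, 0.5, 400), 0.1)
        a = delta_loglik_bits_per_spike(lam, n)
        b = delta_loglik_bits_per_spike(np.tile(lam, 2), np.tile(n, 2))
        assert a == pytest.approx(b)


class TestForwardSelection:
    def _planted(self, seed, T=12000):
        rng = np.random.default_rng(seed)
        fm = _features(rng, T)
        centers = np.arange(10)
        true = {"drive": np.linspace(-0.5, 0.8, 10) - 1.0,
                "angle": np.exp(-0.5 * ((centers - 2.5) / 1.5) ** 2) - 0.5}
        design0 = _design(fm, T=T)
        spikes = simulate_spikes(design0.A, true, DT, rng)
        return BinnedDesign.from_features(fm, spikes, DT)

    def test_planted_features_recovered(self):
        hits = 0
        for seed in (0, 1, 2):
            design = self._planted(seed)
            model = forward_select(design, TuningConfig(max_features=4))
            if set(model.library) == {"drive", "angle"}:
                hits += 1
            assert {"drive", "angle"} <= set(model.library)
        assert hits >= 2

    def test_null_spikes_give_empty_library(self, rng):
        empties = 0
        for seed in (3, 4, 5):
            r = np.random.default_rng(seed)
            fm = _features(r, 9000)
            spikes = SpikeTrain("u", np.sort(r.uniform(0, 9000 * DT, 3000)),
                                0, 9000 * DT)
            design = BinnedDesign.from_features(fm, spikes, DT)
            model = forward_select(design, TuningConfig(max_features=3))
            if not model.library:
                empties += 1
        assert empties >= 2

    def test_duplicate_feature_selected_once(self):
        design = self._planted(0)
        design.A["drive_copy"] = design.A["drive"].copy()
        design.edges["drive_copy"] = design.edges["drive"]
        design.circular["drive_copy"] = False
        model = forward_select(design, TuningConfig(max_features=4))
        assert sum(1 for f in model.library if f.startswith("drive")) <= 2
        # The second copy of an already-admitted feature adds no held-out
        # likelihood, so at most one of the pair carries the selection.
        assert {"drive", "drive_copy"} - set(model.library)

    def test_selection_history_and_gains_recorded(self):
        design = self._planted(1)
        model = forward_select(design, TuningConfig(max_features=3))
        assert len(model.history) == len(model.p_values)
        assert all(len(g) == 10 for g in model.fold_gains)
        # Held-out gain of the admitted model is positive on average.
        assert np.mean(model.fold_gains[0]) > 0


class TestSimulateSpikes:
    def test_zero_curves_give_unit_mean_counts(self, rng):
        fm = _features(rng, 20000)
        design = _design(fm)
        spikes = simulate_spikes(design.A, {"drive": np.zeros(10)}, DT, rng)
        counts = spikes.bin_counts(DT, 20000)
        assert counts.mean() == pytest.approx(1.0, abs=0.03)

    def test_empirical_rate_matches_analytic(self, rng):
        fm = _features(rng, 30000)
        design = _design(fm)
        true = {"drive": np.linspace(-1, 0.5, 10)}
        spikes = simulate_spikes(design.A, true, DT, rng)
        u = design.A["drive"] @ true["drive"]
        assert len(spikes.times) == pytest.approx(np.exp(u).sum(), rel=0.05)

    def test_fixed_seed_reproducible(self, rng):
        fm = _features(rng, 2000)
        design = _design(fm)
        a = simulate_spikes(design.A, {"drive": np.zeros(10)}, DT,
                            np.random.default_rng(7))
        b = simulate_spikes(design.A, {"drive": np.zeros(10)}, DT,
                            np.random.default_rng(7))
        assert np.array_equal(a.times, b.times)


class TestCoEncoding:
    def _model(self, lib):
        from socialtrack3d.neural_tuning import TuningModel
        return TuningModel("u", lib, {}, {}, 20.0, [], [], [])

    def test_single_neuron_two_features(self):
        df, edges = co_encoding([self._model(["a", "b"])], ["a", "b"])
        assert np.array_equal(df.to_numpy(), np.ones((2, 2), dtype=int))
        assert edges == [("a", "b", 1)]

    def test_disjoint_libraries_block_diagonal(self):
        models = [self._model(["a"]), self._model(["b"])]
        df, edges = co_encoding(models, ["a", "b"])
        assert np.array_equal(df.to_numpy(), np.eye(2, dtype=int))
        assert edges == []

    def test_random_libraries_match_combinatorial_oracle(self, rng):
        names = list("abcdef")
        models = []
        libs = []
        for _ in range(20):
            k = rng.integers(0, 5)
            lib = list(rng.choice(names, k, replace=False))
            libs.append(set(lib))
            models.append(self._model(lib))
        df, _ = co_encoding(models, names)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                expected = sum(1 for lib in libs if a in lib and b in lib)
                assert df.iloc[i, j] == expected
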