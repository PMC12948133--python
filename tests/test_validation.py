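"""Validation suite: recovery metrics, null simulation, PPC, coupling."""

import json

import numpy as np
import pandas as pd
import pytest

from sleepddm import generate, validation
from sleepddm.model import RegressionSpec
from sleepddm.trials import Stage
from sleepddm.validation import (NullSimReport, RecoveryQuality,
                                 RecoveryReport, classify_recovery,
                                 coupling_from_deltas,
                                 posterior_predictive_check,
                                 subject_params_from_draw)


class TestClassifyRecovery:
    @pytest.mark.parametrize("r,bias,rmse,expected", [
        (0.990, 0.042, 0.097, RecoveryQuality.EXCELLENT),
        (0.988, 0.014, 0.040, RecoveryQuality.EXCELLENT),
        (0.85, 0.08, 0.15, RecoveryQuality.GOOD),
        (0.75, 0.12, 0.25, RecoveryQuality.ACCEPTABLE),
        (0.60, 0.30, 0.50, RecoveryQuality.FLAGGED),
        # every tier requires all three of its conditions
        (0.99, 0.20, 0.05, RecoveryQuality.FLAGGED),
        (0.95, 0.04, 0.25, RecoveryQuality.ACCEPTABLE),
        (0.65, 0.01, 0.05, RecoveryQuality.FLAGGED),
    ])
    def test_tier_rule(self, r, bias, rmse, expected):
        assert classify_recovery(r, bias, rmse) is expected

    def test_thresholds_are_strict(self):
        # r must exceed (not equal) the tier's bound
        assert classify_recovery(0.90, 0.0, 0.0) is RecoveryQuality.GOOD


def synthetic_pairs(rng, n_iter=6, noise=0.05):
    spec = RegressionSpec.full()
    rows = []
    for it in range(n_iter):
        for fam in "vat":
            for c, name in zip(spec.family_columns(fam), spec.node_names(fam)):
                true = {"v": 1.0, "a": 2.5, "t": 0.5}[fam] if c == 0 else 0.3 / (c + 1)
                rows.append({
                    "iteration": it, "family": fam, "node": name,
                    "node_class": validation._node_class(c, 4),
                    "true": true, "recovered": true + noise * rng.standard_normal(),
                    "converged": True,
                })
    return pd.DataFrame(rows)


class TestRecoveryReport:
    def test_metrics_match_independent_recomputation(self, rng):
        pairs = synthetic_pairs(rng)
        report = RecoveryReport(pairs, 6, 0, [1, 2], "abc")
        m = report.metrics("v")
        sel = pairs[pairs.family == "v"]
        r_direct = np.corrcoef(sel.true, sel.recovered)[0, 1]
        assert m["r"] == pytest.approx(r_direct)
        per_node_bias = sel.groupby("node").apply(
            lambda g: (g.recovered - g.true).mean(), include_groups=False)
        assert m["bias"] == pytest.approx(per_node_bias.mean())
        assert m["abs_bias"] == pytest.approx(per_node_bias.abs().mean())
        rmse_pooled = np.sqrt(np.mean((sel.recovered - sel.true) ** 2))
        assert m["rmse_pooled"] == pytest.approx(rmse_pooled)
        assert m["rmse"] >= abs(m["bias"]) - 1e-12

    def test_shuffled_pairing_destroys_correlation(self, rng):
        pairs = synthetic_pairs(rng, noise=0.01)
        shuffled = pairs.copy()
        shuffled["recovered"] = rng.permutation(shuffled.recovered.to_numpy())
        r_orig = RecoveryReport(pairs, 6, 0, [], "x").metrics("v")["r"]
        r_shuf = RecoveryReport(shuffled, 6, 0, [], "x").metrics("v")["r"]
        assert r_orig > 0.99
        assert abs(r_shuf) < 0.5

    def test_nonconverged_iterations_excluded(self, rng):
        pairs = synthetic_pairs(rng)
        pairs.loc[pairs.iteration == 0, "converged"] = False
        report = RecoveryReport(pairs, 6, 1, [], "x")
        assert report.metrics("v")["n_pairs"] == 50
        assert report.metrics("v", include_nonconverged=True)["n_pairs"] == 60

    def test_stimulus_contrast_pool(self, rng):
        pairs = synthetic_pairs(rng)
        rmse = RecoveryReport(pairs, 6, 0, [], "x").stimulus_contrast_rmse("v")
        sel = pairs[(pairs.family == "v")
                    & pairs.node_class.isin(["stimulus", "interaction"])]
        assert rmse == pytest.approx(
            np.sqrt(np.mean((sel.recovered - sel.true) ** 2)))

    def test_json_round_trip(self, rng, tmp_path):
        report = RecoveryReport(synthetic_pairs(rng), 6, 0, [5], "h")
        payload = json.loads(report.to_json(tmp_path / "r.json"))
        assert payload["n_iter"] == 6 and len(payload["pairs"]) == 180


class TestNullSimReport:
    def test_summaries_match_recomputation(self):
        coefs = [0.05, -0.1, 0.2, 0.12, 0.31]
        rep = NullSimReport(coefs, [], "x", empirical_effect=0.458)
        assert rep.mean == pytest.approx(np.mean(coefs))
        assert rep.sd == pytest.approx(np.std(coefs, ddof=1))
        assert rep.max == pytest.approx(0.31)
        assert rep.p95 <= rep.max
        assert rep.exceeds_max is True
        assert rep.ratio_to_mean == pytest.approx(0.458 / np.mean(coefs))

    def test_comparison_effect_below_max(self):
        rep = NullSimReport([0.5, 0.6], [], "x", empirical_effect=0.458)
        assert rep.exceeds_max is False

    def test_no_empirical_effect(self):
        rep = NullSimReport([0.1], [], "x")
        assert rep.exceeds_max is None and rep.ratio_to_mean is None


class TestCoupling:
    def test_perfect_coupling(self):
        dx = np.array([0.1, -0.2, 0.3, 0.5, -0.4])
        r, p, n = coupling_from_deltas(dx, 2 * dx)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_independent_deltas_stay_small(self):
        rng = np.random.default_rng(99)
        small = 0
        for _ in range(100):
            r, _, _ = coupling_from_deltas(rng.standard_normal(27),
                                           rng.standard_normal(27))
            small += abs(r) < 0.4
        assert small >= 95

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            coupling_from_deltas(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_fit_based_coupling_runs(self, small_fit):
        r, p, n = validation.within_subject_coupling(small_fit)
        assert -1 <= r <= 1 and 0 <= p <= 1
        assert n == len(small_fit.subject_ids)


class TestPpc:
    def test_structure_preserved_and_bands(self, small_fit, small_study):
        rep = posterior_predictive_check(small_fit, small_study["design"],
                                         n_sim=5, seed=3, sim_dt=5e-4)
        assert len(rep.predictive) == 5
        assert set(rep.observed) >= {"accuracy", "rt_median", "rt_q25",
                                     "rt_q75", "rt_tail"}
        lo, hi = rep.band("accuracy")
        assert 0 <= lo <= hi <= 1

    def test_simulated_datasets_match_design_counts(self, small_fit, small_study):
        from collections import Counter
        params = subject_params_from_draw(small_fit, 0, 0)
        sim = generate.simulate_dataset(small_study["design"], params,
                                        seed=4, dt=5e-4)
        design = small_study["design"]
        got = Counter((t.subject_id, t.stage, t.stimulus) for t in sim)
        for sid, cells in design.counts.items():
            for cell, n in cells.items():
                assert got.get((sid, *cell), 0) == n

    def test_self_consistency_accuracy_in_band(self, small_fit, small_study):
        """Data generated from the model fall inside the predictive band."""
        rep = posterior_predictive_check(small_fit, small_study["design"],
                                         n_sim=20, seed=5, sim_dt=5e-4)
        assert rep.inside_band("accuracy")

    def test_collapsed_posterior_matches_absorption_average(self, small_fit, small_study):
        """With the posterior collapsed to one draw, predictive accuracy
        equals the design-weighted absorption probability."""
        from sleepddm._kernels import upper_probability
        params = subject_params_from_draw(small_fit, 0, 10)
        design = small_study["design"]
        exp_correct, n_tot = 0.0, 0
        for sid, _ in design.subjects:
            j = params.subject_ids.index(sid)
            for (stage, stim), n in design.counts[sid].items():
                if n == 0:
                    continue
                v, a, _, z = params.condition_params(j, stim, stage)
                exp_correct += n * upper_probability(v, a, z)
                n_tot += n
        expected = exp_correct / n_tot
        accs = []
        for s in range(6):
            sim = generate.simulate_dataset(design, params, seed=100 + s, dt=5e-4)
            accs.append(np.mean([t.correct for t in sim]))
        se = np.sqrt(expected * (1 - expected) / (n_tot * 6))
        assert abs(np.mean(accs) - expected) < 4 * se


class TestValidationDrivers:
    def test_recovery_requires_iterations(self, small_study):
        with pytest.raises(ValueError):
            validation.run_parameter_recovery(
                small_study["gen"], small_study["design"],
                RegressionSpec.full(), n_iter=1)

    def test_null_sim_requires_positive_threshold(self, small_study):
        with pytest.raises(ValueError):
            validation.run_null_threshold_simulation(
                small_study["design"], fixed_a=-1.0, n_iter=2)

    def test_compare_models_needs_two_specs(self, small_study):
        with pytest.raises(ValueError):
            validation.compare_models(small_study["trials"],
                                      [RegressionSpec.full()])
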