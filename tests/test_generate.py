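"""Synthetic-study generator: designs, parameter draws, trial simulation."""

import numpy as np
import pytest

from sleepddm import ddm, generate
from sleepddm.generate import GeneratingParameters
from sleepddm.trials import Group, Response, Stage, Stimulus


class TestMakeDesign:
    def test_np_profile_defaults(self):
        d = generate.make_design("NP_LIKE", seed=1)
        assert len(d.subjects) == 27
        assert all(g is Group.NP for _, g in d.subjects)
        # ~50 trials per subject on average
        assert 1150 <= d.total_trials() <= 1550
        assert d.stages_present() == {Stage.WAKE, Stage.N1, Stage.N2,
                                      Stage.REM, Stage.LUCID_REM}

    def test_hp_profile_has_no_rem_states(self):
        d = generate.make_design("HP_LIKE", seed=2)
        assert len(d.subjects) == 21
        assert Stage.REM not in d.stages_present()
        assert Stage.LUCID_REM not in d.stages_present()
        assert 450 <= d.total_trials() <= 750

    def test_seed_determinism(self):
        d1 = generate.make_design("NP_LIKE", seed=7)
        d2 = generate.make_design("NP_LIKE", seed=7)
        assert d1.counts == d2.counts

    def test_hp_weights_on_rem_rejected(self):
        with pytest.raises(ValueError):
            generate.make_design("HP_LIKE", imbalance={Stage.WAKE: 0.5, Stage.REM: 0.5}, seed=1)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            generate.make_design("NP_LIKE", imbalance={Stage.WAKE: 0.5, Stage.N1: 0.2}, seed=1)


class TestDrawSubjectParameters:
    def test_zero_spread_gives_identical_subjects(self):
        gen0 = generate.default_generating_parameters()
        gen = GeneratingParameters(
            mu=gen0.mu, sigma={f: np.zeros(10) for f in "vat"},
            mu_z=0.55, sigma_z=0.0)
        design = generate.make_design("NP_LIKE", n_subjects=5, seed=3)
        params = generate.draw_subject_parameters(gen, design, seed=4)
        for f in "vat":
            assert np.allclose(params.beta[f], gen.mu[f])
        assert np.allclose(params.z, 0.55)

    def test_sample_mean_matches_group_mean(self):
        gen = generate.default_generating_parameters()
        design = generate.make_design("NP_LIKE", n_subjects=400, mean_trials=12, seed=5)
        params = generate.draw_subject_parameters(gen, design, seed=6)
        # CLT on the drift intercept (light resampling bias tolerated via 4 SE)
        se = gen.sigma["v"][0] / np.sqrt(400)
        assert abs(params.beta["v"][:, 0].mean() - gen.mu["v"][0]) < 4 * se

    def test_seeded_reproducibility(self):
        gen = generate.default_generating_parameters()
        design = generate.make_design("NP_LIKE", n_subjects=6, seed=7)
        p1 = generate.draw_subject_parameters(gen, design, seed=8)
        p2 = generate.draw_subject_parameters(gen, design, seed=8)
        assert np.array_equal(p1.beta["a"], p2.beta["a"])
        assert np.array_equal(p1.z, p2.z)

    def test_infeasible_generating_parameters_raise(self):
        gen0 = generate.default_generating_parameters()
        mu = dict(gen0.mu)
        mu["a"] = np.array([-5.0] + [0.0] * 9)   # negative threshold everywhere
        gen = GeneratingParameters(mu=mu, sigma={f: np.full(10, 1e-6) for f in "vat"})
        design = generate.make_design("NP_LIKE", n_subjects=2, seed=9)
        with pytest.raises(RuntimeError, match="infeasible"):
            generate.draw_subject_parameters(gen, design, seed=10, max_attempts=50)


class TestSimulateDataset:
    def test_counts_match_design(self, small_study):
        design, data = small_study["design"], small_study["trials"]
        from collections import Counter
        got = Counter((t.subject_id, t.stage, t.stimulus) for t in data)
        for sid, cells in design.counts.items():
            for (stage, stim), n in cells.items():
                assert got.get((sid, stage, stim), 0) == n

    def test_rt_exceeds_condition_nondecision_time(self, small_study):
        params = small_study["params"]
        for t in small_study["trials"]:
            j = params.subject_ids.index(t.subject_id)
            _, _, t0, _ = params.condition_params(j, t.stimulus, t.stage)
            assert t.rt > t0

    def test_high_drift_gives_high_accuracy(self):
        gen0 = generate.default_generating_parameters()
        mu = dict(gen0.mu)
        mu["v"] = np.array([4.0] + [0.0] * 9)
        gen = GeneratingParameters(mu=mu, sigma={f: np.full(10, 1e-9) for f in "vat"},
                                   mu_z=0.5, sigma_z=0.0)
        design = generate.make_design("NP_LIKE", n_subjects=4, mean_trials=250, seed=20)
        params = generate.draw_subject_parameters(gen, design, seed=21)
        data = generate.simulate_dataset(design, params, seed=22, dt=5e-4)
        acc = np.mean([t.correct for t in data])
        assert acc > 0.95

    def test_accuracy_monotone_in_drift(self):
        accs = []
        for v0 in (0.3, 1.0, 2.0):
            gen0 = generate.default_generating_parameters()
            mu = dict(gen0.mu)
            mu["v"] = np.array([v0] + [0.0] * 9)
            gen = GeneratingParameters(mu=mu, sigma={f: np.full(10, 1e-9) for f in "vat"},
                                       mu_z=0.5, sigma_z=0.0)
            design = generate.make_design("NP_LIKE", n_subjects=4, mean_trials=200, seed=23)
            params = generate.draw_subject_parameters(gen, design, seed=24)
            data = generate.simulate_dataset(design, params, seed=25, dt=5e-4)
            accs.append(np.mean([t.correct for t in data]))
        assert accs[0] < accs[1] < accs[2]

    def test_mismatched_subjects_rejected(self, small_study):
        other = generate.make_design("NP_LIKE", n_subjects=3, seed=30)
        with pytest.raises(ValueError):
            generate.simulate_dataset(other, small_study["params"], seed=31)


class TestInjectArtifacts:
    def test_zero_rates_no_op(self, small_study):
        out, planted = generate.inject_artifacts(small_study["trials"], 0, 0, 0, seed=1)
        assert out == list(small_study["trials"])
        assert all(v == 0 for v in planted.values())

    def test_microarousal_rate_binomial(self):
        trials = [generate.TrialRecord(
            subject_id="s", group=Group.NP, session=1, stage=Stage.WAKE,
            stimulus=Stimulus.WORD, response=Response.WORD, rt=1.0,
            n_contractions=2) for _ in range(10_000)]
        _, planted = generate.inject_artifacts(trials, microarousal_rate=0.136, seed=2,
                                               single_contraction_rate=0.0)
        se = np.sqrt(0.136 * 0.864 * 10_000)
        assert abs(planted["microarousal"] - 1360) < 3 * se

    def test_seeded_reproducibility(self, small_study):
        a, pa = generate.inject_artifacts(small_study["trials"], 0.1, 0.05, 0.02, seed=3)
        b, pb = generate.inject_artifacts(small_study["trials"], 0.1, 0.05, 0.02, seed=3)
        assert pa == pb and a == b

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            generate.inject_artifacts([], microarousal_rate=1.5)
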