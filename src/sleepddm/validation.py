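"""Simulation-based validation suite for the hierarchical DDM pipeline.

Four instruments establish that the model can be trusted on data shaped
like this study:

* parameter recovery — simulate from known group-level truth, refit, and
  score agreement (Pearson r, bias, RMSE) per parameter family;
* null-model trade-off simulation — generate with the decision threshold
  held constant across conditions, fit with it free, and measure the
  spurious lucid-REM threshold coefficient attributable purely to
  parameter trade-offs;
* posterior predictive checks — simulate datasets from posterior draws
  under the observed trial structure and compare accuracy/RT summaries;
* DIC model comparison over the four nested regression variants.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .generate import (GeneratingParameters, StudyDesign, SubjectParameters,
                       draw_subject_parameters, null_threshold_parameters,
                       simulate_dataset)
from .model import PosteriorDraws, RegressionSpec, dic, fit_hddm
from .trials import Stage, Stimulus


class RecoveryQuality(enum.Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    ACCEPTABLE = "acceptable"
    FLAGGED = "flagged"


def classify_recovery(r: float, abs_bias: float, rmse: float) -> RecoveryQuality:
    """Tiered recovery-quality rule; a tier requires all three conditions.

    Excellent: r > 0.90, |bias| < 0.05, RMSE < 0.10. Good: r > 0.80,
    |bias| < 0.10, RMSE < 0.20. Acceptable: r > 0.70, |bias| < 0.15,
    RMSE < 0.30. Anything else is flagged for cautious interpretation.
    """
    for q, (r_min, b_max, e_max) in (
        (RecoveryQuality.EXCELLENT, (0.90, 0.05, 0.10)),
        (RecoveryQuality.GOOD, (0.80, 0.10, 0.20)),
        (RecoveryQuality.ACCEPTABLE, (0.70, 0.15, 0.30)),
    ):
        if r > r_min and abs_bias < b_max and rmse < e_max:
            return q
    return RecoveryQuality.FLAGGED


def _settings_hash(settings: Mapping) -> str:
    text = json.dumps({k: repr(v) for k, v in sorted(settings.items())})
    return hashlib.sha256(text.encode()).hexdigest()[:12]


NODE_CLASSES = ("intercept", "stimulus", "stage", "interaction")


def _node_class(column: int, n_stage: int) -> str:
    if column == 0:
        return "intercept"
    if column == 1:
        return "stimulus"
    if column < 2 + n_stage:
        return "stage"
    return "interaction"


@dataclass
class RecoveryReport:
    """Pooled true-vs-recovered pairs and their summary metrics.

    ``pairs`` holds one row per group-level mean node per iteration:
    (iteration, family, node, node_class, true, recovered, converged).
    """

    pairs: pd.DataFrame
    n_iter: int
    n_failed: int
    seeds: list[int]
    settings_hash: str

    def metrics(self, family: str, node_class: str | None = None,
                include_nonconverged: bool = False) -> dict:
        """r / bias / RMSE / quality for one family (optionally one class).

        r pools all nodes and iterations; bias and RMSE are computed per
        node (mean over iterations) and then averaged across nodes, with
        |bias| averaged in magnitude.
        """
        sel = self.pairs[self.pairs.family == family]
        if node_class is not None:
            sel = sel[sel.node_class == node_class]
        if not include_nonconverged:
            sel = sel[sel.converged]
        if len(sel) < 3:
            raise ValueError("too few recovered nodes for metrics")
        true = sel.true.to_numpy()
        rec = sel.recovered.to_numpy()
        r = float(np.corrcoef(true, rec)[0, 1]) if np.ptp(true) > 0 else float("nan")
        per_node = sel.assign(err=rec - true).groupby("node").err
        bias_by_node = per_node.mean()
        rmse_by_node = per_node.apply(lambda e: float(np.sqrt(np.mean(e ** 2))))
        bias = float(bias_by_node.mean())
        abs_bias = float(bias_by_node.abs().mean())
        rmse = float(rmse_by_node.mean())
        return {
            "family": family,
            "node_class": node_class,
            "r": r,
            "bias": bias,
            "abs_bias": abs_bias,
            "rmse": rmse,
            "rmse_pooled": float(np.sqrt(np.mean((rec - true) ** 2))),
            "quality": classify_recovery(r, abs_bias, rmse).value,
            "n_pairs": int(len(sel)),
        }

    def summary(self) -> pd.DataFrame:
        rows = [self.metrics(f) for f in ("v", "a", "t")]
        for f in ("v", "a", "t"):
            for k in NODE_CLASSES:
                if ((self.pairs.family == f) & (self.pairs.node_class == k)).sum() >= 3:
                    rows.append(self.metrics(f, k))
        return pd.DataFrame(rows)

    def stimulus_contrast_rmse(self, family: str,
                               include_nonconverged: bool = False) -> float:
        """Pooled RMSE over the word main-effect and interaction nodes."""
        sel = self.pairs[(self.pairs.family == family)
                         & self.pairs.node_class.isin(["stimulus", "interaction"])]
        if not include_nonconverged:
            sel = sel[sel.converged]
        err = sel.recovered.to_numpy() - sel.true.to_numpy()
        return float(np.sqrt(np.mean(err ** 2)))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_iter": self.n_iter,
            "n_failed": self.n_failed,
            "seeds": self.seeds,
            "settings_hash": self.settings_hash,
            "summary": self.summary().to_dict(orient="records"),
            "pairs": self.pairs.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_parameter_recovery(
    gen: GeneratingParameters,
    design: StudyDesign,
    spec: RegressionSpec,
    n_iter: int = 30,
    seed: int = 0,
    fit_kwargs: Mapping | None = None,
    sim_dt: float = 1e-4,
) -> RecoveryReport:
    """Simulate-and-refit loop scoring group-level coefficient recovery.

    Each iteration draws fresh subject-level coefficients from ``gen``,
    samples every designed trial through the diffusion engine, refits the
    identical regression spec, and pairs the generating group means with
    the recovered group-level posterior means. Iterations whose fit fails
    the R-hat check are recorded and excluded from the metrics.
    """
    if n_iter < 2:
        raise ValueError("need at least 2 recovery iterations")
    fit_kwargs = dict(fit_kwargs or {})
    n_stage = len(spec.stages) - 1
    rows = []
    seeds = []
    n_failed = 0
    for it in range(n_iter):
        it_seed = (seed * 7919 + 104729 * it) % (2**31 - 1)
        seeds.append(it_seed)
        params = draw_subject_parameters(gen, design, seed=it_seed)
        data = simulate_dataset(design, params, seed=it_seed + 1, dt=sim_dt)
        fit = fit_hddm(data, spec, seed=it_seed + 2, **fit_kwargs)
        if not fit.converged:
            n_failed += 1
        means = {name: float(np.mean(fit.stacked(name))) for name in fit.coef_names}
        for f_idx, family in enumerate("vat"):
            for c, name in zip(spec.family_columns(family), spec.node_names(family)):
                rows.append({
                    "iteration": it,
                    "family": family,
                    "node": name,
                    "node_class": _node_class(c, n_stage),
                    "true": float(gen.mu[family][c]),
                    "recovered": means[name],
                    "converged": fit.converged,
                })
    settings = {"n_iter": n_iter, "seed": seed, "spec": spec.name, **fit_kwargs}
    return RecoveryReport(pd.DataFrame(rows), n_iter, n_failed, seeds, _settings_hash(settings))


# ---------------------------------------------------------------------------
# Null-model trade-off simulation
# ---------------------------------------------------------------------------

@dataclass
class NullSimReport:
    """Spurious lucid-REM threshold coefficients under a constant-threshold truth."""

    coefficients: list[float]
    seeds: list[int]
    settings_hash: str
    empirical_effect: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.coefficients))

    @property
    def sd(self) -> float:
        return float(np.std(self.coefficients, ddof=1)) if len(self.coefficients) > 1 else 0.0

    @property
    def max(self) -> float:
        return float(np.max(self.coefficients))

    @property
    def p95(self) -> float:
        return float(np.percentile(self.coefficients, 95))

    @property
    def exceeds_max(self) -> bool | None:
        if self.empirical_effect is None:
            return None
        return bool(self.empirical_effect > self.max)

    @property
    def ratio_to_mean(self) -> float | None:
        if self.empirical_effect is None or self.mean == 0:
            return None
        return float(self.empirical_effect / self.mean)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "coefficients": self.coefficients,
            "mean": self.mean, "sd": self.sd, "max": self.max, "p95": self.p95,
            "empirical_effect": self.empirical_effect,
            "exceeds_max": self.exceeds_max,
            "ratio_to_mean": self.ratio_to_mean,
            "seeds": self.seeds, "settings_hash": self.settings_hash,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_null_threshold_simulation(
    design: StudyDesign,
    spec: RegressionSpec | None = None,
    fixed_a: float = 2.54,
    n_iter: int = 30,
    seed: int = 0,
    fit_kwargs: Mapping | None = None,
    gen: GeneratingParameters | None = None,
    empirical_effect: float | None = None,
    sim_dt: float = 1e-4,
) -> NullSimReport:
    """Generate with thresholds fixed at ``fixed_a`` across conditions,
    fit with thresholds free, and collect the lucid-REM threshold
    coefficient of each fit as the spurious trade-off effect.
    """
    if fixed_a <= 0:
        raise ValueError("fixed_a must be positive")
    spec = spec or RegressionSpec.full()
    gen = gen or null_threshold_parameters(fixed_a)
    fit_kwargs = dict(fit_kwargs or {})
    node = f"a_stage[{Stage.LUCID_REM.value}]"
    coefs, seeds = [], []
    for it in range(n_iter):
        it_seed = (seed * 6007 + 93563 * it) % (2**31 - 1)
        seeds.append(it_seed)
        params = draw_subject_parameters(gen, design, seed=it_seed)
        data = simulate_dataset(design, params, seed=it_seed + 1, dt=sim_dt)
        fit = fit_hddm(data, spec, seed=it_seed + 2, **fit_kwargs)
        coefs.append(float(np.mean(fit.stacked(node))))
    settings = {"n_iter": n_iter, "seed": seed, "fixed_a": fixed_a, **fit_kwargs}
    return NullSimReport(coefs, seeds, _settings_hash(settings), empirical_effect)


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------

@dataclass
class PpcReport:
    observed: dict
    predictive: pd.DataFrame       # one row of summaries per simulated dataset
    n_sim: int
    seed: int

    def band(self, stat: str, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
        vals = self.predictive[stat].to_numpy()
        return float(np.percentile(vals, lo)), float(np.percentile(vals, hi))

    def inside_band(self, stat: str) -> bool:
        lo, hi = self.band(stat)
        return lo <= self.observed[stat] <= hi

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "observed": self.observed,
            "predictive": self.predictive.to_dict(orient="records"),
            "n_sim": self.n_sim, "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


RT_TAIL_CUTOFF = 5.0   # seconds; tail mass beyond this probes the right skew


def _summaries(rt: np.ndarray, correct: np.ndarray, stage_of: np.ndarray,
               stages: Sequence[Stage]) -> dict:
    out = {
        "accuracy": float(np.mean(correct)),
        "rt_median": float(np.median(rt)),
        "rt_q25": float(np.percentile(rt, 25)),
        "rt_q75": float(np.percentile(rt, 75)),
        "rt_tail": float(np.mean(rt > RT_TAIL_CUTOFF)),
    }
    for s_idx, stage in enumerate(stages):
        mask = stage_of == s_idx
        if mask.any():
            out[f"accuracy_{stage.value}"] = float(np.mean(correct[mask]))
    return out


def _stage_of_trials(fit: PosteriorDraws) -> np.ndarray:
    """Recover each trial's stage index from the design-matrix dummies."""
    X = fit._data["X"]
    n_stage = len(fit.spec.stages) - 1
    stage_idx = np.zeros(X.shape[0], dtype=int)
    for k in range(n_stage):
        stage_idx[X[:, 2 + k] == 1.0] = k + 1
    return stage_idx


def subject_params_from_draw(fit: PosteriorDraws, chain: int, idx: int) -> SubjectParameters:
    """Materialize one thinned subject-level draw as generator parameters."""
    spec = fit.spec
    P_full = 2 + 2 * (len(spec.stages) - 1)
    draw = fit.subject[chain, idx]          # (n_subj, P + 1)
    beta = {f: np.zeros((len(fit.subject_ids), P_full)) for f in "vat"}
    k = 0
    for family in "vat":
        for c in spec.family_columns(family):
            beta[family][:, c] = draw[:, k]
            k += 1
    return SubjectParameters(tuple(fit.subject_ids), beta, draw[:, k].copy())


def posterior_predictive_check(
    fit: PosteriorDraws,
    design: StudyDesign,
    n_sim: int = 30,
    seed: int = 0,
    sim_dt: float = 1e-4,
) -> PpcReport:
    """Simulate ``n_sim`` datasets from posterior draws under the observed
    trial structure and compare accuracy/RT summaries with the data."""
    rng = np.random.default_rng(seed)
    data = fit._data
    observed = _summaries(data["rt"], data["up"].astype(float),
                          _stage_of_trials(fit), fit.spec.stages)
    rows = []
    n_chains, n_kept = fit.subject.shape[0], fit.subject.shape[1]
    for _ in range(n_sim):
        chain = int(rng.integers(n_chains))
        idx = int(rng.integers(n_kept))
        params = subject_params_from_draw(fit, chain, idx)
        sim = simulate_dataset(design, params, seed=int(rng.integers(2**31 - 1)), dt=sim_dt)
        rt = np.array([t.rt for t in sim])
        corr = np.array([float(t.correct) for t in sim])
        stage_of = np.array([list(fit.spec.stages).index(t.stage) for t in sim])
        rows.append(_summaries(rt, corr, stage_of, fit.spec.stages))
    return PpcReport(observed, pd.DataFrame(rows), n_sim, seed)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def compare_models(
    trials,
    specs: Sequence[RegressionSpec] | None = None,
    seed: int = 0,
    fit_kwargs: Mapping | None = None,
) -> pd.DataFrame:
    """Fit each regression variant and tabulate DIC, pD and ΔDIC vs best.

    ΔDIC > 10 is flagged as strong evidence against the higher-DIC model.
    """
    if specs is None:
        specs = [RegressionSpec.full(), RegressionSpec.main_effects(),
                 RegressionSpec.const_a(), RegressionSpec.const_t()]
    if len(specs) < 2:
        raise ValueError("model comparison needs at least 2 specs")
    fit_kwargs = dict(fit_kwargs or {})
    rows = []
    for i, spec in enumerate(specs):
        fit = fit_hddm(trials, spec, seed=seed + i, **fit_kwargs)
        d, p_d, mean_dev = dic(fit)
        rows.append({"model": spec.name, "dic": d, "pd": p_d,
                     "mean_deviance": mean_dev, "converged": fit.converged})
    table = pd.DataFrame(rows)
    table["delta_dic"] = table.dic - table.dic.min()
    table["strong_evidence_against"] = table.delta_dic > 10.0
    return table.sort_values("dic").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Within-subject drift/threshold coupling
# ---------------------------------------------------------------------------

def subject_state_estimate(fit: PosteriorDraws, family: str, stage: Stage) -> np.ndarray:
    """Posterior-mean parameter per subject in one stage, averaged over stimuli."""
    means = fit.subject_means()
    spec = fit.spec
    offset = 0
    for f in "vat":
        if f == family:
            break
        offset += len(spec.family_columns(f))
    cols = spec.family_columns(family)
    from .model import design_row
    out = np.zeros(len(fit.subject_ids))
    for stim in (Stimulus.WORD, Stimulus.PSEUDOWORD):
        row = design_row(stim, stage, spec.stages)
        out += 0.5 * (means[:, offset:offset + len(cols)] @ row[cols])
    return out


def within_subject_coupling(
    fit: PosteriorDraws,
    state_a: Stage = Stage.WAKE,
    state_b: Stage = Stage.LUCID_REM,
    param_x: str = "v",
    param_y: str = "a",
) -> tuple[float, float, int]:
    """Pearson correlation between per-subject changes in two parameters.

    Computes Δ = estimate(state_b) - estimate(state_a) per subject for each
    parameter and returns (r, two-sided p from the t transform, n).
    """
    dx = (subject_state_estimate(fit, param_x, state_b)
          - subject_state_estimate(fit, param_x, state_a))
    dy = (subject_state_estimate(fit, param_y, state_b)
          - subject_state_estimate(fit, param_y, state_a))
    return coupling_from_deltas(dx, dy)


def coupling_from_deltas(dx: np.ndarray, dy: np.ndarray) -> tuple[float, float, int]:
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    n = dx.size
    if n < 3 or dy.size != n:
        raise ValueError("need at least 3 paired subject deltas")
    r, p = stats.pearsonr(dx, dy)
    return float(r), float(p), int(n)
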