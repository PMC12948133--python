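"""Bayesian mixed models for trial-level accuracy and reaction time.

Accuracy is modelled with a Bernoulli family and logit link; RT with a
shifted-lognormal family (a single shift shared across conditions within a
fit). Fixed effects are stimulus type, sleep stage and their interaction
(treatment coding, references wake/pseudoword, as in the diffusion-model
regression); participants contribute random intercepts. An optional
control model adds response accuracy as a fixed factor together with the
stimulus x accuracy x stage interaction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .model import DEFAULT_STAGES, compute_rhat, hdi
from .trials import Group, Response, Stage, Stimulus, TrialRecord


class Outcome(enum.Enum):
    ACCURACY = "accuracy"
    RT = "rt"


FAMILY_OF = {Outcome.ACCURACY: "bernoulli_logit", Outcome.RT: "shifted_lognormal"}


@dataclass(frozen=True)
class BlmmSpec:
    outcome: Outcome
    include_accuracy: bool = False     # RT control model only
    stages: tuple[Stage, ...] = DEFAULT_STAGES
    n_chains: int = 4
    n_samples: int = 5_000             # per chain, including warmup
    warmup: int = 500
    beta_prior_scale: float = 5.0

    def __post_init__(self):
        if self.warmup >= self.n_samples:
            raise ValueError("warmup must be smaller than n_samples")
        if self.include_accuracy and self.outcome is not Outcome.RT:
            raise ValueError("the accuracy control factor applies to RT models only")

    @property
    def family(self) -> str:
        return FAMILY_OF[self.outcome]

    def columns(self) -> list[str]:
        n_stage = len(self.stages) - 1
        cols = ["Intercept", "stim[word]"]
        if self.include_accuracy:
            cols.append("acc[correct]")
        cols += [f"stage[{s.value}]" for s in self.stages[1:]]
        if self.include_accuracy:
            cols += [f"stim[word]:acc[correct]:stage[{s.value}]" for s in self.stages[1:]]
        else:
            cols += [f"stim[word]:stage[{s.value}]" for s in self.stages[1:]]
        return cols


def _design(trials: Sequence[TrialRecord], spec: BlmmSpec) -> np.ndarray:
    n_stage = len(spec.stages) - 1
    X = np.zeros((len(trials), len(spec.columns())))
    for i, t in enumerate(trials):
        if t.stage not in spec.stages:
            raise KeyError(f"stage {t.stage} not in the level registry")
        X[i, 0] = 1.0
        word = t.stimulus is Stimulus.WORD
        if word:
            X[i, 1] = 1.0
        off = 2
        if spec.include_accuracy:
            acc = t.correct
            if acc:
                X[i, off] = 1.0
            off += 1
        if t.stage is not spec.stages[0]:
            s_idx = list(spec.stages[1:]).index(t.stage)
            X[i, off + s_idx] = 1.0
            if spec.include_accuracy:
                if word and t.correct:
                    X[i, off + n_stage + s_idx] = 1.0
            elif word:
                X[i, off + n_stage + s_idx] = 1.0
    return X


@dataclass
class BlmmFit:
    """Posterior draws of one mixed-model fit.

    ``draws`` has shape (chains, kept, p + 3); the trailing slots are the
    subject-intercept spread, the lognormal scale and the shift delta (the
    last two are zero for the Bernoulli family).
    """

    spec: BlmmSpec
    node_names: list[str]
    draws: np.ndarray
    subject_ids: list[str]
    subject_intercept_means: np.ndarray
    seed: int
    accept_rates: list[float]
    converged: bool = True
    rhat: dict[str, float] = field(default_factory=dict)

    def stacked(self, node: str) -> np.ndarray:
        try:
            k = self.node_names.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None
        return self.draws[:, :, k].reshape(-1)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for name in self.node_names:
            x = self.stacked(name)
            if np.ptp(x) == 0:
                lo = hi = float(x[0])
            else:
                lo, hi = hdi(x, mass)
            rows.append({
                "node": name, "median": float(np.median(x)), "mean": float(np.mean(x)),
                "hdi_low": lo, "hdi_high": hi, "rhat": self.rhat.get(name, float("nan")),
            })
        return pd.DataFrame(rows).set_index("node")


def fit_blmm(trials: Sequence[TrialRecord], spec: BlmmSpec, seed: int = 0) -> BlmmFit:
    """Fit the mixed model by adaptive Metropolis-within-Gibbs MCMC.

    Group-level (fixed-effect) nodes are checked with rank-normalized split
    R-hat (< 1.1); a failure flags the fit rather than discarding it.
    """
    resp = [t for t in trials if t.response is not Response.NONE]
    if not resp:
        raise ValueError("no response trials to fit")
    subject_ids = sorted({t.subject_id for t in resp})
    if len(subject_ids) < 2:
        raise ValueError(
            "a single subject cannot identify the random intercept spread; "
            "fit a fixed-effects-only model instead")
    order = sorted(range(len(resp)), key=lambda i: subject_ids.index(resp[i].subject_id))
    resp = [resp[i] for i in order]
    X = _design(resp, spec)
    if spec.outcome is Outcome.ACCURACY:
        y = np.array([float(t.correct) for t in resp])
        family = 0
    else:
        y = np.array([t.rt for t in resp])
        family = 1
    sid = np.array([subject_ids.index(t.subject_id) for t in resp])
    starts = np.array([np.nonzero(sid == j)[0][0] for j in range(len(subject_ids))], dtype=np.int64)
    ends = np.array([np.nonzero(sid == j)[0][-1] + 1 for j in range(len(subject_ids))], dtype=np.int64)

    node_names = spec.columns() + ["subject_sd", "sigma_log", "delta"]
    all_draws, u_means, rates = [], [], []
    for c in range(spec.n_chains):
        d, um, r = _kernels.blmm_chain(
            y, X, starts, ends, family, spec.beta_prior_scale,
            spec.n_samples, spec.warmup,
            (seed * 2003 + 31 * c) % (2**31 - 1),
        )
        all_draws.append(d)
        u_means.append(um)
        rates.append(r)
    fit = BlmmFit(
        spec=spec, node_names=node_names, draws=np.stack(all_draws),
        subject_ids=subject_ids,
        subject_intercept_means=np.mean(u_means, axis=0),
        seed=seed, accept_rates=rates,
    )
    p = len(spec.columns())
    for k in range(p):
        fit.rhat[node_names[k]] = compute_rhat(fit.draws[:, :, k])
    checked = [v for v in fit.rhat.values() if np.isfinite(v)]
    fit.converged = bool(checked) and max(checked) < 1.1
    return fit


@dataclass(frozen=True)
class CellMean:
    link_scale: np.ndarray         # posterior draws of the linear predictor
    original_scale: np.ndarray     # probability (Bernoulli) or seconds (RT)
    link_hdi: tuple[float, float]
    original_hdi: tuple[float, float]


def cell_means(fit: BlmmFit, stimulus: Stimulus, stage: Stage,
               correct: bool = True, mass: float = 0.95) -> CellMean:
    """Posterior cell mean on both scales for one factor combination.

    Bernoulli: inverse-logit of the linear predictor (probability of a
    correct response). Shifted lognormal: mean RT, delta + exp(eta +
    sigma_log^2 / 2), per draw.
    """
    spec = fit.spec
    probe = TrialRecord(
        subject_id="_cell", group=Group.NP,
        session=1, stage=stage, stimulus=stimulus,
        response=Response(stimulus.value) if correct else
        (Response.WORD if stimulus is Stimulus.PSEUDOWORD else Response.PSEUDOWORD),
        rt=1.0, n_contractions=2)
    row = _design([probe], spec)[0]
    p = len(spec.columns())
    beta = fit.draws[:, :, :p].reshape(-1, p)
    eta = beta @ row
    if spec.outcome is Outcome.ACCURACY:
        orig = 1.0 / (1.0 + np.exp(-eta))
    else:
        sigma_log = fit.draws[:, :, p + 1].reshape(-1)
        delta = fit.draws[:, :, p + 2].reshape(-1)
        orig = delta + np.exp(eta + sigma_log ** 2 / 2.0)
    return CellMean(eta, orig, hdi(eta, mass), hdi(orig, mass))


# ---------------------------------------------------------------------------
# Family-level simulators (generating processes for recovery checks)
# ---------------------------------------------------------------------------

def simulate_bernoulli_trials(
    design, beta: np.ndarray, subject_sd: float, seed: int = 0,
    stages: tuple[Stage, ...] = DEFAULT_STAGES,
) -> list[TrialRecord]:
    """Draw accuracy outcomes from the Bernoulli-logit mixed model.

    ``beta`` follows the non-control column layout (intercept, word, stage
    dummies, word x stage interactions). RTs are filled with a fixed
    placeholder; only the correctness pattern is model-generated.
    """
    from .model import design_row
    rng = np.random.default_rng(seed)
    records = []
    other = {Stimulus.WORD: Response.PSEUDOWORD, Stimulus.PSEUDOWORD: Response.WORD}
    for sid, group in design.subjects:
        u = rng.normal(0.0, subject_sd)
        for (stage, stim), n in design.counts[sid].items():
            if n == 0:
                continue
            eta = float(design_row(stim, stage, stages) @ beta) + u
            p = 1.0 / (1.0 + np.exp(-eta))
            for correct in rng.random(n) < p:
                records.append(TrialRecord(
                    subject_id=sid, group=group, session=1, stage=stage,
                    stimulus=stim,
                    response=Response(stim.value) if correct else other[stim],
                    rt=1.0, n_contractions=2))
    return records


def simulate_shifted_lognormal_trials(
    design, beta: np.ndarray, subject_sd: float, sigma_log: float,
    delta: float, seed: int = 0, stages: tuple[Stage, ...] = DEFAULT_STAGES,
) -> list[TrialRecord]:
    """Draw RTs from the shifted-lognormal mixed model (all responses correct)."""
    from .model import design_row
    rng = np.random.default_rng(seed)
    records = []
    for sid, group in design.subjects:
        u = rng.normal(0.0, subject_sd)
        for (stage, stim), n in design.counts[sid].items():
            if n == 0:
                continue
            eta = float(design_row(stim, stage, stages) @ beta) + u
            rts = delta + np.exp(rng.normal(eta, sigma_log, size=n))
            for rt in rts:
                records.append(TrialRecord(
                    subject_id=sid, group=group, session=1, stage=stage,
                    stimulus=stim, response=Response(stim.value),
                    rt=float(rt), n_contractions=2))
    return records
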