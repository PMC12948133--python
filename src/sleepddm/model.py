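"""Hierarchical Bayesian drift-diffusion regression.

Drift rate ``v``, boundary separation ``a`` and non-decision time ``t`` are
modelled, per trial, as linear functions of stimulus type, sleep stage and
their interaction (treatment coding; references: wake, pseudoword), with
subject-level coefficients drawn from group-level normal distributions.
The start point ``z`` is a participant-level intercept only. The upper
boundary codes the correct response (accuracy coding), so stimulus and
stage effects load on the parameters rather than on boundary identity.

Fitting uses an adaptive Metropolis-within-Gibbs sampler over subject-level
coefficient blocks and (conjugate where possible) group-level nodes, tuned
during burn-in to the 20-50% acceptance band, with identity links and a
likelihood that returns -inf for invalid implied parameters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .trials import Group, Response, Stage, Stimulus, TrialRecord, to_frame

DEFAULT_STAGES = (Stage.WAKE, Stage.N1, Stage.N2, Stage.REM, Stage.LUCID_REM)
REFERENCE_STAGE = Stage.WAKE
REFERENCE_STIMULUS = Stimulus.PSEUDOWORD


class FactorStructure(enum.Enum):
    INTERCEPT_ONLY = "intercept_only"
    MAIN_EFFECTS = "main_effects"
    FULL_INTERACTION = "full_interaction"


@dataclass(frozen=True)
class RegressionSpec:
    """Which DDM parameters vary with which factors.

    The four named variants mirror the nested model-comparison set: FULL
    (v, a, t all stimulus x stage), MAIN_EFFECTS (no interactions),
    CONST_A (threshold intercept-only) and CONST_T (non-decision time
    intercept-only).
    """

    name: str
    structure: Mapping[str, FactorStructure]
    stages: tuple[Stage, ...] = DEFAULT_STAGES

    def __post_init__(self):
        if set(self.structure) != {"v", "a", "t"}:
            raise ValueError("structure must cover exactly the families v, a, t")
        if self.stages[0] is not REFERENCE_STAGE:
            raise ValueError("first stage must be the reference (wake)")

    @staticmethod
    def full(stages: tuple[Stage, ...] = DEFAULT_STAGES) -> "RegressionSpec":
        return RegressionSpec("FULL", {p: FactorStructure.FULL_INTERACTION for p in "vat"}, stages)

    @staticmethod
    def main_effects(stages: tuple[Stage, ...] = DEFAULT_STAGES) -> "RegressionSpec":
        return RegressionSpec("MAIN_EFFECTS", {p: FactorStructure.MAIN_EFFECTS for p in "vat"}, stages)

    @staticmethod
    def const_a(stages: tuple[Stage, ...] = DEFAULT_STAGES) -> "RegressionSpec":
        return RegressionSpec("CONST_A", {
            "v": FactorStructure.FULL_INTERACTION,
            "a": FactorStructure.INTERCEPT_ONLY,
            "t": FactorStructure.FULL_INTERACTION,
        }, stages)

    @staticmethod
    def const_t(stages: tuple[Stage, ...] = DEFAULT_STAGES) -> "RegressionSpec":
        return RegressionSpec("CONST_T", {
            "v": FactorStructure.FULL_INTERACTION,
            "a": FactorStructure.FULL_INTERACTION,
            "t": FactorStructure.INTERCEPT_ONLY,
        }, stages)

    @staticmethod
    def by_name(name: str, stages: tuple[Stage, ...] = DEFAULT_STAGES) -> "RegressionSpec":
        try:
            factory = {
                "FULL": RegressionSpec.full,
                "MAIN_EFFECTS": RegressionSpec.main_effects,
                "CONST_A": RegressionSpec.const_a,
                "CONST_T": RegressionSpec.const_t,
            }[name.upper()]
        except KeyError:
            raise ValueError(f"unknown model name {name!r}") from None
        return factory(stages)

    def full_columns(self) -> list[str]:
        """Column registry of the full-interaction design matrix."""
        cols = ["Intercept", "stim[word]"]
        cols += [f"stage[{s.value}]" for s in self.stages[1:]]
        cols += [f"stim[word]:stage[{s.value}]" for s in self.stages[1:]]
        return cols

    def family_columns(self, family: str) -> list[int]:
        """Indices into the full design matrix used by one parameter family."""
        n_stage = len(self.stages) - 1
        struct = self.structure[family]
        if struct is FactorStructure.INTERCEPT_ONLY:
            return [0]
        if struct is FactorStructure.MAIN_EFFECTS:
            return list(range(0, 2 + n_stage))
        return list(range(0, 2 + 2 * n_stage))

    def node_names(self, family: str) -> list[str]:
        cols = self.full_columns()
        return [f"{family}_{cols[c]}" for c in self.family_columns(family)]


def design_row(stimulus: Stimulus, stage: Stage, stages: Sequence[Stage] = DEFAULT_STAGES) -> np.ndarray:
    """One row of the full-interaction (treatment-coded) design matrix."""
    n_stage = len(stages) - 1
    row = np.zeros(2 + 2 * n_stage)
    row[0] = 1.0
    word = stimulus is Stimulus.WORD
    if word:
        row[1] = 1.0
    if stage is not stages[0]:
        try:
            s_idx = list(stages[1:]).index(stage)
        except ValueError:
            raise KeyError(f"stage {stage} not in the level registry") from None
        row[2 + s_idx] = 1.0
        if word:
            row[2 + n_stage + s_idx] = 1.0
    return row


def build_design_matrix(
    trials: Sequence[TrialRecord],
    spec: RegressionSpec,
) -> tuple[np.ndarray, list[str]]:
    """Per-trial full-interaction predictor matrix and its column registry.

    Families that vary less than FULL_INTERACTION simply index a prefix of
    these columns (see :meth:`RegressionSpec.family_columns`).
    """
    X = np.empty((len(trials), 2 + 2 * (len(spec.stages) - 1)))
    for i, t in enumerate(trials):
        if t.stage not in spec.stages:
            raise KeyError(f"stage {t.stage} not in the level registry")
        X[i] = design_row(t.stimulus, t.stage, spec.stages)
    return X, spec.full_columns()


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative group-level priors.

    Group means: normal, centered at ``mu_loc`` with scale ``mu_scale``
    (intercepts get the wider scale). Group spreads: half-normal.
    """

    mu_scale_intercept: float = 5.0
    mu_scale_effect: float = 2.0
    sigma_scale_intercept: float = 1.0
    sigma_scale_effect: float = 0.5
    z_bounds: tuple[float, float] = (0.02, 0.98)

    def arrays(self, spec: RegressionSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        locs, mscales, sscales = [], [], []
        for family in "vat":
            for c in spec.family_columns(family):
                intercept = c == 0
                locs.append(0.0)
                mscales.append(self.mu_scale_intercept if intercept else self.mu_scale_effect)
                sscales.append(self.sigma_scale_intercept if intercept else self.sigma_scale_effect)
        return np.array(locs), np.array(mscales), np.array(sscales)


# ---------------------------------------------------------------------------
# Posterior containers
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC output of one hierarchical DDM fit.

    ``group`` has shape (chains, draws, nodes) over the registry in
    ``node_names`` (group means, then group spreads, then the start-point
    hyperparameters). ``subject`` holds thinned subject-level draws with
    shape (chains, kept, subjects, coefficients + 1); the last slot is the
    subject's start point.
    """

    spec: RegressionSpec
    node_names: list[str]
    group: np.ndarray
    deviance: np.ndarray
    subject: np.ndarray
    subject_ids: list[str]
    coef_names: list[str]          # concatenated subject-level coefficient registry
    seed: int
    burn_in: int
    accept_rates: list[float]
    converged: bool = True
    rhat: dict[str, float] = field(default_factory=dict)
    # prepared data retained for deviance/PPC computations
    _data: dict = field(default_factory=dict, repr=False)

    def stacked(self, node: str) -> np.ndarray:
        """All draws of one group node, chains concatenated."""
        try:
            k = self.node_names.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None
        return self.group[:, :, k].reshape(-1)

    def node_draws(self, node: str) -> np.ndarray:
        """Draws of one group node, shape (chains, draws)."""
        k = self.node_names.index(node)
        return self.group[:, :, k]

    def subject_means(self) -> np.ndarray:
        """Posterior-mean subject coefficients, shape (subjects, coefficients + 1)."""
        return self.subject.mean(axis=(0, 1))

    def save(self, path) -> None:
        """Persist draws in a columnar layout with a JSON sidecar.

        The sidecar records the node registry, spec, seed and shapes; the
        arrays go into a single compressed ``draws.npz``. The prepared data
        arrays are not persisted (reload refits need the trial table).
        """
        import json
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path / "draws.npz", group=self.group,
                            deviance=self.deviance, subject=self.subject)
        sidecar = {
            "node_names": self.node_names,
            "coef_names": self.coef_names,
            "subject_ids": self.subject_ids,
            "seed": self.seed,
            "burn_in": self.burn_in,
            "accept_rates": self.accept_rates,
            "converged": self.converged,
            "rhat": self.rhat,
            "spec": {"name": self.spec.name,
                     "structure": {k: v.value for k, v in self.spec.structure.items()},
                     "stages": [s.value for s in self.spec.stages]},
        }
        (path / "sidecar.json").write_text(json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path) -> "PosteriorDraws":
        import json
        from pathlib import Path

        from .trials import Stage

        path = Path(path)
        sidecar = json.loads((path / "sidecar.json").read_text())
        arrays = np.load(path / "draws.npz")
        spec = RegressionSpec(
            sidecar["spec"]["name"],
            {k: FactorStructure(v) for k, v in sidecar["spec"]["structure"].items()},
            tuple(Stage(s) for s in sidecar["spec"]["stages"]))
        return PosteriorDraws(
            spec=spec, node_names=sidecar["node_names"],
            group=arrays["group"], deviance=arrays["deviance"],
            subject=arrays["subject"], subject_ids=sidecar["subject_ids"],
            coef_names=sidecar["coef_names"], seed=sidecar["seed"],
            burn_in=sidecar["burn_in"], accept_rates=sidecar["accept_rates"],
            converged=sidecar["converged"], rhat=sidecar["rhat"])


def _prepare_data(trials: Sequence[TrialRecord], spec: RegressionSpec):
    """Sort trials by subject, build the design matrix and index arrays."""
    resp = [t for t in trials if t.response is not Response.NONE]
    if not resp:
        raise ValueError("no response trials to fit")
    subject_ids = sorted({t.subject_id for t in resp})
    order = sorted(range(len(resp)), key=lambda i: subject_ids.index(resp[i].subject_id))
    resp = [resp[i] for i in order]
    X, cols = build_design_matrix(resp, spec)
    rt = np.array([t.rt for t in resp])
    up = np.array([t.correct for t in resp], dtype=np.bool_)
    starts, ends = [], []
    sid = np.array([subject_ids.index(t.subject_id) for t in resp])
    for j in range(len(subject_ids)):
        idx = np.nonzero(sid == j)[0]
        starts.append(idx[0])
        ends.append(idx[-1] + 1)
    fam, col = [], []
    for f_id, family in enumerate("vat"):
        for c in spec.family_columns(family):
            fam.append(f_id)
            col.append(c)
    return {
        "rt": rt, "up": up, "X": X,
        "subj_start": np.array(starts, dtype=np.int64),
        "subj_end": np.array(ends, dtype=np.int64),
        "fam": np.array(fam, dtype=np.int64),
        "col": np.array(col, dtype=np.int64),
        "subject_ids": subject_ids,
        "columns": cols,
    }


def fit_hddm(
    trials: Sequence[TrialRecord],
    spec: RegressionSpec,
    n_samples: int = 10_000,
    burn_in: int = 1_000,
    n_chains: int = 2,
    seed: int = 0,
    priors: PriorConfig | None = None,
    thin_subject: int = 5,
    tol: float = 1e-6,
) -> PosteriorDraws:
    """Fit the hierarchical DDM regression by MCMC.

    ``n_samples`` counts sweeps per chain including the ``burn_in`` sweeps
    that are discarded. Convergence of group nodes is checked with
    rank-normalized split R-hat (< 1.1); failures set ``converged=False``
    on the result rather than discarding it.
    """
    if burn_in >= n_samples:
        raise ValueError("burn_in must be smaller than n_samples")
    data = _prepare_data(trials, spec)
    if len(data["subject_ids"]) < 2:
        raise ValueError("hierarchical fit requires at least 2 subjects")
    priors = priors or PriorConfig()
    p_loc, p_mscale, p_sscale = priors.arrays(spec)

    coef_names = []
    for family in "vat":
        coef_names += spec.node_names(family)
    node_names = list(coef_names) + [f"{n}_sd" for n in coef_names] + ["z_mu", "z_sd"]

    groups, devs, subjects, rates = [], [], [], []
    for c in range(n_chains):
        g, d, s, r = _kernels.hddm_gibbs_chain(
            data["rt"], data["up"], data["X"],
            data["subj_start"], data["subj_end"],
            data["fam"], data["col"],
            p_loc, p_mscale, p_sscale,
            priors.z_bounds[0], priors.z_bounds[1],
            n_samples, burn_in, thin_subject,
            (seed * 1009 + 17 * c) % (2**31 - 1), tol,
        )
        groups.append(g)
        devs.append(d)
        subjects.append(s)
        rates.append(r)

    fit = PosteriorDraws(
        spec=spec,
        node_names=node_names,
        group=np.stack(groups),
        deviance=np.stack(devs),
        subject=np.stack(subjects),
        subject_ids=data["subject_ids"],
        coef_names=coef_names,
        seed=seed,
        burn_in=burn_in,
        accept_rates=rates,
        _data=data,
    )
    # convergence: group means only (spreads mix more slowly and are nuisance)
    for name in coef_names:
        fit.rhat[name] = compute_rhat(fit.node_draws(name))
    checked = [v for v in fit.rhat.values() if np.isfinite(v)]
    fit.converged = bool(checked) and max(checked) < 1.1
    return fit


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def compute_rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat of one node.

    ``draws`` has shape (chains, iterations); a single chain is split in
    half. Zero-variance draws return NaN as an undefined-value sentinel.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[None, :]
    if draws.shape[0] * draws.shape[1] < 4:
        raise ValueError("need at least 4 draws")
    if np.ptp(draws) == 0:
        return float("nan")
    import arviz as az

    return float(az.rhat(az.convert_to_dataset(draws[:, :, None]))["x"].values[0])


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples for an HDI")
    if not (0 < mass < 1):
        raise ValueError("mass must lie in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass(frozen=True)
class NodeSummary:
    median: float
    mean: float
    hdi_low: float
    hdi_high: float
    rhat: float


def summarize(fit: PosteriorDraws, mass: float = 0.95) -> pd.DataFrame:
    """Median, mean, HDI bounds and R-hat for every group node."""
    rows = []
    for name in fit.node_names:
        x = fit.stacked(name)
        lo, hi = hdi(x, mass)
        rows.append({
            "node": name,
            "median": float(np.median(x)),
            "mean": float(np.mean(x)),
            "hdi_low": lo,
            "hdi_high": hi,
            "rhat": fit.rhat.get(name, float("nan")),
        })
    return pd.DataFrame(rows).set_index("node")


@dataclass(frozen=True)
class ContrastResult:
    draws: np.ndarray
    median: float
    hdi_low: float
    hdi_high: float
    credible: bool


def contrast(fit: PosteriorDraws, node_a: str, node_b: str | None = None, mass: float = 0.95) -> ContrastResult:
    """Posterior of A - B; credible iff the HDI excludes zero.

    ``node_b=None`` contrasts A against zero (i.e., tests the node itself).
    """
    a = fit.stacked(node_a)
    b = fit.stacked(node_b) if node_b is not None else np.zeros_like(a)
    diff = a - b
    if np.ptp(diff) == 0:
        c = float(diff[0])
        return ContrastResult(diff, c, c, c, credible=False)
    lo, hi = hdi(diff, mass)
    return ContrastResult(diff, float(np.median(diff)), lo, hi, credible=not (lo <= 0.0 <= hi))


def dic(fit: PosteriorDraws, tol: float = 1e-6) -> tuple[float, float, float]:
    """Deviance information criterion: (DIC, pD, mean deviance).

    pD uses the Spiegelhalter form (mean deviance minus deviance at the
    posterior mean of the subject-level parameters); if the posterior-mean
    deviance is undefined, falls back to var(deviance)/2.
    """
    mean_dev = float(fit.deviance.mean())
    data = fit._data
    means = fit.subject_means()
    P = len(fit.coef_names)
    n = data["rt"].shape[0]
    lv = np.zeros(n)
    la = np.zeros(n)
    lt = np.zeros(n)
    zz = np.zeros(n)
    for j in range(len(fit.subject_ids)):
        s, e = data["subj_start"][j], data["subj_end"][j]
        for k in range(P):
            xb = data["X"][s:e, data["col"][k]] * means[j, k]
            if data["fam"][k] == 0:
                lv[s:e] += xb
            elif data["fam"][k] == 1:
                la[s:e] += xb
            else:
                lt[s:e] += xb
        zz[s:e] = means[j, P]
    dev_at_mean = -2.0 * _kernels.dataset_loglik(
        data["rt"], data["up"], lv, la, lt, zz, tol)
    if not np.isfinite(dev_at_mean) or dev_at_mean > 1e250:
        p_d = float(fit.deviance.var() / 2.0)
    else:
        p_d = mean_dev - float(dev_at_mean)
    return mean_dev + p_d, p_d, mean_dev
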