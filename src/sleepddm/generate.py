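"""Synthetic-study generator.

Emulates the trial structure of the sleep lexical-decision experiment —
a narcolepsy-like cohort (27 participants, ~50 response trials spread
unevenly over words/pseudowords x wake/N1/N2/REM/lucid-REM) and a
healthy-like cohort (21 participants, ~28 trials concentrated in
wake/N1/N2) — and the hierarchical generating process: group-level
coefficient distributions, subject-level coefficient draws, and trial
sampling through the Wiener first-passage engine with accuracy coding.

The default generating magnitudes are round, plausible values on the
unit-diffusion scale: a word-vs-pseudoword drift contrast of 0.3 that
collapses in N2/REM, a lucid-REM threshold elevation of 0.458 against a
cell-averaged grand-mean threshold of ~2.54, and non-decision contrasts
of 0.05-0.3 s growing with sleep depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _kernels
from .model import DEFAULT_STAGES, design_row
from .trials import Group, Response, Stage, Stimulus, TrialRecord

NP_STAGE_WEIGHTS = {
    Stage.WAKE: 0.40, Stage.N1: 0.20, Stage.N2: 0.15,
    Stage.REM: 0.10, Stage.LUCID_REM: 0.15,
}
HP_STAGE_WEIGHTS = {Stage.WAKE: 0.70, Stage.N1: 0.18, Stage.N2: 0.12}

PROFILE_DEFAULTS = {
    "NP_LIKE": dict(n_subjects=27, mean_trials=50, weights=NP_STAGE_WEIGHTS, group=Group.NP),
    "HP_LIKE": dict(n_subjects=21, mean_trials=28, weights=HP_STAGE_WEIGHTS, group=Group.HP),
}


@dataclass(frozen=True)
class StudyDesign:
    """Subjects and their per-cell trial counts.

    ``counts[subject_id][(stage, stimulus)]`` is the number of response
    trials in that cell.
    """

    subjects: tuple[tuple[str, Group], ...]
    counts: Mapping[str, Mapping[tuple[Stage, Stimulus], int]]
    seed: int

    def total_trials(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def stages_present(self) -> set[Stage]:
        return {k[0] for c in self.counts.values() for k, n in c.items() if n > 0}


def make_design(
    profile: str,
    n_subjects: int | None = None,
    mean_trials: int | None = None,
    imbalance: Mapping[Stage, float] | None = None,
    seed: int = 0,
) -> StudyDesign:
    """Draw a study design matching the NP-like or HP-like trial profile.

    Per-subject totals vary around ``mean_trials`` (Poisson, floored at 10)
    and are split over stage x stimulus cells by a multinomial over the
    stage ``imbalance`` weights with an even word/pseudoword split.
    """
    if profile not in PROFILE_DEFAULTS:
        raise ValueError(f"unknown profile {profile!r}")
    defaults = PROFILE_DEFAULTS[profile]
    n_subjects = n_subjects or defaults["n_subjects"]
    mean_trials = mean_trials or defaults["mean_trials"]
    weights = dict(imbalance or defaults["weights"])
    if profile == "HP_LIKE":
        bad = {s for s in weights if s in (Stage.REM, Stage.LUCID_REM)}
        if bad:
            raise ValueError(f"HP_LIKE profile cannot place trials in {sorted(s.value for s in bad)}")
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError("imbalance weights must sum to 1")

    rng = np.random.default_rng(seed)
    group = defaults["group"]
    stage_list = list(weights)
    p = np.array([weights[s] for s in stage_list])
    prefix = "np" if group is Group.NP else "hp"
    subjects = []
    counts: dict[str, dict[tuple[Stage, Stimulus], int]] = {}
    for j in range(n_subjects):
        sid = f"{prefix}{j + 1:02d}"
        subjects.append((sid, group))
        n = max(10, int(rng.poisson(mean_trials)))
        per_stage = rng.multinomial(n, p)
        cell: dict[tuple[Stage, Stimulus], int] = {}
        for s, ns in zip(stage_list, per_stage):
            n_word = int(rng.binomial(ns, 0.5))
            cell[(s, Stimulus.WORD)] = n_word
            cell[(s, Stimulus.PSEUDOWORD)] = int(ns) - n_word
        counts[sid] = cell
    return StudyDesign(tuple(subjects), counts, seed)


# ---------------------------------------------------------------------------
# Generating parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratingParameters:
    """Group-level truth for the hierarchical generating process.

    ``mu`` / ``sigma`` map each family ('v', 'a', 't') to arrays over the
    full-interaction design columns; ``mu_z`` / ``sigma_z`` govern the
    participant-level start point.
    """

    mu: Mapping[str, np.ndarray]
    sigma: Mapping[str, np.ndarray]
    mu_z: float = 0.55
    sigma_z: float = 0.05
    stages: tuple[Stage, ...] = DEFAULT_STAGES

    def n_columns(self) -> int:
        return 2 + 2 * (len(self.stages) - 1)


def default_generating_parameters() -> GeneratingParameters:
    """Documented plausible generating truth for the NP-like design.

    Columns: Intercept, word, N1, N2, REM, lucidREM, word:N1 ... word:lucidREM.
    """
    # The pattern encodes the study's qualitative findings: the word vs
    # pseudoword drift advantage present in wake/N1 collapses in N2/REM and
    # is restored in lucid REM (interactions cancel the word effect where
    # lexical discrimination is lost); response caution is elevated in lucid
    # REM (+0.458) with a null threshold effect in N1; non-decision time
    # lengthens with sleep depth. Cell-averaged threshold ~2.54.
    mu = {
        #          int   word   N1     N2     REM   lucid  w:N1  w:N2  w:REM w:luc
        "v": np.array([1.00, 0.30, -0.45, -0.75, -0.85, -0.55, -0.10, -0.25, -0.30, 0.00]),
        "a": np.array([2.44, 0.10, 0.00, 0.15, 0.25, 0.458, 0.05, 0.10, 0.10, 0.10]),
        "t": np.array([0.80, -0.10, 0.15, 0.25, 0.30, 0.20, 0.05, 0.08, 0.08, 0.05]),
    }
    sigma = {
        "v": np.array([0.40, 0.15, 0.15, 0.15, 0.15, 0.15, 0.10, 0.10, 0.10, 0.10]),
        "a": np.array([0.30, 0.10, 0.10, 0.10, 0.10, 0.10, 0.05, 0.05, 0.05, 0.05]),
        "t": np.array([0.10, 0.05, 0.05, 0.05, 0.05, 0.05, 0.03, 0.03, 0.03, 0.03]),
    }
    return GeneratingParameters(mu=mu, sigma=sigma)


def null_threshold_parameters(fixed_a: float = 2.54) -> GeneratingParameters:
    """Generating truth with the threshold constant across all conditions.

    Drift and non-decision time keep their default condition structure;
    every threshold effect coefficient is exactly zero (mean and spread),
    and the threshold intercept sits at the grand mean ``fixed_a``.
    """
    base = default_generating_parameters()
    mu = dict(base.mu)
    sigma = dict(base.sigma)
    a_mu = np.zeros_like(mu["a"])
    a_mu[0] = fixed_a
    a_sigma = np.zeros_like(sigma["a"])
    a_sigma[0] = 0.30   # subjects still differ in overall caution
    mu["a"] = a_mu
    sigma["a"] = a_sigma
    return GeneratingParameters(mu=mu, sigma=sigma, mu_z=base.mu_z, sigma_z=base.sigma_z)


@dataclass(frozen=True)
class SubjectParameters:
    """Per-subject realized coefficients; rows align with ``subject_ids``."""

    subject_ids: tuple[str, ...]
    beta: Mapping[str, np.ndarray]   # family -> (n_subjects, n_columns)
    z: np.ndarray

    def condition_params(self, j: int, stimulus: Stimulus, stage: Stage,
                         stages: Sequence[Stage] = DEFAULT_STAGES):
        row = design_row(stimulus, stage, stages)
        return (
            float(self.beta["v"][j] @ row),
            float(self.beta["a"][j] @ row),
            float(self.beta["t"][j] @ row),
            float(self.z[j]),
        )


def draw_subject_parameters(
    gen: GeneratingParameters,
    design: StudyDesign,
    seed: int = 0,
    max_attempts: int = 1000,
) -> SubjectParameters:
    """Draw subject coefficients from the group distributions.

    Subjects whose implied per-condition parameters are invalid (a <= 0,
    t < 0, z outside (0, 1)) are resampled; exceeding ``max_attempts``
    raises.
    """
    rng = np.random.default_rng(seed)
    ids = tuple(sid for sid, _ in design.subjects)
    P = gen.n_columns()
    beta = {f: np.empty((len(ids), P)) for f in "vat"}
    z = np.empty(len(ids))
    rows = {
        (stage, stim): design_row(stim, stage, gen.stages)
        for stage in gen.stages for stim in Stimulus
    }
    for j, sid in enumerate(ids):
        cells = [c for c, n in design.counts[sid].items() if n > 0]
        for attempt in range(max_attempts + 1):
            if attempt == max_attempts:
                raise RuntimeError(
                    f"could not draw valid parameters for subject {sid} "
                    f"after {max_attempts} attempts; generating parameters infeasible")
            cand = {f: gen.mu[f] + gen.sigma[f] * rng.standard_normal(P) for f in "vat"}
            zc = rng.normal(gen.mu_z, gen.sigma_z) if gen.sigma_z > 0 else gen.mu_z
            ok = 0.02 < zc < 0.98
            for stage, stim in cells:
                if not ok:
                    break
                row = rows[(stage, stim)]
                if cand["a"] @ row <= 0 or cand["t"] @ row < 0:
                    ok = False
            if ok:
                for f in "vat":
                    beta[f][j] = cand[f]
                z[j] = zc
                break
    return SubjectParameters(ids, beta, z)


def simulate_dataset(
    design: StudyDesign,
    params: SubjectParameters,
    seed: int = 0,
    dt: float = 1e-4,
    horizon: float = 30.0,
) -> list[TrialRecord]:
    """Sample every designed trial through the Wiener first-passage engine.

    The upper boundary codes the correct response, so an upper passage maps
    to ``response == stimulus`` and a lower passage to the other label.
    Observed RT is decision time plus the subject/condition non-decision
    time. Passages truncated at the horizon keep the horizon RT (they fall
    to the RT-bound exclusion downstream).
    """
    if set(sid for sid, _ in design.subjects) != set(params.subject_ids):
        raise ValueError("design and parameters cover different subject sets")
    rng = np.random.default_rng(seed)
    _kernels.seed_kernel_rng(int(rng.integers(0, 2**31 - 1)))
    records: list[TrialRecord] = []
    other = {Stimulus.WORD: Response.PSEUDOWORD, Stimulus.PSEUDOWORD: Response.WORD}
    for sid, group in design.subjects:
        j = params.subject_ids.index(sid)
        for (stage, stim), n in design.counts[sid].items():
            if n == 0:
                continue
            v, a, t0, z = params.condition_params(j, stim, stage)
            ups, tdecs = _kernels.euler_passage_many(n, v, a, z, dt, horizon)
            for u, tdec in zip(ups, tdecs):
                correct = bool(u != 0)   # truncated (-1) treated as upper
                records.append(TrialRecord(
                    subject_id=sid, group=group, session=1,
                    stage=stage, stimulus=stim,
                    response=Response(stim.value) if correct else other[stim],
                    rt=float(t0 + tdec),
                    microarousal=False, n_contractions=2,
                ))
    return records


def inject_artifacts(
    trials: Sequence[TrialRecord],
    microarousal_rate: float = 0.136,
    single_contraction_rate: float = 0.015,
    nonresponse_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[TrialRecord], dict[str, int]]:
    """Plant artifact flags independently at the given rates.

    Returns the flagged trials and order-aware planted counts keyed like
    the exclusion-report rules (a trial turned into a non-response is not
    also counted under microarousal, matching the exclusion rule order).
    """
    for r in (microarousal_rate, single_contraction_rate, nonresponse_rate):
        if not (0 <= r <= 1):
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[TrialRecord] = []
    planted = {"nonresponse": 0, "microarousal": 0, "single_contraction": 0}
    for t in trials:
        nr = rng.random() < nonresponse_rate
        ma = rng.random() < microarousal_rate
        sc = rng.random() < single_contraction_rate
        if nr:
            planted["nonresponse"] += 1
            out.append(TrialRecord(
                subject_id=t.subject_id, group=t.group, session=t.session,
                stage=t.stage, stimulus=t.stimulus, response=Response.NONE,
                rt=None, microarousal=ma, n_contractions=0))
            continue
        if ma:
            planted["microarousal"] += 1
        elif sc:
            planted["single_contraction"] += 1
        if ma or sc:
            out.append(TrialRecord(
                subject_id=t.subject_id, group=t.group, session=t.session,
                stage=t.stage, stimulus=t.stimulus, response=t.response,
                rt=t.rt, microarousal=ma,
                n_contractions=1 if sc else t.n_contractions))
        else:
            out.append(t)
    return out, planted
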