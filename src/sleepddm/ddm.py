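"""Wiener diffusion engine: first-passage density, absorption probability,
trial sampler and dataset log-likelihood.

The model is the standard two-boundary drift-diffusion process with unit
diffusion coefficient: evidence ``X(t)`` starts at ``z * a``, drifts at rate
``v`` and is absorbed at 0 (lower boundary) or ``a`` (upper boundary).
Observed reaction time is the first-passage (decision) time plus the
non-decision time ``t``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import _kernels


class Boundary(enum.Enum):
    UPPER = "upper"
    LOWER = "lower"


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for a single trial/condition.

    v : drift rate (evidence units per second, signed)
    a : boundary separation, > 0
    t : non-decision time in seconds, >= 0
    z : relative starting point in (0, 1), as a fraction of ``a``
    """

    v: float
    a: float
    t: float
    z: float

    def validate(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not (0 < self.z < 1):
            raise ValueError(f"relative start point must lie in (0, 1), got z={self.z}")
        if not (self.t >= 0):
            raise ValueError(f"non-decision time must be non-negative, got t={self.t}")


@dataclass(frozen=True)
class TrialOutcome:
    boundary: Boundary
    rt: float
    truncated: bool = False


def wfpt_density(rt: float, boundary: Boundary, params: DDMParams, tol: float = 1e-6) -> float:
    """First-passage-time density (per second) at the given boundary.

    Evaluates the density at decision time ``rt - params.t`` using the
    small-time/large-time series pair with truncation error below ``tol``.
    Returns 0 when ``rt <= params.t``.
    """
    params.validate()
    if tol <= 0:
        raise ValueError("tol must be positive")
    tdec = rt - params.t
    if tdec <= 0:
        return 0.0
    if boundary is Boundary.UPPER:
        return float(_kernels.wfpt_density_lower(tdec, -params.v, params.a, 1.0 - params.z, tol))
    return float(_kernels.wfpt_density_lower(tdec, params.v, params.a, params.z, tol))


def absorption_probability(params: DDMParams) -> float:
    """Probability that the process is absorbed at the upper boundary.

    For v != 0 this is (1 - exp(-2 v z a)) / (1 - exp(-2 v a)); for v = 0
    it reduces to z.
    """
    params.validate()
    return float(_kernels.upper_probability(params.v, params.a, params.z))


def sample_trial(
    params: DDMParams,
    rng: np.random.Generator,
    dt: float = 1e-4,
    horizon: float = 30.0,
) -> TrialOutcome:
    """Draw one (boundary, rt) pair by Euler-Maruyama simulation.

    Passages slower than ``horizon`` seconds of decision time are truncated
    at the horizon and flagged.
    """
    params.validate()
    _kernels.seed_kernel_rng(int(rng.integers(0, 2**31 - 1)))
    up, tdec = _kernels.euler_passage(params.v, params.a, params.z, dt, horizon)
    if up < 0:
        return TrialOutcome(Boundary.UPPER, params.t + horizon, truncated=True)
    return TrialOutcome(Boundary.UPPER if up == 1 else Boundary.LOWER, params.t + tdec)


def sample_trials(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    dt: float = 1e-4,
    horizon: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized sampler: returns (upper: bool[n], rt: float[n], truncated: bool[n])."""
    params.validate()
    _kernels.seed_kernel_rng(int(rng.integers(0, 2**31 - 1)))
    ups, tdecs = _kernels.euler_passage_many(n, params.v, params.a, params.z, dt, horizon)
    truncated = ups < 0
    upper = np.where(truncated, True, ups == 1)
    return upper, params.t + tdecs, truncated


def loglik_dataset(trials: list[tuple[TrialOutcome, DDMParams]], tol: float = 1e-6) -> float:
    """Sum of log first-passage densities; -inf when any density is 0."""
    if not trials:
        return 0.0
    total = 0.0
    for outcome, params in trials:
        params.validate()
        ll = _kernels.wfpt_log_density(
            outcome.rt,
            outcome.boundary is Boundary.UPPER,
            params.v, params.a, params.t, params.z,
            tol,
        )
        if ll <= _kernels.LOG_ZERO:
            return -np.inf
        total += ll
    return total
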