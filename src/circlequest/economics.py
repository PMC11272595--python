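"""Trial economy: score, expected value, optimal sampling and search efficiency.

Each active trial starts from a reward reserve ``R0`` from which every
acquired sample subtracts a sampling cost ``eta_s`` and the final placement
error subtracts an error cost ``eta_e`` per pixel:

    score = R0 - s * eta_s - e * eta_e

Replacing the realized error with the expected error EE(s) gives the expected
value of stopping after s samples,

    EV(s) = R0 - s * eta_s - EE(s) * eta_e,

whose argmax s* is the optimal number of samples.  The efficiency of a search
is summarized by the information extraction rate alpha of an exponential
decay of EE over samples toward an asymptote EE_inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .geometry import SampleObservation

__all__ = [
    "TrialEconomics",
    "SamplingTrajectory",
    "EfficiencyFit",
    "OptimalityResult",
    "trial_score",
    "expected_value_curve",
    "optimal_samples",
    "fit_extraction_rate",
    "extraction_curve",
    "deviation_from_optimal",
    "inter_sampling_intervals",
]

#: Default error cost, credits per pixel (constant across the task).
DEFAULT_ERROR_COST = 1.2

#: Default enumeration bound for EV curves, samples.
DEFAULT_S_MAX = 40


@dataclass(frozen=True)
class TrialEconomics:
    """Cost-benefit structure of one trial condition."""

    initial_reserve: float  # R0, credits
    sampling_cost: float  # eta_s, credits per sample
    error_cost: float = DEFAULT_ERROR_COST  # eta_e, credits per pixel
    score_floor: float | None = None  # optional floor (default: none)

    def __post_init__(self) -> None:
        if self.initial_reserve <= 0:
            raise ValueError("initial_reserve must be > 0")
        if self.sampling_cost < 0:
            raise ValueError("sampling_cost must be >= 0")
        if self.error_cost <= 0:
            raise ValueError("error_cost must be > 0")


@dataclass
class SamplingTrajectory:
    """One active trial: sample sequence, per-sample EE, and final placement.

    ``ee_per_sample[0]`` is the EE of the state at trial onset (after the
    initially displayed inside dot, the "0th sample"); each acquired sample
    appends one EE value, so ``len(ee_per_sample) == len(samples) + 1``.
    """

    trial_id: int
    reserve_level: str  # condition label, e.g. "low"/"high"
    cost_level: str
    samples: list[SampleObservation]
    ee_per_sample: list[float]
    placement: tuple[float, float] | None = None
    placement_error: float | None = None
    subject_id: str | None = None
    true_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.ee_per_sample) != len(self.samples) + 1:
            raise ValueError(
                "ee_per_sample must have one more entry than samples "
                f"(got {len(self.ee_per_sample)} vs {len(self.samples)})"
            )
        ts = [s.timestamp for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("sample timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class EfficiencyFit:
    """Per-trial exponential fit of EE over samples."""

    trial_id: int
    alpha: float  # extraction rate, in (0, 1)
    ee_inf: float  # asymptotic EE, pixels, > 0
    ee_start: float  # shared across-trial mean starting EE
    sse: float
    converged: bool
    flagged: bool = False  # degenerate input (constant EE, too few points)


@dataclass(frozen=True)
class OptimalityResult:
    s_star: int
    deviation: int  # samples_taken - s_star; positive = oversampling
    ev_curve: np.ndarray


def trial_score(econ: TrialEconomics, s: int, e: float) -> float:
    """Score in credits: R0 - s*eta_s - e*eta_e (optionally floored)."""
    if s < 0:
        raise ValueError("sample count must be >= 0")
    if e < 0:
        raise ValueError("placement error must be >= 0")
    score = econ.initial_reserve - s * econ.sampling_cost - e * econ.error_cost
    if econ.score_floor is not None:
        score = max(score, econ.score_floor)
    return float(score)


def expected_value_curve(
    econ: TrialEconomics, ee_curve: Sequence[float]
) -> np.ndarray:
    """EV(s) = R0 - s*eta_s - EE(s)*eta_e for s = 0 .. len(ee_curve)-1."""
    ee_arr = np.asarray(ee_curve, dtype=float)
    if ee_arr.size == 0:
        raise ValueError("ee_curve must be nonempty")
    if np.any(ee_arr < 0):
        raise ValueError("EE values must be >= 0")
    s = np.arange(ee_arr.size)
    return econ.initial_reserve - s * econ.sampling_cost - ee_arr * econ.error_cost


def optimal_samples(ev_curve: Sequence[float]) -> int:
    """Smallest s attaining the maximum of the EV curve.

    Ties break toward fewer samples: at equal expected value, not sampling
    weakly dominates.
    """
    ev = np.asarray(ev_curve, dtype=float)
    if ev.size == 0:
        raise ValueError("ev_curve must be nonempty")
    return int(np.argmax(ev))  # argmax returns the first maximizer


def deviation_from_optimal(samples_taken: int, s_star: int) -> int:
    """samples_taken - s_star; positive means oversampling."""
    if samples_taken < 0 or s_star < 0:
        raise ValueError("sample counts must be >= 0")
    return samples_taken - s_star


def extraction_curve(
    ee_start: float, alpha: float, ee_inf: float, n_points: int
) -> np.ndarray:
    """Exponential EE decay: EE(s) = (EE_start - EE_inf)*(1-alpha)^(s-1) + EE_inf.

    ``s`` runs 1 .. n_points, with s = 1 the trial-onset state, so the
    returned array aligns index-for-index with ``ee_per_sample``.
    """
    s = np.arange(1, n_points + 1)
    return (ee_start - ee_inf) * (1.0 - alpha) ** (s - 1) + ee_inf


def _fit_single(
    observed: np.ndarray, ee_start: float, coarse_alphas: np.ndarray
) -> tuple[float, float, float, bool]:
    """Profile fit of (alpha, ee_inf) to one trial's EE sequence.

    Given alpha, the model is linear in ee_inf:
        pred = ee_start*g + ee_inf*(1-g),  g = (1-alpha)^(s-1)
    so ee_inf has a closed-form least-squares solution (clipped to > 0), and
    alpha is found by a coarse scan plus bounded 1-D refinement of the MSE.
    """
    s = np.arange(1, observed.size + 1)
    eps = 1e-9

    def sse_at(alpha: float) -> tuple[float, float]:
        g = (1.0 - alpha) ** (s - 1)
        h = 1.0 - g
        resid_target = observed - ee_start * g
        denom = float(h @ h)
        if denom < eps:
            ee_inf = max(float(np.mean(observed)), eps)
        else:
            ee_inf = float(h @ resid_target) / denom
            ee_inf = max(ee_inf, eps)
        r = resid_target - ee_inf * h
        return float(r @ r), ee_inf

    coarse = [(a, *sse_at(a)) for a in coarse_alphas]
    best_a = min(coarse, key=lambda t: t[1])[0]
    lo = max(eps, best_a - 0.15)
    hi = min(1.0 - eps, best_a + 0.15)
    res = minimize_scalar(
        lambda a: sse_at(a)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    converged = bool(res.success)
    alpha = float(np.clip(res.x, eps, 1.0 - eps))
    sse, ee_inf = sse_at(alpha)
    return alpha, ee_inf, sse, converged


def fit_extraction_rate(
    trajectories: Sequence[SamplingTrajectory],
    n_trials_for_start: int | None = None,
) -> list[EfficiencyFit]:
    """Fit the information extraction rate alpha per trial.

    The starting level is shared across trials: the mean of each trajectory's
    trial-onset EE over the first ``n_trials_for_start`` trajectories (all of
    them by default; the task design uses 60 trials).  Per trial, alpha and
    the asymptote EE_inf are fitted by minimizing mean squared error under
    0 < alpha < 1, EE_inf > 0.

    Trajectories with fewer than two EE values are skipped with a warning;
    near-constant EE sequences yield a flagged boundary fit.
    """
    usable = [t for t in trajectories if len(t.ee_per_sample) >= 2]
    skipped = len(trajectories) - len(usable)
    if skipped:
        warnings.warn(
            f"skipped {skipped} trajectories with a single EE value",
            stacklevel=2,
        )
    if not usable:
        return []
    k = n_trials_for_start or len(usable)
    ee_start = float(np.mean([t.ee_per_sample[0] for t in usable[:k]]))

    coarse_alphas = np.linspace(0.1, 0.9, 9)
    fits: list[EfficiencyFit] = []
    for traj in usable:
        obs = np.asarray(traj.ee_per_sample, dtype=float)
        if np.ptp(obs) < 1e-9:
            # degenerate: no decay information; alpha unidentified
            fits.append(
                EfficiencyFit(
                    trial_id=traj.trial_id,
                    alpha=1e-9,
                    ee_inf=max(float(obs.mean()), 1e-9),
                    ee_start=ee_start,
                    sse=0.0,
                    converged=True,
                    flagged=True,
                )
            )
            continue
        alpha, ee_inf, sse, converged = _fit_single(obs, ee_start, coarse_alphas)
        fits.append(
            EfficiencyFit(
                trial_id=traj.trial_id,
                alpha=alpha,
                ee_inf=ee_inf,
                ee_start=ee_start,
                sse=sse,
                converged=converged,
            )
        )
    return fits


def inter_sampling_intervals(
    trajectory: SamplingTrajectory,
) -> np.ndarray:
    """Successive timestamp gaps (seconds) between acquired samples.

    Returns an empty array for trials with fewer than two samples; summary
    statistics over such trials are reported as missing by the caller.
    """
    ts = np.array([s.timestamp for s in trajectory.samples], dtype=float)
    if ts.size < 2:
        return np.array([])
    gaps = np.diff(ts)
    if np.any(gaps <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return gaps
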