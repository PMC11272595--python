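"""Ideal-observer geometry for hidden-circle localization.

The hidden target is a circle of fixed radius whose center must be inferred
from binary membership queries: each screen touch reveals whether that point
lies inside (purple dot) or outside (white dot) the circle.  Because each
observation is a hard constraint, the posterior over candidate centers is the
uniform distribution on the set of grid centers consistent with every
observation so far.  The operational uncertainty measure is the expected
localization error (EE): the probability-weighted mean Euclidean distance
between the posterior centroid (the best possible placement) and the true
center, taken over the posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "SampleObservation",
    "PosteriorBelief",
    "UncertaintyEstimate",
    "InconsistentObservationError",
    "init_posterior",
    "update_posterior",
    "expected_error",
    "best_placement",
    "ee",
    "simulate_observation",
    "localization_error",
]

#: Sampling window for active trials, seconds.
ACTIVE_TRIAL_WINDOW = 18.0


class InconsistentObservationError(ValueError):
    """An observation eliminated every remaining candidate center.

    Signals a corrupted trial log or a mismatched circle radius: under the
    generative task every observation is consistent with the true center.
    """


@dataclass(frozen=True)
class SearchSpace:
    """Rectangular search space with a fixed-radius hidden circle.

    The default 1280 x 715 px dimensions are chosen so that the circle
    (radius 130 px) covers 5.80% of the space, matching the task's printed
    area fraction; the exact screen dimensions are configurable.  Candidate
    centers are restricted so the full circle fits on screen (inset by the
    radius) and discretized on a square grid.

    Coordinates follow the screen convention: origin top-left, x rightward,
    y downward, in pixels.
    """

    width: float = 1280.0
    height: float = 715.0
    circle_radius: float = 130.0
    grid_step: float = 4.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("search space dimensions must be positive")
        if not 0 < self.circle_radius < min(self.width, self.height) / 2:
            raise ValueError(
                f"circle_radius {self.circle_radius} does not fit in "
                f"{self.width}x{self.height} space (must be < min(w,h)/2)"
            )
        if self.grid_step < 1:
            raise ValueError("grid_step must be >= 1 pixel")

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width and 0 <= y <= self.height

    def candidate_grid(self) -> np.ndarray:
        """(n, 2) array of admissible candidate centers.

        Admissible means the full circle lies inside the space: centers are
        inset from every edge by the circle radius.
        """
        r = self.circle_radius
        xs = np.arange(r, self.width - r + 1e-9, self.grid_step)
        ys = np.arange(r, self.height - r + 1e-9, self.grid_step)
        if xs.size == 0 or ys.size == 0:
            raise ValueError(
                f"grid_step {self.grid_step} too large for "
                f"{self.width}x{self.height} space with radius {r}: "
                "no admissible candidate centers"
            )
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class SampleObservation:
    """One binary membership query: a touched point and its inside/outside label."""

    x: float
    y: float
    label: Literal["inside", "outside"]
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("inside", "outside"):
            raise ValueError(f"label must be 'inside' or 'outside', got {self.label!r}")
        if self.timestamp < 0:
            raise ValueError("timestamp must be >= 0")


@dataclass(frozen=True)
class PosteriorBelief:
    """Discrete posterior over candidate circle centers.

    Support only ever shrinks: every observation is a hard constraint, so the
    posterior stays uniform over the surviving candidate set (uniform prior).
    """

    space: SearchSpace
    candidates: np.ndarray  # (n, 2) surviving candidate centers
    weights: np.ndarray  # (n,) probabilities summing to 1
    observations: tuple[SampleObservation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.candidates.ndim != 2 or self.candidates.shape[1] != 2:
            raise ValueError("candidates must be an (n, 2) array")
        if self.weights.shape != (self.candidates.shape[0],):
            raise ValueError("weights must align with candidates")
        if self.candidates.shape[0] and not math.isclose(
            float(self.weights.sum()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("weights must sum to 1")

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.weights))


@dataclass(frozen=True)
class UncertaintyEstimate:
    """EE summary of a belief: expected error at the centroid placement."""

    ee: float
    centroid: tuple[float, float]
    support_size: int


def init_posterior(space: SearchSpace) -> PosteriorBelief:
    """Uniform prior over all admissible candidate centers."""
    grid = space.candidate_grid()
    n = grid.shape[0]
    return PosteriorBelief(
        space=space,
        candidates=grid,
        weights=np.full(n, 1.0 / n),
        observations=(),
    )


def update_posterior(
    belief: PosteriorBelief, obs: SampleObservation
) -> PosteriorBelief:
    """Condition the belief on one membership observation.

    An inside-labelled sample retains candidates within ``circle_radius`` of
    the touch (inclusive boundary); an outside-labelled sample retains the
    complement.  Weights are renormalized uniformly over the survivors.
    """
    if not belief.space.contains(obs.x, obs.y):
        raise ValueError(f"observation ({obs.x}, {obs.y}) outside search space")
    d2 = (belief.candidates[:, 0] - obs.x) ** 2 + (belief.candidates[:, 1] - obs.y) ** 2
    r2 = belief.space.circle_radius**2
    keep = d2 <= r2 if obs.label == "inside" else d2 > r2
    keep &= belief.weights > 0
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise InconsistentObservationError(
            f"{obs.label} sample at ({obs.x:.1f}, {obs.y:.1f}) is inconsistent "
            "with every remaining candidate center"
        )
    survivors = belief.candidates[keep]
    return PosteriorBelief(
        space=belief.space,
        candidates=survivors,
        weights=np.full(n_keep, 1.0 / n_keep),
        observations=belief.observations + (obs,),
    )


def expected_error(
    belief: PosteriorBelief, placement: tuple[float, float]
) -> float:
    """Probability-weighted mean distance from ``placement`` to the candidates."""
    if belief.candidates.shape[0] == 0:
        raise ValueError("belief has empty support")
    d = np.hypot(
        belief.candidates[:, 0] - placement[0],
        belief.candidates[:, 1] - placement[1],
    )
    return float(np.dot(belief.weights, d))


def best_placement(belief: PosteriorBelief) -> tuple[float, float]:
    """Probability-weighted centroid of the posterior (the best placement)."""
    if belief.candidates.shape[0] == 0:
        raise ValueError("belief has empty support")
    cx, cy = belief.weights @ belief.candidates
    return float(cx), float(cy)


def ee(belief: PosteriorBelief) -> UncertaintyEstimate:
    """Expected localization error at the posterior centroid."""
    centroid = best_placement(belief)
    return UncertaintyEstimate(
        ee=expected_error(belief, centroid),
        centroid=centroid,
        support_size=belief.support_size,
    )


def simulate_observation(
    true_center: tuple[float, float],
    sample: tuple[float, float],
    space: SearchSpace,
    timestamp: float = 0.0,
) -> SampleObservation:
    """Label a touched point against the true circle.

    Uses the same inclusive boundary as :func:`update_posterior` (inside iff
    distance <= radius), so a posterior updated with simulated observations
    never eliminates the true center.
    """
    if not space.contains(*sample):
        raise ValueError(f"sample {sample} outside search space")
    d = math.hypot(true_center[0] - sample[0], true_center[1] - sample[1])
    label: Literal["inside", "outside"] = (
        "inside" if d <= space.circle_radius else "outside"
    )
    return SampleObservation(x=sample[0], y=sample[1], label=label, timestamp=timestamp)


def localization_error(
    placement: tuple[float, float], true_center: tuple[float, float]
) -> float:
    """Euclidean distance in pixels between placement and true center."""
    return math.hypot(placement[0] - true_center[0], placement[1] - true_center[1])


def posterior_from_observations(
    space: SearchSpace, observations: Sequence[SampleObservation]
) -> PosteriorBelief:
    """Fold a sequence of observations into a posterior from the uniform prior."""
    belief = init_posterior(space)
    for obs in observations:
        belief = update_posterior(belief, obs)
    return belief
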