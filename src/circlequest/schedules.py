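"""Trial schedules and stimulus generation for the four experiments.

Exp. 1: active sampling under a 2 (reward reserve: 95/130 credits) x
2 (sampling cost: 1/5 credits) blocked design, 15 trials per condition.
Exp. 2: passive accept/reject offers, 4 reward levels x 5 uncertainty (EE)
bands x 5 repetitions.  Exp. 3: reward (apples) x physical effort (% MVC),
5 x 5 x 5.  Exp. 4: reward x effort x uncertainty-presence, 40 trial types
repeated 5 times over 10 blocks plus 10 catch trials whose EE lies outside
the main uncertainty band.

Passive stimuli are dot configurations (four inside, four outside) generated
by rejection sampling until the configuration's recomputed expected error
falls in the requested band.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np


from .geometry import SampleObservation, SearchSpace

__all__ = [
    "PassiveStimulus",
    "TrialSpec",
    "StimulusBandError",
    "EXP1_RESERVES",
    "EXP1_COSTS",
    "EXP2_REWARDS",
    "EXP2_EE_BANDS",
    "EXP3_REWARDS",
    "EFFORT_LEVELS",
    "EXP4_REWARDS",
    "EXP4_MAIN_BAND",
    "EXP4_CATCH_BANDS",
    "generate_passive_stimulus",
    "exp1_schedule",
    "exp2_schedule",
    "exp3_schedule",
    "exp4_schedule",
]

# Printed design constants.
EXP1_RESERVES = {"low": 95.0, "high": 130.0}  # R0, credits
EXP1_COSTS = {"low": 1.0, "high": 5.0}  # eta_s, credits per sample
EXP1_TRIALS_PER_CONDITION = 15

EXP2_REWARDS = (40, 65, 90, 115)  # credits
EXP2_EE_BANDS = (
    (16.3, 24.4),
    (27.1, 38.9),
    (57.5, 58.9),
    (73.33, 74.18),
    (91.9, 93.3),
)  # pixels
EXP2_REPS = 5

EXP3_REWARDS = (1, 4, 7, 10, 13)  # apples
EFFORT_LEVELS = (16, 32, 48, 64, 80)  # % MVC
EXP3_REPS = 5

EXP4_REWARDS = EXP2_REWARDS
EXP4_MAIN_BAND = (31.8, 73.95)  # EE band when uncertainty present
EXP4_CATCH_BANDS = ((17.9, 23.0), (91.0, 93.3))  # low / high catch uncertainty
EXP4_REPS = 5
EXP4_BLOCKS = 10


class StimulusBandError(RuntimeError):
    """Rejection sampling failed to hit the requested EE band."""


@dataclass(frozen=True)
class PassiveStimulus:
    """Eight-dot configuration (4 inside, 4 outside) with a verified EE."""

    dots: tuple[SampleObservation, ...]
    achieved_ee: float
    ee_band: tuple[float, float]
    true_center: tuple[float, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        n_in = sum(1 for d in self.dots if d.label == "inside")
        n_out = sum(1 for d in self.dots if d.label == "outside")
        if (n_in, n_out) != (4, 4):
            raise ValueError(f"need 4 inside + 4 outside dots, got {n_in}+{n_out}")


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial with its design attributes."""

    experiment: str  # exp1 | exp2 | exp3 | exp4
    trial_index: int
    block: int
    reward: float | None = None  # credits (exp1/2/4) or apples (exp3)
    effort: float | None = None  # % MVC
    ee_band: tuple[float, float] | None = None
    ee_nominal: float | None = None  # EE drawn within the band (uncertain trials)
    uncertainty_present: bool | None = None  # exp4 presence flag
    reserve: float | None = None  # R0, exp1
    sampling_cost: float | None = None  # eta_s, exp1
    reserve_level: str | None = None
    cost_level: str | None = None
    is_catch: bool = False

    def __post_init__(self) -> None:
        if self.is_catch and self.experiment != "exp4":
            raise ValueError("catch trials occur only in exp4")


def _belief_ee_from_dots(
    space: SearchSpace,
    center: np.ndarray,
    inside: np.ndarray,
    outside: np.ndarray,
) -> float | None:
    """EE of the posterior under the 8 dots, or None if support empties.

    Vectorized equivalent of folding the dots through update_posterior;
    used only inside the rejection loop for speed.
    """
    grid = space.candidate_grid()
    r2 = space.circle_radius**2
    keep = np.ones(grid.shape[0], dtype=bool)
    for pt in inside:
        keep &= (grid[:, 0] - pt[0]) ** 2 + (grid[:, 1] - pt[1]) ** 2 <= r2
    for pt in outside:
        keep &= (grid[:, 0] - pt[0]) ** 2 + (grid[:, 1] - pt[1]) ** 2 > r2
    pts = grid[keep]
    if pts.shape[0] == 0:
        return None
    c = pts.mean(axis=0)
    return float(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]).mean())


def _propose_dots(
    rng: np.random.Generator, space: SearchSpace, spread: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a candidate configuration controlled by a spread parameter.

    ``spread`` in (0, 1] scales how dispersed the inside dots are around the
    true center and how tightly the outside dots hug the circle boundary.
    Dispersed inside dots and close outside dots carve a small consistent
    region (low EE); clustered inside dots with distant outside dots leave a
    large, possibly annular region (high EE).
    """
    r = space.circle_radius
    lo = np.array([0.0, 0.0])
    hi = np.array([space.width, space.height])
    center = rng.uniform(
        [r, r], [space.width - r, space.height - r]
    )
    # inside: uniform in a disk of radius spread*r around the center
    ang = rng.uniform(0, 2 * np.pi, 4)
    rad = spread * r * np.sqrt(rng.uniform(0, 1, 4))
    inside = center + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    inside = np.clip(inside, lo, hi)
    # outside: just beyond the boundary when spread is large, far when small
    ang = rng.uniform(0, 2 * np.pi, 4)
    margin = rng.uniform(1.0, 1.0 + (1.0 - spread) * 2.5 * r, 4)
    outside = center + np.column_stack(
        [(r + margin) * np.cos(ang), (r + margin) * np.sin(ang)]
    )
    outside = np.clip(outside, lo, hi)
    # clipping to the screen may push an "outside" dot inside the circle
    d = np.hypot(outside[:, 0] - center[0], outside[:, 1] - center[1])
    if np.any(d <= r):
        return _propose_dots(rng, space, spread)
    return center, inside, outside


def _propose_dots_bimodal(
    rng: np.random.Generator, space: SearchSpace, d_frac: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """High-uncertainty proposal: carve the center out of the consistent disk.

    Inside dots cluster tightly at a point p; two pairs of outside dots sit
    at p +/- d on a random axis, each deleting a radius-r disk that covers
    the middle of the consistent region.  What survives are two distant caps
    perpendicular to the axis, so the posterior is bimodal with nearly all
    mass far from its centroid — EE beyond the full-disk value.  ``d_frac``
    (outside-dot offset as a fraction of r) tunes how large the caps are and
    hence the EE.  The true center is drawn inside one surviving cap.
    """
    r = space.circle_radius
    d = d_frac * r
    margin = 1.2 * r
    p = rng.uniform(
        [margin, margin], [space.width - margin, space.height - margin]
    )
    theta = rng.uniform(0, 2 * np.pi)
    e1 = np.array([np.cos(theta), np.sin(theta)])
    e2 = np.array([-np.sin(theta), np.cos(theta)])
    # true center in one of the two surviving caps
    y_lo = np.sqrt(max(r**2 - d**2, 0.0)) + 1.0
    if y_lo >= r:
        return None
    y = rng.uniform(y_lo, r)
    c = p + y * e2 * rng.choice([-1.0, 1.0])
    inside = p + rng.normal(0.0, 2.0, (4, 2))
    outside = np.vstack(
        [
            p + d * e1 + rng.normal(0.0, 2.0, (2, 2)),
            p - d * e1 + rng.normal(0.0, 2.0, (2, 2)),
        ]
    )
    pts = np.vstack([inside, outside, [c]])
    if np.any(pts < 0) or np.any(pts[:, 0] > space.width) or np.any(
        pts[:, 1] > space.height
    ):
        return None
    # verify intended labels against the drawn center
    if np.any(np.hypot(*(inside - c).T) > r):
        return None
    if np.any(np.hypot(*(outside - c).T) <= r):
        return None
    return c, inside, outside


def generate_passive_stimulus(
    space: SearchSpace,
    band: tuple[float, float],
    seed: int | np.random.Generator,
    max_attempts: int = 10_000,
) -> PassiveStimulus:
    """Rejection-sample an 8-dot stimulus whose EE lies in ``band``.

    Proposals sweep a spread parameter across attempts so both very low and
    very high EE bands are reachable; acceptance requires the EE recomputed
    from the dots alone to fall inside the band.
    """
    if band[0] < 0 or band[1] <= band[0]:
        raise ValueError(f"invalid EE band {band}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    seed_val = seed if isinstance(seed, int) else None
    # map the band midpoint to a first-guess spread: high EE needs clustered
    # inside dots (small spread), low EE needs dispersed ones
    mid = 0.5 * (band[0] + band[1])
    # a single consistent disk tops out near 2r/3; higher bands need the
    # bimodal (center-carved) construction
    use_bimodal = mid > 0.62 * space.circle_radius
    base_spread = float(np.clip(1.0 - mid / (space.circle_radius * 1.05), 0.02, 1.0))
    for attempt in range(max_attempts):
        # widen the sweep around the first guess as attempts accumulate
        width = 0.05 + 0.5 * attempt / max_attempts
        if use_bimodal:
            d_frac = float(np.clip(rng.uniform(0.1, 0.999), 0.05, 0.999))
            proposal = _propose_dots_bimodal(rng, space, d_frac)
            if proposal is None:
                continue
            center, inside, outside = proposal
        else:
            spread = float(
                np.clip(base_spread + rng.uniform(-width, width), 0.02, 1.0)
            )
            center, inside, outside = _propose_dots(rng, space, spread)
        ee_val = _belief_ee_from_dots(space, center, inside, outside)
        if ee_val is None:
            continue
        if band[0] <= ee_val <= band[1]:
            dots = tuple(
                SampleObservation(float(p[0]), float(p[1]), "inside")
                for p in inside
            ) + tuple(
                SampleObservation(float(p[0]), float(p[1]), "outside")
                for p in outside
            )
            return PassiveStimulus(
                dots=dots,
                achieved_ee=ee_val,
                ee_band=band,
                true_center=(float(center[0]), float(center[1])),
                seed=seed_val,
            )
    raise StimulusBandError(
        f"no stimulus with EE in [{band[0]}, {band[1]}] after "
        f"{max_attempts} attempts; band may be infeasible for this space"
    )


def _latin_square_order(n: int, seed: int) -> list[int]:
    """Cyclic Latin-square row indexed by seed (between-participant counterbalancing)."""
    row = seed % n
    return [(row + i) % n for i in range(n)]


def exp1_schedule(seed: int) -> list[TrialSpec]:
    """2 reserve x 2 cost blocked design, 15 trials per condition, 60 total."""
    conditions = [
        (rl, cl) for rl in ("low", "high") for cl in ("low", "high")
    ]
    order = _latin_square_order(len(conditions), seed)
    trials: list[TrialSpec] = []
    idx = 0
    for block, cond_i in enumerate(order):
        rl, cl = conditions[cond_i]
        for _ in range(EXP1_TRIALS_PER_CONDITION):
            trials.append(
                TrialSpec(
                    experiment="exp1",
                    trial_index=idx,
                    block=block,
                    reserve=EXP1_RESERVES[rl],
                    sampling_cost=EXP1_COSTS[cl],
                    reserve_level=rl,
                    cost_level=cl,
                )
            )
            idx += 1
    return trials


def _with_nominal_ee(
    rng: np.random.Generator, band: tuple[float, float]
) -> float:
    return float(rng.uniform(band[0], band[1]))


def exp2_schedule(seed: int) -> list[TrialSpec]:
    """4 rewards x 5 EE bands x 5 reps = 100 shuffled trials."""
    rng = np.random.default_rng(seed)
    cells = [
        (r, band)
        for r in EXP2_REWARDS
        for band in EXP2_EE_BANDS
        for _ in range(EXP2_REPS)
    ]
    rng.shuffle(cells)
    return [
        TrialSpec(
            experiment="exp2",
            trial_index=i,
            block=0,
            reward=float(r),
            ee_band=band,
            ee_nominal=_with_nominal_ee(rng, band),
        )
        for i, (r, band) in enumerate(cells)
    ]


def exp3_schedule(seed: int) -> list[TrialSpec]:
    """5 rewards (apples) x 5 efforts (% MVC) x 5 reps = 125 shuffled trials."""
    rng = np.random.default_rng(seed)
    cells = [
        (r, ef)
        for r in EXP3_REWARDS
        for ef in EFFORT_LEVELS
        for _ in range(EXP3_REPS)
    ]
    rng.shuffle(cells)
    return [
        TrialSpec(
            experiment="exp3",
            trial_index=i,
            block=0,
            reward=float(r),
            effort=float(ef),
        )
        for i, (r, ef) in enumerate(cells)
    ]


def exp4_schedule(seed: int) -> list[TrialSpec]:
    """4 rewards x 5 efforts x 2 uncertainty x 5 reps in 10 blocks + 10 catch.

    The 40 main trial types each repeat five times (200 main trials).  One
    catch trial per block: the two catch uncertainty levels (EE below / above
    the main band) each crossed with the five effort levels, at a random
    position within the block.
    """
    rng = np.random.default_rng(seed)
    types = [
        (r, ef, unc)
        for r in EXP4_REWARDS
        for ef in EFFORT_LEVELS
        for unc in (True, False)
    ]
    assert len(types) == 40
    # 200 main trials shuffled, then chunked into 10 blocks of 20
    main: list[tuple] = [t for _ in range(EXP4_REPS) for t in types]
    rng.shuffle(main)
    blocks: list[list[tuple]] = [
        main[b * 20 : (b + 1) * 20] for b in range(EXP4_BLOCKS)
    ]
    # catch trials: 2 uncertainty levels x 5 efforts, one per block
    catch = [
        (band, ef) for band in EXP4_CATCH_BANDS for ef in EFFORT_LEVELS
    ]
    rng.shuffle(catch)

    trials: list[TrialSpec] = []
    idx = 0
    for b, block_cells in enumerate(blocks):
        pos = int(rng.integers(0, len(block_cells) + 1))
        band_c, ef_c = catch[b]
        for j, cell in enumerate(block_cells):
            if j == pos:
                trials.append(
                    TrialSpec(
                        experiment="exp4",
                        trial_index=idx,
                        block=b,
                        reward=float(rng.choice(EXP4_REWARDS)),
                        effort=float(ef_c),
                        ee_band=band_c,
                        ee_nominal=_with_nominal_ee(rng, band_c),
                        uncertainty_present=True,
                        is_catch=True,
                    )
                )
                idx += 1
            r, ef, unc = cell
            trials.append(
                TrialSpec(
                    experiment="exp4",
                    trial_index=idx,
                    block=b,
                    reward=float(r),
                    effort=float(ef),
                    ee_band=EXP4_MAIN_BAND if unc else None,
                    ee_nominal=(
                        _with_nominal_ee(rng, EXP4_MAIN_BAND) if unc else None
                    ),
                    uncertainty_present=unc,
                )
            )
            idx += 1
        if pos == len(block_cells):  # catch at the end of the block
            band_c, ef_c = catch[b]
            trials.append(
                TrialSpec(
                    experiment="exp4",
                    trial_index=idx,
                    block=b,
                    reward=float(rng.choice(EXP4_REWARDS)),
                    effort=float(ef_c),
                    ee_band=band_c,
                    ee_nominal=_with_nominal_ee(rng, band_c),
                    uncertainty_present=True,
                    is_catch=True,
                )
            )
            idx += 1
    return trials
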