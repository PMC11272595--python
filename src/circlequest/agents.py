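"""Synthetic participants: choice, confidence and active-sampling policies.

Agents embody the behavioural phenotypes of interest.  Passive accept/reject
choices follow a logistic model over standardized offer attributes (reward,
uncertainty, effort); a multiplicative context factor ``gamma_context``
attenuates reward and effort sensitivity when uncertainty is present,
emulating the lesion phenotype (blunted reward/effort weighting under
uncertainty with intact uncertainty sensitivity).  Active sampling uses a
greedy information-optimal policy — each touch targets the point that most
reduces posterior expected error — with Gaussian spatial jitter, and stops
when the subjective one-step value gain ``dEE*eta_e - w_cost*eta_s`` is
exhausted or the 18-second window runs out.  ``w_cost`` scales the agent's
subjective sampling cost: 1 is a cost-sensitive (near-optimal) sampler,
values near 0 give a cost-blind oversampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

from . import schedules
from .economics import SamplingTrajectory, TrialEconomics
from .geometry import (
    ACTIVE_TRIAL_WINDOW,
    PosteriorBelief,
    SampleObservation,
    SearchSpace,
    best_placement,
    ee,
    init_posterior,
    localization_error,
    simulate_observation,
    update_posterior,
)
from .schedules import TrialSpec

__all__ = [
    "AgentParams",
    "CohortConfig",
    "ChoiceRecord",
    "passive_choice",
    "active_sampling_episode",
    "confidence_report",
    "simulate_cohort",
    "default_cohort_config",
    "design_standardizer",
    "expected_posterior_ee",
]


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic participant."""

    group: str = "control"  # control | lesion
    beta0: float = 0.5  # choice intercept
    beta_reward: float = 1.5  # per standardized reward unit
    beta_uncertainty: float = -1.5  # per standardized EE / presence unit
    beta_effort: float = -1.2  # per standardized effort unit
    gamma_context: float = 1.0  # attenuation of reward/effort under uncertainty
    w_cost: float = 1.0  # subjective weight on sampling cost
    sampling_jitter: float = 12.0  # px sd around the information-optimal point
    isi_base: float = 0.45  # s, floor of the inter-sampling interval
    isi_slope: float = 0.8  # s, jitter-linked ISI component
    conf_intercept: float = 100.0  # confidence at EE = 0
    conf_slope: float = -0.9  # confidence units per EE pixel (<= 0)
    conf_noise: float = 8.0  # sd of the rating noise
    motor_noise: float = 5.0  # px sd on the final placement
    rt_mu: float = -0.3  # log-normal response-time location (log seconds)
    rt_sigma: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.gamma_context <= 1:
            raise ValueError("gamma_context must be in (0, 1]")
        if self.w_cost < 0 or self.sampling_jitter < 0:
            raise ValueError("w_cost and sampling_jitter must be >= 0")
        if self.conf_slope > 0:
            raise ValueError("conf_slope must be <= 0 (higher EE, lower confidence)")

    def isi(self) -> float:
        """Mean inter-sampling interval: fast (jittery) samplers pause less."""
        return self.isi_base + self.isi_slope / (1.0 + self.sampling_jitter / 10.0)


@dataclass(frozen=True)
class ChoiceRecord:
    """One accept/reject decision with its offer attributes."""

    subject_id: str
    experiment: str
    trial_index: int
    reward: float
    accepted: bool
    response_time: float
    ee: float | None = None
    effort: float | None = None
    uncertainty_present: bool | None = None
    is_catch: bool = False


@dataclass
class CohortConfig:
    """Cohort sizes and per-group parameter distributions (mean, sd)."""

    n_per_group: int
    distributions: dict[str, dict[str, tuple[float, float]]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for group, dists in self.distributions.items():
            for name, (_, sd) in dists.items():
                if sd < 0:
                    raise ValueError(f"{group}.{name} sd must be >= 0")


_PARAM_BOUNDS = {
    "gamma_context": (1e-6, 1.0),
    "w_cost": (0.0, np.inf),
    "sampling_jitter": (0.0, np.inf),
    "isi_base": (0.05, np.inf),
    "isi_slope": (0.0, np.inf),
    "conf_slope": (-np.inf, 0.0),
    "conf_noise": (0.0, np.inf),
    "motor_noise": (0.0, np.inf),
    "rt_sigma": (0.01, np.inf),
}


def default_cohort_config(n_per_group: int = 19, seed: int = 0) -> CohortConfig:
    """Control vs. lesion cohort emulating the study's phenotypes.

    Controls are cost-sensitive near-optimal samplers with full reward/effort
    weighting; the lesion group keeps intact uncertainty sensitivity but has
    attenuated reward/effort weighting under uncertainty (gamma = 0.4) and a
    strongly reduced subjective sampling cost (w_cost = 0.15, oversampling).
    """
    control = {
        "beta0": (0.5, 0.4),
        "beta_reward": (1.5, 0.3),
        "beta_uncertainty": (-1.5, 0.3),
        "beta_effort": (-1.2, 0.3),
        "gamma_context": (1.0, 0.0),
        "w_cost": (1.0, 0.15),
        "sampling_jitter": (12.0, 4.0),
        "conf_slope": (-0.9, 0.1),
        "conf_intercept": (100.0, 4.0),
    }
    lesion = dict(control)
    lesion["gamma_context"] = (0.4, 0.05)
    lesion["w_cost"] = (0.15, 0.05)
    return CohortConfig(
        n_per_group=n_per_group,
        distributions={"control": control, "lesion": lesion},
        seed=seed,
    )


def draw_agent(
    group: str, dists: dict[str, tuple[float, float]], rng: np.random.Generator
) -> AgentParams:
    """Draw one agent from per-parameter normal distributions, clipped to bounds."""
    values: dict[str, float] = {}
    for name, (mean, sd) in dists.items():
        v = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
        lo, hi = _PARAM_BOUNDS.get(name, (-np.inf, np.inf))
        values[name] = float(np.clip(v, lo, hi))
    return AgentParams(group=group, **values)


def design_standardizer(experiment: str) -> dict[str, tuple[float, float]]:
    """(mean, sd) per attribute over the experiment's factorial design.

    Predictors are z-scored against these design-level moments so that choice
    sensitivities are expressed per standardized unit and comparable across
    attributes.  Uncertainty enters as EE for the continuous designs and as a
    presence flag for the two-level design.
    """

    def ms(vals: Sequence[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        return float(arr.mean()), float(arr.std())

    if experiment == "exp2":
        mids = [0.5 * (lo + hi) for lo, hi in schedules.EXP2_EE_BANDS]
        return {"reward": ms(schedules.EXP2_REWARDS), "ee": ms(mids)}
    if experiment == "exp3":
        return {
            "reward": ms(schedules.EXP3_REWARDS),
            "effort": ms(schedules.EFFORT_LEVELS),
        }
    if experiment == "exp4":
        return {
            "reward": ms(schedules.EXP4_REWARDS),
            "effort": ms(schedules.EFFORT_LEVELS),
            "presence": (0.5, 0.5),
        }
    raise ValueError(f"no passive design for {experiment!r}")


def _z(value: float, moments: tuple[float, float]) -> float:
    mean, sd = moments
    return (value - mean) / sd if sd > 0 else 0.0


def passive_choice(
    agent: AgentParams,
    trial: TrialSpec,
    rng: np.random.Generator,
    standardizer: dict[str, tuple[float, float]] | None = None,
) -> ChoiceRecord:
    """One accept/reject decision under the logistic choice model.

    P(accept) = logistic(beta0 + bR*z(reward) + beta_unc*z(uncertainty)
    [+ bE*z(effort)]), where bR and bE are attenuated by ``gamma_context``
    when the offer carries uncertainty.
    """
    std = standardizer or design_standardizer(trial.experiment)
    uncertain = (
        trial.uncertainty_present
        if trial.uncertainty_present is not None
        else trial.ee_nominal is not None
    )
    gamma = agent.gamma_context if uncertain else 1.0
    logit = agent.beta0 + agent.beta_reward * gamma * _z(trial.reward, std["reward"])
    if trial.experiment == "exp2":
        logit += agent.beta_uncertainty * _z(trial.ee_nominal, std["ee"])
    elif trial.experiment == "exp4":
        logit += agent.beta_uncertainty * _z(float(uncertain), std["presence"])
    if trial.effort is not None and "effort" in std:
        logit += agent.beta_effort * gamma * _z(trial.effort, std["effort"])
    p_accept = 1.0 / (1.0 + math.exp(-logit))
    accepted = bool(rng.random() < p_accept)
    rt = float(rng.lognormal(agent.rt_mu, agent.rt_sigma))
    return ChoiceRecord(
        subject_id="",
        experiment=trial.experiment,
        trial_index=trial.trial_index,
        reward=float(trial.reward),
        accepted=accepted,
        response_time=rt,
        ee=trial.ee_nominal,
        effort=trial.effort,
        uncertainty_present=trial.uncertainty_present,
        is_catch=trial.is_catch,
    )


def _probe_lattice(space: SearchSpace, nx: int = 16, ny: int = 12) -> np.ndarray:
    """Coarse lattice of candidate sample points covering the space."""
    xs = np.linspace(space.width * 0.04, space.width * 0.96, nx)
    ys = np.linspace(space.height * 0.04, space.height * 0.96, ny)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def expected_posterior_ee(
    belief: PosteriorBelief, probes: np.ndarray
) -> np.ndarray:
    """Expected EE after one observation at each probe point.

    For a probe q, the observation comes back "inside" with probability equal
    to the posterior mass within the circle radius of q; the expected EE is
    the mass-weighted mean of the EE of the two conditioned posteriors.
    Probes whose outcome is already certain leave the EE unchanged.
    """
    pts = belief.candidates
    w = belief.weights
    r2 = belief.space.circle_radius**2
    # (n_candidates, n_probes) membership matrix
    d2 = (
        (pts[:, 0, None] - probes[None, :, 0]) ** 2
        + (pts[:, 1, None] - probes[None, :, 1]) ** 2
    )
    inside = d2 <= r2
    wm = w[:, None] * inside
    p_in = wm.sum(axis=0)
    out = np.empty(probes.shape[0])
    cur = ee(belief).ee
    for j in range(probes.shape[0]):
        pj = p_in[j]
        if pj <= 0.0 or pj >= 1.0:
            out[j] = cur
            continue
        m_in = inside[:, j]
        ee_in = _subset_ee(pts[m_in], w[m_in])
        ee_out = _subset_ee(pts[~m_in], w[~m_in])
        out[j] = pj * ee_in + (1.0 - pj) * ee_out
    return out


def _subset_ee(pts: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    wn = w / wsum
    c = wn @ pts
    return float(wn @ np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]))


def active_sampling_episode(
    agent: AgentParams,
    econ: TrialEconomics,
    space: SearchSpace,
    true_center: tuple[float, float],
    rng: np.random.Generator,
    trial_id: int = 0,
    reserve_level: str = "",
    cost_level: str = "",
    probe_shape: tuple[int, int] = (16, 12),
) -> SamplingTrajectory:
    """Simulate one active trial under the agent's sampling policy.

    The trial opens with a displayed inside dot (the 0th sample).  The agent
    then repeatedly aims at the probe point minimizing expected posterior EE
    (plus Gaussian jitter), stopping when the subjective one-step gain
    ``dEE*eta_e - w_cost*eta_s`` is non-positive or the next touch would fall
    outside the 18-second window.  Placement is the posterior centroid plus
    motor noise.
    """
    probes = _probe_lattice(space, *probe_shape)
    # displayed initial dot: uniform within the hidden circle
    ang = rng.uniform(0, 2 * np.pi)
    rad = space.circle_radius * math.sqrt(rng.uniform())
    x0 = float(np.clip(true_center[0] + rad * math.cos(ang), 0, space.width))
    y0 = float(np.clip(true_center[1] + rad * math.sin(ang), 0, space.height))
    belief = update_posterior(
        init_posterior(space),
        SampleObservation(x0, y0, "inside", timestamp=0.0),
    )
    ee_values = [ee(belief).ee]
    samples: list[SampleObservation] = []
    t = 0.0
    while True:
        isi = agent.isi() * float(rng.lognormal(0.0, 0.08))
        if t + isi > ACTIVE_TRIAL_WINDOW:
            break
        exp_ee = expected_posterior_ee(belief, probes)
        j = int(np.argmin(exp_ee))
        delta = ee_values[-1] - float(exp_ee[j])
        if delta * econ.error_cost - agent.w_cost * econ.sampling_cost <= 0:
            break
        target = probes[j] + rng.normal(0.0, agent.sampling_jitter, 2)
        target = np.clip(target, [0, 0], [space.width, space.height])
        t += isi
        obs = simulate_observation(
            true_center, (float(target[0]), float(target[1])), space, timestamp=t
        )
        belief = update_posterior(belief, obs)
        samples.append(obs)
        ee_values.append(ee(belief).ee)
    cx, cy = best_placement(belief)
    placement = (
        float(cx + rng.normal(0, agent.motor_noise)),
        float(cy + rng.normal(0, agent.motor_noise)),
    )
    return SamplingTrajectory(
        trial_id=trial_id,
        reserve_level=reserve_level,
        cost_level=cost_level,
        samples=samples,
        ee_per_sample=ee_values,
        placement=placement,
        placement_error=localization_error(placement, true_center),
        true_center=true_center,
    )


def confidence_report(
    agent: AgentParams,
    stimulus_ee: float,
    rng: np.random.Generator,
) -> float:
    """0-100 confidence rating: linear in EE with Gaussian noise, clipped."""
    raw = agent.conf_intercept + agent.conf_slope * stimulus_ee
    if agent.conf_noise > 0:
        raw += rng.normal(0, agent.conf_noise)
    return float(np.clip(raw, 0.0, 100.0))


_SCHEDULES = {
    "exp1": schedules.exp1_schedule,
    "exp2": schedules.exp2_schedule,
    "exp3": schedules.exp3_schedule,
    "exp4": schedules.exp4_schedule,
}


def simulate_cohort(
    config: CohortConfig,
    experiment: str,
    space: SearchSpace | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate a full cohort on one experiment's schedule.

    Returns a dict of tables: ``choices`` (passive experiments), ``sampling``
    (exp1, one row per sample event with trial-level columns repeated),
    ``confidence`` (uncertain stimuli), and ``truth`` (the generative agent
    parameters, for recovery testing only — estimators must not read it).
    Each subject gets a fresh schedule seed derived from the master seed.
    """
    if experiment not in _SCHEDULES:
        raise ValueError(f"unknown experiment {experiment!r}")
    space = space or SearchSpace()
    master = np.random.SeedSequence(config.seed)
    groups = sorted(config.distributions)
    subject_seeds = master.spawn(config.n_per_group * len(groups))

    choices: list[dict] = []
    sampling: list[dict] = []
    confidence: list[dict] = []
    truth: list[dict] = []
    std = design_standardizer(experiment) if experiment != "exp1" else None

    i_subj = 0
    for group in groups:
        for _ in range(config.n_per_group):
            ss = subject_seeds[i_subj]
            rng = np.random.default_rng(ss)
            sched_seed = int(ss.generate_state(1)[0] % (2**31))
            subject_id = f"{group}_{i_subj:03d}"
            agent = draw_agent(group, config.distributions[group], rng)
            truth.append(
                {"subject_id": subject_id, "group": group}
                | {f.name: getattr(agent, f.name) for f in fields(agent)
                   if f.name != "group"}
            )
            trials = _SCHEDULES[experiment](sched_seed)
            if experiment == "exp1":
                for trial in trials:
                    grid = space.candidate_grid()
                    center = grid[int(rng.integers(grid.shape[0]))]
                    econ = TrialEconomics(
                        initial_reserve=trial.reserve,
                        sampling_cost=trial.sampling_cost,
                    )
                    traj = active_sampling_episode(
                        agent,
                        econ,
                        space,
                        (float(center[0]), float(center[1])),
                        rng,
                        trial_id=trial.trial_index,
                        reserve_level=trial.reserve_level,
                        cost_level=trial.cost_level,
                    )
                    base = {
                        "subject_id": subject_id,
                        "group": group,
                        "trial_id": trial.trial_index,
                        "reserve_level": trial.reserve_level,
                        "cost_level": trial.cost_level,
                        "reserve": trial.reserve,
                        "sampling_cost": trial.sampling_cost,
                        "placement_x": traj.placement[0],
                        "placement_y": traj.placement[1],
                        "placement_error": traj.placement_error,
                        "true_x": center[0],
                        "true_y": center[1],
                        "n_samples": traj.n_samples,
                    }
                    events = [
                        {"sample_index": 0, "x": np.nan, "y": np.nan,
                         "label": "inside", "timestamp": 0.0,
                         "ee_after": traj.ee_per_sample[0]}
                    ]
                    for k, (obs, ee_v) in enumerate(
                        zip(traj.samples, traj.ee_per_sample[1:]), start=1
                    ):
                        events.append(
                            {"sample_index": k, "x": obs.x, "y": obs.y,
                             "label": obs.label, "timestamp": obs.timestamp,
                             "ee_after": ee_v}
                        )
                    sampling.extend(base | ev for ev in events)
            else:
                for trial in trials:
                    rec = passive_choice(agent, trial, rng, std)
                    choices.append(
                        {
                            "subject_id": subject_id,
                            "group": group,
                            "experiment": experiment,
                            "trial_index": trial.trial_index,
                            "reward": rec.reward,
                            "effort": rec.effort,
                            "ee": rec.ee,
                            "uncertainty_present": rec.uncertainty_present,
                            "is_catch": rec.is_catch,
                            "accepted": rec.accepted,
                            "response_time": rec.response_time,
                        }
                    )
                    if trial.ee_nominal is not None:
                        confidence.append(
                            {
                                "subject_id": subject_id,
                                "group": group,
                                "trial_index": trial.trial_index,
                                "ee": trial.ee_nominal,
                                "confidence": confidence_report(
                                    agent, trial.ee_nominal, rng
                                ),
                            }
                        )
            i_subj += 1

    out: dict[str, pd.DataFrame] = {"truth": pd.DataFrame(truth)}
    if choices:
        out["choices"] = pd.DataFrame(choices)
    if sampling:
        out["sampling"] = pd.DataFrame(sampling)
    if confidence:
        out["confidence"] = pd.DataFrame(confidence)
    return out
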