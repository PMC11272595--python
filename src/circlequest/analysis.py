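"""Estimation of behavioural read-outs from trial logs.

Per-subject logistic regressions recover choice sensitivities (reward,
uncertainty, effort); ordinary least squares on sign-flipped confidence
ratings gives uncertainty-estimation accuracy; the active-sampling logs
yield deviation-from-optimal and a cost-sensitivity index; group contrasts
use a two-sided t-test (Cohen's d) or Wilcoxon rank-sum (Cliff's delta)
chosen by a Shapiro-Wilk normality gate; and regional volumes are adjusted
for intracranial volume before a robust (bisquare) regression of sensitivity
on volume.  All tests are two-tailed at alpha = 0.05 and no multiplicity
correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .economics import (
    SamplingTrajectory,
    TrialEconomics,
    deviation_from_optimal,
    expected_value_curve,
    optimal_samples,
)
from .geometry import SampleObservation

__all__ = [
    "SensitivityEstimate",
    "GroupContrast",
    "fit_choice_sensitivities",
    "uncertainty_estimation_accuracy",
    "oversampling_metrics",
    "group_contrast",
    "cliffs_delta",
    "cohens_d",
    "icv_adjust",
    "volume_sensitivity_regression",
    "trajectories_from_table",
]

ALPHA_LEVEL = 0.05  # two-tailed


@dataclass(frozen=True)
class SensitivityEstimate:
    """Per-subject logistic coefficients (sensitivities) with standard errors."""

    subject_id: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    separation: bool  # Firth fallback used


@dataclass(frozen=True)
class GroupContrast:
    metric: str
    group_names: tuple[str, str]
    means: tuple[float, float]
    medians: tuple[float, float]
    test: str  # "t" or "ranksum"
    statistic: float
    p_value: float
    effect_size: float  # Cohen's d (t) or Cliff's delta (ranksum)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _design_matrix(df: pd.DataFrame, experiment: str) -> tuple[np.ndarray, list[str]]:
    cols: list[tuple[str, np.ndarray]] = []
    if experiment == "exp2":
        cols.append(("reward", _zscore(df["reward"].to_numpy(float))))
        cols.append(("uncertainty", _zscore(df["ee"].to_numpy(float))))
    elif experiment == "exp3":
        cols.append(("reward", _zscore(df["reward"].to_numpy(float))))
        cols.append(("effort", _zscore(df["effort"].to_numpy(float))))
    elif experiment == "exp4":
        zr = _zscore(df["reward"].to_numpy(float))
        zef = _zscore(df["effort"].to_numpy(float))
        zu = _zscore(df["uncertainty_present"].to_numpy(float))
        cols += [
            ("reward", zr),
            ("effort", zef),
            ("uncertainty", zu),
            ("reward_x_uncertainty", zr * zu),
            ("effort_x_uncertainty", zef * zu),
        ]
    else:
        raise ValueError(f"no choice design for {experiment!r}")
    names = ["intercept"] + [n for n, _ in cols]
    X = np.column_stack([np.ones(len(df))] + [v for _, v in cols])
    return X, names


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Firth-penalized logistic fit (Jeffreys-prior score correction).

    Newton iterations on the modified score U*_j = sum_i (y_i - p_i +
    h_i (1/2 - p_i)) x_ij, where h_i are leverages of the weighted hat
    matrix.  Finite estimates exist even under complete separation.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        # dampen oversized steps for stability
        norm = np.abs(step).max()
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    return beta


def fit_choice_sensitivities(
    choices: pd.DataFrame, experiment: str, include_catch: bool = False
) -> pd.DataFrame:
    """Per-subject logistic ML fit of acceptance on standardized attributes.

    Returns one row per subject with coefficient, standard-error, convergence
    and separation columns.  Complete separation (or a diverging MLE) falls
    back to a Firth-penalized fit and raises the ``separation`` flag;
    subjects who accepted everything or nothing are returned non-converged
    with NaN sensitivities.
    """
    rows = []
    df_all = choices if include_catch else choices[~choices.get(
        "is_catch", pd.Series(False, index=choices.index)
    ).astype(bool)]
    for subject_id, df in df_all.groupby("subject_id", sort=True):
        X, names = _design_matrix(df, experiment)
        y = df["accepted"].to_numpy(float)
        row: dict = {"subject_id": subject_id}
        if "group" in df.columns:
            row["group"] = df["group"].iloc[0]
        if y.min() == y.max():
            row |= {n: np.nan for n in names}
            row |= {f"se_{n}": np.nan for n in names}
            row |= {"converged": False, "separation": False}
            rows.append(row)
            continue
        separation = False
        params = se = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                params = fit.params
                se = fit.bse
                converged = bool(fit.mle_retvals["converged"])
                if not converged or np.abs(params).max() > 15 or np.any(
                    ~np.isfinite(se)
                ):
                    separation = True
            except Exception:
                separation = True
        if separation:
            params = _firth_logit(X, y)
            p = 1.0 / (1.0 + np.exp(-(X @ params)))
            w = p * (1 - p)
            info = (X.T * w) @ X
            se = np.sqrt(np.diag(np.linalg.pinv(info)))
            converged = True
        row |= dict(zip(names, params))
        row |= {f"se_{n}": v for n, v in zip(names, se)}
        row |= {"converged": converged, "separation": separation}
        rows.append(row)
    return pd.DataFrame(rows)


def uncertainty_estimation_accuracy(confidence: pd.DataFrame) -> pd.DataFrame:
    """Per-subject slope of z-scored, sign-flipped confidence on EE.

    A positive slope means ratings track objective uncertainty (higher EE,
    lower confidence).  Requires at least three rating pairs with EE
    variance; zero EE variance is an error.
    """
    rows = []
    for subject_id, df in confidence.groupby("subject_id", sort=True):
        ee_vals = df["ee"].to_numpy(float)
        conf = df["confidence"].to_numpy(float)
        if len(df) < 3:
            raise ValueError(f"{subject_id}: need >= 3 (EE, confidence) pairs")
        if ee_vals.std() == 0:
            raise ValueError(f"{subject_id}: EE variance is zero")
        y = _zscore(-conf)
        slope, intercept = np.polyfit(ee_vals, y, 1)
        pred = slope * ee_vals + intercept
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        row = {"subject_id": subject_id, "slope": float(slope), "r2": r2}
        if "group" in df.columns:
            row["group"] = df["group"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def trajectories_from_table(sampling: pd.DataFrame) -> dict[str, list[SamplingTrajectory]]:
    """Rebuild per-subject trajectories from the long sampling table."""
    out: dict[str, list[SamplingTrajectory]] = {}
    for (subject_id, trial_id), df in sampling.groupby(
        ["subject_id", "trial_id"], sort=True
    ):
        df = df.sort_values("sample_index")
        obs = [
            SampleObservation(
                float(r.x), float(r.y), str(r.label), float(r.timestamp)
            )
            for r in df.itertuples()
            if r.sample_index > 0
        ]
        first = df.iloc[0]
        traj = SamplingTrajectory(
            trial_id=int(trial_id),
            reserve_level=str(first["reserve_level"]),
            cost_level=str(first["cost_level"]),
            samples=obs,
            ee_per_sample=df["ee_after"].tolist(),
            placement=(float(first["placement_x"]), float(first["placement_y"])),
            placement_error=float(first["placement_error"]),
            subject_id=str(subject_id),
        )
        out.setdefault(str(subject_id), []).append(traj)
    return out


def oversampling_metrics(
    sampling: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deviation from optimal sampling per subject and condition cell.

    Per trial, the realized EE-over-samples curve is converted to an
    expected-value curve under that trial's economy and maximized to get the
    optimal count s*; deviation is samples_taken - s*.  Because EV is
    evaluated on the trial's own sampling dynamics, the metric quantifies
    oversampling (stopping past the EV peak); a trial stopped while EV was
    still rising scores zero rather than a negative deviation.  Returns
    (per-cell table, index table) where the cost-sensitivity index is the
    drop in mean samples from the low- to the high-cost condition at high
    reward reserve.
    """
    cell_rows = []
    for subject_id, group in sampling.groupby("subject_id", sort=True):
        trajs = trajectories_from_table(group)[str(subject_id)]
        econ_by_trial = {
            int(r.trial_id): TrialEconomics(
                initial_reserve=float(r.reserve),
                sampling_cost=float(r.sampling_cost),
            )
            for r in group.drop_duplicates("trial_id").itertuples()
        }
        per_cell: dict[tuple[str, str], list[int]] = {}
        n_by_cell: dict[tuple[str, str], list[int]] = {}
        for traj in trajs:
            ev = expected_value_curve(
                econ_by_trial[traj.trial_id], traj.ee_per_sample
            )
            s_star = optimal_samples(ev)
            dev = deviation_from_optimal(traj.n_samples, s_star)
            key = (traj.reserve_level, traj.cost_level)
            per_cell.setdefault(key, []).append(dev)
            n_by_cell.setdefault(key, []).append(traj.n_samples)
        grp = group["group"].iloc[0] if "group" in group.columns else ""
        for (rl, cl), devs in sorted(per_cell.items()):
            cell_rows.append(
                {
                    "subject_id": subject_id,
                    "group": grp,
                    "reserve_level": rl,
                    "cost_level": cl,
                    "mean_deviation": float(np.mean(devs)),
                    "mean_samples": float(np.mean(n_by_cell[(rl, cl)])),
                    "n_trials": len(devs),
                }
            )
    cells = pd.DataFrame(cell_rows)
    idx_rows = []
    for subject_id, df in cells.groupby("subject_id", sort=True):
        high = df[df["reserve_level"] == "high"]
        low_cost = high[high["cost_level"] == "low"]["mean_samples"]
        high_cost = high[high["cost_level"] == "high"]["mean_samples"]
        index = (
            float(low_cost.iloc[0] - high_cost.iloc[0])
            if len(low_cost) and len(high_cost)
            else np.nan
        )
        idx_rows.append(
            {
                "subject_id": subject_id,
                "group": df["group"].iloc[0],
                "cost_sensitivity_index": index,
            }
        )
    return cells, pd.DataFrame(idx_rows)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference."""
    na, nb = len(a), len(b)
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / sp) if sp > 0 else np.nan


def cliffs_delta(a: np.ndarray, b: np.ndarray) -> float:
    """P(a > b) - P(a < b) over all cross-group pairs; in [-1, 1]."""
    diff = a[:, None] - b[None, :]
    return float((np.sign(diff)).mean())


def group_contrast(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    metric: str = "metric",
    normality_alpha: float = 0.05,
) -> GroupContrast:
    """Two-group contrast with a Shapiro-Wilk parametric/non-parametric gate.

    If both groups pass Shapiro-Wilk at ``normality_alpha`` (and have
    non-degenerate variance), an independent two-sided t-test with Cohen's d
    is used; otherwise a Wilcoxon rank-sum test with Cliff's delta.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group")
    degenerate = a.std() == 0 or b.std() == 0
    parametric = False
    if not degenerate and len(a) >= 3 and len(b) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pa = stats.shapiro(a).pvalue
            pb = stats.shapiro(b).pvalue
        parametric = pa > normality_alpha and pb > normality_alpha
    if parametric:
        res = stats.ttest_ind(a, b)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
        effect = cohens_d(a, b)
    else:
        if np.array_equal(np.sort(a), np.sort(b)):
            test, stat, p = "ranksum", 0.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test, stat, p = "ranksum", float(res.statistic), float(res.pvalue)
        effect = cliffs_delta(a, b)
    return GroupContrast(
        metric=metric,
        group_names=(str(names[0]), str(names[1])),
        means=(float(a.mean()), float(b.mean())),
        medians=(float(np.median(a)), float(np.median(b))),
        test=test,
        statistic=stat,
        p_value=p,
        effect_size=effect,
    )


def icv_adjust(
    volumes: pd.DataFrame,
    reference_slope: float | None = None,
    reference_mean_icv: float | None = None,
) -> pd.DataFrame:
    """Head-size adjustment: V_adj = V - beta * (ICV - mean ICV).

    ``reference_slope`` and ``reference_mean_icv`` come from a designated
    reference sample; when omitted they are estimated by OLS of volume on
    ICV over the supplied rows (treated as the reference controls).
    """
    v = volumes["volume"].to_numpy(float)
    icv = volumes["icv"].to_numpy(float)
    if np.any(v <= 0) or np.any(icv <= 0):
        raise ValueError("volumes and ICV must be positive")
    if reference_slope is None or reference_mean_icv is None:
        slope = float(np.polyfit(icv, v, 1)[0])
        mean_icv = float(icv.mean())
    else:
        slope, mean_icv = float(reference_slope), float(reference_mean_icv)
    out = volumes.copy()
    out["adjusted_volume"] = v - slope * (icv - mean_icv)
    return out


def volume_sensitivity_regression(
    volumes: np.ndarray,
    sensitivities: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Robust regression of sensitivity on (adjusted) volume.

    Iteratively reweighted least squares with Tukey bisquare weights
    (tuning constant 4.685), optional covariates.  Reports the volume slope
    with a 95% CI and an R-squared computed from the robust fit.
    """
    volumes = np.asarray(volumes, dtype=float)
    sensitivities = np.asarray(sensitivities, dtype=float)
    if len(volumes) < 5:
        raise ValueError("need >= 5 paired observations")
    X = np.column_stack([np.ones_like(volumes), volumes])
    names = ["intercept", "volume"]
    if covariates is not None:
        X = np.column_stack([X, covariates.to_numpy(float)])
        names += list(covariates.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    model = sm.RLM(sensitivities, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    fit = model.fit()
    pred = fit.fittedvalues
    ss_res = float(((sensitivities - pred) ** 2).sum())
    ss_tot = float(((sensitivities - sensitivities.mean()) ** 2).sum())
    ci = fit.conf_int(alpha=ALPHA_LEVEL)
    i_vol = names.index("volume")
    return {
        "slope": float(fit.params[i_vol]),
        "slope_se": float(fit.bse[i_vol]),
        "slope_ci": (float(ci[i_vol, 0]), float(ci[i_vol, 1])),
        "intercept": float(fit.params[0]),
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        "params": dict(zip(names, map(float, fit.params))),
        "n": int(len(volumes)),
    }
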