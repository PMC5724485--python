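"""Standardized effect trajectories and the area-between-curves summary.

Per-occasion treatment coefficients are divided by the pooled within-group
standard deviation of the (transformed) observed outcome at that occasion
(pooling arm cells, and sd-stratum cells when configured, by degrees of
freedom), anchored at the baseline occasion with d = 0 by randomization.
The trapezium-rule area over follow-up time is a linear combination of the
d's, tested by a Wald z using the joint coefficient covariance with the
scaling SDs treated as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from trajarea.occasions import OccasionSpec
from trajarea.dataset import TrialDataset, timed_columns
from trajarea.sur import FittedSUR, SurProblem, _fit_problem, build_problem


@dataclass
class EffectTrajectory:
    """Per-occasion standardized effects, anchored at baseline with d = 0."""

    times: np.ndarray          # all vertices, anchor first
    d: np.ndarray
    se: np.ndarray             # 0 at the anchor
    sd_within: np.ndarray      # NaN at the anchor
    beta: np.ndarray           # NaN at the anchor
    cov_d: np.ndarray          # covariance of the non-anchor d's
    anchor_time: float
    negative_is_benefit: bool = True

    def __post_init__(self):
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("occasions must be sorted by strictly increasing time")
        if self.times[0] != self.anchor_time:
            raise ValueError("baseline anchor must be the earliest occasion")

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "d": self.d.tolist(),
            "se": self.se.tolist(),
            "sd_within": self.sd_within.tolist(),
            "beta": self.beta.tolist(),
            "cov_d": self.cov_d.tolist(),
            "anchor_time": self.anchor_time,
            "negative_is_benefit": self.negative_is_benefit,
        }


@dataclass
class AreaResult:
    """Trapezium area of the effect trajectory with Wald test."""

    area: float                # ES x months
    span: float                # months
    averaged_es: float         # area / span
    se_area: float
    z: float
    p: float
    weights: np.ndarray        # trapezium weight per vertex (sums to span)
    times: np.ndarray
    d: np.ndarray
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "area": self.area,
            "span": self.span,
            "averaged_es": self.averaged_es,
            "se_area": self.se_area,
            "z": self.z,
            "p": self.p,
            "weights": self.weights.tolist(),
            "times": self.times.tolist(),
            "d": self.d.tolist(),
            "converged": self.converged,
        }


def pooled_within_sd(values: np.ndarray, arm: np.ndarray, stratum=None) -> float:
    """Pooled within-cell SD: cells are arms (crossed with sd-stratum if given),
    pooled by degrees of freedom; cells with fewer than 2 observations are
    skipped."""
    obs = ~np.isnan(values)
    if stratum is not None:
        obs &= ~np.isnan(stratum)
    cells = arm[obs] if stratum is None else arm[obs] * 1000 + stratum[obs]
    vals = values[obs]
    ss = 0.0
    df = 0
    for c in np.unique(cells):
        v = vals[cells == c]
        if v.size >= 2:
            ss += (v.size - 1) * v.var(ddof=1)
            df += v.size - 1
    if df == 0:
        raise ValueError("no cell has >= 2 observations; within-group SD undefined")
    return float(np.sqrt(ss / df))


def _infer_anchor(specs, fallback_times) -> float:
    for spec in specs:
        if spec.baseline_column:
            timed = timed_columns([spec.baseline_column])
            if spec.baseline_column in timed:
                return float(timed[spec.baseline_column][1])
    # no parsable baseline: anchor one median gap before the first occasion
    times = np.sort(np.asarray(fallback_times, dtype=float))
    gap = np.median(np.diff(times)) if times.size > 1 else 1.0
    return float(times[0] - gap)


def standardize(fit: FittedSUR, dataset: TrialDataset | None = None, specs=None,
                anchor_time: float | None = None) -> EffectTrajectory:
    """Convert fitted treatment coefficients into a Cohen's-d trajectory.

    ``dataset``/``specs`` are only needed when the fit does not carry its
    source problem (e.g. a deserialized fit).  The anchor defaults to the
    occasion of the earliest baseline covariate named in the specs.
    """
    problem = fit.problem
    if problem is None:
        if dataset is None or specs is None:
            raise ValueError("fit carries no source data; pass dataset and specs")
        specs = [s if isinstance(s, OccasionSpec) else OccasionSpec.from_dict(s) for s in specs]
        problem = build_problem(dataset, specs)
    if not fit.converged:
        raise ValueError("cannot standardize a non-converged fit")
    if anchor_time is None and specs is not None:
        specs = [s if isinstance(s, OccasionSpec) else OccasionSpec.from_dict(s) for s in specs]
        anchor_time = _infer_anchor(specs, fit.times)
    return _standardize_problem(fit, problem, anchor_time)


def _standardize_problem(fit: FittedSUR, problem: SurProblem,
                         anchor_time: float | None) -> EffectTrajectory:
    if anchor_time is None and problem.baseline_times:
        known = [t for t in problem.baseline_times if t is not None]
        if known:
            anchor_time = float(min(known))
    K = problem.n_equations
    sw = np.empty(K)
    for k in range(K):
        s = pooled_within_sd(problem.y[:, k], problem.arm, problem.strata[k])
        if s <= 0:
            raise ValueError(
                f"zero within-group SD at occasion {problem.labels[k]!r}; cannot standardize"
            )
        sw[k] = s
    beta_t = fit.treatment_effects
    cov_t = fit.treatment_cov
    d = beta_t / sw
    se = np.sqrt(np.diag(cov_t)) / sw
    cov_d = cov_t / np.outer(sw, sw)
    if anchor_time is None:
        anchor_time = _infer_anchor([], fit.times)
    order = np.argsort(fit.times)
    return EffectTrajectory(
        times=np.concatenate([[anchor_time], fit.times[order]]),
        d=np.concatenate([[0.0], d[order]]),
        se=np.concatenate([[0.0], se[order]]),
        sd_within=np.concatenate([[np.nan], sw[order]]),
        beta=np.concatenate([[np.nan], beta_t[order]]),
        cov_d=cov_d[np.ix_(order, order)],
        anchor_time=float(anchor_time),
    )


def trapezium_weights(times: np.ndarray) -> np.ndarray:
    """Vertex weights w such that sum(w * d) is the trapezium-rule area;
    they sum to the time span."""
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 time points including the anchor")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    w = np.zeros_like(t)
    w[0] = (t[1] - t[0]) / 2
    w[-1] = (t[-1] - t[-2]) / 2
    w[1:-1] = (t[2:] - t[:-2]) / 2
    return w


def area_between_curves(traj: EffectTrajectory, fit: FittedSUR | None = None) -> AreaResult:
    """Combine the d trajectory into a trapezium area with a Wald z test.

    Variance treats the scaling SDs as fixed: Var(area) = w' Cov(d) w over
    the non-anchor vertices (the anchor is a constant 0).
    """
    w = trapezium_weights(traj.times)
    area = float(w @ traj.d)
    span = float(traj.times[-1] - traj.times[0])
    wf = w[1:]  # non-anchor weights
    var = float(wf @ traj.cov_d @ wf)
    if not np.isfinite(var) or var < 0:
        raise ValueError("singular or invalid covariance of the effect estimates")
    se = float(np.sqrt(var))
    if se == 0:
        raise ValueError("degenerate (zero-variance) area estimate")
    z = area / se
    p = float(2 * stats.norm.sf(abs(z)))
    return AreaResult(
        area=area,
        span=span,
        averaged_es=area / span,
        se_area=se,
        z=float(z),
        p=p,
        weights=w,
        times=traj.times.copy(),
        d=traj.d.copy(),
    )


def leave_one_out_areas(dataset: TrialDataset, specs, anchor_time: float | None = None):
    """Refit the full pipeline omitting each participant in turn.

    Returns (records, max_abs_deviation): one record per omitted participant
    holding the participant id and that reduced-data AreaResult (or the
    failure reason); non-convergence is recorded, not fatal.
    """
    specs = [s if isinstance(s, OccasionSpec) else OccasionSpec.from_dict(s) for s in specs]
    problem = build_problem(dataset, specs)
    if anchor_time is None:
        anchor_time = _infer_anchor(specs, problem.times)
    full_fit = _fit_problem(problem)
    full_area = area_between_curves(_standardize_problem(full_fit, problem, anchor_time))
    records = []
    deviations = []
    all_rows = np.arange(problem.n)
    for i in range(problem.n):
        sub = problem.subset(all_rows[all_rows != i])
        rec = {"participant_id": str(problem.participant_ids[i])}
        try:
            fit_i = _fit_problem(sub)
            if not fit_i.converged:
                rec["error"] = "fit did not converge"
            else:
                res = area_between_curves(_standardize_problem(fit_i, sub, anchor_time))
                rec["area"] = res
                deviations.append(abs(res.area - full_area.area))
        except (ValueError, np.linalg.LinAlgError) as exc:
            rec["error"] = str(exc)
        records.append(rec)
    max_dev = float(max(deviations)) if deviations else float("nan")
    return records, max_dev
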