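"""Bootstrap confidence intervals for area effect sizes.

Participants are resampled with replacement, stratified within arm so every
replicate keeps the trial's allocation, and the full pipeline (joint fit,
standardization, trapezium area) is re-run per replicate.  Intervals are
percentile intervals whose endpoints are exact order statistics of the
converged replicate areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from trajarea.dataset import TrialDataset
from trajarea.occasions import OccasionSpec
from trajarea.sur import _fit_problem, build_problem
from trajarea.effects import AreaResult, _infer_anchor, _standardize_problem, area_between_curves


class BootstrapFailure(RuntimeError):
    """Raised when too many replicates fail to converge."""


@dataclass
class BootstrapResult:
    n_requested: int
    n_converged: int
    values: np.ndarray          # replicate areas (converged only)
    averaged_values: np.ndarray  # replicate areas / span
    ci_area: tuple
    ci_averaged: tuple
    level: float
    seed: int | None
    point: AreaResult

    def to_dict(self) -> dict:
        return {
            "n_requested": self.n_requested,
            "n_converged": self.n_converged,
            "ci_area": list(self.ci_area),
            "ci_averaged": list(self.ci_averaged),
            "level": self.level,
            "seed": self.seed,
            "point_area": self.point.area,
            "point_averaged_es": self.point.averaged_es,
        }


def percentile_ci(values: np.ndarray, level: float) -> tuple:
    """Percentile interval with order-statistic endpoints (ranks clamped to [1, m])."""
    v = np.sort(np.asarray(values, dtype=float))
    m = v.size
    alpha = 1 - level
    lo_rank = int(np.floor(alpha / 2 * (m + 1)))
    hi_rank = int(np.ceil((1 - alpha / 2) * (m + 1)))
    lo_rank = min(max(lo_rank, 1), m)
    hi_rank = min(max(hi_rank, 1), m)
    return float(v[lo_rank - 1]), float(v[hi_rank - 1])


def bootstrap_area(dataset: TrialDataset, specs, B: int = 1000, level: float = 0.95,
                   seed: int | None = None, anchor_time: float | None = None,
                   force: bool = False, max_failure_frac: float = 0.2) -> BootstrapResult:
    """Bootstrap the area effect size by resampling participants within arm.

    Deterministic for a fixed ``seed``.  Replicates whose joint fit fails to
    converge are dropped and counted; more than ``max_failure_frac`` failures
    raises :class:`BootstrapFailure` unless ``force``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    specs = [s if isinstance(s, OccasionSpec) else OccasionSpec.from_dict(s) for s in specs]
    problem = build_problem(dataset, specs)
    if anchor_time is None:
        anchor_time = _infer_anchor(specs, problem.times)
    fit = _fit_problem(problem)
    point = area_between_curves(_standardize_problem(fit, problem, anchor_time))

    rng = np.random.default_rng(seed)
    arm_groups = [np.nonzero(problem.arm == v)[0] for v in np.unique(problem.arm)]
    areas = []
    n_failed = 0
    for _ in range(B):
        rows = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in arm_groups])
        sub = problem.subset(rows)
        try:
            fit_b = _fit_problem(sub, init=(fit.beta, fit.resid_cov))
            if not fit_b.converged:
                n_failed += 1
                continue
            res = area_between_curves(_standardize_problem(fit_b, sub, anchor_time))
            areas.append(res.area)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > max_failure_frac * B:
        msg = f"{n_failed}/{B} bootstrap replicates failed to converge"
        if not force:
            raise BootstrapFailure(msg + " (pass force=True to accept)")
        warnings.warn(msg, stacklevel=2)
    if not areas:
        raise BootstrapFailure("no bootstrap replicate converged")

    areas = np.asarray(areas)
    averaged = areas / point.span
    return BootstrapResult(
        n_requested=B,
        n_converged=int(areas.size),
        values=areas,
        averaged_values=averaged,
        ci_area=percentile_ci(areas, level),
        ci_averaged=percentile_ci(averaged, level),
        level=level,
        seed=seed,
        point=point,
    )
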