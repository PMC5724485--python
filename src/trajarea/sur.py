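"""Joint ML estimation of occasion-specific regressions with correlated errors.

Each participant contributes the marginal multivariate-normal density of
their observed outcome components given covariates (full-information ML),
so incomplete records are retained.  Estimation alternates an exact GLS
update of the coefficients given the residual covariance with an EM update
of the residual covariance given the coefficients; both steps increase the
observed-data likelihood, so the path is monotone.

The joint coefficient covariance is the inverse GLS information evaluated
at a degrees-of-freedom-adjusted residual covariance (per-equation factor
n_k / (n_k - p_k)), a small-sample correction for the downward bias of the
ML residual covariance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trajarea.dataset import TrialDataset, timed_columns
from trajarea.occasions import OccasionSpec
from trajarea.transforms import apply_transform

logger = logging.getLogger(__name__)

TREATMENT_NAME = "treatment"


class DesignError(ValueError):
    """Invalid or degenerate design (missing equations, collinearity, ...)."""


@dataclass
class SurProblem:
    """Numeric arrays extracted once from a dataset + occasion specs.

    Row-subsettable so bootstrap and leave-one-out refits avoid re-parsing
    the dataset.
    """

    y: np.ndarray                 # (n, K) transformed outcomes, NaN = missing
    X: list                       # K design matrices (n, p_k)
    coef_names: list              # K lists of coefficient names
    treat_pos: list               # index of the treatment coefficient per equation
    labels: list
    times: np.ndarray
    arm: np.ndarray               # (n,) 0/1 treatment indicator
    strata: list                  # K arrays (n,) of sd-stratum codes, or None
    participant_ids: np.ndarray
    baseline_times: list = None
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_equations(self) -> int:
        return self.y.shape[1]

    def subset(self, rows) -> "SurProblem":
        rows = np.asarray(rows)
        return SurProblem(
            y=self.y[rows],
            X=[x[rows] for x in self.X],
            coef_names=self.coef_names,
            treat_pos=self.treat_pos,
            labels=self.labels,
            times=self.times,
            arm=self.arm[rows],
            strata=[s[rows] if s is not None else None for s in self.strata],
            participant_ids=self.participant_ids[rows],
            baseline_times=self.baseline_times,
            n_dropped=self.n_dropped,
        )


@dataclass
class FittedSUR:
    """Joint fit: stacked coefficients, their covariance, residual covariance."""

    beta: np.ndarray              # stacked coefficient vector
    param_cov: np.ndarray         # joint covariance of beta (df-adjusted)
    param_names: list             # "<label>:<coef>" per stacked entry
    slices: list                  # per-equation slice into beta
    treat_indices: np.ndarray     # stacked position of each treatment coefficient
    resid_cov: np.ndarray         # Sigma across equations (ML)
    loglik: float
    loglik_path: list
    n_per_equation: np.ndarray
    labels: list
    coef_names: list
    times: np.ndarray
    converged: bool
    n_iter: int
    problem: SurProblem = field(repr=False, default=None)

    @property
    def treatment_effects(self) -> np.ndarray:
        return self.beta[self.treat_indices]

    @property
    def treatment_cov(self) -> np.ndarray:
        return self.param_cov[np.ix_(self.treat_indices, self.treat_indices)]

    @property
    def resid_corr(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.resid_cov))
        return self.resid_cov / np.outer(d, d)

    def coefficients(self, label: str) -> pd.Series:
        k = self.labels.index(label)
        return pd.Series(self.beta[self.slices[k]], index=self.coef_names[k])

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "times": self.times.tolist(),
            "coefficients": {lab: self.coefficients(lab).to_dict() for lab in self.labels},
            "param_names": list(self.param_names),
            "beta": self.beta.tolist(),
            "param_cov": self.param_cov.tolist(),
            "treat_indices": self.treat_indices.tolist(),
            "resid_cov": self.resid_cov.tolist(),
            "loglik": self.loglik,
            "n_per_equation": self.n_per_equation.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def _encode_column(df: pd.DataFrame, col: str):
    """Return (matrix, names) encoding one covariate column numerically."""
    s = df[col]
    if s.dtype.kind in "ifub":
        return s.to_numpy(dtype=float)[:, None], [col]
    levels = sorted(s.dropna().unique())
    if len(levels) < 2:
        raise DesignError(f"covariate {col!r} is constant")
    mats, names = [], []
    for lev in levels[1:]:
        mats.append((s == lev).to_numpy(dtype=float)[:, None])
        names.append(f"{col}[{lev}]")
    return np.hstack(mats), names


def build_problem(dataset: TrialDataset, specs) -> SurProblem:
    """Extract outcomes, designs and grouping arrays for a list of occasions.

    Participants missing any adjustment covariate are dropped with a warning;
    a missing baseline-measure value marks only that equation's outcome as
    missing, preserving the participant's other records.
    """
    if len(specs) == 0:
        raise DesignError("at least one occasion spec is required")
    df = dataset.df
    for spec in specs:
        for col in (spec.outcome_column, spec.treatment_column, *(spec.covariate_columns or ()),
                    *( (spec.baseline_column,) if spec.baseline_column else () ),
                    *( (spec.sd_stratum_column,) if spec.sd_stratum_column else () )):
            if col not in df.columns:
                raise DesignError(f"occasion {spec.label!r}: column {col!r} not in dataset")

    cov_cols = sorted({c for spec in specs for c in spec.covariate_columns})
    cov_ok = ~df[cov_cols].isna().any(axis=1) if cov_cols else pd.Series(True, index=df.index)
    n_dropped = int((~cov_ok).sum())
    if n_dropped:
        dropped = df.loc[~cov_ok, "participant_id"].tolist()
        logger.warning("dropping %d participant(s) with missing covariates: %s", n_dropped, dropped)
        warnings.warn(f"dropping {n_dropped} participant(s) with missing covariates", stacklevel=2)
    df = df.loc[cov_ok].reset_index(drop=True)

    treat_col = specs[0].treatment_column
    tvals = df[treat_col]
    if tvals.dtype.kind in "if":
        arm = tvals.to_numpy(dtype=float)
    else:
        arm = (tvals == "intervention").to_numpy(dtype=float)

    y_cols, X_list, names_list, treat_pos, strata = [], [], [], [], []
    for spec in specs:
        y = apply_transform(df[spec.outcome_column], spec.transform)
        blocks = [np.ones((len(df), 1)), arm[:, None]]
        names = ["intercept", TREATMENT_NAME]
        if spec.baseline_column:
            base = df[spec.baseline_column].to_numpy(dtype=float)
            y = np.where(np.isnan(base), np.nan, y)  # baseline-incomplete: drop from this equation
            base = np.where(np.isnan(base), np.nanmean(base), base)
            blocks.append(base[:, None])
            names.append(spec.baseline_column)
        for col in spec.covariate_columns:
            mat, nm = _encode_column(df, col)
            blocks.append(mat)
            names.extend(nm)
        X = np.hstack(blocks)
        obs = ~np.isnan(y)
        if obs.sum() == 0:
            raise DesignError(f"occasion {spec.label!r}: all outcomes missing")
        if obs.sum() <= X.shape[1]:
            raise DesignError(
                f"occasion {spec.label!r}: {int(obs.sum())} observed outcomes for "
                f"{X.shape[1]} predictors"
            )
        _check_collinear(X[obs], names, spec.label)
        y_cols.append(y)
        X_list.append(X)
        names_list.append(names)
        treat_pos.append(1)
        if spec.sd_stratum_column:
            svals = df[spec.sd_stratum_column]
            codes = pd.factorize(svals, use_na_sentinel=True)[0].astype(float)
            codes[codes < 0] = np.nan
            strata.append(codes)
        else:
            strata.append(None)

    baseline_times = []
    for spec in specs:
        bt = None
        if spec.baseline_column:
            timed = timed_columns([spec.baseline_column])
            if spec.baseline_column in timed:
                bt = float(timed[spec.baseline_column][1])
        baseline_times.append(bt)
    return SurProblem(
        y=np.column_stack(y_cols),
        X=X_list,
        coef_names=names_list,
        treat_pos=treat_pos,
        labels=[s.label for s in specs],
        times=np.array([float(s.time) for s in specs]),
        arm=arm,
        strata=strata,
        participant_ids=df["participant_id"].to_numpy(),
        baseline_times=baseline_times,
        n_dropped=n_dropped,
    )


def _check_collinear(X: np.ndarray, names, label: str) -> None:
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < 1e-10 * max(s[0], 1.0):
        _, _, vt = np.linalg.svd(X)
        involved = [names[j] for j in np.nonzero(np.abs(vt[-1]) > 1e-6)[0]]
        raise DesignError(f"occasion {label!r}: collinear design columns {involved}")


def _patterns(mask: np.ndarray):
    """Group rows by missingness pattern; yields (obs_indices, row_indices)."""
    pat, inverse = np.unique(mask, axis=0, return_inverse=True)
    out = []
    for p in range(pat.shape[0]):
        obs = np.nonzero(pat[p])[0]
        if obs.size:
            out.append((obs, np.nonzero(inverse == p)[0]))
    return out


def _gls_system(problem: SurProblem, sigma: np.ndarray, patterns):
    """Stacked normal equations A beta = b for the observed-data likelihood."""
    sizes = [x.shape[1] for x in problem.X]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    P = offsets[-1]
    A = np.zeros((P, P))
    b = np.zeros(P)
    for obs, rows in patterns:
        W = np.linalg.inv(sigma[np.ix_(obs, obs)])
        Xs = [problem.X[k][rows] for k in obs]
        ys = [problem.y[rows, k] for k in obs]
        for a, k in enumerate(obs):
            sk = slice(offsets[k], offsets[k + 1])
            for c, l in enumerate(obs):
                sl = slice(offsets[l], offsets[l + 1])
                A[sk, sl] += W[a, c] * (Xs[a].T @ Xs[c])
                b[sk] += W[a, c] * (Xs[a].T @ ys[c])
    return A, b, offsets


def _residuals(problem: SurProblem, beta: np.ndarray, offsets) -> np.ndarray:
    mu = np.column_stack(
        [problem.X[k] @ beta[offsets[k]:offsets[k + 1]] for k in range(problem.n_equations)]
    )
    return problem.y - mu


def observed_loglik(problem: SurProblem, beta: np.ndarray, sigma: np.ndarray,
                    offsets=None, patterns=None) -> float:
    """Observed-data log-likelihood by direct summation over participants."""
    if offsets is None:
        sizes = [x.shape[1] for x in problem.X]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
    if patterns is None:
        patterns = _patterns(~np.isnan(problem.y))
    resid = _residuals(problem, beta, offsets)
    ll = 0.0
    for obs, rows in patterns:
        sub = sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(sub)
        if sign <= 0:
            return -np.inf
        r = resid[np.ix_(rows, obs)]
        quad = np.einsum("ij,ij->i", r @ np.linalg.inv(sub), r)
        ll += -0.5 * (rows.size * (obs.size * np.log(2 * np.pi) + logdet) + quad.sum())
    return float(ll)


def _fit_problem(problem: SurProblem, tol: float = 1e-8, max_iter: int = 500,
                 ddof_adjust: bool = True, init=None) -> FittedSUR:
    n, K = problem.y.shape
    mask = ~np.isnan(problem.y)
    n_per_eq = mask.sum(axis=0)
    if (n_per_eq == 0).any():
        bad = [problem.labels[k] for k in np.nonzero(n_per_eq == 0)[0]]
        raise DesignError(f"equations with all outcomes missing: {bad}")
    for k in range(K):
        vals = problem.y[mask[:, k], k]
        if vals.size >= 2 and vals.var() <= 1e-24:
            raise DesignError(
                f"outcome at occasion {problem.labels[k]!r} has zero variance"
            )
    patterns = _patterns(mask)
    sizes = [x.shape[1] for x in problem.X]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    P = int(offsets[-1])
    eq_slices = [slice(int(offsets[k]), int(offsets[k + 1])) for k in range(K)]

    # per-pattern caches: designs, outcomes and Gram blocks are iteration-invariant
    cache = []
    for obs, rows in patterns:
        Xs = [problem.X[k][rows] for k in obs]
        ys = problem.y[np.ix_(rows, obs)]
        m = len(obs)
        G = [[Xs[a].T @ Xs[c] for c in range(m)] for a in range(m)]
        Hy = [[Xs[a].T @ ys[:, c] for c in range(m)] for a in range(m)]
        mis = np.array([k for k in range(K) if k not in set(obs.tolist())], dtype=int)
        cache.append((obs, mis, rows, Xs, ys, G, Hy))

    if init is not None:
        beta = np.array(init[0], dtype=float)
        sigma = np.array(init[1], dtype=float)
    else:
        # start from equation-wise OLS on each equation's observed rows
        beta = np.zeros(P)
        resid0 = np.full((n, K), np.nan)
        for k in range(K):
            rows_k = mask[:, k]
            coef, *_ = np.linalg.lstsq(problem.X[k][rows_k], problem.y[rows_k, k], rcond=None)
            beta[eq_slices[k]] = coef
            resid0[rows_k, k] = problem.y[rows_k, k] - problem.X[k][rows_k] @ coef
        sigma = pd.DataFrame(resid0).cov(min_periods=2).to_numpy()
        diag = np.nanvar(resid0, axis=0, ddof=1)
        bad = ~np.isfinite(np.diag(sigma))
        sigma[~np.isfinite(sigma)] = 0.0
        sigma[np.diag_indices(K)] = np.where(~bad, np.diag(sigma), diag)
    sigma = _nearest_pd(sigma)

    def _factors(sig):
        out = []
        for obs, *_ in cache:
            sub = sig[np.ix_(obs, obs)]
            sign, logdet = np.linalg.slogdet(sub)
            if sign <= 0:
                return None
            out.append((np.linalg.inv(sub), logdet))
        return out

    fac = _factors(sigma)
    if fac is None:
        sigma = _nearest_pd(sigma)
        fac = _factors(sigma)

    log2pi = np.log(2 * np.pi)
    ll_path = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # exact GLS maximization over beta given sigma
        A = np.zeros((P, P))
        b = np.zeros(P)
        for (obs, mis, rows, Xs, ys, G, Hy), (W, _) in zip(cache, fac):
            for a, k in enumerate(obs):
                sk = eq_slices[k]
                for c, l in enumerate(obs):
                    A[sk, eq_slices[l]] += W[a, c] * G[a][c]
                    b[sk] += W[a, c] * Hy[a][c]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise DesignError(f"singular joint design: {exc}") from exc

        # EM update of sigma given beta, reusing the same sigma factors
        S = np.zeros((K, K))
        resids = []
        for (obs, mis, rows, Xs, ys, G, Hy), (W, _) in zip(cache, fac):
            r_o = ys - np.column_stack([Xs[a] @ beta[eq_slices[k]] for a, k in enumerate(obs)])
            resids.append(r_o)
            S[np.ix_(obs, obs)] += r_o.T @ r_o
            if mis.size:
                B = sigma[np.ix_(mis, obs)] @ W
                m_hat = r_o @ B.T
                cond = sigma[np.ix_(mis, mis)] - B @ sigma[np.ix_(obs, mis)]
                S[np.ix_(mis, obs)] += m_hat.T @ r_o
                S[np.ix_(obs, mis)] += r_o.T @ m_hat
                S[np.ix_(mis, mis)] += m_hat.T @ m_hat + rows.size * cond
        sigma = (S + S.T) / (2 * n)

        fac_new = _factors(sigma)
        if fac_new is None:
            sigma = _nearest_pd(sigma)
            fac_new = _factors(sigma)
        ll = 0.0
        for (obs, mis, rows, *_), r_o, (W, logdet) in zip(cache, resids, fac_new):
            quad = np.einsum("ij,ij->i", r_o @ W, r_o).sum()
            ll += -0.5 * (rows.size * (obs.size * log2pi + logdet) + quad)
        fac = fac_new
        ll_path.append(ll)
        if np.isfinite(ll) and abs(ll - ll_prev) <= tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll

    if not converged:
        logger.warning("SUR fit did not converge in %d iterations (last ll=%.6g)", it, ll_path[-1])

    sigma_adj = sigma.copy()
    if ddof_adjust:
        d = np.sqrt(n_per_eq / np.maximum(n_per_eq - np.array(sizes), 1))
        sigma_adj = sigma * np.outer(d, d)
    A_adj, _, _ = _gls_system(problem, sigma_adj, patterns)
    param_cov = np.linalg.inv(A_adj)
    param_cov = (param_cov + param_cov.T) / 2

    param_names = [
        f"{problem.labels[k]}:{nm}" for k in range(K) for nm in problem.coef_names[k]
    ]
    treat_idx = np.array([offsets[k] + problem.treat_pos[k] for k in range(K)])
    return FittedSUR(
        beta=beta,
        param_cov=param_cov,
        param_names=param_names,
        slices=eq_slices,
        treat_indices=treat_idx,
        resid_cov=sigma,
        loglik=ll_path[-1],
        loglik_path=ll_path,
        n_per_equation=n_per_eq,
        labels=list(problem.labels),
        coef_names=[list(nm) for nm in problem.coef_names],
        times=problem.times.copy(),
        converged=converged,
        n_iter=it,
        problem=problem,
    )


def _nearest_pd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2)
    vals = np.maximum(vals, floor * max(vals.max(), 1.0))
    return vecs @ np.diag(vals) @ vecs.T


def fit_sur(dataset: TrialDataset, specs, tol: float = 1e-8, max_iter: int = 500,
            ddof_adjust: bool = True) -> FittedSUR:
    """Jointly fit occasion-specific regressions by full-information ML.

    Parameters
    ----------
    dataset
        Wide trial table, one row per participant.
    specs
        List of :class:`OccasionSpec`, one regression per assessment occasion.

    Returns a :class:`FittedSUR`; if the likelihood iteration stalls the fit
    is returned with ``converged=False`` rather than raising.
    """
    specs = [s if isinstance(s, OccasionSpec) else OccasionSpec.from_dict(s) for s in specs]
    problem = build_problem(dataset, specs)
    return _fit_problem(problem, tol=tol, max_iter=max_iter, ddof_adjust=ddof_adjust)
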