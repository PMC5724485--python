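"""Categorical diagnostic-outcome tests and coder-reliability ICCs.

Exact 2xK conditional test by full enumeration of the margin-fixed table
lattice; proportional-odds cumulative-logit regression fit by Newton
iteration with step halving; one-way-random and two-way absolute-agreement
single-measures intraclass correlations from ANOVA mean squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

ENUMERATION_GUARD = 500
TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# exact 2 x K test


def _log_table_prob(row1, col_totals, n1, n_total) -> float:
    # hypergeometric-product probability of a 2xK table given both margins
    lp = -math.lgamma(n_total + 1) + math.lgamma(n1 + 1) + math.lgamma(n_total - n1 + 1)
    for a, c in zip(row1, col_totals):
        lp += math.lgamma(c + 1) - math.lgamma(a + 1) - math.lgamma(c - a + 1)
    return lp


def _first_rows(col_totals, total):
    """All nonnegative first rows bounded by column totals summing to `total`."""
    if len(col_totals) == 1:
        if 0 <= total <= col_totals[0]:
            yield (total,)
        return
    c0 = col_totals[0]
    for a in range(max(0, total - sum(col_totals[1:])), min(c0, total) + 1):
        for rest in _first_rows(col_totals[1:], total - a):
            yield (a, *rest)


def fisher_freeman_halton(table) -> float:
    """Two-sided Freeman–Halton exact p for a 2xK contingency table.

    Enumerates every table with the observed margins and sums the
    hypergeometric-product probabilities of tables no more probable than the
    observed one (tie tolerance 1e-12 on the probability).
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError(f"expected a 2xK table with K >= 2, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be nonnegative integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    n_total = int(t.sum())
    if n_total == 0:
        raise ValueError("table grand total must be positive")
    if n_total > ENUMERATION_GUARD:
        raise ValueError(
            f"grand total {n_total} exceeds the exact-enumeration guard "
            f"({ENUMERATION_GUARD}); a Monte-Carlo mode is not provided"
        )
    col_totals = t.sum(axis=0).tolist()
    n1 = int(t[0].sum())
    p_obs = math.exp(_log_table_prob(t[0].tolist(), col_totals, n1, n_total))
    p = 0.0
    for row1 in _first_rows(col_totals, n1):
        pr = math.exp(_log_table_prob(row1, col_totals, n1, n_total))
        if pr <= p_obs + TIE_TOL:
            p += pr
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# proportional-odds ordinal regression


@dataclass
class ProportionalOddsResult:
    odds_ratio: float
    coef: float
    se: float
    z: float
    p: float
    thresholds: np.ndarray
    loglik: float
    n_iter: int


def proportional_odds(outcomes, arm, flip_indicator: bool = False,
                      tol: float = 1e-10, max_iter: int = 100) -> ProportionalOddsResult:
    """Cumulative-logit proportional-odds regression on a single indicator.

    ``outcomes`` are ordered category codes (or labels orderable by sort);
    ``arm`` is the covariate (1 = no-intervention under the default coding;
    ``flip_indicator`` recodes x -> 1 - x).  Model: P(Y <= j | x) =
    logistic(alpha_j - x * beta); returns exp(beta) with Wald SE and p.
    """
    y = np.asarray(outcomes)
    x = np.asarray(arm, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcomes and arm must have the same length")
    if flip_indicator:
        x = 1.0 - x
    levels, y_codes = np.unique(y, return_inverse=True)
    J = len(levels)
    if J < 2:
        raise ValueError("need at least 2 observed outcome levels")
    if J == 2 and len(np.unique(x)) < 2:
        raise ValueError("arm indicator is constant")

    # start: marginal cumulative log-odds, zero slope
    cum = np.cumsum(np.bincount(y_codes, minlength=J))[:-1] / len(y)
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    theta = np.concatenate([np.log(cum / (1 - cum)), [0.0]])

    def negll_grad_hess(th):
        alpha, beta = th[:-1], th[-1]
        eta = alpha[None, :] - x[:, None] * beta
        gamma = expit(eta)
        full = np.column_stack([np.zeros(len(x)), gamma, np.ones(len(x))])
        probs = np.diff(full, axis=1)
        pi = probs[np.arange(len(x)), y_codes]
        if (pi <= 0).any():
            return np.inf, None, None
        ll = np.log(pi).sum()
        # gradient/hessian by numeric differentiation of the analytic gradient
        # is avoided: use exact first derivative, numeric second
        g = np.zeros_like(th)
        dgam = gamma * (1 - gamma)                   # d gamma_j / d alpha_j
        for j in range(J - 1):
            # d pi_i / d alpha_j: +dgam if y_i == j, -dgam if y_i == j+1
            contrib = np.where(y_codes == j, dgam[:, j], 0.0) - np.where(
                y_codes == j + 1, dgam[:, j], 0.0
            )
            g[j] = (contrib / pi).sum()
        num = np.zeros(len(x))
        for j in range(J - 1):
            num += np.where(y_codes == j, -x * dgam[:, j], 0.0) + np.where(
                y_codes == j + 1, x * dgam[:, j], 0.0
            )
        g[-1] = (num / pi).sum()
        return -ll, -g, None

    def numeric_hessian(th, h=1e-5):
        p = len(th)
        H = np.zeros((p, p))
        for i in range(p):
            tp, tm = th.copy(), th.copy()
            tp[i] += h
            tm[i] -= h
            _, gp, _ = negll_grad_hess(tp)
            _, gm, _ = negll_grad_hess(tm)
            if gp is None or gm is None:
                raise FloatingPointError("hessian evaluation left the domain")
            H[i] = (gp - gm) / (2 * h)
        return (H + H.T) / 2

    nll, g, _ = negll_grad_hess(theta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        H = numeric_hessian(theta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = g / max(np.abs(np.diag(H)).max(), 1.0)
        # step halving to keep the likelihood improving and in-domain
        scale = 1.0
        for _ in range(40):
            cand = theta - scale * step
            nll_new, g_new, _ = negll_grad_hess(cand)
            if np.isfinite(nll_new) and nll_new <= nll + 1e-12:
                break
            scale /= 2
        else:
            raise RuntimeError(
                "proportional-odds Newton iteration failed to improve the likelihood; "
                "data may be completely separated by the arm indicator"
            )
        moved = np.max(np.abs(theta - cand))
        theta, nll, g = cand, nll_new, g_new
        if moved < tol and np.max(np.abs(g)) < 1e-6:
            break
    else:
        raise RuntimeError("proportional-odds fit did not converge")

    if np.abs(theta[-1]) > 15:
        raise RuntimeError(
            "proportional-odds coefficient diverged; complete separation between arms"
        )
    H = numeric_hessian(theta)
    cov = np.linalg.inv(H)
    se = float(np.sqrt(cov[-1, -1]))
    beta = float(theta[-1])
    z = beta / se
    return ProportionalOddsResult(
        odds_ratio=float(np.exp(beta)),
        coef=beta,
        se=se,
        z=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
        thresholds=theta[:-1].copy(),
        loglik=-float(nll),
        n_iter=n_iter,
    )


def expand_counts(table) -> tuple:
    """Expand a 2xK count table into (outcome_codes, arm_indicator) records,
    arm = 1 for the first row."""
    t = np.asarray(table, dtype=int)
    y, x = [], []
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            y.extend([j] * t[i, j])
            x.extend([1 - i] * t[i, j])
    return np.array(y), np.array(x)


# ---------------------------------------------------------------------------
# intraclass correlations


def _anova_mean_squares(r: np.ndarray):
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)            # between subjects
    msw = ((r - row_means[:, None]) ** 2).sum() / (n * (k - 1))     # within subjects
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)            # between raters
    sse = ((r - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return msb, msw, msc, mse


def _check_ratings(ratings) -> np.ndarray:
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix with k >= 2 raters")
    if r.shape[0] < 3:
        raise ValueError("need at least 3 rated subjects")
    if np.isnan(r).any():
        raise ValueError("ratings must have no missing cells")
    if np.allclose(r, r.flat[0]):
        raise ValueError("all ratings identical; ICC undefined")
    return r


def icc_oneway(ratings) -> float:
    """ICC(1,1): one-way random effects, single measures."""
    r = _check_ratings(ratings)
    k = r.shape[1]
    msb, msw, _, _ = _anova_mean_squares(r)
    return float((msb - msw) / (msb + (k - 1) * msw))


def icc_agreement(ratings) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measures."""
    r = _check_ratings(ratings)
    n, k = r.shape
    msb, _, msc, mse = _anova_mean_squares(r)
    return float((msb - mse) / (msb + (k - 1) * mse + (k / n) * (msc - mse)))
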