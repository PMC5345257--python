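"""Grouped binomial logistic likelihood machinery.

Every test in this package reduces to maximum-likelihood fits of
``logit P(case | genotype g) = alpha + sum_k beta_k x_k(g)`` over at most
three covariate patterns (the genotype classes). Fits use Newton-Raphson
with a step-halving safeguard; the implementation is fully vectorised over
replicate tables so Monte-Carlo studies can fit tens of thousands of
tables per call.

The two-slope (additive + dominance-deviation) model is saturated over the
three genotype classes, so its maximised log-likelihood has a closed form;
the closed forms live here too and double as internal cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, xlogy

from .counts import CodingScheme, GenotypeCounts

#: Coefficients are capped at this magnitude (log-odds scale) when the
#: likelihood is monotone (separation); the deviance is numerically stable
#: at the cap even though the MLE is at infinity.
COEF_CAP = 30.0
MAX_ITER = 100
LL_RTOL = 1e-10
_ETA_CLIP = 35.0


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of a grouped logistic model.

    Attributes
    ----------
    coefficients
        Intercept followed by the slope term(s), log-odds scale.
    log_likelihood
        Maximised grouped binomial log-likelihood (<= 0).
    converged
        False when Newton-Raphson hit the iteration limit or a coefficient
        was capped (monotone likelihood / separation).
    standard_errors
        Wald standard errors from the inverse observed information; NaN
        where the information matrix is singular.
    covariance
        Full coefficient covariance matrix (for contrast intervals).
    """

    coefficients: np.ndarray
    log_likelihood: float
    converged: bool
    standard_errors: np.ndarray
    covariance: np.ndarray = field(repr=False, default=None)


def saturated_loglik(y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Closed-form maximised log-likelihood of the saturated model.

    ``y`` cases out of ``n`` observations per covariate pattern, summed over
    the last axis; empty patterns (n = 0) contribute nothing.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    return (xlogy(y, y) + xlogy(n - y, n - y) - xlogy(n, n)).sum(axis=-1)


def null_loglik(y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Maximised log-likelihood of the intercept-only model."""
    Y = np.asarray(y, dtype=float).sum(axis=-1)
    N = np.asarray(n, dtype=float).sum(axis=-1)
    return xlogy(Y, Y) + xlogy(N - Y, N - Y) - xlogy(N, N)


def collapsed_loglik(y: np.ndarray, n: np.ndarray, groups: tuple[tuple[int, ...], ...]) -> np.ndarray:
    """Saturated log-likelihood after merging genotype classes.

    A single-slope model whose covariate takes only two distinct values is
    saturated over the two merged classes, so e.g. the dominant-coded fit
    has this closed form with groups ({AA}, {Aa, aa}).
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    yg = np.stack([y[..., list(g)].sum(axis=-1) for g in groups], axis=-1)
    ng = np.stack([n[..., list(g)].sum(axis=-1) for g in groups], axis=-1)
    return saturated_loglik(yg, ng)


def _batch_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    eta = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    # y*eta - n*log(1+e^eta), stable via log1p on the negative side
    return (y * eta - n * np.logaddexp(0.0, eta)).sum(axis=-1)


def batch_fit(
    y: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    *,
    tol: float = LL_RTOL,
    max_iter: int = MAX_ITER,
    cap: float = COEF_CAP,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit grouped logistic models to a batch of tables by Newton-Raphson.

    Parameters
    ----------
    y, n : arrays of shape (R, G)
        Case counts and totals per covariate pattern for R tables.
    X : array of shape (G, P)
        Design matrix (intercept column included), shared across tables.

    Returns
    -------
    beta : (R, P) fitted coefficients, capped at ``cap`` in magnitude
    loglik : (R,) maximised log-likelihood
    converged : (R,) bool; False on iteration-limit or capped coefficients

    Patterns with ``n == 0`` drop out of the likelihood automatically
    (their score and information contributions are zero).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    X = np.asarray(X, dtype=float)
    R, G = y.shape
    P = X.shape[1]

    beta = np.zeros((R, P))
    Y, N = y.sum(axis=1), n.sum(axis=1)
    with np.errstate(divide="ignore"):
        p0 = np.clip(Y / N, 1e-12, 1 - 1e-12)
    beta[:, 0] = np.log(p0 / (1 - p0))
    ll = _batch_loglik(beta, X, y, n)

    eye = np.eye(P)
    converged = np.zeros(R, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = n * p * (1.0 - p)
        score = np.einsum("rg,gp->rp", y - n * p, X)
        H = np.einsum("rg,gi,gj->rij", w, X, X)
        # ridge keeps the solve defined under separation / empty classes
        ridge = np.maximum(np.trace(H, axis1=1, axis2=2) * 1e-12, 1e-12)
        H = H + ridge[:, None, None] * eye
        step = np.linalg.solve(H, score[..., None])[..., 0]

        new_beta = np.clip(beta + step, -cap, cap)
        new_ll = _batch_loglik(new_beta, X, y, n)
        for _ in range(30):  # step-halving safeguard
            worse = new_ll < ll - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
            new_beta = np.clip(beta + step, -cap, cap)
            new_ll = _batch_loglik(new_beta, X, y, n)

        converged = np.abs(new_ll - ll) <= tol * (np.abs(new_ll) + 1.0)
        beta, ll = new_beta, new_ll
        if converged.all():
            break

    at_cap = (np.abs(beta) >= cap - 1e-9).any(axis=1)
    return beta, ll, converged & ~at_cap


def design_matrix(codings: list[CodingScheme]) -> np.ndarray:
    """Intercept plus one column of genotype codes per coding scheme."""
    cols = [np.ones(3)] + [np.asarray(c.codes, dtype=float) for c in codings]
    return np.column_stack(cols)


def fit_grouped_logistic(
    counts: GenotypeCounts,
    codings: CodingScheme | list[CodingScheme] | str | list[str],
) -> LogisticFit:
    """Maximum-likelihood fit of a grouped logistic model on one 2x3 table.

    ``codings`` supplies one or two slope terms (e.g. ``"additive"`` alone
    for a trend model, or ``["additive", "domdev"]`` for the full two-term
    model, which is saturated over the three genotype classes).

    Genotype classes with zero total observations contribute nothing to the
    likelihood. Under a monotone likelihood (separation) the coefficient is
    capped at +/-30 log-odds and ``converged`` is False; the reported
    log-likelihood is evaluated at the cap.
    """
    if isinstance(codings, (CodingScheme, str)):
        codings = [codings]
    codings = [
        c if isinstance(c, CodingScheme) else CodingScheme.from_name(c)
        for c in codings
    ]
    if not 1 <= len(codings) <= 2:
        raise ValueError("between one and two slope terms are supported")

    y, n = counts.as_arrays()
    X = design_matrix(codings)
    beta, ll, conv = batch_fit(y[None, :], n[None, :], X)
    beta, ll, conv = beta[0], float(ll[0]), bool(conv[0])

    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    p = expit(eta)
    H = (X * (n * p * (1 - p))[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1],) * 2, np.nan)
        se = np.full(X.shape[1], np.nan)
    return LogisticFit(beta, ll, conv, se, cov)


def intercept_only_fit(counts: GenotypeCounts) -> LogisticFit:
    """Null (intercept-only) fit; closed form."""
    y, n = counts.as_arrays()
    Y, N = y.sum(), n.sum()
    p = Y / N
    ll = float(null_loglik(y, n))
    if 0 < p < 1:
        alpha = float(np.log(p / (1 - p)))
        se = float(np.sqrt(1.0 / (N * p * (1 - p))))
        conv = True
    else:
        alpha = np.sign(p - 0.5) * COEF_CAP if N > 0 else 0.0
        se, conv = np.nan, False
    return LogisticFit(
        np.array([alpha]), ll, conv, np.array([se]), np.array([[se**2]])
    )
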