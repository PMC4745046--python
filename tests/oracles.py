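"""Independent oracles used by the test suite.

These re-derive expected values through routes that do not share code with
the package: brute-force numerical quadrature of the Bayesian evidence
integrand, direct Gamma-function arithmetic, exhaustive enumeration, and
ordinary least squares.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats
from scipy.special import gammaln


def nig_log_evidence_quadrature(
    y: np.ndarray,
    X: np.ndarray,
    nu: float,
    sigma2_0: float,
    n_w: int = 81,
    n_s: int = 241,
) -> float:
    """Brute-force log marginal likelihood of the conjugate Gaussian family.

    Integrates  N(y | [1 X] w, s2 I) * N(w | 0, (s2/nu) I)
              * InvGamma(s2 | nu/2, nu*sigma2_0/2)
    over w (Simpson on a per-s2 box) and s2 (Simpson on a log grid).
    The grid placement uses a ridge solve only to center the box; every
    integrand value is evaluated directly.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        return 0.0
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    d = Xd.shape[1]
    a0 = nu / 2.0
    b0 = nu * sigma2_0 / 2.0

    # log-s2 grid spanning far beyond the prior and data scales
    s2_scale = sigma2_0 + float(y @ y) / max(n, 1)
    log_s2 = np.linspace(math.log(s2_scale / 500.0), math.log(s2_scale * 500.0), n_s)
    s2_grid = np.exp(log_s2)

    # box for w: ridge center, generous width
    center = np.linalg.solve(nu * np.eye(d) + Xd.T @ Xd, Xd.T @ y)
    log_vals = np.empty(n_s)
    for si, s2 in enumerate(s2_grid):
        post_cov = s2 * np.linalg.inv(nu * np.eye(d) + Xd.T @ Xd)
        half = 10.0 * math.sqrt(float(np.max(np.diag(post_cov)))) + 1e-6
        axes = [np.linspace(c - half, c + half, n_w) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        W = np.stack([m.ravel() for m in mesh], axis=1)  # (n_w^d, d)
        resid = y[None, :] - W @ Xd.T
        log_lik = -0.5 * n * math.log(2 * math.pi * s2) - (resid**2).sum(
            axis=1
        ) / (2 * s2)
        log_prior_w = (
            -0.5 * d * math.log(2 * math.pi * s2 / nu)
            - (W**2).sum(axis=1) * nu / (2 * s2)
        )
        vals = np.exp(log_lik + log_prior_w).reshape([n_w] * d)
        inner = vals
        for c in range(d):
            inner = _simpson(inner, axes[d - 1 - c][1] - axes[d - 1 - c][0], axis=-1)
        log_prior_s2 = (
            a0 * math.log(b0) - gammaln(a0) - (a0 + 1) * math.log(s2) - b0 / s2
        )
        # +log(s2) jacobian for the log-s2 substitution
        log_vals[si] = math.log(max(float(inner), 1e-320)) + log_prior_s2 + math.log(
            s2
        )

    h = log_s2[1] - log_s2[0]
    peak = log_vals.max()
    integrand = np.exp(log_vals - peak)
    return float(peak + math.log(_simpson(integrand, h, axis=0)))


def _simpson(values: np.ndarray, h: float, axis: int = -1) -> np.ndarray:
    from scipy.integrate import simpson

    return simpson(values, dx=h, axis=axis)


def prequential_log_evidence(
    y: np.ndarray, X: np.ndarray, nu: float, sigma2_0: float
) -> float:
    """Product of one-step posterior-predictive Student-t densities."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    d = Xd.shape[1]
    Vinv = nu * np.eye(d)
    Xty = np.zeros(d)
    a = nu / 2.0
    b = nu * sigma2_0 / 2.0
    total = 0.0
    for i in range(n):
        x = Xd[i]
        w = np.linalg.solve(Vinv, Xty)
        V = np.linalg.inv(Vinv)
        scale2 = (b / a) * (1.0 + float(x @ V @ x))
        total += stats.t.logpdf(y[i], df=2 * a, loc=float(x @ w), scale=math.sqrt(scale2))
        # conjugate update with the new observation
        Vinv = Vinv + np.outer(x, x)
        Xty = Xty + x * y[i]
        w_new = np.linalg.solve(Vinv, Xty)
        a += 0.5
        b = nu * sigma2_0 / 2.0 + 0.5 * (
            float(y[: i + 1] @ y[: i + 1]) - float(w_new @ Vinv @ w_new)
        )
    return total


def dirichlet_multinomial_log_evidence(
    counts: dict[str, int], alpha: dict[str, float]
) -> float:
    """Direct Gamma-function evaluation of the Dirichlet-multinomial evidence."""
    a_total = sum(alpha.values())
    n_total = sum(counts.values())
    out = gammaln(a_total) - gammaln(a_total + n_total)
    for state, a in alpha.items():
        out += gammaln(a + counts.get(state, 0)) - gammaln(a)
    return float(out)


def exhaustive_best_parent_sets(
    score_family, children, parents, max_parents: int
) -> dict[str, tuple[str, ...]]:
    """Global argmax of a decomposable score by per-child enumeration."""
    best = {}
    for child in children:
        options = []
        for k in range(max_parents + 1):
            for combo in itertools.combinations(sorted(parents), k):
                options.append((score_family(child, combo), combo))
        options.sort(key=lambda t: (-t[0], t[1]))
        best[child] = options[0][1]
    return best


def ols_coefficients(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS (intercept first) with standard errors, via lstsq."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    dof = n - Xd.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Xd.T @ Xd)
    return beta, np.sqrt(np.diag(cov))
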