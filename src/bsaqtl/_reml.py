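"""REML machinery for crossed random-effects models on trial data.

Two engines share one interface:

* a spectral engine for *balanced* factorial layouts, where every variance
  term is a Kronecker product of identity and all-ones matrices across the
  design factors.  The covariance is then simultaneously diagonalisable and
  the restricted likelihood separates into independent ANOVA strata, each
  contributing ``d_s * log(lam_s) + SS_s / lam_s``.  When the implied
  stratum-wise estimates are all non-negative they are the exact REML
  solution in closed form; otherwise the same stratum likelihood is
  maximised under non-negativity bounds.

* a dense Woodbury engine for unbalanced data, profiling the restricted
  likelihood over arbitrary independent random factors.

BLUPs come from Henderson's mixed-model equations at the fitted variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "RemlFit",
    "Stratum",
    "reml_from_strata",
    "strata_two_way",
    "strata_plot_model",
    "reml_unbalanced",
    "blup_two_way",
]

_EPS = 1e-12


@dataclass
class Stratum:
    """One eigenspace of a balanced design: dimension, sum of squares and
    the row of coefficients mapping variance components to its eigenvalue."""

    name: str
    dim: int
    ss: float
    coef: np.ndarray  # length n_components + 1; last entry multiplies sigma_error^2


@dataclass
class RemlFit:
    components: dict[str, float]
    sigma_error2: float
    loglik: float
    converged: bool
    n_obs: int
    method: str
    mu: float = 0.0
    messages: list[str] = field(default_factory=list)

    def as_array(self, names: list[str]) -> np.ndarray:
        return np.array([self.components[n] for n in names] + [self.sigma_error2])


def _stratum_loglik(theta: np.ndarray, strata: list[Stratum]) -> float:
    ll = 0.0
    for s in strata:
        lam = float(s.coef @ theta)
        lam = max(lam, _EPS)
        ll -= 0.5 * (s.dim * np.log(lam) + s.ss / lam)
    return ll


def reml_from_strata(
    strata: list[Stratum], names: list[str]
) -> RemlFit:
    """Exact REML for a balanced design expressed as independent strata.

    ``names`` labels the variance components (excluding error, which is
    always the last coefficient column).
    """
    k = len(names) + 1
    n_obs = sum(s.dim for s in strata) + 1
    total_ss = sum(s.ss for s in strata)
    if total_ss <= _EPS * max(1, n_obs):
        # Degenerate: constant response.
        return RemlFit(
            components={n: 0.0 for n in names},
            sigma_error2=0.0,
            loglik=0.0,
            converged=True,
            n_obs=n_obs,
            method="spectral-degenerate",
        )

    # Closed form: set each stratum eigenvalue to its mean square, solve the
    # (square, full-rank in our designs) linear system for the components.
    A = np.vstack([s.coef for s in strata])
    ms = np.array([s.ss / s.dim if s.dim > 0 else 0.0 for s in strata])
    theta, *_ = np.linalg.lstsq(A, ms, rcond=None)
    if np.all(theta >= -1e-10 * max(ms.max(), 1.0)):
        theta = np.clip(theta, 0.0, None)
        return RemlFit(
            components=dict(zip(names, theta[:-1])),
            sigma_error2=float(theta[-1]),
            loglik=_stratum_loglik(theta, strata),
            converged=True,
            n_obs=n_obs,
            method="spectral-closed-form",
        )

    # Boundary case: maximise under non-negativity.
    scale = max(ms.max(), _EPS)
    x0 = np.clip(theta, 1e-8 * scale, None)
    res = optimize.minimize(
        lambda t: -_stratum_loglik(t, strata),
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (k - 1) + [(1e-10 * scale, None)],
    )
    theta = np.clip(res.x, 0.0, None)
    return RemlFit(
        components=dict(zip(names, theta[:-1])),
        sigma_error2=float(theta[-1]),
        loglik=_stratum_loglik(theta, strata),
        converged=bool(res.success),
        n_obs=n_obs,
        method="spectral-bounded",
    )


def reml_profile_loglik(
    strata: list[Stratum], names: list[str], fixed: dict[str, float]
) -> RemlFit:
    """REML with some components held fixed (for likelihood-ratio tests)."""
    k = len(names) + 1
    free = [i for i, n in enumerate(names) if n not in fixed]
    n_obs = sum(s.dim for s in strata) + 1
    ms = np.array([s.ss / max(s.dim, 1) for s in strata])
    scale = max(ms.max(), _EPS)

    def expand(x: np.ndarray) -> np.ndarray:
        theta = np.empty(k)
        for i, n in enumerate(names):
            theta[i] = fixed.get(n, np.nan)
        theta[free] = x[:-1] if len(free) else x[:0]
        theta[-1] = x[-1]
        return theta

    x0 = np.full(len(free) + 1, 0.3 * scale)
    res = optimize.minimize(
        lambda x: -_stratum_loglik(expand(x), strata),
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * len(free) + [(1e-10 * scale, None)],
    )
    theta = expand(np.clip(res.x, 0.0, None))
    return RemlFit(
        components=dict(zip(names, theta[:-1])),
        sigma_error2=float(theta[-1]),
        loglik=_stratum_loglik(theta, strata),
        converged=bool(res.success),
        n_obs=n_obs,
        method="spectral-fixed",
    )


# ---------------------------------------------------------------------------
# Stratum builders
# ---------------------------------------------------------------------------

def strata_two_way(y: np.ndarray, names: tuple[str, str]) -> list[Stratum]:
    """Strata for ``y[a, b] = mu + A + B + eps`` with one observation per
    cell, both factors random.  Component order: (sigma_A^2, sigma_B^2)."""
    a, b = y.shape
    m = y.mean()
    ma = y.mean(axis=1)
    mb = y.mean(axis=0)
    ss_a = b * float(((ma - m) ** 2).sum())
    ss_b = a * float(((mb - m) ** 2).sum())
    ss_res = float(((y - ma[:, None] - mb[None, :] + m) ** 2).sum())
    return [
        Stratum(names[0], a - 1, ss_a, np.array([b, 0.0, 1.0])),
        Stratum(names[1], b - 1, ss_b, np.array([0.0, a, 1.0])),
        Stratum("residual", (a - 1) * (b - 1), ss_res, np.array([0.0, 0.0, 1.0])),
    ]


def strata_plot_model(y: np.ndarray) -> list[Stratum]:
    """Strata for the plot-level model on a balanced (g, e, r) cube:
    ``y = mu + G + E + GEI + block(E) + eps``, all terms random.

    Component order: (sigma_G^2, sigma_E^2, sigma_GEI^2, sigma_block^2).
    """
    g, e, r = y.shape
    m = y.mean()
    mg = y.mean(axis=(1, 2))
    me = y.mean(axis=(0, 2))
    mge = y.mean(axis=2)
    mer = y.mean(axis=0)  # (e, r) block-within-env means
    ss_g = e * r * float(((mg - m) ** 2).sum())
    ss_e = g * r * float(((me - m) ** 2).sum())
    ss_gei = r * float(((mge - mg[:, None] - me[None, :] + m) ** 2).sum())
    ss_blk = g * float(((mer - me[:, None]) ** 2).sum())
    resid = y - mge[:, :, None] - mer[None, :, :] + me[None, :, None]
    ss_res = float((resid ** 2).sum())
    return [
        Stratum("genotype", g - 1, ss_g, np.array([e * r, 0.0, r, 0.0, 1.0])),
        Stratum("environment", e - 1, ss_e, np.array([0.0, g * r, r, g, 1.0])),
        Stratum("gei", (g - 1) * (e - 1), ss_gei, np.array([0.0, 0.0, r, 0.0, 1.0])),
        Stratum("block", e * (r - 1), ss_blk, np.array([0.0, 0.0, 0.0, g, 1.0])),
        Stratum("residual", (g - 1) * e * (r - 1), ss_res, np.array([0.0, 0.0, 0.0, 0.0, 1.0])),
    ]


# ---------------------------------------------------------------------------
# General (unbalanced) engine
# ---------------------------------------------------------------------------

def _factor_design(codes: np.ndarray) -> np.ndarray:
    q = int(codes.max()) + 1
    Z = np.zeros((codes.size, q))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _woodbury_neg2reml(
    theta: np.ndarray, y: np.ndarray, Zs: list[np.ndarray]
) -> float:
    """-2 restricted log-likelihood (up to constant) for
    V = sum_k theta_k Z_k Z_k' + theta[-1] I, fixed effect = intercept."""
    n = y.size
    se2 = max(theta[-1], _EPS)
    cols = [np.sqrt(max(t, 0.0)) * Z for t, Z in zip(theta[:-1], Zs)]
    if cols:
        Zt = np.hstack(cols)
        q = Zt.shape[1]
        C = Zt.T @ Zt / se2 + np.eye(q)
        L = np.linalg.cholesky(C)
        logdet_v = n * np.log(se2) + 2.0 * np.log(np.diag(L)).sum()

        def vinv(x: np.ndarray) -> np.ndarray:
            w = np.linalg.solve(L, Zt.T @ x)
            w = np.linalg.solve(L.T, w)
            return (x - Zt @ w / se2) / se2
    else:
        logdet_v = n * np.log(se2)

        def vinv(x: np.ndarray) -> np.ndarray:
            return x / se2

    one = np.ones(n)
    vi_one = vinv(one)
    xtvx = float(one @ vi_one)
    beta = float(one @ vinv(y)) / xtvx
    r = y - beta
    quad = float(r @ vinv(r))
    return logdet_v + np.log(xtvx) + quad


def reml_unbalanced(
    y: np.ndarray, factors: dict[str, np.ndarray]
) -> RemlFit:
    """Dense REML for ``y = mu + sum_k u_k[factor_k] + eps`` with arbitrary
    (possibly unbalanced) factor codings.  Suited to modest n."""
    names = list(factors)
    Zs = [_factor_design(np.asarray(factors[n], dtype=int)) for n in names]
    vy = float(np.var(y))
    if vy <= _EPS:
        return RemlFit(
            components={n: 0.0 for n in names},
            sigma_error2=0.0,
            loglik=0.0,
            converged=True,
            n_obs=y.size,
            method="woodbury-degenerate",
            mu=float(y.mean()),
        )
    k = len(names) + 1
    x0 = np.full(k, vy / k)
    res = optimize.minimize(
        lambda t: _woodbury_neg2reml(t, y, Zs),
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (k - 1) + [(1e-10 * vy, None)],
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
    )
    theta = np.clip(res.x, 0.0, None)
    fit = RemlFit(
        components=dict(zip(names, theta[:-1])),
        sigma_error2=float(theta[-1]),
        loglik=-0.5 * _woodbury_neg2reml(theta, y, Zs),
        converged=bool(res.success),
        n_obs=y.size,
        method="woodbury",
    )
    return fit


def blup_two_way(
    y: np.ndarray,
    codes_a: np.ndarray,
    codes_b: np.ndarray | None,
    var_a: float,
    var_b: float,
    var_e: float,
) -> tuple[float, np.ndarray]:
    """Henderson MME BLUPs of factor-A effects for
    ``y = mu + a[codes_a] + b[codes_b] + eps``; returns (mu_hat, u_a).

    Factor B (and its equations) is dropped when ``codes_b`` is None or
    ``var_b`` is 0; with ``var_e`` ~ 0 the solution approaches the
    unshrunken factor-A means.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    qa = int(codes_a.max()) + 1
    use_b = codes_b is not None and var_b > _EPS
    qb = int(codes_b.max()) + 1 if use_b else 0
    if var_a <= _EPS:
        mu = float(y.mean())
        return mu, np.zeros(qa)
    se2 = max(var_e, _EPS * max(var_a, 1.0))

    dim = 1 + qa + qb
    C = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    Za = _factor_design(codes_a)
    X = np.ones((n, 1))
    blocks = [X, Za] + ([_factor_design(codes_b)] if use_b else [])
    W = np.hstack(blocks)
    C = W.T @ W
    rhs = W.T @ y
    # ridge from the variance ratios on the random-effect diagonals
    C[1 : 1 + qa, 1 : 1 + qa] += np.eye(qa) * (se2 / var_a)
    if use_b:
        C[1 + qa :, 1 + qa :] += np.eye(qb) * (se2 / var_b)
    sol = np.linalg.solve(C, rhs)
    return float(sol[0]), sol[1 : 1 + qa]
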