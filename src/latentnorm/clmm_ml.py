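"""Maximum-likelihood cumulative link mixed model with crossed random intercepts.

The marginal likelihood integrates the random effects out of an ordinal
(cumulative link) likelihood.  Crossed item/participant intercepts do not
factorise, so the integral is approximated by a Laplace expansion around the
joint conditional mode of the stacked random-effect vector; the inner
problem is solved by damped Newton iterations on the penalised log-likelihood
(the ordinal probit/logit log-likelihood is concave in the linear predictor,
so the penalised Hessian is positive definite).  The outer optimisation runs
over transformed parameters: the first threshold free, remaining thresholds
as log-increments, random-effect SDs on the log scale.

The conditional modes of the item random effects at the optimum are the
latent-mean norms; their conditional SDs come from the inverse penalised
Hessian blocks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse
from scipy.special import logsumexp

from latentnorm.ordinal_core import (
    CDF_CEIL,
    PROB_FLOOR,
    LinkFunction,
    get_link,
)

__all__ = [
    "CLMMSpec",
    "CLMMFit",
    "fit_thresholds_only",
    "fit_clmm",
    "marginal_loglik_quadrature",
    "ranef",
    "ConvergenceWarning",
]

_FACTOR_COLUMNS = {"item": "item_id", "participant": "participant_id"}
_SD_FLOOR = 1e-6
_CLAMP = 10.0


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class CLMMSpec:
    """Model specification: link, level count and random-intercept factors."""

    n_levels: int
    factors: tuple[str, ...] = ("item",)
    link: str = "probit"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not self.factors:
            raise ValueError("at least one grouping factor is required")
        for f in self.factors:
            if f not in _FACTOR_COLUMNS:
                raise ValueError(f"unknown grouping factor {f!r}")


@dataclass
class CLMMFit:
    """Result of a Laplace-approximated ML fit."""

    spec: CLMMSpec
    tau_hat: np.ndarray
    re_sd_hat: dict[str, float]
    levels: dict[str, np.ndarray]
    modes: dict[str, np.ndarray]
    cond_sd: dict[str, np.ndarray]
    loglik: float
    converged: bool
    n_outer_iter: int
    message: str = ""
    boundary: bool = False

    def to_json(self, path=None) -> str:
        payload = {
            "package": "latentnorm",
            "model": "clmm_ml",
            "link": self.spec.link,
            "n_levels": self.spec.n_levels,
            "factors": list(self.spec.factors),
            "tau_hat": self.tau_hat.tolist(),
            "re_sd_hat": self.re_sd_hat,
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_outer_iter": self.n_outer_iter,
            "message": self.message,
            "ranef": {
                f: {
                    "levels": self.levels[f].tolist(),
                    "modes": self.modes[f].tolist(),
                    "cond_sd": self.cond_sd[f].tolist(),
                }
                for f in self.spec.factors
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_thresholds_only(
    responses: Sequence[int] | np.ndarray,
    n_levels: int,
    link: str | LinkFunction = "probit",
    clamp: float = _CLAMP,
) -> np.ndarray:
    """Intercept-only threshold MLEs: link-inverse of cumulative proportions.

    This is the exact maximum-likelihood solution for the no-random-effects,
    intercept-only cumulative link model, used both as a starting-value
    generator and as a closed-form oracle.  Cumulative proportions of 0 or 1
    (unobserved extreme categories) are clamped to ``+-clamp``.
    """
    y = np.asarray(responses, dtype=int)
    if y.size == 0:
        raise ValueError("empty response vector")
    if y.min() < 1 or y.max() > n_levels:
        raise ValueError("responses outside 1..K")
    counts = np.bincount(y, minlength=n_levels + 1)[1:]
    if (counts > 0).sum() < 2:
        k = int(np.flatnonzero(counts)[0]) + 1
        raise ValueError(
            f"degenerate data: all responses equal category {k}"
        )
    lk = get_link(link)
    cum = np.cumsum(counts)[:-1] / y.size
    with np.errstate(divide="ignore"):
        tau = lk.ppf(cum)
    tau = np.clip(tau, -clamp, clamp)
    # equal neighbours (interior empty categories at the edges of clamping)
    # are separated minimally to preserve strict ordering
    for k in range(1, tau.size):
        if tau[k] <= tau[k - 1]:
            tau[k] = tau[k - 1] + 1e-8
    return tau


# ---------------------------------------------------------------------------
# ordinal likelihood derivatives


def _link_funcs(link: LinkFunction):
    """cdf, pdf and pdf-derivative callables for a link."""
    if link.name == "probit":
        from scipy.stats import norm

        def dpdf(z):
            return -z * norm.pdf(z)

        return norm.cdf, norm.pdf, dpdf
    if link.name == "logit":
        from scipy.stats import logistic

        def dpdf(z):
            return logistic.pdf(z) * (1.0 - 2.0 * logistic.cdf(z))

        return logistic.cdf, logistic.pdf, dpdf
    raise ValueError(f"unsupported link {link.name!r}")


class _OrdinalData:
    """Preprocessed response data for fast likelihood evaluations."""

    def __init__(self, trials: pd.DataFrame, spec: CLMMSpec):
        y = trials["response"].to_numpy()
        if not np.issubdtype(np.asarray(y).dtype, np.integer):
            y = y.astype(int)
        K = spec.n_levels
        if y.min() < 1 or y.max() > K:
            raise ValueError("responses outside declared 1..K")
        if len(np.unique(y)) < 2:
            raise ValueError("fewer than 2 observed response categories")
        self.y = y
        self.K = K
        self.n = y.size
        self.spec = spec
        self.link = get_link(spec.link)
        self._cdf, self._pdf, self._dpdf = _link_funcs(self.link)

        self.factor_levels: dict[str, np.ndarray] = {}
        self.factor_index: dict[str, np.ndarray] = {}
        for f in spec.factors:
            col = _FACTOR_COLUMNS[f]
            if col not in trials.columns:
                raise ValueError(f"column {col!r} required for factor {f!r}")
            codes, levels = pd.factorize(trials[col], sort=True)
            self.factor_levels[f] = np.asarray(levels)
            self.factor_index[f] = codes
        self.q_f = {f: len(self.factor_levels[f]) for f in spec.factors}
        self.q = sum(self.q_f.values())
        self.offsets = {}
        off = 0
        for f in spec.factors:
            self.offsets[f] = off
            off += self.q_f[f]

        obs = np.sort(np.unique(y))
        interior = np.setdiff1d(np.arange(obs.min(), obs.max() + 1), obs)
        if interior.size:
            raise ValueError(
                f"interior response categories unobserved: {interior.tolist()}"
            )
        self.k_min, self.k_max = int(obs.min()), int(obs.max())
        # free thresholds: tau_{k_min} .. tau_{k_max - 1}; others clamped
        self.free_lo = self.k_min  # 1-based threshold index of first free
        self.free_hi = self.k_max - 1
        self.n_free = self.free_hi - self.free_lo + 1
        if self.n_free < 1:
            raise ValueError("fewer than 2 observed response categories")
        if self.k_min > 1 or self.k_max < K:
            warnings.warn(
                "unobserved extreme categories; adjacent thresholds clamped "
                f"to +-{_CLAMP}",
                ConvergenceWarning,
                stacklevel=3,
            )

    def full_tau(self, tau_free: np.ndarray) -> np.ndarray:
        """Embed free thresholds into the length K-1 vector with clamps."""
        tau = np.empty(self.K - 1)
        lo, hi = self.free_lo, self.free_hi  # 1-based
        tau[lo - 1 : hi] = tau_free
        for k in range(lo - 2, -1, -1):
            tau[k] = -_CLAMP - 0.5 * (lo - 1 - k - 1)
        for k in range(hi, self.K - 1):
            tau[k] = _CLAMP + 0.5 * (k - hi)
        return tau

    def eta(self, b: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n)
        for f in self.spec.factors:
            off = self.offsets[f]
            out += b[off + self.factor_index[f]]
        return out

    def loglik_terms(self, tau: np.ndarray, eta: np.ndarray):
        """Per-observation log-probability plus first/second eta-derivatives."""
        tau_pad = np.concatenate(([-np.inf], tau, [np.inf]))
        z_hi = tau_pad[self.y] - eta
        z_lo = tau_pad[self.y - 1] - eta
        F_hi = np.where(np.isinf(z_hi), 1.0, self._cdf(np.where(np.isinf(z_hi), 0, z_hi)))
        F_lo = np.where(np.isinf(z_lo), 0.0, self._cdf(np.where(np.isinf(z_lo), 0, z_lo)))
        f_hi = np.where(np.isinf(z_hi), 0.0, self._pdf(np.where(np.isinf(z_hi), 0, z_hi)))
        f_lo = np.where(np.isinf(z_lo), 0.0, self._pdf(np.where(np.isinf(z_lo), 0, z_lo)))
        d_hi = np.where(np.isinf(z_hi), 0.0, self._dpdf(np.where(np.isinf(z_hi), 0, z_hi)))
        d_lo = np.where(np.isinf(z_lo), 0.0, self._dpdf(np.where(np.isinf(z_lo), 0, z_lo)))
        p = np.clip(F_hi - F_lo, PROB_FLOOR, CDF_CEIL)
        lp = np.log(p)
        A = f_hi - f_lo
        C = d_hi - d_lo
        g1 = -A / p                      # d lp / d eta
        w = (A * A - C * p) / (p * p)    # -(d2 lp / d eta2) >= 0 for probit
        return lp, g1, w


def _inner_mode(
    data: _OrdinalData,
    tau: np.ndarray,
    prec: np.ndarray,
    b0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Find the joint conditional mode of the stacked random effects.

    ``prec`` holds per-coordinate prior precisions (1/sigma_f^2).  Returns
    the mode, the penalised objective value there, the (dense) penalised
    negative Hessian, and a convergence flag.
    """
    b = b0.copy()
    spec = data.spec

    def objective(bv):
        lp, g1, w = data.loglik_terms(tau, data.eta(bv))
        return lp.sum() - 0.5 * np.sum(prec * bv * bv), g1, w

    g, g1, w = objective(b)
    converged = False
    H = None
    for _ in range(max_iter):
        grad = -prec * b
        for f in spec.factors:
            off = data.offsets[f]
            grad[off : off + data.q_f[f]] += np.bincount(
                data.factor_index[f], weights=g1, minlength=data.q_f[f]
            )
        H = _penalised_hessian(data, w, prec)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            c, low = linalg.cho_factor(H, check_finite=False)
            delta = linalg.cho_solve((c, low), grad, check_finite=False)
        except linalg.LinAlgError:
            delta = np.linalg.solve(H + 1e-6 * np.eye(H.shape[0]), grad)
        step = 1.0
        for _ in range(30):
            b_new = b + step * delta
            g_new, g1_new, w_new = objective(b_new)
            if g_new >= g - 1e-12:
                b, g, g1, w = b_new, g_new, g1_new, w_new
                break
            step *= 0.5
        else:
            break
    if H is None:
        H = _penalised_hessian(data, w, prec)
    return b, g, H, converged


def _penalised_hessian(data: _OrdinalData, w: np.ndarray, prec: np.ndarray):
    spec = data.spec
    q = data.q
    H = np.zeros((q, q))
    for f in spec.factors:
        off = data.offsets[f]
        d = np.bincount(data.factor_index[f], weights=w, minlength=data.q_f[f])
        idx = np.arange(off, off + data.q_f[f])
        H[idx, idx] = d
    if len(spec.factors) == 2:
        f1, f2 = spec.factors
        o1, o2 = data.offsets[f1], data.offsets[f2]
        cross = sparse.coo_matrix(
            (w, (data.factor_index[f1], data.factor_index[f2])),
            shape=(data.q_f[f1], data.q_f[f2]),
        ).toarray()
        H[o1 : o1 + data.q_f[f1], o2 : o2 + data.q_f[f2]] += cross
        H[o2 : o2 + data.q_f[f2], o1 : o1 + data.q_f[f1]] += cross.T
    H[np.diag_indices(q)] += prec
    return H


def _laplace_loglik(data: _OrdinalData, theta: np.ndarray, state: dict) -> float:
    """Laplace-approximated marginal log-likelihood at transformed theta."""
    spec = data.spec
    nf = data.n_free
    tau_free = np.empty(nf)
    tau_free[0] = theta[0]
    if nf > 1:
        tau_free[1:] = theta[0] + np.cumsum(np.exp(theta[1:nf]))
    tau = data.full_tau(tau_free)
    log_sd = theta[nf:]
    sds = np.maximum(np.exp(log_sd), _SD_FLOOR)
    prec = np.empty(data.q)
    for i, f in enumerate(spec.factors):
        off = data.offsets[f]
        prec[off : off + data.q_f[f]] = 1.0 / sds[i] ** 2
    b0 = state.get("b", np.zeros(data.q))
    b_hat, g, H, inner_ok = _inner_mode(data, tau, prec, b0)
    state["b"] = b_hat
    state["H"] = H
    state["tau"] = tau
    state["sds"] = sds
    state["inner_ok"] = inner_ok
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    penalty_const = sum(
        data.q_f[f] * np.log(sds[i]) for i, f in enumerate(spec.factors)
    )
    return g - penalty_const - 0.5 * logdet


def fit_clmm(
    trials: pd.DataFrame,
    spec: CLMMSpec,
    start_sd: float = 0.5,
    max_outer_iter: int = 200,
    outer_tol: float = 1e-8,
) -> CLMMFit:
    """Fit the equal-variance CLMM by Laplace-approximated ML.

    The latent grand mean is fixed at zero for identifiability, so the
    conditional modes of the item factor are the latent-mean norms.
    """
    data = _OrdinalData(trials, spec)
    nf = data.n_free
    tau0_full = fit_thresholds_only(data.y, data.K, spec.link)
    tau0 = tau0_full[data.free_lo - 1 : data.free_hi]
    theta0 = np.empty(nf + len(spec.factors))
    theta0[0] = tau0[0]
    if nf > 1:
        incr = np.maximum(np.diff(tau0), 1e-3)
        theta0[1:nf] = np.log(incr)
    theta0[nf:] = np.log(start_sd)

    state: dict = {}

    def negloglik(theta):
        return -_laplace_loglik(data, theta, state)

    bounds = [(None, None)] * nf + [(np.log(_SD_FLOOR), 5.0)] * len(spec.factors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            negloglik,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": max_outer_iter,
                "ftol": outer_tol,
                "gtol": 1e-6,
            },
        )
    # refresh state at the optimum
    loglik = _laplace_loglik(data, res.x, state)
    tau, sds, H = state["tau"], state["sds"], state["H"]
    b_hat = state["b"]
    try:
        Hinv = np.linalg.inv(H)
        cond_var = np.clip(np.diag(Hinv), 0.0, None)
    except np.linalg.LinAlgError:
        cond_var = np.full(data.q, np.nan)

    re_sd_hat, levels, modes, cond_sd = {}, {}, {}, {}
    boundary = False
    for i, f in enumerate(spec.factors):
        off = data.offsets[f]
        sl = slice(off, off + data.q_f[f])
        re_sd_hat[f] = float(sds[i])
        levels[f] = data.factor_levels[f]
        modes[f] = b_hat[sl]
        cond_sd[f] = np.sqrt(cond_var[sl])
        if sds[i] <= _SD_FLOOR * 1.01:
            boundary = True
    converged = bool(res.success) and state.get("inner_ok", False)
    if not converged:
        warnings.warn(
            f"CLMM fit did not fully converge: {res.message}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return CLMMFit(
        spec=spec,
        tau_hat=tau,
        re_sd_hat=re_sd_hat,
        levels=levels,
        modes=modes,
        cond_sd=cond_sd,
        loglik=float(loglik),
        converged=converged,
        n_outer_iter=int(res.nit),
        message=str(res.message),
        boundary=boundary,
    )


def ranef(fit: CLMMFit, factor: str = "item") -> pd.DataFrame:
    """Conditional modes (the norms) and conditional SDs for one factor."""
    if factor not in fit.spec.factors:
        raise ValueError(f"factor {factor!r} not in fit (has {fit.spec.factors})")
    return pd.DataFrame(
        {
            "level": fit.levels[factor],
            "mode": fit.modes[factor],
            "cond_sd": fit.cond_sd[factor],
        }
    )


def marginal_loglik_quadrature(
    trials: pd.DataFrame,
    tau: np.ndarray,
    re_sd: float,
    n_nodes: int = 50,
    link: str = "probit",
    factors: tuple[str, ...] = ("item",),
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood (single-factor oracle).

    Valid only when the likelihood factorises by group, i.e. exactly one
    grouping factor; the per-group integral over the random effect is
    evaluated on nodes recentred at the group's conditional mode and scaled
    by its conditional SD.
    """
    if len(factors) != 1:
        raise ValueError("quadrature oracle supports exactly one grouping factor")
    if n_nodes < 5:
        raise ValueError("n_nodes must be >= 5")
    factor = factors[0]
    spec = CLMMSpec(n_levels=len(tau) + 1, factors=(factor,), link=link)
    data = _OrdinalData(trials, spec)
    tau = np.asarray(tau, dtype=float)

    if re_sd <= 0:
        lp, _, _ = data.loglik_terms(tau, np.zeros(data.n))
        return float(lp.sum())

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    log_w = np.log(weights)
    idx = data.factor_index[factor]
    total = 0.0
    for g in range(data.q_f[factor]):
        mask = idx == g
        y_g = data.y[mask]
        sub = _SubGroup(data, y_g, tau)

        # 1-D Newton for the mode of loglik(b) + log N(b; 0, re_sd)
        b = 0.0
        for _ in range(50):
            g1, w_ = sub.derivs(b)
            grad = g1 - b / re_sd**2
            hess = -(w_ + 1.0 / re_sd**2)
            step = -grad / hess
            b += step
            if abs(step) < 1e-10:
                break
        _, w_ = sub.derivs(b)
        sigma_hat = 1.0 / np.sqrt(w_ + 1.0 / re_sd**2)
        pts = b + np.sqrt(2.0) * sigma_hat * nodes
        log_f = np.array(
            [
                sub.loglik(p)
                - 0.5 * (p / re_sd) ** 2
                - 0.5 * np.log(2 * np.pi * re_sd**2)
                for p in pts
            ]
        )
        total += logsumexp(log_w + nodes**2 + log_f) + np.log(
            np.sqrt(2.0) * sigma_hat
        )
    return float(total)


class _SubGroup:
    """Per-group ordinal likelihood helper for the quadrature oracle."""

    def __init__(self, data: _OrdinalData, y: np.ndarray, tau: np.ndarray):
        self.data = data
        self.y = y
        self.tau = tau
        self.tau_pad = np.concatenate(([-np.inf], tau, [np.inf]))

    def _terms(self, b: float):
        d = self.data
        z_hi = self.tau_pad[self.y] - b
        z_lo = self.tau_pad[self.y - 1] - b
        F_hi = np.where(np.isinf(z_hi), 1.0, d._cdf(np.where(np.isinf(z_hi), 0, z_hi)))
        F_lo = np.where(np.isinf(z_lo), 0.0, d._cdf(np.where(np.isinf(z_lo), 0, z_lo)))
        f_hi = np.where(np.isinf(z_hi), 0.0, d._pdf(np.where(np.isinf(z_hi), 0, z_hi)))
        f_lo = np.where(np.isinf(z_lo), 0.0, d._pdf(np.where(np.isinf(z_lo), 0, z_lo)))
        dd_hi = np.where(np.isinf(z_hi), 0.0, d._dpdf(np.where(np.isinf(z_hi), 0, z_hi)))
        dd_lo = np.where(np.isinf(z_lo), 0.0, d._dpdf(np.where(np.isinf(z_lo), 0, z_lo)))
        p = np.clip(F_hi - F_lo, PROB_FLOOR, CDF_CEIL)
        return p, f_hi - f_lo, dd_hi - dd_lo

    def loglik(self, b: float) -> float:
        p, _, _ = self._terms(b)
        return float(np.log(p).sum())

    def derivs(self, b: float):
        p, A, C = self._terms(b)
        g1 = float(np.sum(-A / p))
        w = float(np.sum((A * A - C * p) / (p * p)))
        return g1, max(w, 1e-10)
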