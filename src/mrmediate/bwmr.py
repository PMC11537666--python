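"""Bayesian-weighted MR: a hierarchical Gaussian model with outlier down-weighting.

Model. Each instrument j has a latent true exposure effect
``gamma_j ~ N(0, sigma0^2)`` and a latent outcome effect
``Gamma_j = beta * gamma_j + alpha_j`` where the pleiotropic deviation
``alpha_j ~ N(0, tau^2)`` captures polygenic horizontal pleiotropy. Observed
summary effects are Gaussian about the latents with their reported standard
errors: ``bx_j ~ N(gamma_j, sx_j^2)`` and ``by_j ~ N(beta*gamma_j, sy_j^2 + tau^2)``
after marginalizing alpha. Weakly-informative inverse-gamma(1e-3, 1e-3)
priors regularize tau^2 and sigma0^2.

Estimation. (beta, tau^2, sigma0^2) are fit by variational EM on a weighted
evidence lower bound: the E-step gives each gamma_j's exact Gaussian
posterior; the M-step maximizes the weighted expected complete-data
log-posterior (closed form for beta and sigma0^2, one-dimensional
optimization for tau^2). Robustness comes from per-SNP Bayesian weights
computed from each SNP's evidence under the current fit,
``w_j = min(1, exp((c^2 - d_j^2)/2))`` with c = 2 and d_j the standardized
marginal residual of by_j; weights are recomputed between EM rounds and held
fixed within a round so every round's ELBO trace is non-decreasing. The
standard error of beta comes from the curvature (observed information) of
the weighted marginal log-likelihood profile at the optimum.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import InsufficientInstrumentsError
from .mr_core import MRResult, _finish, extract_pairs, ivw

_PRIOR_A = 1e-3  # inverse-gamma shape for tau^2 and sigma0^2
_PRIOR_B = 1e-3  # inverse-gamma scale
_WEIGHT_C = 2.0  # standardized-residual scale at which down-weighting starts


@dataclass
class BwmrFit:
    beta: float
    se: float
    pval: float
    tau2: float
    sigma02: float
    weights: np.ndarray
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_snp: int = 0

    def to_mr_result(self) -> MRResult:
        res = _finish("BWMR", self.beta, self.se, self.n_snp,
                      info={"tau2": self.tau2, "sigma02": self.sigma02,
                            "converged": self.converged})
        return res


def _elbo(bx, by, sx, sy, w, beta, sigma02, tau2):
    """Weighted ELBO = weighted expected complete-data log-posterior + entropy.

    With the exact Gaussian E-step this equals the weighted marginal
    log-likelihood plus the (weight-independent) prior terms.
    """
    vy = sy ** 2 + tau2
    prec = 1.0 / sigma02 + 1.0 / sx ** 2 + beta ** 2 / vy
    var_g = 1.0 / prec
    mu_g = var_g * (bx / sx ** 2 + beta * by / vy)
    eg2 = mu_g ** 2 + var_g
    ll = (
        -0.5 * (np.log(2 * np.pi * sx ** 2) + ((bx - mu_g) ** 2 + var_g) / sx ** 2)
        - 0.5 * (np.log(2 * np.pi * vy) + ((by - beta * mu_g) ** 2 + beta ** 2 * var_g) / vy)
        - 0.5 * (np.log(2 * np.pi * sigma02) + eg2 / sigma02)
        + 0.5 * (np.log(2 * np.pi * var_g) + 1.0)  # entropy of q(gamma_j)
    )
    prior = (
        -(_PRIOR_A + 1) * np.log(tau2) - _PRIOR_B / tau2
        - (_PRIOR_A + 1) * np.log(sigma02) - _PRIOR_B / sigma02
    )
    return float(np.sum(w * ll) + prior), mu_g, var_g


def _weighted_loglik(bx, by, sx, sy, w, beta, sigma02, tau2):
    """Weighted marginal log-likelihood of the bivariate Gaussian per SNP."""
    v_x = sigma02 + sx ** 2
    v_y = beta ** 2 * sigma02 + tau2 + sy ** 2
    c_xy = beta * sigma02
    det = v_x * v_y - c_xy ** 2
    quad = (v_y * bx ** 2 - 2 * c_xy * bx * by + v_x * by ** 2) / det
    ll = -np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad
    return float(np.sum(w * ll))


def _em_round(bx, by, sx, sy, w, beta, sigma02, tau2, max_iter, tol):
    """One EM round with fixed weights; returns params and the ELBO trace."""
    trace = []
    sw = np.sum(w)
    for _ in range(max_iter):
        # E-step
        vy = sy ** 2 + tau2
        prec = 1.0 / sigma02 + 1.0 / sx ** 2 + beta ** 2 / vy
        var_g = 1.0 / prec
        mu_g = var_g * (bx / sx ** 2 + beta * by / vy)
        eg2 = mu_g ** 2 + var_g
        # M-step: beta closed form
        beta = float(np.sum(w * mu_g * by / vy) / np.sum(w * eg2 / vy))
        # sigma0^2 closed form (with inverse-gamma prior)
        sigma02 = float((np.sum(w * eg2) + 2 * _PRIOR_B) / (sw + 2 * (_PRIOR_A + 1)))
        # tau^2 by 1-d maximization of the expected complete-data objective
        r2 = (by - beta * mu_g) ** 2 + beta ** 2 * var_g

        def neg_obj(log_t2):
            t2 = np.exp(log_t2)
            v = sy ** 2 + t2
            val = -0.5 * np.sum(w * (np.log(v) + r2 / v))
            val += -(_PRIOR_A + 1) * log_t2 - _PRIOR_B / t2
            return -val

        res = optimize.minimize_scalar(neg_obj, bounds=(np.log(1e-12), np.log(1e2)),
                                       method="bounded", options={"xatol": 1e-10})
        tau2 = float(np.exp(res.x))
        elbo, _, _ = _elbo(bx, by, sx, sy, w, beta, sigma02, tau2)
        trace.append(elbo)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            break
    return beta, sigma02, tau2, trace


def _weights(bx, by, sx, sy, beta, sigma02, tau2):
    """Evidence-based down-weighting from the standardized marginal residual of by."""
    v_x = sigma02 + sx ** 2
    c_xy = beta * sigma02
    v_y = beta ** 2 * sigma02 + tau2 + sy ** 2
    mu = c_xy / v_x * bx           # E[by | bx]
    var = v_y - c_xy ** 2 / v_x    # Var[by | bx]
    d2 = (by - mu) ** 2 / var
    return np.minimum(1.0, np.exp(0.5 * (_WEIGHT_C ** 2 - d2)))


def bwmr_fit(
    pairs: Sequence,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    n_rounds: int = 3,
) -> BwmrFit:
    """Fit the Bayesian-weighted MR model.

    ``seed`` is accepted for interface uniformity; the fit itself is
    deterministic (variational EM from a fixed IVW start). ``elbo_trace``
    records the final reweighting round, within which the ELBO is
    non-decreasing by EM monotonicity.
    """
    bx, by, sx, sy = extract_pairs(pairs)
    J = bx.size
    if J < 3:
        raise InsufficientInstrumentsError(f"BWMR needs >= 3 instruments (got {J})")

    beta = ivw((bx, by, sx, sy), mode="fixed").beta
    sigma02 = float(np.var(bx, ddof=1)) or 1e-4
    tau2 = 1e-6
    w = np.ones(J)
    trace: list[float] = []
    converged = True
    for rnd in range(n_rounds):
        beta, sigma02, tau2, trace = _em_round(
            bx, by, sx, sy, w, beta, sigma02, tau2, max_iter, tol
        )
        if len(trace) >= max_iter:
            converged = False
        if rnd < n_rounds - 1:
            w = _weights(bx, by, sx, sy, beta, sigma02, tau2)

    # SE from the curvature of the weighted profile log-likelihood in beta
    def profile(b):
        return _weighted_loglik(bx, by, sx, sy, w, b, sigma02, tau2)

    h = max(1e-5, 1e-4 * abs(beta))
    d2 = (profile(beta + h) - 2.0 * profile(beta) + profile(beta - h)) / h ** 2
    se = float(1.0 / np.sqrt(max(-d2, 1e-12)))
    pval = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
    return BwmrFit(beta=float(beta), se=se, pval=pval, tau2=tau2, sigma02=sigma02,
                   weights=w, elbo_trace=trace, converged=converged, n_snp=J)
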