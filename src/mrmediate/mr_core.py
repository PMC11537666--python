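"""Two-sample MR estimators from harmonized per-SNP effect pairs.

Given J harmonized instruments with exposure effects ``bx`` (SE ``sx``) and
outcome effects ``by`` (SE ``sy``), the estimators implemented here are:

* inverse-variance weighting (IVW): the zero-intercept weighted regression of
  ``by`` on ``bx`` with weights 1/sy², in fixed-effect and multiplicative
  random-effects flavours;
* MR-Egger: the same regression with a free intercept, whose intercept
  estimates directional pleiotropy;
* the weighted median of per-SNP Wald ratios, consistent when at least half
  the weight comes from valid instruments;
* simple and weighted mode estimators, the mode of a kernel-smoothed density
  of the Wald ratios;
* the Wald ratio itself for the single-instrument fallback.

All causal effects are on the scale of the outcome betas (log-odds for
case-control outcomes); results carry the exponentiated effect as an odds
ratio with matching CI.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError
from .gwas_io import HarmonizedPair


@dataclass
class MRResult:
    """Causal estimate from one MR method."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    n_snp: int
    info: dict = field(default_factory=dict)


def extract_pairs(pairs: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pull (bx, by, sx, sy) arrays from analyzable harmonized pairs.

    Accepts a list of :class:`~mrmediate.gwas_io.HarmonizedPair` (dropped
    entries are excluded) or a 4-tuple of array-likes.
    """
    if len(pairs) == 4 and not isinstance(pairs[0], HarmonizedPair) and np.ndim(pairs[0]) >= 1:
        bx, by, sx, sy = (np.asarray(a, dtype=float) for a in pairs)
        return bx, by, sx, sy
    kept = [p for p in pairs if p.analyzable()]
    bx = np.array([p.beta_exp for p in kept], dtype=float)
    by = np.array([p.beta_out for p in kept], dtype=float)
    sx = np.array([p.se_exp for p in kept], dtype=float)
    sy = np.array([p.se_out for p in kept], dtype=float)
    return bx, by, sx, sy


def _finish(method: str, beta: float, se: float, n_snp: int, info: dict | None = None) -> MRResult:
    z = stats.norm.ppf(0.975)
    lo, hi = beta - z * se, beta + z * se
    pval = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    pval = min(max(pval, np.nextafter(0, 1)), 1.0)
    with np.errstate(over="ignore"):  # extreme CIs exponentiate to inf, which is fine
        or_, or_lo, or_hi = np.exp(beta), np.exp(lo), np.exp(hi)
    return MRResult(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(lo), ci_high=float(hi), pval=pval,
        odds_ratio=float(or_), or_ci_low=float(or_lo), or_ci_high=float(or_hi),
        n_snp=n_snp, info=dict(info or {}),
    )


def wald_ratio(pairs: Sequence) -> MRResult:
    """Single-instrument ratio estimate by = beta_out / beta_exp (first-order SE)."""
    bx, by, sx, sy = extract_pairs(pairs)
    if bx.size != 1:
        raise InsufficientInstrumentsError("wald_ratio takes exactly one instrument")
    beta = by[0] / bx[0]
    se = abs(sy[0] / bx[0])
    return _finish("Wald_ratio", beta, se, 1)


def cochran_q_from_fit(bx, by, sy, fitted: np.ndarray) -> float:
    return float(np.sum(((by - fitted) / sy) ** 2))


def ivw(pairs: Sequence, mode: str = "fixed") -> MRResult:
    """Inverse-variance-weighted estimate.

    ``fixed`` uses SE = (sum w bx²)^(-1/2); ``random`` inflates it by
    max(1, sqrt(Q/(J-1))) (multiplicative random effects).
    """
    bx, by, sx, sy = extract_pairs(pairs)
    J = bx.size
    if J < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs >= 2 instruments (got {J}); use wald_ratio for a single SNP"
        )
    w = 1.0 / sy ** 2
    sww = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by)) / sww
    se_fixed = sww ** -0.5
    q = cochran_q_from_fit(bx, by, sy, beta * bx)
    se = se_fixed
    if mode == "random":
        se = se_fixed * max(1.0, np.sqrt(q / (J - 1)))
    elif mode != "fixed":
        raise ValueError("mode must be 'fixed' or 'random'")
    return _finish(f"IVW_{mode}", beta, se, J, info={"Q": q, "Q_df": J - 1})


def egger(pairs: Sequence) -> tuple[MRResult, float, float]:
    """MR-Egger regression: weighted fit of by on bx with a free intercept.

    Pairs are oriented so every bx >= 0 before fitting (the estimate must not
    depend on which allele was coded as effect allele). Returns the slope
    result plus the intercept and its SE for the pleiotropy test. Slope and
    intercept SEs use a multiplicative dispersion factor max(1, Q/(J-2)).
    """
    bx, by, sx, sy = extract_pairs(pairs)
    J = bx.size
    if J < 3:
        raise InsufficientInstrumentsError(f"Egger needs >= 3 instruments (got {J})")
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    w = 1.0 / sy ** 2
    # weighted normal equations for [intercept, slope]
    s0, s1, s2 = np.sum(w), np.sum(w * x), np.sum(w * x ** 2)
    t0, t1 = np.sum(w * y), np.sum(w * x * y)
    det = s0 * s2 - s1 ** 2
    intercept = (s2 * t0 - s1 * t1) / det
    slope = (s0 * t1 - s1 * t0) / det
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid ** 2))
    disp = max(1.0, q / (J - 2)) if J > 2 else 1.0
    var_int = disp * s2 / det
    var_slope = disp * s0 / det
    result = _finish(
        "Egger", slope, np.sqrt(var_slope), J,
        info={"Q": q, "Q_df": J - 2, "intercept": float(intercept),
              "intercept_se": float(np.sqrt(var_int))},
    )
    return result, float(intercept), float(np.sqrt(var_int))


def _ratio_weights(pairs, weighted: bool):
    bx, by, sx, sy = extract_pairs(pairs)
    nonzero = bx != 0
    if not np.all(nonzero):
        warnings.warn(
            f"excluding {int(np.sum(~nonzero))} pair(s) with beta_exp = 0 from ratio-based estimator",
            stacklevel=3,
        )
    bx, by, sx, sy = bx[nonzero], by[nonzero], sx[nonzero], sy[nonzero]
    ratios = by / bx
    w = bx ** 2 / sy ** 2 if weighted else np.ones_like(ratios)
    return bx, by, sx, sy, ratios, w


def weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    """Linearly interpolated weighted percentile (cumulative mass at bin centres)."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    if q <= cum[0]:
        return float(v[0])
    if q >= cum[-1]:
        return float(v[-1])
    return float(np.interp(q, cum, v))


def weighted_median(pairs: Sequence, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of Wald ratios; SE by parametric bootstrap (fixed seed)."""
    bx, by, sx, sy, ratios, w = _ratio_weights(pairs, weighted=True)
    J = ratios.size
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 usable instruments (got {J})")
    beta = weighted_percentile(ratios, w, 0.5)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.normal(0.0, sx)
        byb = by + rng.normal(0.0, sy)
        ok = bxb != 0
        rb = byb[ok] / bxb[ok]
        wb = bxb[ok] ** 2 / sy[ok] ** 2
        boots[b] = weighted_percentile(rb, wb, 0.5)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", beta, se, J, info={"seed": seed, "n_boot": n_boot})


def _silverman_bandwidth(ratios: np.ndarray, factor: float) -> float:
    # modified Silverman rule: robust spread estimate, n^(-1/5) rate
    n = ratios.size
    sd = np.std(ratios, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return factor * 0.9 * spread * n ** (-1 / 5)


def _density_mode(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    if h <= 0:
        # degenerate spread: all mass at (weighted) modal point
        return float(ratios[np.argmax(weights)]) if np.ptp(ratios) == 0 else float(np.median(ratios))
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_estimators(
    pairs: Sequence,
    kind: str = "simple",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Mode-based estimate: argmax of the smoothed density of Wald ratios.

    ``simple`` weights every ratio equally; ``weighted`` uses inverse-variance
    weights bx²/sy². Bandwidth is ``bandwidth_factor`` times a modified
    Silverman rule on the ratios; SE by parametric bootstrap.
    """
    if kind not in ("simple", "weighted"):
        raise ValueError("kind must be 'simple' or 'weighted'")
    bx, by, sx, sy, ratios, w = _ratio_weights(pairs, weighted=(kind == "weighted"))
    J = ratios.size
    if J < 3:
        raise InsufficientInstrumentsError(f"mode estimator needs >= 3 usable instruments (got {J})")
    if np.ptp(ratios) == 0:
        return _finish(f"{kind}_mode", float(ratios[0]), 0.0, J, info={"seed": seed})
    h = _silverman_bandwidth(ratios, bandwidth_factor)
    beta = _density_mode(ratios, w / w.sum(), h)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.normal(0.0, sx)
        byb = by + rng.normal(0.0, sy)
        ok = bxb != 0
        rb = byb[ok] / bxb[ok]
        wb = bxb[ok] ** 2 / sy[ok] ** 2 if kind == "weighted" else np.ones(ok.sum())
        hb = _silverman_bandwidth(rb, bandwidth_factor)
        boots[b] = _density_mode(rb, wb / wb.sum(), hb)
    se = float(np.std(boots, ddof=1))
    return _finish(f"{kind}_mode", beta, se, J, info={"seed": seed, "bandwidth": h, "n_boot": n_boot})


def run_methods(
    pairs: Sequence,
    methods: Sequence[str] = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"),
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MRResult]:
    """Run a battery of estimators, falling back to the Wald ratio for one SNP."""
    bx, _, _, _ = extract_pairs(pairs)
    if bx.size == 1:
        return [wald_ratio(pairs)]
    results: list[MRResult] = []
    for m in methods:
        try:
            if m == "ivw":
                results.append(ivw(pairs, mode="fixed"))
                results.append(ivw(pairs, mode="random"))
            elif m == "egger":
                results.append(egger(pairs)[0])
            elif m == "weighted_median":
                results.append(weighted_median(pairs, n_boot=n_boot, seed=seed))
            elif m == "simple_mode":
                results.append(mode_estimators(pairs, "simple", n_boot=n_boot, seed=seed))
            elif m == "weighted_mode":
                results.append(mode_estimators(pairs, "weighted", n_boot=n_boot, seed=seed))
            elif m == "bwmr":
                from .bwmr import bwmr_fit
                results.append(bwmr_fit(pairs, seed=seed).to_mr_result())
            else:
                raise ValueError(f"unknown method {m!r}")
        except InsufficientInstrumentsError:
            continue
    return results
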