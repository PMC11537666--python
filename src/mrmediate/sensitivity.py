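"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

The battery mirrors standard two-sample MR practice: Cochran's Q for
heterogeneity under the IVW and Egger fits, the Egger intercept as a test of
directional pleiotropy, an MR-PRESSO-style residual-sum-of-squares simulation
test that detects and removes outlying instruments, and leave-one-out IVW
refits to flag influential single SNPs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .mr_core import MRResult, egger, extract_pairs, ivw


@dataclass
class HeterogeneityResult:
    method: str          # IVW | Egger
    q: float
    q_df: int
    q_pval: float


@dataclass
class PleiotropyResult:
    egger_intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class PressoResult:
    global_pval: float
    outlier_ids: list[str] = field(default_factory=list)
    outlier_pvals: dict = field(default_factory=dict)
    distortion_pval: float | None = None
    beta_raw: MRResult | None = None
    beta_corrected: MRResult | None = None


def _ids(pairs) -> list[str]:
    try:
        return [p.variant_id for p in pairs if p.analyzable()]
    except AttributeError:
        return [f"snp_{i}" for i in range(len(extract_pairs(pairs)[0]))]


def cochran_q(pairs: Sequence, fit: str = "IVW") -> HeterogeneityResult:
    """Q = sum of squared standardized residuals about the chosen fit.

    df = J-1 for the zero-intercept IVW fit, J-2 for Egger; p from the
    upper tail of the chi-square distribution.
    """
    bx, by, sx, sy = extract_pairs(pairs)
    J = bx.size
    if fit.upper() == "IVW":
        res = ivw(pairs, mode="fixed")
        fitted = res.beta * bx
        df = J - 1
    elif fit.lower() == "egger":
        res, intercept, _ = egger(pairs)
        sign = np.where(bx < 0, -1.0, 1.0)
        fitted = sign * (intercept + res.beta * bx * sign)
        df = J - 2
    else:
        raise ValueError("fit must be 'IVW' or 'Egger'")
    q = float(np.sum(((by - fitted) / sy) ** 2))
    pval = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return HeterogeneityResult(method="IVW" if fit.upper() == "IVW" else "Egger",
                               q=q, q_df=df, q_pval=pval)


def egger_intercept_test(pairs: Sequence) -> PleiotropyResult:
    """Directional-pleiotropy test: two-sided normal p for the Egger intercept."""
    _, intercept, intercept_se = egger(pairs)
    pval = float(2.0 * stats.norm.sf(abs(intercept) / intercept_se))
    return PleiotropyResult(egger_intercept=intercept, intercept_se=intercept_se,
                            intercept_pval=pval)


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes, vectorized over the left-out index."""
    s1 = np.sum(w * bx ** 2)
    s2 = np.sum(w * bx * by)
    return (s2 - w * bx * by) / (s1 - w * bx ** 2)


def mr_presso(
    pairs: Sequence,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    significance: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test.

    Global test: the observed RSS of standardized residuals about
    leave-one-out IVW predictions is compared to a parametric-bootstrap null
    (``n_sim`` simulated datasets drawn about the LOO fitted values with the
    observed SEs). Per-SNP outlier test: each SNP's observed squared residual
    against its own simulated distribution, Bonferroni-adjusted; outliers are
    only called when the global test is significant. Distortion test: the
    relative change of the IVW estimate after outlier removal, referred to a
    null built by removing random same-size subsets. Empirical p-values use
    the (r+1)/(n+1) convention.
    """
    bx, by, sx, sy = extract_pairs(pairs)
    ids = _ids(pairs)
    J = bx.size
    if J < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments (got {J})")
    w = 1.0 / sy ** 2
    rng = np.random.default_rng(seed)

    slopes_loo = _loo_slopes(bx, by, w)
    obs_resid2 = ((by - slopes_loo * bx) / sy) ** 2
    rss_obs = float(np.sum(obs_resid2))

    # parametric bootstrap about the LOO expectations
    bx_sim = bx + rng.normal(0.0, sx, size=(n_sim, J))
    by_sim = slopes_loo * bx_sim + rng.normal(0.0, sy, size=(n_sim, J))
    s1 = np.sum(w * bx_sim ** 2, axis=1, keepdims=True)
    s2 = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    slopes_sim = (s2 - w * bx_sim * by_sim) / (s1 - w * bx_sim ** 2)
    resid2_sim = ((by_sim - slopes_sim * bx_sim) / sy) ** 2
    rss_sim = np.sum(resid2_sim, axis=1)

    global_pval = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    result = PressoResult(global_pval=global_pval, beta_raw=ivw(pairs, mode="random"))

    if global_pval < significance:
        p_raw = (np.sum(resid2_sim >= obs_resid2[None, :], axis=0) + 1) / (n_sim + 1)
        p_adj = np.minimum(p_raw * J, 1.0)
        out_mask = p_adj < outlier_alpha
        result.outlier_ids = [ids[i] for i in np.flatnonzero(out_mask)]
        result.outlier_pvals = {ids[i]: float(p_adj[i]) for i in range(J)}
        if result.outlier_ids and J - len(result.outlier_ids) >= 2:
            keep = ~out_mask
            sub = (bx[keep], by[keep], sx[keep], sy[keep])
            result.beta_corrected = ivw(sub, mode="random")
            # distortion: relative shift vs removing random same-size subsets
            n_out = int(out_mask.sum())
            obs_d = (result.beta_raw.beta - result.beta_corrected.beta) / abs(result.beta_corrected.beta)
            clean_idx = np.flatnonzero(keep)
            n_draw = min(n_sim, 1000)
            dists = np.empty(n_draw)
            for b in range(n_draw):
                drop = rng.choice(clean_idx, size=n_out, replace=False)
                mask = np.ones(J, dtype=bool)
                mask[drop] = False
                sub_b = (bx[mask], by[mask], sx[mask], sy[mask])
                beta_b = ivw(sub_b, mode="fixed").beta
                dists[b] = (result.beta_raw.beta - beta_b) / abs(beta_b)
            result.distortion_pval = float(
                (np.sum(np.abs(dists) >= abs(obs_d)) + 1) / (n_draw + 1)
            )
    return result


def leave_one_out(pairs: Sequence) -> list[tuple[str, MRResult]]:
    """IVW refit omitting each instrument in turn (influence diagnostic)."""
    bx, by, sx, sy = extract_pairs(pairs)
    ids = _ids(pairs)
    J = bx.size
    if J < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 3 instruments (got {J})")
    results = []
    for j in range(J):
        mask = np.ones(J, dtype=bool)
        mask[j] = False
        sub = (bx[mask], by[mask], sx[mask], sy[mask])
        results.append((ids[j], ivw(sub, mode="fixed")))
    return results


def sensitivity_table(
    pairs: Sequence,
    exposure: str = "exposure",
    outcome: str = "outcome",
    presso_nsim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Three-row report per exposure: Egger, IVW (heterogeneity) and MR-PRESSO.

    Columns: Q / Q_df / Q_pval for the two fits, the Egger intercept with SE
    and p on the Egger row, the PRESSO global p on its row, and a pass flag
    (p > alpha means the diagnostic raises no concern).
    """
    het_egger = cochran_q(pairs, "Egger")
    het_ivw = cochran_q(pairs, "IVW")
    pleio = egger_intercept_test(pairs)
    presso = mr_presso(pairs, n_sim=presso_nsim, seed=seed)
    rows = [
        {
            "exposure": exposure, "outcome": outcome, "method": "MR Egger",
            "Q": het_egger.q, "Q_df": het_egger.q_df, "Q_pval": het_egger.q_pval,
            "egger_intercept": pleio.egger_intercept,
            "intercept_se": pleio.intercept_se, "intercept_pval": pleio.intercept_pval,
            "pval": pleio.intercept_pval,
            "pass": het_egger.q_pval > alpha and pleio.intercept_pval > alpha,
        },
        {
            "exposure": exposure, "outcome": outcome, "method": "IVW",
            "Q": het_ivw.q, "Q_df": het_ivw.q_df, "Q_pval": het_ivw.q_pval,
            "egger_intercept": None, "intercept_se": None, "intercept_pval": None,
            "pval": None,
            "pass": het_ivw.q_pval > alpha,
        },
        {
            "exposure": exposure, "outcome": outcome, "method": "MR-PRESSO",
            "Q": None, "Q_df": None, "Q_pval": None,
            "egger_intercept": None, "intercept_se": None, "intercept_pval": None,
            "pval": presso.global_pval,
            "pass": presso.global_pval > alpha,
        },
    ]
    return pd.DataFrame(rows)
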