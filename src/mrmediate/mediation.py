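"""Two-step MR mediation analysis.

The total effect of an exposure on the outcome is decomposed through a
mediator using three two-sample MR estimates:

* total:  exposure -> outcome;
* beta1:  exposure -> mediator (step 1);
* beta2:  mediator -> outcome (step 2, instrumented by the mediator's SNPs).

The indirect (mediated) effect is the product beta1*beta2, the direct effect
is total - indirect, and the mediation proportion is 100*indirect/total.
Uncertainty for the product uses the first-order delta method:
Var(b1*b2) = b1^2*se2^2 + b2^2*se1^2 (an option adds the second-order term
se1^2*se2^2). All effects must share a scale — log-odds for a binary
outcome.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, PipelineError
from .gwas_io import SummaryStatRecord, harmonize
from .instruments import ClumpSpec, clump, filter_weak_instruments, select_by_pvalue
from .mr_core import MRResult, ivw, wald_ratio

Z95 = stats.norm.ppf(0.975)


@dataclass
class MediationResult:
    total_effect: float
    se_total: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    direct: float
    proportion: float | None          # percent of total effect mediated
    ci_indirect: tuple[float, float]
    ci_proportion: tuple[float, float] | None = None
    legs: dict = field(default_factory=dict)  # MRResult per leg when run from datasets


def two_step_mediation(
    total: tuple[float, float],
    step1: tuple[float, float],
    step2: tuple[float, float],
    second_order: bool = False,
) -> MediationResult:
    """Combine three (estimate, SE) pairs into a mediation decomposition.

    ``total`` is the exposure->outcome effect, ``step1`` the
    exposure->mediator effect (beta1), ``step2`` the mediator->outcome effect
    (beta2). The total effect is an independently estimated quantity, not
    reconstructed from the two steps.
    """
    t, se_t = total
    b1, se1 = step1
    b2, se2 = step2
    indirect = b1 * b2
    var = b1 ** 2 * se2 ** 2 + b2 ** 2 * se1 ** 2
    if second_order:
        var += se1 ** 2 * se2 ** 2
    se_ind = float(np.sqrt(var))
    direct = t - indirect
    ci_ind = (indirect - Z95 * se_ind, indirect + Z95 * se_ind)

    proportion: float | None
    ci_prop: tuple[float, float] | None
    if t == 0:
        warnings.warn("total effect is zero: mediation proportion undefined", stacklevel=2)
        proportion, ci_prop = None, None
    else:
        proportion = 100.0 * indirect / t
        # delta method on the ratio, treating the two estimates as independent
        var_ratio = var / t ** 2 + (indirect * se_t) ** 2 / t ** 4
        se_prop = 100.0 * float(np.sqrt(var_ratio))
        ci_prop = (proportion - Z95 * se_prop, proportion + Z95 * se_prop)
    return MediationResult(
        total_effect=t, se_total=se_t, beta1=b1, se1=se1, beta2=b2, se2=se2,
        indirect=indirect, se_indirect=se_ind, direct=direct,
        proportion=proportion, ci_indirect=ci_ind, ci_proportion=ci_prop,
    )


def _mr_leg(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    p_threshold: float,
    clump_spec: ClumpSpec | None,
    f_min: float,
    leg: str,
    ld=None,
    drop_all_palindromic: bool = True,
) -> MRResult:
    """One two-sample MR leg: select instruments, harmonize, IVW (or Wald ratio)."""
    selected = select_by_pvalue(exposure, p_threshold)
    if clump_spec is not None:
        selected = clump(selected, clump_spec, ld=ld)
    selected = filter_weak_instruments(selected, f_min)
    if not selected:
        raise PipelineError(f"{leg}: no instruments survive selection")
    pairs = harmonize(selected, list(outcome), drop_all_palindromic=drop_all_palindromic)
    usable = [p for p in pairs if p.analyzable()]
    if len(usable) == 0:
        raise PipelineError(f"{leg}: no instruments survive harmonization")
    try:
        if len(usable) == 1:
            return wald_ratio(usable)
        # heterogeneity-guided IVW: fixed effects unless Cochran Q flags
        # overdispersion, then multiplicative random effects
        result = ivw(usable, mode="fixed")
        q_pval = stats.chi2.sf(result.info["Q"], result.info["Q_df"])
        if q_pval <= 0.05:
            result = ivw(usable, mode="random")
        return result
    except InsufficientInstrumentsError as exc:  # pragma: no cover - guarded above
        raise PipelineError(f"{leg}: {exc}") from exc


def mediation_pipeline(
    exposure: Sequence[SummaryStatRecord],
    mediator: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    p_threshold: float = 1e-5,
    clump_spec: ClumpSpec | None = None,
    f_min: float = 10.0,
    ld=None,
    drop_all_palindromic: bool = True,
    second_order: bool = False,
) -> MediationResult:
    """Run the three MR legs from raw summary statistics and combine them.

    Instrument selection (p-value threshold, optional clumping, F > f_min)
    and harmonization are applied per leg: the exposure's instruments serve
    the total and step-1 legs, the mediator's own instruments serve step 2.
    """
    total = _mr_leg(exposure, outcome, p_threshold, clump_spec, f_min,
                    "exposure->outcome (total)", ld, drop_all_palindromic)
    leg1 = _mr_leg(exposure, mediator, p_threshold, clump_spec, f_min,
                   "exposure->mediator (beta1)", ld, drop_all_palindromic)
    leg2 = _mr_leg(mediator, outcome, p_threshold, clump_spec, f_min,
                   "mediator->outcome (beta2)", ld, drop_all_palindromic)
    result = two_step_mediation(
        (total.beta, total.se), (leg1.beta, leg1.se), (leg2.beta, leg2.se),
        second_order=second_order,
    )
    result.legs = {"total": total, "step1": leg1, "step2": leg2}
    return result
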