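"""Synthetic GWAS summary statistics with known causal ground truth.

The generator emulates the structure of a two-sample MR mediation study:

* an exposure GWAS (a flow-cytometry immune trait scale, N ~ 3757);
* a mediator GWAS (a circulating-protein meta-analysis scale, N ~ 14,824);
* a binary-outcome case-control GWAS reporting log-odds effects
  (N ~ 160,589 with ~0.9% cases).

The structural model is linear: the mediator is M = theta1*X + e, the
outcome liability carries theta2*M + theta_direct*X, and causal parameters
are expressed directly on the log-odds scale so the ground-truth total
effect of X on Y is exactly theta_direct + theta1*theta2. Summary-statistic
noise follows the standard per-allele approximation for a standardized
trait, SE = (2*N*maf*(1-maf))^(-1/2); for the case-control outcome the
effective sample size N*v*(1-v) replaces N. Invalid instruments receive
additive pleiotropic outcome effects (directional when the mean is
nonzero); a configurable fraction of SNPs is made palindromic (A/T or C/G)
and a fraction of outcome rows is presented with swapped alleles so the
harmonization path is exercised end to end.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .gwas_io import SummaryStatRecord, flip_record

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class TripletConfig:
    """Generative parameters for one exposure–mediator–outcome triplet."""

    n_snps_exposure: int = 30      # true instruments for the exposure
    n_snps_mediator: int = 30      # true instruments specific to the mediator
    n_snps_outcome: int = 0        # SNPs acting on the outcome only (reverse-MR fodder)
    n_null_snps: int = 40          # SNPs with no effect anywhere
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 3757
    n_med: int = 14_824
    n_out: int = 160_589
    case_fraction: float = 1388 / 160_589
    theta1: float = 0.0            # exposure -> mediator
    theta2: float = 0.0            # mediator -> outcome (log-odds per mediator SD)
    theta_direct: float = 0.0      # exposure -> outcome not via mediator (log-odds)
    r2_exposure: float = 0.08      # total exposure variance explained by its instruments
    r2_mediator: float = 0.08
    r2_outcome: float = 0.02       # liability-scale variance for outcome-only SNPs
    pleiotropy_frac: float = 0.0   # fraction of exposure instruments that are invalid
    pleiotropy_mean: float = 0.0   # mean pleiotropic outcome effect (directional if != 0)
    pleiotropy_sd: float = 0.0
    include_palindromic: float = 0.0  # fraction of all SNPs given A/T or C/G alleles
    swap_outcome_frac: float = 0.0    # fraction of outcome rows written allele-swapped
    seed: int = 0
    structure_seed: int | None = None  # shared truth across cohorts; None -> seed

    @property
    def total_effect(self) -> float:
        return self.theta_direct + self.theta1 * self.theta2

    def validate(self) -> None:
        for name in ("pleiotropy_frac", "include_palindromic", "swap_outcome_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not (0.0 < self.case_fraction < 1.0):
            raise ConfigurationError("case_fraction must be in (0, 1)")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("r2_exposure", "r2_mediator", "r2_outcome"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi < 1")


@dataclass
class TruthRecord:
    """Everything the generator knows that an analyst would not."""

    theta1: float
    theta2: float
    theta_direct: float
    total_effect: float
    exposure_instruments: list[str]
    mediator_instruments: list[str]
    outcome_instruments: list[str]
    pleiotropic_ids: list[str]
    per_snp_beta_exposure: dict = field(default_factory=dict)
    config: TripletConfig | None = None


@dataclass
class TripletData:
    exposure: list[SummaryStatRecord]
    mediator: list[SummaryStatRecord]
    outcome: list[SummaryStatRecord]
    truth: TruthRecord


def _scaled_effects(rng, mafs, target_r2):
    """Per-allele effects scaled so the total variance explained is exactly target_r2."""
    z = rng.standard_normal(mafs.size)
    het = 2.0 * mafs * (1.0 - mafs)
    denom = np.sum(z ** 2 * het)
    if denom == 0:
        return np.zeros_like(mafs)
    return z * np.sqrt(target_r2 / denom)


def _alleles(rng, n, palindromic_fraction):
    n_pal = int(round(palindromic_fraction * n))
    pairs = [
        _PALINDROMIC[rng.integers(len(_PALINDROMIC))] if i < n_pal
        else _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        for i in range(n)
    ]
    rng.shuffle(pairs)
    return pairs


def _records(ids, chroms, positions, alleles, mafs, betas, ses, n):
    recs = []
    for i, vid in enumerate(ids):
        beta = float(betas[i])
        se = float(ses[i])
        pval = float(min(max(2.0 * stats.norm.sf(abs(beta) / se), np.nextafter(0, 1)), 1.0))
        recs.append(SummaryStatRecord(
            variant_id=vid, chrom=str(chroms[i]), pos=int(positions[i]),
            effect_allele=alleles[i][0], other_allele=alleles[i][1],
            eaf=float(mafs[i]), beta=beta, se=se, pval=pval, n=float(n),
        ))
    return recs


def simulate_triplet(config: TripletConfig) -> TripletData:
    """Generate exposure, mediator and outcome summary statistics plus the truth.

    ``structure_seed`` fixes the generative truth (MAFs, alleles, true SNP
    effects, pleiotropy assignments); ``seed`` drives the sampling noise. Two
    configs sharing a ``structure_seed`` but differing in ``seed`` emulate
    independent GWAS cohorts of the same traits, as needed for multi-cohort
    validation.
    """
    config.validate()
    s_seed = config.seed if config.structure_seed is None else config.structure_seed
    # distinct stream keys: structure and noise must stay independent even
    # when the two seeds coincide
    rng = np.random.default_rng([s_seed, 0])
    noise_rng = np.random.default_rng([config.seed, 1])

    n_x, n_m, n_y, n_0 = (config.n_snps_exposure, config.n_snps_mediator,
                          config.n_snps_outcome, config.n_null_snps)
    total = n_x + n_m + n_y + n_0
    if total == 0:
        raise ConfigurationError("no SNPs requested")

    ids = [f"rs{i + 1:07d}" for i in range(total)]
    chroms = [str(i % 22 + 1) for i in range(total)]
    positions = [20_000_000 * (i // 22 + 1) for i in range(total)]  # > clump window apart
    mafs = rng.uniform(*config.maf_range, size=total)
    alleles = _alleles(rng, total, config.include_palindromic)
    het = 2.0 * mafs * (1.0 - mafs)

    # true per-allele effects on each trait
    b_x = np.zeros(total)   # SNP -> exposure
    g_m = np.zeros(total)   # SNP -> mediator, direct (mediator's own instruments)
    g_y = np.zeros(total)   # SNP -> outcome, direct (outcome's own instruments)
    sl_x = slice(0, n_x)
    sl_m = slice(n_x, n_x + n_m)
    sl_y = slice(n_x + n_m, n_x + n_m + n_y)
    b_x[sl_x] = _scaled_effects(rng, mafs[sl_x], config.r2_exposure) if n_x else 0.0
    if n_m:
        g_m[sl_m] = _scaled_effects(rng, mafs[sl_m], config.r2_mediator)
    if n_y:
        g_y[sl_y] = _scaled_effects(rng, mafs[sl_y], config.r2_outcome)

    # pleiotropic outcome effects on a subset of exposure instruments
    n_pleio = int(round(config.pleiotropy_frac * n_x))
    pleio_idx = rng.choice(n_x, size=n_pleio, replace=False) if n_pleio else np.array([], dtype=int)
    alpha = np.zeros(total)
    if n_pleio:
        alpha[pleio_idx] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, n_pleio)

    # structural model on the common (log-odds for Y) scale
    b_m = g_m + config.theta1 * b_x
    b_y = g_y + config.theta2 * b_m + config.theta_direct * b_x + alpha

    se_x = 1.0 / np.sqrt(config.n_exp * het)
    se_m = 1.0 / np.sqrt(config.n_med * het)
    v = config.case_fraction
    neff = config.n_out * v * (1.0 - v)
    se_y = 1.0 / np.sqrt(neff * het)

    # feasibility: instruments should be detectable in principle
    if n_x and config.r2_exposure > 0:
        mean_chi2 = config.n_exp * config.r2_exposure / n_x
        if mean_chi2 < 1.0:
            raise ConfigurationError(
                "r2_exposure infeasible for n_exp: expected per-SNP chi-square < 1"
            )

    bx_hat = b_x + noise_rng.normal(0.0, se_x)
    bm_hat = b_m + noise_rng.normal(0.0, se_m)
    by_hat = b_y + noise_rng.normal(0.0, se_y)

    exposure = _records(ids, chroms, positions, alleles, mafs, bx_hat, se_x, config.n_exp)
    mediator = _records(ids, chroms, positions, alleles, mafs, bm_hat, se_m, config.n_med)
    outcome = _records(ids, chroms, positions, alleles, mafs, by_hat, se_y, config.n_out)

    if config.swap_outcome_frac > 0:
        n_swap = int(round(config.swap_outcome_frac * total))
        swap_idx = set(noise_rng.choice(total, size=n_swap, replace=False).tolist())
        outcome = [flip_record(r) if i in swap_idx else r for i, r in enumerate(outcome)]

    truth = TruthRecord(
        theta1=config.theta1, theta2=config.theta2, theta_direct=config.theta_direct,
        total_effect=config.total_effect,
        exposure_instruments=ids[sl_x], mediator_instruments=ids[sl_m],
        outcome_instruments=ids[sl_y],
        pleiotropic_ids=[ids[i] for i in pleio_idx],
        per_snp_beta_exposure={ids[i]: float(b_x[i]) for i in range(n_x)},
        config=config,
    )
    return TripletData(exposure=exposure, mediator=mediator, outcome=outcome, truth=truth)


@dataclass
class ScreenPanel:
    exposures: dict            # name -> list[SummaryStatRecord]
    outcome: list[SummaryStatRecord]
    truth: "object"            # pandas.DataFrame: exposure, causal, effect


def simulate_screen_panel(
    n_exposures: int,
    n_causal: int,
    template: TripletConfig,
    effect_size: float | None = None,
) -> ScreenPanel:
    """Many exposures screened against one shared outcome.

    The first ``n_causal`` exposures receive a true causal effect on the
    outcome (``effect_size``, defaulting to the template's total effect);
    the rest are null. Each exposure carries its own disjoint instrument
    set; the outcome dataset is the union of all SNPs. Per-exposure seeds
    derive from the panel seed, so the panel is reproducible as a whole.
    """
    import pandas as pd

    if n_causal > n_exposures:
        raise ConfigurationError("n_causal must be <= n_exposures")
    if effect_size is None:
        effect_size = template.total_effect

    rng = np.random.default_rng(template.seed)
    exposures: dict[str, list[SummaryStatRecord]] = {}
    outcome_all: list[SummaryStatRecord] = []
    rows = []
    for i in range(n_exposures):
        causal = i < n_causal
        sub_seed = int(rng.integers(2 ** 31 - 1))
        cfg = replace(
            template,
            seed=sub_seed,
            n_snps_mediator=0, n_snps_outcome=0,
            theta1=0.0, theta2=0.0,
            theta_direct=effect_size if causal else 0.0,
        )
        trip = simulate_triplet(cfg)
        name = f"exposure_{i + 1:03d}"
        prefix = f"e{i + 1:03d}_"
        exposures[name] = [replace(r, variant_id=prefix + r.variant_id) for r in trip.exposure]
        outcome_all.extend(replace(r, variant_id=prefix + r.variant_id) for r in trip.outcome)
        rows.append({"exposure": name, "causal": causal,
                     "effect": effect_size if causal else 0.0})
    return ScreenPanel(exposures=exposures, outcome=outcome_all,
                       truth=pd.DataFrame(rows))
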