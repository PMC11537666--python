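"""Instrument selection and strength diagnostics.

Instruments are SNPs robustly associated with the exposure: selected by a
p-value threshold, pruned to approximate linkage-equilibrium by greedy
clumping, and screened on the F statistic

    F = ((N - K - 1) / K) * (R^2 / (1 - R^2)),

where N is the exposure GWAS sample size, K the number of instruments and
R^2 the variance in the exposure they explain, with the per-SNP variance
explained computed from summary statistics as

    R^2 = beta^2 * EAF * (1 - EAF) / (SE^2 * N).

The conventional screening rule keeps instruments with F > 10.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from scipy import stats

from .errors import DataError, DomainError
from .gwas_io import SummaryStatRecord

LDLookup = Callable[[str, str], float] | Mapping[frozenset, float]


@dataclass
class ClumpSpec:
    """Greedy-clumping parameters: pairwise r² ceiling within a physical window."""

    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    ld_source: str = "matrix"  # matrix | distance_only

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold < 1.0):
            raise DomainError("r2_threshold must be in (0, 1)")
        if self.window_kb <= 0:
            raise DomainError("window_kb must be positive")
        if self.ld_source not in ("matrix", "distance_only"):
            raise DomainError("ld_source must be 'matrix' or 'distance_only'")


@dataclass
class InstrumentMetrics:
    """Set-level strength summary for a chosen instrument set."""

    r2: float        # total variance explained
    f_stat: float    # set-level F
    k: int           # number of instruments
    n: float         # exposure sample size


def select_by_pvalue(records: Sequence[SummaryStatRecord], threshold: float) -> list[SummaryStatRecord]:
    """Keep records with ``pval < threshold`` (strict), preserving order."""
    return [r for r in records if r.pval < threshold]


def compute_r2(record: SummaryStatRecord) -> float:
    """Per-SNP proportion of exposure variance explained."""
    r2 = record.beta ** 2 * record.eaf * (1.0 - record.eaf) / (record.se ** 2 * record.n)
    cap = 1.0 - 1e-12
    if r2 > cap:
        warnings.warn(
            f"{record.variant_id}: R^2 formula gave {r2:.4g} > 1; clipping", stacklevel=2
        )
        return cap
    return r2


def compute_f(n: float, k: int, r2_total: float) -> float:
    """Set-level F statistic for K instruments jointly explaining ``r2_total``."""
    if n <= k + 1:
        raise DomainError(f"need n > k+1 (got n={n}, k={k})")
    if not (0.0 <= r2_total < 1.0):
        raise DomainError("r2_total must be in [0, 1)")
    return ((n - k - 1) / k) * (r2_total / (1.0 - r2_total))


def per_snp_f(record: SummaryStatRecord) -> float:
    """Single-instrument F (K = 1); screening happens before the set is known."""
    return compute_f(record.n, 1, compute_r2(record))


def instrument_metrics(records: Sequence[SummaryStatRecord]) -> InstrumentMetrics:
    if not records:
        raise DataError("empty instrument set")
    r2_total = min(sum(compute_r2(r) for r in records), 1.0 - 1e-12)
    n = min(r.n for r in records)
    k = len(records)
    return InstrumentMetrics(r2=r2_total, f_stat=compute_f(n, k, r2_total), k=k, n=n)


def filter_weak_instruments(
    records: Sequence[SummaryStatRecord], f_min: float = 10.0
) -> list[SummaryStatRecord]:
    """Keep records whose per-SNP F exceeds ``f_min`` (strict, per F > 10)."""
    return [r for r in records if per_snp_f(r) > f_min]


def _ld_r2(ld: LDLookup | None, a: str, b: str) -> float:
    """Pairwise r²; absent entries are treated as independence (0)."""
    if ld is None:
        return 0.0
    if callable(ld):
        return float(ld(a, b))
    return float(ld.get(frozenset((a, b)), 0.0))


def clump(
    records: Sequence[SummaryStatRecord],
    spec: ClumpSpec | None = None,
    ld: LDLookup | None = None,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping.

    Sort by ascending p-value (ties broken by variant_id); accept a SNP iff it
    is compatible with every already-accepted SNP: in ``matrix`` mode its r²
    with each accepted SNP lying within ``window_kb`` on the same chromosome is
    below ``r2_threshold`` (SNPs with unknown positions are compared
    unconditionally); in ``distance_only`` mode no accepted SNP may lie within
    the window on the same chromosome. Output preserves the input's order.
    """
    spec = spec or ClumpSpec()
    if spec.ld_source == "distance_only":
        for r in records:
            if r.chrom is None or r.pos is None:
                raise DataError(
                    f"{r.variant_id}: distance_only clumping requires chrom and pos"
                )

    window_bp = spec.window_kb * 1000.0
    order = sorted(records, key=lambda r: (r.pval, r.variant_id))
    accepted: list[SummaryStatRecord] = []
    for cand in order:
        ok = True
        for acc in accepted:
            in_window = True
            if cand.chrom is not None and acc.chrom is not None:
                if cand.chrom != acc.chrom:
                    in_window = False
                elif cand.pos is not None and acc.pos is not None:
                    in_window = abs(cand.pos - acc.pos) <= window_bp
            if not in_window:
                continue
            if spec.ld_source == "distance_only":
                ok = False
                break
            if _ld_r2(ld, cand.variant_id, acc.variant_id) >= spec.r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(cand)
    keep = {r.variant_id for r in accepted}
    return [r for r in records if r.variant_id in keep]


def power_binary_outcome(
    n: float,
    case_fraction: float,
    r2_total: float,
    odds_ratio: float,
    alpha: float = 0.05,
) -> float:
    """Approximate power of an MR test against a binary outcome.

    Normal approximation: the causal log-odds estimate has standard error
    about 1/sqrt(n * R^2 * v * (1 - v)) for outcome sample size ``n`` with
    case fraction ``v`` and instruments explaining ``r2_total`` of the
    exposure, giving non-centrality ncp = n * R^2 * v * (1 - v) * ln(OR)^2 and

        power = Phi(sqrt(ncp) - z_{1-a/2}) + Phi(-sqrt(ncp) - z_{1-a/2}).

    A null effect (OR = 1) or an uninformative instrument set (R^2 = 0)
    returns exactly ``alpha``.
    """
    if not (0.0 < case_fraction < 1.0):
        raise DomainError("case_fraction must be in (0, 1)")
    if odds_ratio <= 0:
        raise DomainError("odds_ratio must be positive")
    if not (0.0 <= r2_total < 1.0):
        raise DomainError("r2_total must be in [0, 1)")
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must be in (0, 1)")
    v = case_fraction
    ncp = n * r2_total * v * (1.0 - v) * math.log(odds_ratio) ** 2
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    root = math.sqrt(ncp)
    return float(stats.norm.cdf(root - z) + stats.norm.cdf(-root - z))
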