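"""Read, validate, write and harmonize GWAS summary statistics.

A summary-statistic table has one row per SNP: variant id, effect/other
allele, effect-allele frequency (EAF), per-allele effect ``beta`` (log-odds
for binary traits), its standard error, p-value and sample size.
Harmonization aligns an exposure table against an outcome table onto a
common effect allele, flipping outcome effects where the allele order is
swapped, resolving strand complements, and dropping palindromic (A/T, C/G)
or irreconcilable variants.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order on write
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

REQUIRED_COLUMNS = [
    "variant_id", "effect_allele", "other_allele", "eaf", "beta", "se",
    "pval", "n",
]


@dataclass
class SummaryStatRecord:
    """One SNP's association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    chrom: str | None = None
    pos: int | None = None

    def validation_errors(self) -> list[str]:
        """Hard invariant violations; a non-empty list means the row is rejected."""
        errors: list[str] = []
        if self.effect_allele not in BASES:
            errors.append(f"effect_allele {self.effect_allele!r} not a single base")
        if self.other_allele not in BASES:
            errors.append(f"other_allele {self.other_allele!r} not a single base")
        if self.effect_allele in BASES and self.effect_allele == self.other_allele:
            errors.append("effect_allele equals other_allele")
        if not (0.0 < self.eaf < 1.0):
            errors.append("eaf out of range")
        if not (self.se > 0.0):
            errors.append("se not positive")
        if not (0.0 < self.pval <= 1.0):
            errors.append("pval out of range")
        if not (self.n > 0):
            errors.append("n not positive")
        return errors

    def validation_warnings(self) -> list[str]:
        """Soft checks: reported p should match beta/se within a factor of 10."""
        warnings: list[str] = []
        if self.se > 0 and 0 < self.pval <= 1:
            implied = 2.0 * stats.norm.sf(abs(self.beta) / self.se)
            if implied > 0 and not (implied / 10.0 <= self.pval <= min(1.0, implied * 10.0)):
                warnings.append(
                    f"pval {self.pval:.3g} inconsistent with beta/se (implies {implied:.3g})"
                )
        return warnings

    def is_palindromic(self) -> bool:
        return COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class RejectedRow:
    line: int
    reason: str
    raw: dict


@dataclass
class ReadResult:
    """Validated records plus the rows that failed validation (never silently dropped)."""

    records: list[SummaryStatRecord]
    rejects: list[RejectedRow] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HarmonizedPair:
    """Exposure/outcome effects aligned to a common effect allele."""

    variant_id: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    eaf_exp: float
    beta_out: float
    se_out: float
    eaf_out: float
    action: str  # kept | flipped | dropped
    drop_reason: str | None = None  # palindromic | incompatible_alleles | missing_in_outcome

    def analyzable(self) -> bool:
        return self.action in ("kept", "flipped")


def _resolve_columns(columns: Sequence[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical names to actual file columns, case-insensitively."""
    column_map = dict(column_map or {})
    lower = {c.lower(): c for c in columns}
    # common aliases seen in GWAS-catalog / OpenGWAS exports
    aliases = {
        "variant_id": ["variant_id", "snp", "rsid", "rs_id", "markername", "id"],
        "chrom": ["chrom", "chr", "chromosome"],
        "pos": ["pos", "bp", "position", "base_pair_location"],
        "effect_allele": ["effect_allele", "ea", "a1", "allele1"],
        "other_allele": ["other_allele", "oa", "a2", "allele2", "non_effect_allele"],
        "eaf": ["eaf", "effect_allele_frequency", "freq", "af", "maf"],
        "beta": ["beta", "b", "effect", "es"],
        "se": ["se", "standard_error", "stderr"],
        "pval": ["pval", "p", "p_value", "pvalue"],
        "n": ["n", "samplesize", "sample_size", "ntotal"],
    }
    resolved: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        if canon in column_map:
            if column_map[canon] not in columns:
                raise ConfigurationError(
                    f"column {column_map[canon]!r} (mapped for {canon!r}) not in file"
                )
            resolved[canon] = column_map[canon]
            continue
        for alias in aliases[canon]:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    missing = [c for c in REQUIRED_COLUMNS if c not in resolved]
    if missing:
        raise ConfigurationError(f"required column(s) not resolvable: {', '.join(missing)}")
    return resolved


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ReadResult:
    """Read a TSV/CSV summary-statistic table.

    Rows failing :meth:`SummaryStatRecord.validation_errors` are collected in
    ``rejects`` with their 1-based data line number and reason; soft p-value
    inconsistencies go to ``warnings``.
    """
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=sep, dtype=str)
    resolved = _resolve_columns(list(df.columns), column_map)

    records: list[SummaryStatRecord] = []
    rejects: list[RejectedRow] = []
    warnings: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        try:
            rec = SummaryStatRecord(
                variant_id=str(raw[resolved["variant_id"]]),
                effect_allele=str(raw[resolved["effect_allele"]]).upper(),
                other_allele=str(raw[resolved["other_allele"]]).upper(),
                eaf=float(raw[resolved["eaf"]]),
                beta=float(raw[resolved["beta"]]),
                se=float(raw[resolved["se"]]),
                pval=float(raw[resolved["pval"]]),
                n=float(raw[resolved["n"]]),
                chrom=str(raw[resolved["chrom"]]) if "chrom" in resolved and not _isna(raw[resolved["chrom"]]) else None,
                pos=int(float(raw[resolved["pos"]])) if "pos" in resolved and not _isna(raw[resolved["pos"]]) else None,
            )
        except (TypeError, ValueError) as exc:
            rejects.append(RejectedRow(line=i, reason=f"unparsable numeric: {exc}", raw=raw))
            continue
        issues = rec.validation_errors()
        if issues:
            rejects.append(RejectedRow(line=i, reason="; ".join(issues), raw=raw))
            continue
        for w in rec.validation_warnings():
            warnings.append(f"line {i} ({rec.variant_id}): {w}")
        records.append(rec)
    return ReadResult(records=records, rejects=rejects, warnings=warnings)


def _isna(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and value.strip().lower() in ("", "na", "nan", "none")
    )


def records_to_frame(records: Iterable[SummaryStatRecord]) -> pd.DataFrame:
    rows = [
        {c: getattr(r, c) for c in CANONICAL_COLUMNS}
        for r in records
    ]
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path, sep: str = "\t") -> None:
    """Write records in canonical column order."""
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def write_rejects(rejects: Iterable[RejectedRow], path: str | Path) -> None:
    rows = [{"line": r.line, "reason": r.reason, **{f"raw_{k}": v for k, v in r.raw.items()}} for r in rejects]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _check_unique(records: Sequence[SummaryStatRecord], label: str) -> dict[str, SummaryStatRecord]:
    index: dict[str, SummaryStatRecord] = {}
    for rec in records:
        if rec.variant_id in index:
            raise DataError(f"duplicate variant_id {rec.variant_id!r} in {label} dataset")
        index[rec.variant_id] = rec
    return index


def flip_record(rec: SummaryStatRecord) -> SummaryStatRecord:
    """Swap effect/other allele, negating beta and complementing EAF (an involution)."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        eaf=1.0 - rec.eaf,
        beta=-rec.beta,
    )


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    drop_all_palindromic: bool = True,
    eaf_window: tuple[float, float] = (0.42, 0.58),
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Matching is by ``variant_id``. For each exposure SNP found in the outcome:
    same allele pair in the same orientation is kept; the swapped orientation is
    flipped (outcome beta negated, EAF complemented); strand-complement matches
    are resolved by complementing outcome alleles first; palindromic (A/T, C/G)
    exposure SNPs are dropped outright when ``drop_all_palindromic`` (the
    default) or, otherwise, only when either EAF falls inside ``eaf_window``
    (strand ambiguity cannot be resolved at intermediate frequency); anything
    else is dropped as incompatible. Exposure SNPs absent from the outcome are
    dropped as ``missing_in_outcome``.
    """
    _check_unique(exposure, "exposure")
    out_index = _check_unique(outcome, "outcome")

    pairs: list[HarmonizedPair] = []
    for exp in exposure:
        out = out_index.get(exp.variant_id)
        if out is None:
            pairs.append(_dropped(exp, None, "missing_in_outcome"))
            continue
        if exp.is_palindromic():
            if drop_all_palindromic:
                pairs.append(_dropped(exp, out, "palindromic"))
                continue
            lo, hi = eaf_window
            if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
                pairs.append(_dropped(exp, out, "palindromic"))
                continue
            # frequency-resolvable: make the minor-allele assignments agree
            aligned = out
            if aligned.effect_allele not in (exp.effect_allele, exp.other_allele):
                aligned = replace(
                    aligned,
                    effect_allele=COMPLEMENT[aligned.effect_allele],
                    other_allele=COMPLEMENT[aligned.other_allele],
                )
            if (exp.eaf < 0.5) != (aligned.eaf < 0.5):
                aligned = flip_record(aligned)
            pairs.append(_aligned(exp, aligned, "flipped" if aligned.beta != out.beta or aligned.eaf != out.eaf else "kept"))
            continue

        exp_set = (exp.effect_allele, exp.other_allele)
        aligned = out
        if (aligned.effect_allele, aligned.other_allele) not in (exp_set, exp_set[::-1]):
            comp = replace(
                aligned,
                effect_allele=COMPLEMENT[aligned.effect_allele],
                other_allele=COMPLEMENT[aligned.other_allele],
            )
            if (comp.effect_allele, comp.other_allele) in (exp_set, exp_set[::-1]):
                aligned = comp
            else:
                pairs.append(_dropped(exp, out, "incompatible_alleles"))
                continue
        if (aligned.effect_allele, aligned.other_allele) == exp_set:
            pairs.append(_aligned(exp, aligned, "kept"))
        else:
            pairs.append(_aligned(exp, flip_record(aligned), "flipped"))
    return pairs


def _aligned(exp: SummaryStatRecord, out: SummaryStatRecord, action: str) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exp.variant_id,
        effect_allele=exp.effect_allele,
        beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf,
        beta_out=out.beta, se_out=out.se, eaf_out=out.eaf,
        action=action,
    )


def _dropped(exp: SummaryStatRecord, out: SummaryStatRecord | None, reason: str) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exp.variant_id,
        effect_allele=exp.effect_allele,
        beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf,
        beta_out=out.beta if out else float("nan"),
        se_out=out.se if out else float("nan"),
        eaf_out=out.eaf if out else float("nan"),
        action="dropped",
        drop_reason=reason,
    )
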