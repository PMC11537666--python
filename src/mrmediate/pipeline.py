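"""End-to-end workflow: forward screen, validation, reverse MR, mediation.

The workflow mirrors a screening MR study: every exposure in a panel is
tested against the discovery outcome with the full estimator battery and
sensitivity diagnostics; hits (IVW p < alpha with a clean sensitivity
battery) are re-tested in validation cohorts, where a hit is retained only
if the IVW effect is direction-consistent and significant in every cohort;
reverse MR at a genome-wide threshold guards against reverse causation; and
mediation is quantified for validated exposures whose two mediation legs are
both significant. Benjamini–Hochberg q-values are reported alongside the
unadjusted screen p-values for transparency but are not used for flagging.
"""
from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientInstrumentsError, PipelineError
from .gwas_io import SummaryStatRecord, harmonize, read_summary_stats
from .instruments import ClumpSpec, clump, filter_weak_instruments, select_by_pvalue
from .mediation import mediation_pipeline
from .mr_core import MRResult, ivw, run_methods, wald_ratio
from .sensitivity import sensitivity_table

logger = logging.getLogger("mrmediate")


@dataclass
class AnalysisConfig:
    """Thresholds applied at every stage; all are logged when used."""

    p_forward: float = 1e-5
    p_reverse: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    clump_mode: str = "matrix"     # matrix | distance_only | off
    f_min: float = 10.0
    alpha: float = 0.05
    power_min: float = 0.80
    drop_all_palindromic: bool = True
    n_boot: int = 1000
    presso_nsim: int = 1000
    seed: int = 0

    def clump_spec(self) -> ClumpSpec | None:
        if self.clump_mode == "off":
            return None
        return ClumpSpec(r2_threshold=self.clump_r2, window_kb=self.clump_kb,
                         ld_source=self.clump_mode)


@dataclass
class ExposureScreenResult:
    exposure: str
    results: list[MRResult]
    sensitivity: pd.DataFrame | None
    n_instruments: int
    flagged: bool
    error: str | None = None
    q_value: float | None = None

    @property
    def ivw_result(self) -> MRResult | None:
        for r in self.results:
            if r.method in ("IVW_fixed", "Wald_ratio"):
                return r
        return None


@dataclass
class ScreenReport:
    screen: list[ExposureScreenResult] = field(default_factory=list)
    validation: dict = field(default_factory=dict)   # exposure -> {cohort: MRResult}
    validated: list[str] = field(default_factory=list)
    reverse: dict = field(default_factory=dict)      # trait -> MRResult | "untestable"
    mediation: dict = field(default_factory=dict)    # exposure -> MediationResult
    log: list[str] = field(default_factory=list)

    def flagged(self) -> list[str]:
        return [e.exposure for e in self.screen if e.flagged]


def prepare_instruments(
    records: Sequence[SummaryStatRecord],
    p_threshold: float,
    config: AnalysisConfig,
    ld=None,
) -> list[SummaryStatRecord]:
    """p-value selection, then clumping, then F screening (in that order)."""
    selected = select_by_pvalue(records, p_threshold)
    spec = config.clump_spec()
    if spec is not None:
        selected = clump(selected, spec, ld=ld)
    return filter_weak_instruments(selected, config.f_min)


def _log(report: ScreenReport, message: str) -> None:
    stamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    line = f"{stamp} {message}"
    report.log.append(line)
    logger.info(message)


def analyze_exposure(
    name: str,
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    config: AnalysisConfig,
    p_threshold: float | None = None,
    ld=None,
    run_sensitivity: bool = True,
) -> ExposureScreenResult:
    """Full single-exposure analysis: instruments, harmonization, methods, diagnostics."""
    p_threshold = config.p_forward if p_threshold is None else p_threshold
    instruments = prepare_instruments(exposure, p_threshold, config, ld=ld)
    if not instruments:
        return ExposureScreenResult(exposure=name, results=[], sensitivity=None,
                                    n_instruments=0, flagged=False,
                                    error="no instruments survive selection")
    pairs = harmonize(instruments, list(outcome),
                      drop_all_palindromic=config.drop_all_palindromic)
    usable = [p for p in pairs if p.analyzable()]
    if not usable:
        return ExposureScreenResult(exposure=name, results=[], sensitivity=None,
                                    n_instruments=0, flagged=False,
                                    error="no instruments survive harmonization")
    results = run_methods(usable, n_boot=config.n_boot, seed=config.seed)
    sens = None
    flagged = False
    ivw_res = next((r for r in results if r.method in ("IVW_fixed", "Wald_ratio")), None)
    if len(usable) >= 4 and run_sensitivity:
        try:
            sens = sensitivity_table(usable, exposure=name,
                                     presso_nsim=config.presso_nsim,
                                     alpha=config.alpha, seed=config.seed)
            clean = bool(sens["pass"].all())
        except InsufficientInstrumentsError:
            clean = True
    else:
        clean = True  # sensitivity not applicable at < 4 instruments
    if ivw_res is not None and ivw_res.pval < config.alpha and clean:
        flagged = True
    return ExposureScreenResult(exposure=name, results=results, sensitivity=sens,
                                n_instruments=len(usable), flagged=flagged)


def forward_screen(
    exposures: Mapping[str, Sequence[SummaryStatRecord]],
    outcome: Sequence[SummaryStatRecord],
    config: AnalysisConfig,
    report: ScreenReport | None = None,
    run_sensitivity: bool = True,
) -> ScreenReport:
    """Screen every exposure against the discovery outcome."""
    report = report or ScreenReport()
    _log(report, f"forward screen: {len(exposures)} exposures, "
                 f"p<{config.p_forward}, clump r2<{config.clump_r2} within "
                 f"{config.clump_kb}kb ({config.clump_mode}), F>{config.f_min}, "
                 f"alpha={config.alpha}, seed={config.seed}")
    if not exposures:
        _log(report, "warning: empty exposure collection")
        return report
    for name, records in exposures.items():
        try:
            res = analyze_exposure(name, records, outcome, config,
                                   run_sensitivity=run_sensitivity)
        except (PipelineError, ConfigurationError) as exc:
            res = ExposureScreenResult(exposure=name, results=[], sensitivity=None,
                                       n_instruments=0, flagged=False, error=str(exc))
            _log(report, f"exposure {name} failed: {exc}")
        report.screen.append(res)
    # BH q-values over the screen IVW p-values (reported, not used for flagging)
    pvals = [(i, e.ivw_result.pval) for i, e in enumerate(report.screen)
             if e.ivw_result is not None]
    if pvals:
        _, qvals, _, _ = multipletests([p for _, p in pvals], method="fdr_bh")
        for (i, _), q in zip(pvals, qvals):
            report.screen[i].q_value = float(q)
    _log(report, f"screen flagged {len(report.flagged())} exposure(s)")
    return report


def validate_hits(
    report: ScreenReport,
    exposures: Mapping[str, Sequence[SummaryStatRecord]],
    validation_outcomes: Mapping[str, Sequence[SummaryStatRecord]],
    config: AnalysisConfig,
) -> ScreenReport:
    """Retain a hit only if IVW is direction-consistent and significant in every cohort."""
    discovery_sign = {e.exposure: np.sign(e.ivw_result.beta)
                      for e in report.screen if e.flagged and e.ivw_result}
    for name in report.flagged():
        per_cohort: dict[str, MRResult] = {}
        ok = True
        for cohort, outcome in validation_outcomes.items():
            res = analyze_exposure(name, exposures[name], outcome, config,
                                   run_sensitivity=False)
            r = res.ivw_result
            if r is None:
                ok = False
                continue
            per_cohort[cohort] = r
            if not (np.sign(r.beta) == discovery_sign[name] and r.pval < config.alpha):
                ok = False
        report.validation[name] = per_cohort
        if ok and validation_outcomes:
            report.validated.append(name)
    _log(report, f"validated {len(report.validated)} of {len(report.flagged())} hits "
                 f"across {len(validation_outcomes)} cohort(s)")
    return report


def reverse_mr(
    outcome: Sequence[SummaryStatRecord],
    traits: Mapping[str, Sequence[SummaryStatRecord]],
    config: AnalysisConfig,
    report: ScreenReport | None = None,
) -> ScreenReport:
    """Treat the outcome as exposure at the genome-wide threshold (p < p_reverse)."""
    report = report or ScreenReport()
    instruments = prepare_instruments(outcome, config.p_reverse, config)
    _log(report, f"reverse MR: {len(instruments)} instrument(s) at p<{config.p_reverse}")
    if not instruments:
        for name in traits:
            report.reverse[name] = "untestable"
        _log(report, "reverse MR untestable: no genome-wide-significant SNPs in outcome")
        return report
    for name, trait_records in traits.items():
        pairs = harmonize(instruments, list(trait_records),
                          drop_all_palindromic=config.drop_all_palindromic)
        usable = [p for p in pairs if p.analyzable()]
        if not usable:
            report.reverse[name] = "untestable"
        elif len(usable) == 1:
            report.reverse[name] = wald_ratio(usable)
        else:
            report.reverse[name] = ivw(usable, mode="fixed")
    return report


def _screen_frame(report: ScreenReport) -> pd.DataFrame:
    rows = []
    for e in report.screen:
        if e.error:
            rows.append({"exposure": e.exposure, "method": None, "error": e.error})
            continue
        for r in e.results:
            rows.append({
                "exposure": e.exposure, "method": r.method, "n_snp": r.n_snp,
                "beta": r.beta, "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "pval": r.pval, "odds_ratio": r.odds_ratio,
                "or_ci_low": r.or_ci_low, "or_ci_high": r.or_ci_high,
                "q_value": e.q_value, "flagged": e.flagged, "error": None,
            })
    return pd.DataFrame(rows)


def _mediation_frame(report: ScreenReport) -> pd.DataFrame:
    rows = []
    for name, m in report.mediation.items():
        rows.append({
            "exposure": name, "total_effect": m.total_effect,
            "direct_effect_A": m.beta1, "direct_effect_B": m.beta2,
            "indirect_effect": m.indirect, "direct_effect": m.direct,
            "mediation_proportion_pct": m.proportion,
            "indirect_ci_low": m.ci_indirect[0], "indirect_ci_high": m.ci_indirect[1],
            "proportion_ci_low": m.ci_proportion[0] if m.ci_proportion else None,
            "proportion_ci_high": m.ci_proportion[1] if m.ci_proportion else None,
        })
    return pd.DataFrame(rows)


def _load_datasets(spec, column_map=None) -> dict[str, list[SummaryStatRecord]]:
    """Load {name: path} or a directory of .tsv files into record lists."""
    datasets: dict[str, list[SummaryStatRecord]] = {}
    if isinstance(spec, (str, Path)):
        path = Path(spec)
        if path.is_dir():
            for f in sorted(path.glob("*.tsv")):
                datasets[f.stem] = read_summary_stats(f, column_map).records
        else:
            datasets[path.stem] = read_summary_stats(path, column_map).records
        return datasets
    for name, p in spec.items():
        datasets[name] = read_summary_stats(p, column_map).records
    return datasets


def run_full(config: Mapping | str | Path, outdir: str | Path | None = None) -> ScreenReport:
    """Execute screen -> validation -> reverse -> mediation from a config mapping/YAML.

    Config layout::

        exposures: dir-or-{name: path}
        outcome: path                 # discovery cohort
        validation: {name: path}      # optional
        mediator: path                # optional; enables the mediation stage
        thresholds: {p_forward, p_reverse, clump_r2, clump_kb, f_min, alpha, ...}
        seed: int
        outdir: path                  # optional; tables + run log written there
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if "exposures" not in config or "outcome" not in config:
        raise ConfigurationError("config must define 'exposures' and 'outcome'")

    thresholds = dict(config.get("thresholds", {}))
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(thresholds) - known
    if unknown:
        raise ConfigurationError(f"unknown threshold key(s): {', '.join(sorted(unknown))}")
    acfg = AnalysisConfig(**thresholds)
    if "seed" in config:
        acfg.seed = int(config["seed"])

    exposures = _load_datasets(config["exposures"])
    outcome = _load_datasets(config["outcome"])
    outcome_records = next(iter(outcome.values()))

    report = forward_screen(exposures, outcome_records, acfg)
    if config.get("validation"):
        validation = {k: next(iter(_load_datasets(v).values()))
                      for k, v in dict(config["validation"]).items()}
        validate_hits(report, exposures, validation, acfg)
    else:
        report.validated = list(report.flagged())
        _log(report, "no validation cohorts configured; discovery hits carried forward")

    reverse_mr(outcome_records, {n: exposures[n] for n in report.validated}, acfg, report)

    if config.get("mediator"):
        mediator = next(iter(_load_datasets(config["mediator"]).values()))
        for name in report.validated:
            try:
                med = mediation_pipeline(
                    exposures[name], mediator, outcome_records,
                    p_threshold=acfg.p_forward, clump_spec=acfg.clump_spec(),
                    f_min=acfg.f_min,
                    drop_all_palindromic=acfg.drop_all_palindromic,
                )
                step1, step2 = med.legs["step1"], med.legs["step2"]
                if step1.pval < acfg.alpha and step2.pval < acfg.alpha:
                    report.mediation[name] = med
                else:
                    _log(report, f"mediation legs not significant for {name}; skipped")
            except PipelineError as exc:
                _log(report, f"mediation failed for {name}: {exc}")
    else:
        _log(report, "no mediator configured; mediation stage skipped")

    outdir = outdir or config.get("outdir")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _screen_frame(report).to_csv(outdir / "screen_results.tsv", sep="\t", index=False)
        sens_frames = [e.sensitivity for e in report.screen if e.sensitivity is not None]
        if sens_frames:
            pd.concat(sens_frames).to_csv(outdir / "sensitivity_table.tsv",
                                          sep="\t", index=False)
        med_frame = _mediation_frame(report)
        if not med_frame.empty:
            med_frame.to_csv(outdir / "mediation_table.tsv", sep="\t", index=False)
        (outdir / "run.log").write_text("\n".join(report.log) + "\n")
    return report
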