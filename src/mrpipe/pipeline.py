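"""End-to-end orchestration: select -> harmonize -> estimate -> diagnose -> screen.

:func:`run_full_analysis` wires the stage functions together for one
exposure against any number of outcomes and writes, per outcome, the
harmonization report, the eight-method results table, heterogeneity and
Egger-intercept tables, the leave-one-out table and the single-variant
forest/funnel table, plus one combined cross-outcome summary with
Bonferroni flags and a JSON run manifest (seed, thresholds, input
digests).  Outputs carry no timestamps, so a rerun with the same config
and seed is byte-identical.  Composition is stateless: running the
stages by hand on the same inputs gives the same numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diagnostics import (
    bonferroni_threshold,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    single_snp_table,
)
from .estimators import (
    EstimatorConfig,
    InsufficientInstrumentsError,
    results_table,
    run_all_methods,
)
from .harmonization import (
    GENOME_WIDE_P,
    PALINDROME_EAF_BAND,
    PROXY_R2,
    PRUNE_R2,
    active,
    filter_genomewide,
    harmonization_report,
    harmonize_pair,
    ld_prune,
    substitute_proxies,
)
from .pleiotropy_screen import (
    ScreenConfig,
    screen_and_rerun,
    screen_report_rows,
)
from .summary_io import LDTable, SummaryTable, read_summary_table

logger = logging.getLogger("mrpipe")


@dataclass
class AnalysisConfig:
    """Everything one full run needs; loadable from YAML/JSON."""

    exposure: str = ""
    outcomes: dict[str, str] = field(default_factory=dict)
    ld: str | None = None
    trait_panel: dict[str, str] = field(default_factory=dict)
    gw_threshold: float = GENOME_WIDE_P
    prune_r2: float = PRUNE_R2
    proxy_r2: float = PROXY_R2
    palindrome_eaf_band: float = PALINDROME_EAF_BAND
    snp_alpha: float = 0.05
    alpha: float = 0.05
    n_traits: int = 1
    n_outcomes: int | None = None
    n_boot: int = 1000
    seed: int | None = None
    out_dir: str = "mr_results"

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def validate(self) -> None:
        for path in [self.exposure, *self.outcomes.values(),
                     *(self.trait_panel.values()),
                     *( [self.ld] if self.ld else [] )]:
            if not Path(path).exists():
                raise FileNotFoundError(path)
        for name, value in [("gw_threshold", self.gw_threshold),
                            ("prune_r2", self.prune_r2),
                            ("proxy_r2", self.proxy_r2),
                            ("snp_alpha", self.snp_alpha),
                            ("alpha", self.alpha)]:
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} outside (0,1]: {value}")


@dataclass
class OutcomeBundle:
    """In-memory results for one outcome."""

    outcome_id: str
    instruments: list
    results: list
    heterogeneity: object | None = None
    egger_intercept: tuple | None = None
    loo: object | None = None
    funnel: object | None = None
    screen_reports: list = field(default_factory=list)
    soft_failures: list[str] = field(default_factory=list)


def _write_rows(rows: list[dict], path: Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def analyse_one_outcome(
    instruments,
    outcome_id: str,
    est_config: EstimatorConfig,
    alpha: float = 0.05,
    trait_tables: list[SummaryTable] | None = None,
    screen_config: ScreenConfig | None = None,
) -> OutcomeBundle:
    """Estimators + diagnostics (+ optional screen) on harmonized instruments."""
    bundle = OutcomeBundle(outcome_id=outcome_id, instruments=instruments,
                           results=run_all_methods(instruments, est_config))
    usable = active(instruments)
    for label, call in [
        ("heterogeneity", lambda: cochran_q(usable)),
        ("egger_intercept", lambda: egger_intercept_test(usable)),
        ("leave_one_out", lambda: leave_one_out(usable, alpha=alpha)),
        ("single_snp", lambda: single_snp_table(usable)),
    ]:
        try:
            value = call()
        except InsufficientInstrumentsError as exc:
            bundle.soft_failures.append(f"{label}: {exc}")
            logger.warning("%s: %s skipped (%s)", outcome_id, label, exc)
            continue
        if label == "heterogeneity":
            bundle.heterogeneity = value
        elif label == "egger_intercept":
            bundle.egger_intercept = value
        elif label == "leave_one_out":
            bundle.loo = value
        else:
            bundle.funnel = value
    if trait_tables:
        try:
            bundle.screen_reports = screen_and_rerun(
                usable, trait_tables, screen_config)
        except (InsufficientInstrumentsError, ValueError) as exc:
            bundle.soft_failures.append(f"screen: {exc}")
    return bundle


def run_full_analysis(config: AnalysisConfig) -> dict[str, OutcomeBundle]:
    """Run the whole pipeline per the config and write the report bundle."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exposure = read_summary_table(config.exposure, trait_id="exposure")
    ld = LDTable.from_tsv(config.ld) if config.ld else LDTable()
    candidates = filter_genomewide(exposure, config.gw_threshold)
    pruned = ld_prune(candidates, ld, config.prune_r2)
    logger.info("instrument selection: %d candidates -> %d retained",
                len(candidates), len(pruned))

    est_config = EstimatorConfig(n_boot=config.n_boot, seed=config.seed)
    trait_tables = [
        read_summary_table(path, trait_id=name)
        for name, path in config.trait_panel.items()
    ]
    screen_config = ScreenConfig(snp_alpha=config.snp_alpha,
                                 alpha=config.alpha)

    bundles: dict[str, OutcomeBundle] = {}
    summary_rows = []
    n_outcomes = config.n_outcomes or max(1, len(config.outcomes))
    corrected = bonferroni_threshold(config.alpha, config.n_traits, n_outcomes)
    for outcome_id, path in config.outcomes.items():
        outcome = read_summary_table(path, trait_id=outcome_id)
        proxies = substitute_proxies(pruned, outcome, ld, config.proxy_r2)
        instruments = harmonize_pair(pruned, outcome,
                                     config.palindrome_eaf_band, proxies)
        bundle = analyse_one_outcome(
            instruments, outcome_id, est_config, config.alpha,
            trait_tables or None, screen_config)
        bundles[outcome_id] = bundle
        _write_outcome(bundle, out_dir, outcome_id)
        for res in bundle.results:
            summary_rows.append({
                "outcome": outcome_id, "method": res.method,
                "n_snp": res.n_snp, "beta": res.beta, "se": res.se,
                "pval": res.pval,
                "significant_bonferroni": bool(res.pval < corrected)
                if res.pval == res.pval else False,
            })
    _write_rows(summary_rows, out_dir / "summary.tsv")

    manifest = {
        "package": "mrpipe",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "gw_threshold": config.gw_threshold,
            "prune_r2": config.prune_r2,
            "proxy_r2": config.proxy_r2,
            "palindrome_eaf_band": config.palindrome_eaf_band,
            "snp_alpha": config.snp_alpha,
            "alpha": config.alpha,
            "bonferroni_corrected_alpha": corrected,
        },
        "inputs": {
            "exposure": _digest(config.exposure),
            **{f"outcome:{k}": _digest(v) for k, v in config.outcomes.items()},
            **({"ld": _digest(config.ld)} if config.ld else {}),
            **{f"trait:{k}": _digest(v)
               for k, v in config.trait_panel.items()},
        },
        "n_candidates": len(candidates),
        "n_instruments": len(pruned),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return bundles


def _write_outcome(bundle: OutcomeBundle, out_dir: Path, outcome_id: str) -> None:
    prefix = out_dir / outcome_id
    prefix.mkdir(exist_ok=True)
    _write_rows(harmonization_report(bundle.instruments),
                prefix / "harmonization.tsv")
    _write_rows(results_table(bundle.results), prefix / "results.tsv")
    if bundle.heterogeneity is not None:
        het = bundle.heterogeneity
        _write_rows([{"method": "ivw", "q": het.q, "df": het.df,
                      "pval": het.pval}], prefix / "heterogeneity.tsv")
    if bundle.egger_intercept is not None:
        est, se, lo, hi, p = bundle.egger_intercept
        _write_rows([{"intercept": est, "se": se, "ci_low": lo,
                      "ci_high": hi, "pval": p}],
                    prefix / "egger_intercept.tsv")
    if bundle.loo is not None:
        _write_rows([
            {"excluded_rsid": row.excluded_rsid or "(none)",
             "beta": row.result.beta, "se": row.result.se,
             "ci_low": row.result.ci_low, "ci_high": row.result.ci_high,
             "pval": row.result.pval, "influential": row.influential}
            for row in bundle.loo.rows
        ], prefix / "leave_one_out.tsv")
    if bundle.funnel is not None:
        wald_results, funnel = bundle.funnel
        _write_rows([
            {"rsid": rsid, "ratio": ratio, "precision": precision}
            for rsid, ratio, precision in funnel.rows
        ], prefix / "funnel.tsv")
        _write_rows(results_table(wald_results), prefix / "single_snp.tsv")
    if bundle.screen_reports:
        _write_rows(screen_report_rows(bundle.screen_reports),
                    prefix / "screen.tsv")
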