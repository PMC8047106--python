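"""Risk-factor pleiotropy screening.

A variant instrumenting the exposure may also act on the outcome through
an intermediate risk factor, violating the exclusion restriction.  The
screen takes a panel of risk-factor association tables, flags
instruments significantly associated with each factor, removes them, and
re-estimates the exposure -> outcome effect on the retained set with
random-effects IVW.  A factor whose removal step makes a previously
significant causal estimate non-significant is marked a potential
influencer of the association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

from .estimators import MRResult, ivw, wald_ratio
from .harmonization import HarmonizedInstrument, active
from .summary_io import SummaryTable, normalize_rsid

logger = logging.getLogger("mrpipe")

#: the 16 risk-factor slots of the default screening template
DEFAULT_TRAIT_PANEL = (
    "BMI", "years_of_schooling", "moderate_physical_activity",
    "alcohol_consumption", "current_smoking", "HDL", "LDL", "TC", "TG",
    "pulse_rate", "SBP", "DBP", "AF", "CHD", "FBG", "T2DM",
)


class EmptyOverlapError(ValueError):
    """No shared variants between instruments and a trait table."""


@dataclass
class ScreenConfig:
    snp_alpha: float = 0.05
    criterion: str = "association_p"  # or "wald_p"
    alpha: float = 0.05               # significance level for the rerun
    bonferroni_across_traits: bool = False


@dataclass
class ScreenReport:
    """Outcome of screening one risk factor."""

    trait_id: str
    flagged: dict[str, float] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)
    rerun: MRResult | None = None
    full: MRResult | None = None
    influencer: bool = False

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def flag_pleiotropic_snps(
    exposure_instruments: Sequence[HarmonizedInstrument],
    trait_outcome: SummaryTable,
    snp_alpha: float = 0.05,
    criterion: str = "association_p",
) -> set[str]:
    """Instruments significantly associated with one risk-factor trait.

    ``criterion="association_p"`` flags on the trait table's own
    association p-value; ``"wald_p"`` recomputes a per-variant Wald-ratio
    p of the exposure -> trait effect.  Only instruments present in the
    trait table can be flagged; zero overlap raises
    :class:`EmptyOverlapError`.
    """
    if criterion not in {"association_p", "wald_p"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    insts = {i.rsid: i for i in active(list(exposure_instruments))}
    trait = trait_outcome.by_rsid()
    overlap = insts.keys() & trait.keys()
    if not overlap:
        raise EmptyOverlapError(
            f"no instruments overlap trait table {trait_outcome.trait_id!r}")
    flagged: set[str] = set()
    for rsid in overlap:
        rec = trait[rsid]
        if criterion == "association_p":
            p = rec.pval
            if p is None:
                if rec.se <= 0:
                    continue
                p = 2.0 * stats.norm.sf(abs(rec.beta / rec.se))
        else:
            inst = insts[rsid]
            res = wald_ratio(HarmonizedInstrument(
                rsid=rsid, beta_exp=inst.beta_exp, se_exp=inst.se_exp,
                beta_out=rec.beta, se_out=rec.se))
            p = res.pval
        if p < snp_alpha:
            flagged.add(rsid)
    logger.info("trait %s: flagged %d/%d instruments at alpha=%g",
                trait_outcome.trait_id, len(flagged), len(overlap), snp_alpha)
    return flagged


def screen_and_rerun(
    exposure_instruments: Sequence[HarmonizedInstrument],
    trait_panel: Iterable[SummaryTable],
    config: ScreenConfig | None = None,
) -> list[ScreenReport]:
    """Per-trait screen of harmonized exposure -> outcome instruments.

    For each risk-factor table independently: flag instruments against
    that trait only, exclude them, and re-run random-effects IVW on the
    retained set.  A trait is marked a potential influencer when the
    full-set estimate is significant at ``config.alpha`` but the retained
    re-run is not.  An emptied instrument set yields a report whose
    ``rerun`` is ``None`` (not estimable) rather than an error.
    """
    cfg = config or ScreenConfig()
    insts = active(list(exposure_instruments))
    traits = list(trait_panel)
    snp_alpha = cfg.snp_alpha
    if cfg.bonferroni_across_traits and traits:
        snp_alpha = cfg.snp_alpha / len(traits)
    full = ivw(insts, "random") if insts else None
    reports: list[ScreenReport] = []
    for trait in traits:
        flagged_set = flag_pleiotropic_snps(insts, trait, snp_alpha,
                                            cfg.criterion)
        trait_p = {r.rsid: r.pval for r in trait.records}
        retained = [i for i in insts if i.rsid not in flagged_set]
        report = ScreenReport(
            trait_id=trait.trait_id,
            flagged={rsid: trait_p.get(rsid) for rsid in sorted(flagged_set)},
            retained=[i.rsid for i in retained],
            full=full,
        )
        if retained:
            report.rerun = ivw(retained, "random")
            report.influencer = bool(
                full is not None and full.significant(cfg.alpha)
                and not report.rerun.significant(cfg.alpha))
        else:
            logger.warning("trait %s: all instruments flagged; rerun not "
                           "estimable", trait.trait_id)
        reports.append(report)
    return reports


def subset_rerun(
    exposure_instruments: Sequence[HarmonizedInstrument],
    subset: Iterable[str],
) -> MRResult:
    """Random-effects IVW on an explicitly named instrument subset."""
    insts = {i.rsid: i for i in active(list(exposure_instruments))}
    wanted = [normalize_rsid(r) for r in subset]
    unknown = [r for r in wanted if r not in insts]
    if unknown:
        raise KeyError(f"unknown instrument rsids: {', '.join(unknown)}")
    result = ivw([insts[r] for r in wanted], "random")
    result.extra["subset"] = wanted
    return result


def screen_report_rows(reports: Sequence[ScreenReport]) -> list[dict]:
    """Rows for the per-trait screening TSV."""
    rows = []
    for rep in reports:
        rows.append({
            "trait_id": rep.trait_id,
            "n_flagged": rep.n_flagged,
            "n_retained": rep.n_retained,
            "flagged_rsids": ";".join(sorted(rep.flagged)),
            "rerun_beta": rep.rerun.beta if rep.rerun else float("nan"),
            "rerun_se": rep.rerun.se if rep.rerun else float("nan"),
            "rerun_pval": rep.rerun.pval if rep.rerun else float("nan"),
            "influencer": rep.influencer,
        })
    return rows
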