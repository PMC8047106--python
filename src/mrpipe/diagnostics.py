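"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q measures dispersion of the per-variant Wald ratios around
the pooled estimate; under homogeneity it is chi-square with J - 1
degrees of freedom (J - 2 for the Egger fit, where an intercept is
estimated).  The Egger intercept tests for average directional
pleiotropy.  Leave-one-out re-estimation and the single-variant
forest/funnel coordinates localize influence to individual variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import (
    MRResult,
    InsufficientInstrumentsError,
    egger,
    ivw,
    wald_ratio,
)
from .harmonization import HarmonizedInstrument, active

logger = logging.getLogger("mrpipe")


@dataclass
class HeterogeneityStat:
    """Cochran's Q with its degrees of freedom and upper-tail p."""

    q: float
    df: int
    pval: float


@dataclass
class LeaveOneOutRow:
    excluded_rsid: str | None  # None marks the all-variant row
    result: MRResult
    influential: bool = False


@dataclass
class LeaveOneOutTable:
    rows: list[LeaveOneOutRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def full(self) -> MRResult:
        return next(r.result for r in self.rows if r.excluded_rsid is None)

    def influential_rsids(self) -> list[str]:
        return [r.excluded_rsid for r in self.rows
                if r.excluded_rsid is not None and r.influential]


@dataclass
class FunnelData:
    """Per-variant ratio estimates against precision (1/SE)."""

    rows: list[tuple[str, float, float]] = field(default_factory=list)


def cochran_q(
    instruments: Sequence[HarmonizedInstrument],
    pooled: MRResult | None = None,
    method: str = "ivw",
) -> HeterogeneityStat:
    """Cochran's Q about the pooled estimate with fixed-effects weights.

    ``Q = sum_j w_j (ratio_j - beta_pooled)^2`` with ``w_j`` the IVW
    weights; df is J - 1, or J - 2 when ``method="egger"`` (residual Q
    about the Egger line).  Fixed-effects weights are used regardless of
    the reporting model, which makes the multiplicative random-effects
    dispersion exactly ``sqrt(Q / df)``.
    """
    insts = active(list(instruments))
    j = len(insts)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    bx = np.array([i.beta_exp for i in insts])
    by = np.array([i.beta_out for i in insts])
    sy = np.array([i.se_out for i in insts])
    r = by / bx
    w = (bx / sy) ** 2
    if method == "egger":
        if j < 3:
            raise InsufficientInstrumentsError("Egger Q needs >= 3 instruments")
        fit = pooled if pooled is not None and pooled.method == "egger" \
            else egger(instruments)
        sign = np.where(bx < 0, -1.0, 1.0)
        resid = by * sign - fit.extra["intercept"] - fit.beta * np.abs(bx)
        q = float(np.sum(resid**2 / sy**2))
        df = j - 2
    else:
        beta = (pooled.beta if pooled is not None
                else ivw(instruments, "fixed").beta)
        q = float(np.sum(w * (r - beta) ** 2))
        df = j - 1
    return HeterogeneityStat(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(
    instruments: Sequence[HarmonizedInstrument],
    level: float = 0.95,
    truncate_underdispersion: bool = True,
) -> tuple[float, float, float, float, float]:
    """(intercept, se, ci_low, ci_high, pval) of the Egger pleiotropy intercept.

    CI at ``level`` and two-sided p from t with J - 2 degrees of freedom.
    With the default multiplicative scaling truncated below at 1, an
    exactly-fitting line keeps the unscaled SE; set
    ``truncate_underdispersion=False`` to let a perfect fit drive the SE
    (and p) to zero.
    """
    fit = egger(instruments, level=level,
                truncate_underdispersion=truncate_underdispersion)
    est = fit.extra["intercept"]
    se = fit.extra["intercept_se"]
    df = fit.n_snp - 2
    t = stats.t.ppf(0.5 + level / 2.0, df)
    return (est, se, est - t * se, est + t * se, fit.extra["intercept_p"])


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    method: str = "ivw_random",
    level: float = 0.95,
    alpha: float = 0.05,
) -> LeaveOneOutTable:
    """Re-estimate with each instrument removed in turn.

    Each row is the estimator applied afresh to the J-1 remaining
    instruments (no incremental updating); the all-variant row is
    included, giving J + 1 rows.  A variant is flagged influential when
    its removal shifts the pooled estimate by more than one pooled SE or
    changes significance status at ``alpha``.
    """
    insts = active(list(instruments))
    if len(insts) < 2:
        raise InsufficientInstrumentsError("leave-one-out needs >= 2 instruments")
    effects_model = "fixed" if method == "ivw_fixed" else "random"
    full = ivw(insts, effects_model, level)
    rows = [LeaveOneOutRow(None, full)]
    for i, inst in enumerate(insts):
        subset = insts[:i] + insts[i + 1:]
        res = ivw(subset, effects_model, level)
        shifted = abs(res.beta - full.beta) > full.se
        flipped = res.significant(alpha) != full.significant(alpha)
        rows.append(LeaveOneOutRow(inst.rsid, res, shifted or flipped))
    return LeaveOneOutTable(rows=rows)


def single_snp_table(
    instruments: Sequence[HarmonizedInstrument], level: float = 0.95
) -> tuple[list[MRResult], FunnelData]:
    """Per-variant Wald estimates (forest-plot data) and funnel coordinates."""
    insts = active(list(instruments))
    if not insts:
        raise InsufficientInstrumentsError("no usable instruments")
    results = [wald_ratio(i, level) for i in insts]
    funnel = FunnelData(rows=[
        (i.rsid, res.beta, 1.0 / res.se)
        for i, res in zip(insts, results)
    ])
    return results, funnel


def bonferroni_threshold(alpha: float, n_traits: int, n_outcomes: int) -> float:
    """Family-wise corrected per-test threshold alpha / (traits x outcomes)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha outside (0,1): {alpha}")
    if n_traits < 1 or n_outcomes < 1:
        raise ValueError("comparison counts must be >= 1")
    return alpha / (n_traits * n_outcomes)
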