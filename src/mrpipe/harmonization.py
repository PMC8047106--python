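"""Instrument selection and exposure/outcome allele alignment.

An instrument set for two-sample MR is built in four steps: keep
genome-wide-significant exposure variants, prune them to near-linkage
equilibrium, substitute high-LD proxies for variants missing from the
outcome dataset, and align effect alleles between the two studies.
Instrument strength is summarized by the F-statistic
``F = [(n - k - 1) / k] * [R^2 / (1 - R^2)]`` for k instruments jointly
explaining a fraction R^2 of exposure variance in n subjects; values
far above 10 indicate negligible weak-instrument bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .summary_io import (
    LDTable,
    SummaryTable,
    VariantAssociation,
    normalize_rsid,
)

logger = logging.getLogger("mrpipe")

GENOME_WIDE_P = 5e-8
PRUNE_R2 = 0.01
PROXY_R2 = 0.9
PALINDROME_EAF_BAND = 0.08

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome effects for one variant on a shared allele.

    ``action`` records what alignment did: ``kept`` (alleles already
    matched, possibly after strand complementing), ``flipped`` (outcome
    alleles were swapped, so beta_out was negated exactly once),
    ``proxy_substituted`` (outcome effect read from a high-LD proxy),
    or ``dropped`` with a ``drop_reason``.
    """

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action: str = "kept"
    drop_reason: str | None = None
    proxy_rsid: str | None = None

    @property
    def dropped(self) -> bool:
        return self.action == "dropped"

    def validate(self) -> None:
        if self.action not in {"kept", "flipped", "proxy_substituted", "dropped"}:
            raise ValueError(f"unknown action {self.action!r}")
        if not self.dropped and (self.se_exp <= 0 or self.se_out <= 0):
            raise ValueError(f"{self.rsid}: non-dropped instrument needs positive SEs")


@dataclass
class InstrumentDiagnostics:
    """Counts and strength summary for a selected instrument set."""

    n_candidates: int
    n_retained: int
    r2_explained: float
    f_statistic: float


def active(instruments: list[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Instruments actually usable by estimators (non-dropped)."""
    return [inst for inst in instruments if not inst.dropped]


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def filter_genomewide(
    exposure: SummaryTable, threshold: float = GENOME_WIDE_P
) -> SummaryTable:
    """Keep exposure variants with association p below ``threshold``."""
    kept = [r for r in exposure.records if r.pval is not None and r.pval < threshold]
    if not kept:
        logger.warning("no variants pass p < %.3g", threshold)
    return SummaryTable(trait_id=exposure.trait_id, records=kept,
                        provenance=exposure.provenance)


def ld_prune(
    candidates: SummaryTable, ld: LDTable, r2_max: float = PRUNE_R2
) -> SummaryTable:
    """Greedy LD pruning (clumping convention).

    Candidates are ranked by ascending p-value (ties keep input order) and
    visited in that order; a variant is kept iff its r² with every
    already-kept variant is <= ``r2_max``.  Pairs absent from ``ld`` are
    assumed independent (r² = 0), which is logged.  Kept records are
    returned in their original input order.
    """
    order = sorted(
        range(len(candidates.records)),
        key=lambda i: (
            candidates.records[i].pval
            if candidates.records[i].pval is not None else 1.0,
            i,
        ),
    )
    kept_idx: list[int] = []
    n_assumed = 0
    for i in order:
        rec = candidates.records[i]
        conflict = False
        for j in kept_idx:
            other = candidates.records[j]
            if (rec.rsid, other.rsid) not in ld:
                n_assumed += 1
            if ld.r2(rec.rsid, other.rsid) > r2_max:
                conflict = True
                logger.info("pruning %s (r2 > %.3g with %s)",
                            rec.rsid, r2_max, other.rsid)
                break
        if not conflict:
            kept_idx.append(i)
    if n_assumed:
        logger.info("%d variant pairs absent from LD table assumed independent",
                    n_assumed)
    kept_idx.sort()
    return SummaryTable(
        trait_id=candidates.trait_id,
        records=[candidates.records[i] for i in kept_idx],
        provenance=candidates.provenance,
    )


def find_proxy(
    target: str,
    ld: LDTable,
    available: set[str],
    r2_min: float = PROXY_R2,
) -> str | None:
    """Best available proxy for a variant missing from the outcome data.

    Returns the available rsid with maximal r² to ``target`` among those
    with r² strictly above ``r2_min``; ties break lexicographically by
    rsid; ``None`` when no candidate qualifies.
    """
    target = normalize_rsid(target)
    best: tuple[float, str] | None = None
    for cand in sorted(normalize_rsid(c) for c in available):
        if cand == target:
            continue
        r2 = ld.r2(target, cand)
        if r2 > r2_min and (best is None or r2 > best[0]):
            best = (r2, cand)
    return best[1] if best else None


def substitute_proxies(
    exposure: SummaryTable,
    outcome: SummaryTable,
    ld: LDTable | None,
    r2_min: float = PROXY_R2,
) -> dict[str, str]:
    """Proxy plan: exposure rsid -> outcome rsid for missing instruments."""
    if ld is None:
        return {}
    outcome_rsids = set(outcome.rsids)
    plan: dict[str, str] = {}
    for rec in exposure.records:
        if rec.rsid in outcome_rsids:
            continue
        proxy = find_proxy(rec.rsid, ld, outcome_rsids, r2_min)
        if proxy is not None:
            plan[rec.rsid] = proxy
            logger.info("using proxy %s for %s", proxy, rec.rsid)
    return plan


# ---------------------------------------------------------------------------
# allele alignment
# ---------------------------------------------------------------------------

def _is_palindromic(a: str, b: str) -> bool:
    return {a, b} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str | None:
    out = []
    for base in allele:
        if base not in _COMPLEMENT:
            return None
        out.append(_COMPLEMENT[base])
    return "".join(out)


def harmonize_pair(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_eaf_band: float = PALINDROME_EAF_BAND,
    proxy_map: dict[str, str] | None = None,
) -> list[HarmonizedInstrument]:
    """Align outcome effects to the exposure effect allele, variant by variant.

    For each exposure variant found in the outcome table (directly or via
    ``proxy_map``): matching alleles are kept; swapped alleles negate the
    outcome beta (action ``flipped``); strand-complemented alleles are
    complemented then aligned (non-palindromic variants only).  Palindromic
    (A/T, C/G) variants are kept only when both effect-allele frequencies
    are available, both lie outside 0.5 +/- ``palindrome_eaf_band`` and
    fall on the same side of 0.5; otherwise they are dropped as ambiguous.
    Variants whose alleles cannot be reconciled, or which are absent from
    the outcome data, are returned dropped with a reason, never raised.
    When either side lacks allele labels the pair is assumed pre-aligned,
    which is logged.
    """
    proxy_map = {normalize_rsid(k): normalize_rsid(v)
                 for k, v in (proxy_map or {}).items()}
    out_by_rsid = outcome.by_rsid()
    instruments: list[HarmonizedInstrument] = []
    for exp in exposure.records:
        proxy = proxy_map.get(exp.rsid)
        out = out_by_rsid.get(proxy) if proxy else out_by_rsid.get(exp.rsid)
        if out is None:
            instruments.append(_dropped(exp, "missing_in_outcome"))
            continue
        inst = _align_one(exp, out, palindrome_eaf_band)
        if proxy is not None and not inst.dropped:
            inst.proxy_rsid = proxy
            inst.action = "proxy_substituted"
        instruments.append(inst)
    return instruments


def _dropped(exp: VariantAssociation, reason: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        rsid=exp.rsid, beta_exp=exp.beta, se_exp=exp.se,
        beta_out=float("nan"), se_out=float("nan"),
        action="dropped", drop_reason=reason,
    )


def _align_one(
    exp: VariantAssociation,
    out: VariantAssociation,
    band: float,
) -> HarmonizedInstrument:
    if exp.effect_allele is None or out.effect_allele is None \
            or exp.other_allele is None or out.other_allele is None:
        logger.info("%s: allele labels absent on one side; assuming aligned",
                    exp.rsid)
        return HarmonizedInstrument(exp.rsid, exp.beta, exp.se, out.beta, out.se)

    ea, oa = exp.effect_allele, exp.other_allele
    oea, ooa = out.effect_allele, out.other_allele

    if _is_palindromic(ea, oa):
        if {oea, ooa} != {ea, oa}:
            return _dropped(exp, "allele_mismatch")
        if exp.eaf is None or out.eaf is None:
            return _dropped(exp, "palindromic_ambiguous")
        # outcome EAF refers to the outcome's own effect allele
        out_eaf = out.eaf if oea == ea else 1.0 - out.eaf
        lo, hi = 0.5 - band, 0.5 + band
        inside = lo <= exp.eaf <= hi or lo <= out_eaf <= hi
        same_side = (exp.eaf < 0.5) == (out_eaf < 0.5)
        if inside or not same_side:
            return _dropped(exp, "palindromic_ambiguous")
        if oea == ea:
            return HarmonizedInstrument(exp.rsid, exp.beta, exp.se,
                                        out.beta, out.se)
        return HarmonizedInstrument(exp.rsid, exp.beta, exp.se,
                                    -out.beta, out.se, action="flipped")

    if (oea, ooa) == (ea, oa):
        return HarmonizedInstrument(exp.rsid, exp.beta, exp.se, out.beta, out.se)
    if (oea, ooa) == (oa, ea):
        return HarmonizedInstrument(exp.rsid, exp.beta, exp.se,
                                    -out.beta, out.se, action="flipped")

    # strand-complement resolution, non-palindromic variants only
    cea, coa = _complement(oea), _complement(ooa)
    if cea is not None and coa is not None:
        if (cea, coa) == (ea, oa):
            return HarmonizedInstrument(exp.rsid, exp.beta, exp.se,
                                        out.beta, out.se)
        if (cea, coa) == (oa, ea):
            return HarmonizedInstrument(exp.rsid, exp.beta, exp.se,
                                        -out.beta, out.se, action="flipped")
    return _dropped(exp, "allele_mismatch")


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------

def f_statistic(r2_explained: float, n: int, k: int) -> float:
    """Joint instrument-strength F for k instruments explaining R² in n subjects."""
    if not (0.0 < r2_explained < 1.0):
        raise ValueError(f"R^2 must lie in (0,1): {r2_explained}")
    if k < 1 or n <= k + 1:
        raise ValueError(f"need n > k + 1 >= 2, got n={n}, k={k}")
    return ((n - k - 1) / k) * (r2_explained / (1.0 - r2_explained))


def per_instrument_f(instruments: list[HarmonizedInstrument]) -> dict[str, float]:
    """Per-variant strength (beta_exp / se_exp)² for reporting."""
    return {i.rsid: (i.beta_exp / i.se_exp) ** 2 for i in active(instruments)}


def compute_diagnostics(
    n_candidates: int, n_retained: int, r2_explained: float, n: int
) -> InstrumentDiagnostics:
    return InstrumentDiagnostics(
        n_candidates=n_candidates,
        n_retained=n_retained,
        r2_explained=r2_explained,
        f_statistic=f_statistic(r2_explained, n, n_retained),
    )


def harmonization_report(
    instruments: list[HarmonizedInstrument],
) -> "list[dict[str, object]]":
    """Rows for the harmonization-report TSV: one per candidate variant."""
    return [
        {
            "rsid": i.rsid,
            "action": i.action,
            "drop_reason": i.drop_reason or "",
            "proxy_rsid": i.proxy_rsid or "",
            "beta_exp": i.beta_exp,
            "se_exp": i.se_exp,
            "beta_out": i.beta_out,
            "se_out": i.se_out,
        }
        for i in instruments
    ]
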