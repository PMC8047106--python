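"""Synthetic two-sample summary statistics with known ground truth.

The generator emulates the statistical regime of a homocysteine-style
instrument panel: J = 13 independent variants jointly explaining about
5.9% of the variance of a standardized continuous exposure measured in
~44k subjects, against a binary outcome of MEGASTROKE-like size
(~440k subjects, ~1.2% cases), which puts the outcome log-odds SEs on
the ~0.02 scale.  True per-variant exposure effects gamma_j are drawn
and rescaled so that ``sum_j 2 p_j (1 - p_j) gamma_j^2`` equals the
target R²; direct (pleiotropic) outcome effects alpha_j are normal with
configurable mean, SD and correlation with gamma_j (a nonzero
correlation violates InSIDE).  Observed effects add independent normal
noise at the GWAS-approximation SEs

* continuous exposure:  s_x = 1 / sqrt(2 p (1-p) n)
* binary outcome:       s_y = 1 / sqrt(2 p (1-p) n v (1-v)),  v = case fraction

All randomness flows from a single seed through one generator stream,
so identical configurations reproduce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .summary_io import SummaryTable, VariantAssociation

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic two-sample dataset."""

    n_snp: int = 13
    beta_true: float = 0.3
    exposure_effect_range: tuple[float, float] = (0.5, 1.5)
    n_exposure: int = 44147
    n_outcome: int = 440328
    r2_target: float = 0.059
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: float = 0.0
    case_fraction: float = 0.0122
    swap_fraction: float = 0.25
    palindromic_fraction: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if not (0.0 < self.r2_target < 1.0):
            raise ValueError(f"r2_target outside (0,1): {self.r2_target}")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if abs(self.inside_violation) > 1:
            raise ValueError("inside_violation must lie in [-1,1]")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0,1)")


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset.

    ``realized_r2`` is the variance explained by the true effects (equal
    to the configured target up to floating point, by construction);
    ``estimated_r2`` is the debiased plug-in estimate from the noisy
    per-variant effects, i.e. what a practitioner could compute.
    """

    gamma: np.ndarray
    alpha: np.ndarray
    realized_r2: float
    beta_true: float
    estimated_r2: float = float("nan")
    rsids: list[str] = field(default_factory=list)


def _rsid(i: int) -> str:
    return f"rs{i + 1:06d}"


def simulate_two_sample(
    config: SimConfig,
) -> tuple[SummaryTable, SummaryTable, SimTruth]:
    """Draw one exposure table, one outcome table and their ground truth.

    A configurable fraction of outcome rows is emitted with swapped
    allele labels (beta negated) and a fraction of variants is made
    palindromic, so harmonization has real work to do; by default no
    palindromic variants are emitted and the harmonized instrument count
    equals ``n_snp``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.n_snp

    eaf = rng.uniform(0.1, 0.9, size=j)
    lo, hi = config.exposure_effect_range
    gamma = rng.uniform(lo, hi, size=j)
    var_terms = 2.0 * eaf * (1.0 - eaf)
    scale = np.sqrt(config.r2_target / np.sum(var_terms * gamma**2))
    gamma *= scale

    sx = 1.0 / np.sqrt(var_terms * config.n_exposure)
    v = config.case_fraction
    sy = 1.0 / np.sqrt(var_terms * config.n_outcome * v * (1.0 - v))

    rho = config.inside_violation
    z_gamma = (gamma - np.mean(gamma)) / (np.std(gamma) or 1.0)
    alpha = config.pleiotropy_mean + config.pleiotropy_sd * (
        rho * z_gamma + np.sqrt(1.0 - rho**2) * rng.standard_normal(j))

    gamma_hat = gamma + rng.standard_normal(j) * sx
    big_gamma_hat = config.beta_true * gamma + alpha \
        + rng.standard_normal(j) * sy

    n_pal = int(round(config.palindromic_fraction * j))
    is_pal = np.zeros(j, dtype=bool)
    is_pal[rng.choice(j, size=n_pal, replace=False)] = True
    swap = rng.random(j) < config.swap_fraction

    exp_records, out_records, rsids = [], [], []
    for i in range(j):
        rsid = _rsid(i)
        rsids.append(rsid)
        pool = _PALINDROMIC_PAIRS if is_pal[i] else _NONPALINDROMIC_PAIRS
        ea, oa = pool[rng.integers(len(pool))]
        exp_records.append(VariantAssociation(
            rsid=rsid, effect_allele=ea, other_allele=oa, eaf=float(eaf[i]),
            beta=float(gamma_hat[i]), se=float(sx[i]),
            pval=float(2.0 * stats.norm.sf(abs(gamma_hat[i] / sx[i]))),
            n=config.n_exposure, trait_id="exposure",
        ))
        o_beta, o_ea, o_oa, o_eaf = big_gamma_hat[i], ea, oa, eaf[i]
        if swap[i]:
            o_beta, o_ea, o_oa, o_eaf = -o_beta, oa, ea, 1.0 - eaf[i]
        out_records.append(VariantAssociation(
            rsid=rsid, effect_allele=o_ea, other_allele=o_oa,
            eaf=float(o_eaf), beta=float(o_beta), se=float(sy[i]),
            pval=float(2.0 * stats.norm.sf(abs(o_beta / sy[i]))),
            n=config.n_outcome, trait_id="outcome",
        ))

    realized_r2 = float(np.sum(var_terms * gamma**2))
    # debiased plug-in estimate from the noisy effects
    estimated_r2 = float(np.sum(var_terms * (gamma_hat**2 - sx**2)))
    truth = SimTruth(gamma=gamma, alpha=alpha, realized_r2=realized_r2,
                     beta_true=config.beta_true, estimated_r2=estimated_r2,
                     rsids=rsids)
    exposure = SummaryTable("exposure", exp_records,
                            provenance=f"simulated (seed={config.seed})")
    outcome = SummaryTable("outcome", out_records,
                           provenance=f"simulated (seed={config.seed})")
    return exposure, outcome, truth


def simulate_invalid_subset(
    config: SimConfig,
    n_invalid: int,
    direct_effect: float,
    invalid_weight_cap: float | None = 0.5,
) -> tuple[SummaryTable, SummaryTable, SimTruth]:
    """Dataset where a fixed-size instrument subset carries a constant
    direct (pleiotropic) outcome effect; the remainder is valid.

    The invalid subset is drawn uniformly among ``n_invalid``-subsets
    whose share of the total inverse-variance instrument weight is below
    ``invalid_weight_cap`` (default: under half), the regime in which
    majority-weight robust estimators are designed to hold up; pass
    ``invalid_weight_cap=None`` to take the first ``n_invalid`` variants
    unconditionally.  The invalid variants are identifiable from the
    returned truth as ``alpha != 0``.
    """
    if not (0 <= n_invalid <= config.n_snp):
        raise ValueError("n_invalid outside 0..n_snp")
    base = replace(config, pleiotropy_mean=0.0, pleiotropy_sd=0.0)
    exposure, outcome, truth = simulate_two_sample(base)
    if invalid_weight_cap is None or n_invalid == 0:
        chosen = np.arange(n_invalid)
    else:
        eaf = np.array([r.eaf for r in exposure.records])
        weight = 2.0 * eaf * (1.0 - eaf) * truth.gamma**2  # prop. to (gamma/sy)^2
        sub_rng = np.random.default_rng(
            None if config.seed is None else config.seed + 15485863)
        for _ in range(1000):
            chosen = sub_rng.choice(config.n_snp, size=n_invalid,
                                    replace=False)
            if weight[chosen].sum() / weight.sum() < invalid_weight_cap:
                break
        else:
            raise ValueError(
                f"no {n_invalid}-subset satisfies the weight cap "
                f"{invalid_weight_cap}")
    alpha = np.zeros(config.n_snp)
    alpha[chosen] = direct_effect
    for i in chosen:
        rec = outcome.records[i]
        # direct effect enters on the variant's simulated strand orientation
        sign = 1.0 if rec.effect_allele == exposure.records[i].effect_allele \
            else -1.0
        rec.beta = rec.beta + sign * direct_effect
        rec.pval = float(2.0 * stats.norm.sf(abs(rec.beta / rec.se)))
    truth.alpha = alpha
    return exposure, outcome, truth


def simulate_trait_panel(
    config: SimConfig,
    n_traits: int,
    assoc_pattern: Mapping[str, Iterable] | None = None,
    n_trait_sample: int = 300000,
    effect_multiple: float = 5.0,
) -> list[SummaryTable]:
    """Risk-factor association tables matched to the simulated instruments.

    ``assoc_pattern`` maps trait label -> variants truly associated with
    it, given as rsids or 1-based instrument indices; those rows get a
    true effect of ``effect_multiple`` times their SE (power ~1 at
    alpha = 0.05 for the default multiple of 5), all other rows are pure
    null noise.  Traits absent from the pattern are fully null.  Trait
    SEs use the continuous-trait approximation at ``n_trait_sample``.
    """
    config.validate()
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 104729)
    j = config.n_snp
    eaf_rng = np.random.default_rng(config.seed)
    eaf = eaf_rng.uniform(0.1, 0.9, size=j)  # same stream head as exposure
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_trait_sample)
    rsids = [_rsid(i) for i in range(j)]

    pattern: dict[str, set[str]] = {}
    for trait, subset in (assoc_pattern or {}).items():
        resolved = set()
        for item in subset:
            if isinstance(item, (int, np.integer)):
                if not (1 <= int(item) <= j):
                    raise ValueError(f"instrument index {item} outside 1..{j}")
                resolved.add(rsids[int(item) - 1])
            else:
                resolved.add(str(item).lower())
        pattern[trait] = resolved

    tables = []
    for t in range(n_traits):
        trait_id = f"trait_{t + 1}"
        truly = pattern.get(trait_id, set())
        records = []
        for i, rsid in enumerate(rsids):
            mean = effect_multiple * se[i] if rsid in truly else 0.0
            beta = mean + rng.standard_normal() * se[i]
            records.append(VariantAssociation(
                rsid=rsid, effect_allele=None, other_allele=None,
                eaf=float(eaf[i]), beta=float(beta), se=float(se[i]),
                pval=float(2.0 * stats.norm.sf(abs(beta / se[i]))),
                n=n_trait_sample, trait_id=trait_id,
            ))
        tables.append(SummaryTable(trait_id, records,
                                   provenance="simulated trait panel"))
    return tables
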