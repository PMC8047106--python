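"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized instruments with exposure effects gamma_j (SE s_xj)
and outcome effects Gamma_j (SE s_yj), the per-variant Wald ratio is
``Gamma_j / gamma_j`` with first-order standard error ``s_yj / |gamma_j|``.
The estimators implemented here pool those ratios under different
assumptions about invalid instruments:

* inverse-variance weighting (fixed and multiplicative random effects),
  valid when all instruments satisfy the exclusion restriction;
* maximum likelihood, jointly modelling measurement error on both sides;
* MR-Egger regression, allowing a common directional pleiotropy
  intercept under the InSIDE assumption;
* simple/weighted median, consistent when under half the (weight of)
  instruments are invalid;
* simple/weighted mode, consistent when the largest group of instruments
  shares the true ratio (ZEMPA).

Standard errors for the median and mode come from a seeded parametric
bootstrap; everything else is closed-form or profile-likelihood based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .harmonization import HarmonizedInstrument, active
from .summary_io import beta_se_to_or_ci

logger = logging.getLogger("mrpipe")

#: report order for the full method battery
METHOD_ORDER = (
    "ivw_random",
    "ivw_fixed",
    "maximum_likelihood",
    "egger",
    "simple_median",
    "weighted_median",
    "simple_mode",
    "weighted_mode",
)

DEFAULT_N_BOOT = 1000
MODE_GRID_POINTS = 512


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateInstrumentError(ValueError):
    """An instrument unusable for a ratio (zero exposure effect or SE)."""


class ConvergenceError(RuntimeError):
    """Numerical optimization failed; carries the optimizer trace."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace


@dataclass
class MRResult:
    """One estimator's pooled causal estimate (log-OR per SD exposure)."""

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    extra: dict = field(default_factory=dict)

    @property
    def skipped(self) -> bool:
        return "skipped" in self.extra

    def or_scale(self, level: float = 0.95) -> tuple[float, float, float]:
        """(OR, CI low, CI high) on the odds-ratio scale."""
        return beta_se_to_or_ci(self.beta, self.se, level)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.pval < alpha


def _skipped(method: str, reason: str) -> MRResult:
    nan = float("nan")
    return MRResult(method=method, n_snp=0, beta=nan, se=nan, ci_low=nan,
                    ci_high=nan, pval=nan, extra={"skipped": reason})


# ---------------------------------------------------------------------------
# ratio plumbing
# ---------------------------------------------------------------------------

def _arrays(instruments: Sequence[HarmonizedInstrument]):
    insts = active(list(instruments))
    bx = np.array([i.beta_exp for i in insts], dtype=float)
    sx = np.array([i.se_exp for i in insts], dtype=float)
    by = np.array([i.beta_out for i in insts], dtype=float)
    sy = np.array([i.se_out for i in insts], dtype=float)
    if len(bx) and (np.any(sx <= 0) or np.any(sy <= 0)):
        raise DegenerateInstrumentError("all instrument SEs must be > 0")
    if len(bx) and np.any(bx == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    return bx, sx, by, sy


def _ratios(bx, sx, by, sy):
    """First-order Wald ratios and their delta-method SEs."""
    return by / bx, sy / np.abs(bx)


def _finish(method, n_snp, beta, se, level, dist="norm", df=None, extra=None):
    z = stats.norm.ppf(0.5 + level / 2.0) if dist == "norm" \
        else stats.t.ppf(0.5 + level / 2.0, df)
    if se > 0:
        stat = abs(beta / se)
        pval = 2.0 * (stats.norm.sf(stat) if dist == "norm"
                      else stats.t.sf(stat, df))
    else:
        pval = 0.0 if beta != 0 else 1.0
    return MRResult(method=method, n_snp=n_snp, beta=float(beta), se=float(se),
                    ci_low=float(beta - z * se), ci_high=float(beta + z * se),
                    pval=float(pval), extra=extra or {})


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(inst: HarmonizedInstrument, level: float = 0.95) -> MRResult:
    """Single-variant causal estimate Gamma/gamma with SE s_y/|gamma|."""
    if inst.beta_exp == 0:
        raise DegenerateInstrumentError(f"{inst.rsid}: zero exposure effect")
    if inst.se_out <= 0:
        raise DegenerateInstrumentError(f"{inst.rsid}: outcome SE must be > 0")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    res = _finish("wald_ratio", 1, beta, se, level)
    res.extra["rsid"] = inst.rsid
    return res


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    effects_model: str = "random",
    level: float = 0.95,
    truncate_underdispersion: bool = True,
) -> MRResult:
    """Inverse-variance-weighted pooled estimate.

    Equivalent to weighted least squares of outcome on exposure effects
    through the origin with weights 1/s_yj².  Fixed and random effects
    share the point estimate; the multiplicative random-effects SE scales
    the fixed SE by the residual dispersion ``phi = sqrt(Q / (J - 1))``,
    truncated below at 1 unless ``truncate_underdispersion=False``.
    With a single instrument the result reduces to its Wald ratio.
    """
    if effects_model not in {"fixed", "random"}:
        raise ValueError(f"unknown effects model {effects_model!r}")
    bx, sx, by, sy = _arrays(instruments)
    if len(bx) == 0:
        raise InsufficientInstrumentsError("IVW needs at least 1 instrument")
    r, sr = _ratios(bx, sx, by, sy)
    w = 1.0 / sr**2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - beta) ** 2))
    extra = {"q": q, "effects_model": effects_model}
    se = se_fixed
    if effects_model == "random" and len(bx) > 1:
        phi2 = q / (len(bx) - 1)
        phi = math.sqrt(phi2)
        extra["phi"] = phi
        se = se_fixed * (max(1.0, phi) if truncate_underdispersion else phi)
    label = f"ivw_{effects_model}"
    return _finish(label, len(bx), beta, se, level, extra=extra)


def maximum_likelihood(
    instruments: Sequence[HarmonizedInstrument], level: float = 0.95
) -> MRResult:
    """Bivariate-normal maximum likelihood with free per-variant exposure effects.

    Minimizes ``sum_j [(gamma_hat_j - gamma_j)^2 / s_xj^2
    + (Gamma_hat_j - beta * gamma_j)^2 / s_yj^2]`` over (gamma_1..J, beta).
    Profiling out the gamma_j gives the 1-d objective
    ``g(beta) = sum_j (Gamma_hat_j - beta gamma_hat_j)^2 / (s_yj^2 + beta^2 s_xj^2)``,
    which is minimized from the fixed-effects IVW start; the SE comes from
    the observed information ``g''(beta)/2`` of the profile.
    """
    bx, sx, by, sy = _arrays(instruments)
    if len(bx) < 2:
        raise InsufficientInstrumentsError("maximum likelihood needs >= 2 instruments")

    def g(b: float) -> float:
        return float(np.sum((by - b * bx) ** 2 / (sy**2 + b**2 * sx**2)))

    b0 = ivw(instruments, effects_model="fixed").beta
    res = optimize.minimize(lambda v: g(v[0]), x0=[b0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 2000})
    if not res.success:
        raise ConvergenceError(f"profile-likelihood optimization failed: "
                               f"{res.message}", trace=res)
    beta = float(res.x[0])
    h = 1e-5 * max(1.0, abs(beta))
    d2 = (g(beta + h) - 2.0 * g(beta) + g(beta - h)) / h**2
    if d2 <= 0:
        raise ConvergenceError("non-positive curvature at optimum", trace=res)
    se = math.sqrt(2.0 / d2)
    return _finish("maximum_likelihood", len(bx), beta, se, level,
                   extra={"objective": float(res.fun), "n_iter": int(res.nit)})


def _oriented(bx, by):
    """Orient each instrument so the exposure effect is positive."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def egger(
    instruments: Sequence[HarmonizedInstrument],
    level: float = 0.95,
    truncate_underdispersion: bool = True,
) -> MRResult:
    """MR-Egger regression: weighted line with a pleiotropy intercept.

    Instruments are oriented to positive exposure effects; outcome effects
    are regressed on exposure effects with an unconstrained intercept and
    weights 1/s_yj².  The slope estimates the causal effect under InSIDE;
    the intercept estimates average directional pleiotropy.  Both SEs are
    multiplied by the residual scale (truncated below at 1) and p-values
    use t with J - 2 degrees of freedom.  ``extra`` carries the intercept
    triple (estimate, SE, p).
    """
    bx, sx, by, sy = _arrays(instruments)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    x, y = _oriented(bx, by)
    w = 1.0 / sy**2

    import statsmodels.api as sm

    design = sm.add_constant(x)
    fit = sm.WLS(y, design, weights=w).fit()
    scale = float(fit.scale)  # sum(w r^2) / (J - 2)
    base_se = fit.bse / math.sqrt(scale)  # unscaled (X'WX)^-1 diagonal
    mult = max(1.0, math.sqrt(scale)) if truncate_underdispersion \
        else math.sqrt(scale)
    inter_se, slope_se = float(base_se[0] * mult), float(base_se[1] * mult)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    df = j - 2
    inter_p = float(2.0 * stats.t.sf(abs(intercept / inter_se), df))
    extra = {
        "intercept": intercept,
        "intercept_se": inter_se,
        "intercept_p": inter_p,
        "residual_scale": math.sqrt(scale),
        "q": float(scale * df),
    }
    return _finish("egger", j, slope, slope_se, level, dist="t", df=df,
                   extra=extra)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight median with linear interpolation at the 0.5 crossing."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot, seed) -> float:
    """Parametric bootstrap SE: resample effects from normals at their SEs."""
    if n_boot < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.standard_normal(bx.shape) * sx
        byb = by + rng.standard_normal(by.shape) * sy
        estimates[b] = point_fn(bxb, byb)
    return float(np.std(estimates, ddof=1))


def _median_weights(weighting, r, sr):
    if weighting == "simple":
        return np.full_like(r, 1.0 / len(r))
    if weighting == "weighted":
        return (1.0 / sr**2) / np.sum(1.0 / sr**2)
    raise ValueError(f"unknown weighting {weighting!r}")


def median_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighting: str = "weighted",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    level: float = 0.95,
) -> MRResult:
    """Simple or inverse-variance-weighted median of the Wald ratios.

    The estimate interpolates the cumulative-weight function
    ``s_j = (sum_{i<=j} w_i - w_j/2) / sum w`` at 0.5 over the sorted
    ratios; the SE is a seeded parametric bootstrap (``n_boot`` resamples
    of both effect sides from normals at their reported SEs).
    """
    bx, sx, by, sy = _arrays(instruments)
    if len(bx) < 3:
        raise InsufficientInstrumentsError("median estimator needs >= 3 instruments")
    r, sr = _ratios(bx, sx, by, sy)
    weights = _median_weights(weighting, r, sr)
    beta = _weighted_median(r, weights)

    def point(bxb, byb):
        rb, srb = _ratios(bxb, sx, byb, sy)
        return _weighted_median(rb, _median_weights(weighting, rb, srb))

    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    return _finish(f"{weighting}_median", len(bx), beta, se, level,
                   extra={"n_boot": n_boot})


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    j = len(r)
    sd = float(np.std(r, ddof=1)) if j > 1 else 0.0
    mad = float(np.median(np.abs(r - np.median(r)))) / 0.6745
    # a zero MAD (clustered majority) falls back to the SD spread
    if mad > 0 and sd > 0:
        s = min(sd, mad)
    else:
        s = max(sd, mad)
    return phi * 0.9 * s * j ** (-1.0 / 5.0)


def _mode_point(r, weights, h, n_grid=MODE_GRID_POINTS) -> float:
    if h <= 0 or np.ptp(r) == 0:
        return float(r[0])
    grid = np.linspace(np.min(r) - 3 * h, np.max(r) + 3 * h, n_grid)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighting: str = "weighted",
    bandwidth_factor: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    level: float = 0.95,
    n_grid: int = MODE_GRID_POINTS,
) -> MRResult:
    """Mode of a normal-kernel density over the Wald ratios.

    Bandwidth ``h = phi * 0.9 * min(sd, mad/0.6745) * J^(-1/5)``; the
    density is evaluated on an ``n_grid``-point grid spanning the ratio
    range extended by 3h on each side.  Identical ratios (zero bandwidth)
    return the common ratio directly.  SE by parametric bootstrap.
    """
    bx, sx, by, sy = _arrays(instruments)
    if len(bx) < 3:
        raise InsufficientInstrumentsError("mode estimator needs >= 3 instruments")
    r, sr = _ratios(bx, sx, by, sy)
    weights = _median_weights(weighting, r, sr)
    h = _mode_bandwidth(r, bandwidth_factor)
    beta = _mode_point(r, weights, h, n_grid)

    def point(bxb, byb):
        rb, srb = _ratios(bxb, sx, byb, sy)
        wb = _median_weights(weighting, rb, srb)
        return _mode_point(rb, wb, _mode_bandwidth(rb, bandwidth_factor), n_grid)

    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    return _finish(f"{weighting}_mode", len(bx), beta, se, level,
                   extra={"n_boot": n_boot, "bandwidth": h})


@dataclass
class EstimatorConfig:
    """Settings shared by the full method battery."""

    level: float = 0.95
    n_boot: int = DEFAULT_N_BOOT
    seed: int | None = None
    bandwidth_factor: float = 1.0
    truncate_underdispersion: bool = True


def run_all_methods(
    instruments: Sequence[HarmonizedInstrument],
    config: EstimatorConfig | None = None,
) -> list[MRResult]:
    """All eight estimators in the fixed report order.

    Methods whose preconditions fail (too few usable instruments) are
    returned as skipped rows carrying the reason rather than raised.
    """
    cfg = config or EstimatorConfig()
    seed = cfg.seed

    def call(method, fn):
        try:
            return fn()
        except (InsufficientInstrumentsError, DegenerateInstrumentError) as exc:
            logger.info("skipping %s: %s", method, exc)
            return _skipped(method, str(exc))

    return [
        call("ivw_random", lambda: ivw(
            instruments, "random", cfg.level, cfg.truncate_underdispersion)),
        call("ivw_fixed", lambda: ivw(instruments, "fixed", cfg.level)),
        call("maximum_likelihood",
             lambda: maximum_likelihood(instruments, cfg.level)),
        call("egger", lambda: egger(
            instruments, cfg.level, cfg.truncate_underdispersion)),
        call("simple_median", lambda: median_estimator(
            instruments, "simple", cfg.n_boot, seed, cfg.level)),
        call("weighted_median", lambda: median_estimator(
            instruments, "weighted", cfg.n_boot, seed, cfg.level)),
        call("simple_mode", lambda: mode_estimator(
            instruments, "simple", cfg.bandwidth_factor, cfg.n_boot, seed,
            cfg.level)),
        call("weighted_mode", lambda: mode_estimator(
            instruments, "weighted", cfg.bandwidth_factor, cfg.n_boot, seed,
            cfg.level)),
    ]


def results_table(results: Sequence[MRResult], level: float = 0.95):
    """Rows for the results TSV, with odds-ratio columns alongside."""
    import json as _json

    rows = []
    for res in results:
        if res.skipped or not np.isfinite(res.se):
            or_val = or_lo = or_hi = float("nan")
        else:
            or_val, or_lo, or_hi = res.or_scale(level)
        rows.append({
            "method": res.method, "n_snp": res.n_snp, "beta": res.beta,
            "se": res.se, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "pval": res.pval, "or": or_val, "or_ci_low": or_lo,
            "or_ci_high": or_hi, "extra": _json.dumps(res.extra, sort_keys=True),
        })
    return rows
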