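"""Reading, writing and rescaling GWAS summary statistics.

Summary-statistic exchange in two-sample Mendelian randomization is
per-variant: an effect size (beta), its standard error, the allele the
effect is reported for, and optionally the effect-allele frequency,
p-value and sample size.  Binary outcomes are usually published as odds
ratios with 95% confidence intervals; all internal computation happens
on the log-odds scale, so this module owns the OR <-> (beta, se)
conversions as well.

Bundled with the package are the per-variant odds-ratio tables for the
13 plasma-homocysteine instruments against five cerebrovascular and
five neurodegenerative outcomes, transcribed from published
consortium-based association results.  They are outcome-side tables
only (SNP -> disease); the exposure-side per-variant effects
(SNP -> homocysteine, in SD units) were not printed alongside them.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrpipe")

#: two-sided 97.5% normal quantile used for 95% confidence intervals
Z_95 = 1.959964

VALID_BASES = frozenset("ACGT")


class ConfigurationError(ValueError):
    """A required column or setting is missing or malformed."""


class EmptyInputError(ValueError):
    """An input table contained no usable rows."""


class DuplicateVariantError(ValueError):
    """The same rsid appeared more than once in one table."""


class UnknownFixtureError(KeyError):
    """Requested bundled table does not exist."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele change in the trait: SD units for
    continuous traits, log-odds for binary ones.  ``se`` may be zero only
    for degenerate rows recovered from heavily rounded published tables;
    :func:`read_summary_table` never emits such rows.
    """

    rsid: str
    effect_allele: str | None
    other_allele: str | None
    eaf: float | None
    beta: float
    se: float
    pval: float | None = None
    n: float | None = None
    trait_id: str = ""

    def __post_init__(self) -> None:
        self.rsid = normalize_rsid(self.rsid)
        if self.effect_allele is not None:
            self.effect_allele = str(self.effect_allele).upper()
        if self.other_allele is not None:
            self.other_allele = str(self.other_allele).upper()

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated field invariant."""
        if not self.rsid:
            raise ValueError("empty rsid")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: non-finite beta")
        if not np.isfinite(self.se) or self.se < 0:
            raise ValueError(f"{self.rsid}: se must be finite and >= 0")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.rsid}: eaf must lie strictly in (0,1)")
        if self.pval is not None and not (0.0 <= self.pval <= 1.0):
            raise ValueError(f"{self.rsid}: pval outside [0,1]")
        if self.effect_allele is not None and self.other_allele is not None:
            if self.effect_allele == self.other_allele:
                raise ValueError(f"{self.rsid}: identical alleles")


@dataclass
class LDTable:
    """Pairwise linkage-disequilibrium lookups, symmetric in the pair."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        a, b = normalize_rsid(a), normalize_rsid(b)
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 out of [0,1]: {r2}")
        self.entries[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str, default: float = 0.0) -> float:
        """r² between two variants; a variant with itself is 1."""
        if normalize_rsid(a) == normalize_rsid(b):
            return 1.0
        return self.entries.get(self._key(a, b), default)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDTable":
        """Read a three-column (rsid_a, rsid_b, r2) delimited table."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 3:
            raise ConfigurationError("LD table needs columns rsid_a, rsid_b, r2")
        table = cls()
        for a, b, r2 in df.iloc[:, :3].itertuples(index=False):
            table.set(str(a), str(b), float(r2))
        return table


@dataclass
class SummaryTable:
    """All per-variant associations of one trait, keyed by unique rsid."""

    trait_id: str
    records: list[VariantAssociation] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise DuplicateVariantError(
                    f"duplicate rsid {rec.rsid} in table {self.trait_id!r}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [rec.rsid for rec in self.records]

    def by_rsid(self) -> dict[str, VariantAssociation]:
        return {rec.rsid: rec for rec in self.records}

    def get(self, rsid: str) -> VariantAssociation | None:
        return self.by_rsid().get(normalize_rsid(rsid))

    def subset(self, rsids: Iterable[str]) -> "SummaryTable":
        keep = {normalize_rsid(r) for r in rsids}
        return SummaryTable(
            trait_id=self.trait_id,
            records=[r for r in self.records if r.rsid in keep],
            provenance=self.provenance,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pval": [r.pval for r in self.records],
                "n": [r.n for r in self.records],
            }
        )

    def write_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the table as TSV plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {"trait_id": self.trait_id, "n_records": len(self),
                    "provenance": self.provenance}
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2) + "\n")


def normalize_rsid(rsid: str) -> str:
    return str(rsid).strip().lower()


# ---------------------------------------------------------------------------
# effect-scale conversions
# ---------------------------------------------------------------------------

def _z_quantile(level: float) -> float:
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level outside (0,1): {level}")
    if abs(level - 0.95) < 1e-12:
        return Z_95
    return float(stats.norm.ppf(0.5 + level / 2.0))


def or_ci_to_beta_se(
    or_value: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """Convert an odds ratio with confidence interval to (log-odds, se).

    Under the normal approximation the CI half-width on the log scale is
    z * se, hence ``beta = ln(OR)`` and
    ``se = (ln ci_high - ln ci_low) / (2 z)``.
    """
    if min(or_value, ci_low, ci_high) <= 0.0:
        raise ValueError("odds ratio and CI bounds must be positive")
    if not (ci_low <= or_value <= ci_high):
        raise ValueError(
            f"CI ({ci_low}, {ci_high}) does not bracket OR {or_value}")
    z = _z_quantile(level)
    beta = math.log(or_value)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return beta, se


def beta_se_to_or_ci(
    beta: float, se: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Inverse of :func:`or_ci_to_beta_se`: exp-transform with z half-width."""
    if se < 0:
        raise ValueError(f"negative se: {se}")
    z = _z_quantile(level)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


# ---------------------------------------------------------------------------
# delimited-table ingestion
# ---------------------------------------------------------------------------

#: default column names for GWAS-catalog-style sharing formats
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_MANDATORY = ("rsid", "beta", "se")


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
    delimiter: str = "\t",
) -> SummaryTable:
    """Read a delimited per-variant table into a :class:`SummaryTable`.

    Rows violating field invariants (se <= 0, eaf outside (0,1), p outside
    [0,1], identical alleles) are dropped and counted in the log; duplicated
    rsids raise :class:`DuplicateVariantError`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=delimiter)
    for key in _MANDATORY:
        if cmap[key] not in df.columns:
            raise ConfigurationError(
                f"column {cmap[key]!r} (field {key!r}) missing from {path}")

    def cell(row, key):
        col = cmap.get(key)
        if col is None or col not in df.columns:
            return None
        val = row[col]
        return None if pd.isna(val) else val

    records: list[VariantAssociation] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            rec = VariantAssociation(
                rsid=str(cell(row, "rsid")),
                effect_allele=cell(row, "effect_allele"),
                other_allele=cell(row, "other_allele"),
                eaf=_opt_float(cell(row, "eaf")),
                beta=float(cell(row, "beta")),
                se=float(cell(row, "se")),
                pval=_opt_float(cell(row, "pval")),
                n=_opt_float(cell(row, "n")),
                trait_id=trait_id or str(path),
            )
            rec.validate()
            if rec.se == 0.0:
                raise ValueError(f"{rec.rsid}: se must be > 0")
        except (TypeError, ValueError) as exc:
            n_dropped += 1
            logger.info("dropping row from %s: %s", path, exc)
            continue
        records.append(rec)
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows", path, n_dropped)
    if not records:
        raise EmptyInputError(f"no valid rows in {path}")
    table = SummaryTable(trait_id=trait_id or str(path), records=records,
                         provenance=f"read from {path}")
    table.n_dropped = n_dropped  # type: ignore[attr-defined]
    return table


def _opt_float(value) -> float | None:
    return None if value is None else float(value)


# ---------------------------------------------------------------------------
# bundled homocysteine -> disease tables
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "SAO", "LAA", "CE", "nonsubtyped_IS", "TIA",
    "MS", "AD", "PD", "ALS", "FTD",
)

_SAO_NOTE = (
    "Pooled estimate reported for this outcome: OR 1.329; the source "
    "prints two different 95% CIs for it (1.047-1.612 in the abstract, "
    "1.002-1.763 in the results text). The per-variant rows here are "
    "stored as printed; the discrepancy is noted, not resolved."
)


def _fixture_frame() -> pd.DataFrame:
    with resources.files("mrpipe").joinpath(
            "data/outcome_associations.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"proxy": "string"})
    return df.rename(columns={"or": "or_value"})


def load_fixture(name: str) -> SummaryTable:
    """Load one bundled outcome table, converted to the log-odds scale.

    ``name`` is one of :data:`FIXTURE_NAMES`.  Rows printed "NA" in the
    source (variant absent from that outcome dataset) are omitted and the
    omission logged.  Rows published as 1.00 (1.00-1.00) -- tiny effects
    rounded away on a linear risk scale -- convert to beta 0, se 0 and are
    retained so record counts match the published tables; estimators
    reject them separately.  Only outcome-side (SNP -> disease) tables are
    bundled: no per-variant exposure-side table was published with them.
    """
    if name not in FIXTURE_NAMES:
        raise UnknownFixtureError(
            f"unknown bundled table {name!r}; available outcome-side tables: "
            f"{', '.join(FIXTURE_NAMES)} (exposure-side per-variant effects "
            "are not bundled)")
    df = _fixture_frame()
    df = df[df["outcome"] == name]
    records: list[VariantAssociation] = []
    proxies: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if pd.isna(row.or_value):
            logger.info("fixture %s: omitting NA row %s", name, row.rsid)
            continue
        or_value, ci_low, ci_high = float(row.or_value), float(row.ci_low), float(row.ci_high)
        beta, se = or_ci_to_beta_se(or_value, ci_low, ci_high)
        rec = VariantAssociation(
            rsid=row.rsid, effect_allele=None, other_allele=None, eaf=None,
            beta=beta, se=se, pval=float(row.pval), trait_id=name,
        )
        records.append(rec)
        if isinstance(row.proxy, str) and row.proxy:
            proxies[rec.rsid] = normalize_rsid(row.proxy)
    provenance = (
        f"bundled outcome-side association table {name!r}; ORs/CIs converted "
        "to log-odds on load; NA rows omitted."
    )
    if name == "SAO":
        provenance += " " + _SAO_NOTE
    if proxies:
        provenance += " Proxy variants used in the source: " + ", ".join(
            f"{t} (proxy: {p})" for t, p in proxies.items())
    table = SummaryTable(trait_id=name, records=records, provenance=provenance)
    table.proxies = proxies  # type: ignore[attr-defined]
    return table


def fixture_proxies(name: str) -> dict[str, str]:
    """Mapping instrument rsid -> proxy rsid used in a bundled table."""
    return dict(getattr(load_fixture(name), "proxies", {}))
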