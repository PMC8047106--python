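import numpy as np
import pytest

from mrpipe.harmonization import HarmonizedInstrument
from mrpipe.summary_io import SummaryTable, VariantAssociation


def make_instruments(bx, sx, by, sy) -> list[HarmonizedInstrument]:
    """Harmonized instruments straight from effect/SE arrays."""
    return [
        HarmonizedInstrument(
            rsid=f"rs{i + 1:06d}", beta_exp=float(b), se_exp=float(s),
            beta_out=float(bo), se_out=float(so))
        for i, (b, s, bo, so) in enumerate(zip(bx, sx, by, sy))
    ]


def random_instruments(rng, j=10, beta=0.3):
    """Instruments with heterogeneous SEs around a common true ratio."""
    bx = rng.uniform(0.05, 0.2, j) * rng.choice([-1.0, 1.0], j)
    sx = rng.uniform(0.005, 0.02, j)
    sy = rng.uniform(0.01, 0.05, j)
    by = beta * bx + rng.standard_normal(j) * sy
    return make_instruments(bx, sx, by, sy)


def make_table(trait_id, rsids, betas, ses, pvals=None, eafs=None,
               alleles=None):
    records = []
    for i, rsid in enumerate(rsids):
        ea, oa = alleles[i] if alleles else (None, None)
        records.append(VariantAssociation(
            rsid=rsid, effect_allele=ea, other_allele=oa,
            eaf=None if eafs is None else eafs[i],
            beta=betas[i], se=ses[i],
            pval=None if pvals is None else pvals[i],
            trait_id=trait_id))
    return SummaryTable(trait_id=trait_id, records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
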