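import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrmediate.gwas_io import SummaryStatRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=None,
    n=10_000,
    chrom=None,
    pos=None,
):
    """Record builder with a p-value consistent with beta/se unless overridden."""
    from scipy import stats

    if pval is None:
        pval = float(min(max(2 * stats.norm.sf(abs(beta) / se), 1e-300), 1.0))
    return SummaryStatRecord(
        variant_id=variant_id, effect_allele=effect_allele, other_allele=other_allele,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n, chrom=chrom, pos=pos,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate_pairs(seed, J=20, theta=0.3, sx=0.005, sy=0.02, b_scale=0.1,
                   pleiotropy=None):
    """Plain (bx, by, sx, sy) arrays from the linear instrument model."""
    r = np.random.default_rng(seed)
    b = r.normal(0, b_scale, J)
    sxa = np.full(J, sx)
    sya = np.full(J, sy)
    bx = b + r.normal(0, sxa)
    by = theta * b + r.normal(0, sya)
    if pleiotropy is not None:
        by = by + pleiotropy
    return bx, by, sxa, sya
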