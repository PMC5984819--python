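import numpy as np
import pytest

from varprov.model import VariantRecord
from varprov.simulate import SimConfig, simulate_study

# a desk-scale study: same structure as the default conditions, smaller counts
SMALL_CONFIG = SimConfig(
    seed=11,
    fp_per_sample=200,
    panel_positions=400,
    panel_accessions=25,
    n_expressed_panel_positions=150,
    n_cluster_variants=40,
)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared across test modules (read-only)."""
    return simulate_study(SMALL_CONFIG)


def make_record(
    chrom="Chr01",
    pos=100,
    ref="A",
    alt="G",
    qual=500.0,
    fs=1.0,
    qd=20.0,
    calls=(0,),
    depths=None,
):
    """Terse VariantRecord builder for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    if depths is None:
        depths = np.full(len(calls), 30, dtype=np.int32)
    else:
        depths = np.asarray(depths, dtype=np.int32)
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, fs=fs, qd=qd,
        calls=calls, depths=depths,
    )
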