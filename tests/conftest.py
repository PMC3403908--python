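import numpy as np
import pytest

from ibdbench.core import GeneticMap, HaplotypePanel, uniform_map


@pytest.fixture
def simple_map() -> GeneticMap:
    """Uniform 1 cM/Mb map over 10 cM."""
    return uniform_map("1", 10.0)


def make_panel(haplotypes, cm=None, chrom="1", gmap=None, bp_per_cm=1_000_000):
    """Hand-built panel from a {0,1} matrix; sites evenly spaced in cM."""
    H = np.asarray(haplotypes, dtype=np.uint8)
    m = H.shape[1]
    if cm is None:
        cm = np.arange(1, m + 1, dtype=float) * 0.01
    cm = np.asarray(cm, dtype=float)
    bp = np.round(cm * bp_per_cm).astype(np.int64)
    n_samples = H.shape[0] // 2
    return HaplotypePanel(
        chrom=chrom,
        samples=[f"S{i:04d}" for i in range(n_samples)],
        bp=bp,
        cm=cm,
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "G", dtype=object),
        haplotypes=H,
        gmap=gmap,
    )


@pytest.fixture
def two_sample_panel() -> HaplotypePanel:
    """2 samples x 6 sites, sites at 0.01..0.06 cM."""
    return make_panel([
        [0, 1, 0, 1, 0, 1],
        [1, 1, 0, 0, 1, 1],
        [0, 1, 1, 1, 0, 0],
        [1, 0, 0, 0, 1, 1],
    ])
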