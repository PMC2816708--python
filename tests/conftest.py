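import numpy as np
import pytest

from eboxlink import BackgroundModel, MotifMatrix, PromoterRecord, ScanParams


@pytest.fixture
def uniform_bg():
    return BackgroundModel(np.full(4, 0.25), "uniform")


@pytest.fixture
def scan_params():
    return ScanParams(prior=0.1, strands="both")


@pytest.fixture
def ebox_matrix():
    return MotifMatrix.from_consensus("EBOX-CACGTG", "CACGTG")


def make_promoter(seq, gene_id="g1", window_up=None, window_down=None, offset=None):
    """Promoter helper: by default the whole sequence is downstream of the TSS."""
    if window_up is None and offset is None:
        window_up, offset = 0, 0
    elif offset is None:
        offset = -window_up
    if window_down is None:
        window_down = len(seq) - (window_up or 0)
    return PromoterRecord(gene_id, window_up or 0, window_down, seq, offset)


@pytest.fixture
def random_promoters():
    """Deterministic batch of random 300 bp promoters (TSS at base 250)."""
    rng = np.random.default_rng(42)
    out = []
    for i in range(20):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=300))
        out.append(PromoterRecord(f"g{i:02d}", 250, 50, seq, -250))
    return out
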