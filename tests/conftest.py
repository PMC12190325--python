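import numpy as np
import pytest

from spikeprom import seqdata
from spikeprom.model import ModelConfig, build


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_cfg():
    """A small but structurally complete model: every stage present."""
    return ModelConfig(L=16, T=3, channels=4, K=3, heads=2, dropout_p=0.0)


@pytest.fixture
def tiny_net(tiny_cfg):
    return build(tiny_cfg, seed=7)


@pytest.fixture
def strong_motif_records():
    """Easily separable synthetic set: near-exact -35/-10 boxes."""
    spec = seqdata.prok81_spec(60, 60, seed=3, sub_prob=0.05)
    return seqdata.generate_synthetic(spec)


@pytest.fixture
def fasta_pair(tmp_path, strong_motif_records):
    pos = [r for r in strong_motif_records if r.label == 1]
    neg = [r for r in strong_motif_records if r.label == 0]
    ppath, npath = tmp_path / "pos.fasta", tmp_path / "neg.fasta"
    seqdata.write_fasta(pos, ppath)
    seqdata.write_fasta(neg, npath)
    return ppath, npath
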