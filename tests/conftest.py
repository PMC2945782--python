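import numpy as np
import pytest

from adiporeg.motifs import BASES, PWM
from adiporeg.promoters import Promoter


def make_promoter(
    gene_id="p1",
    sequence="ACGT" * 25,
    conservation=None,
    chrom="chr1",
    start=0,
    strand="+",
):
    seq = sequence
    cons = (
        np.ones(len(seq)) if conservation is None else np.asarray(conservation, float)
    )
    return Promoter(gene_id, chrom, start, start + len(seq), strand, seq, cons)


@pytest.fixture
def promoter_factory():
    return make_promoter


def random_promoter(rng, length, gene_id="p"):
    seq = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
    cons = rng.uniform(0.0, 1.0, size=length)
    return make_promoter(gene_id, seq, cons)


def random_count_pwm(rng, width, total=20):
    counts = rng.multinomial(total, [0.25] * 4, size=width).T.astype(float)
    return PWM(motif_id="rnd", counts=counts)
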