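import numpy as np
import pytest

from locusplot import make_locus_set
from locusplot.model import Feature, Locus


@pytest.fixture
def small_truth(tmp_path):
    """4-locus synthetic set with files on disk."""
    return make_locus_set(n_loci=4, n_core=10, n_cargo_pool=8,
                          cargo_per_locus=2, seed=11, outdir=tmp_path)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_simple_locus(locus_id="L1", length=1000, genes=(), circular=False):
    """Quick locus with (start, end, strand, label, group, cls) gene tuples."""
    feats = []
    for i, (start, end, strand, label, group, cls) in enumerate(genes):
        feats.append(
            Feature(
                feature_id=f"{locus_id}_g{i + 1}",
                type="CDS",
                start=start, end=end, strand=strand,
                label=label, protein_seq="M" + "A" * 20,
                group_id=group, group_class=cls,
            )
        )
    return Locus(locus_id=locus_id, length_bp=length, sequence="A" * length,
                 circular=circular, features=feats)
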