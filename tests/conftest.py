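import numpy as np
import pytest

from famvar import make_pedigree
from famvar.types import HET, HOM_ALT, HOM_REF, MISSING, AnnotatedVariant, ScorePanel


@pytest.fixture
def roles():
    """4 cases, 1 possible carrier, 1 control (the study family layout)."""
    return make_pedigree(n_cases=4, n_controls=1, n_carriers=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_variant(pos=100, genotypes=None, **kwargs):
    """Minimal valid variant for unit tests."""
    gts = genotypes or {"S1": HET}
    defaults = dict(
        chrom="1", pos=pos, ref="A", alt="G", genotypes=gts,
        qual=50.0, depth=20, fwd_reads=5, rev_reads=5, caller_filter="PASS",
    )
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


def random_genotype_variant(rng, roles, pos, p_carrier=0.3, p_missing=0.05):
    """Variant with i.i.d. random genotypes over the pedigree samples."""
    gts = {}
    for s in roles.sample_ids:
        u = rng.random()
        if u < p_missing:
            gts[s] = MISSING
        elif u < p_missing + p_carrier:
            gts[s] = HET if rng.random() < 0.8 else HOM_ALT
        else:
            gts[s] = HOM_REF
    return make_variant(pos=pos, genotypes=gts)
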