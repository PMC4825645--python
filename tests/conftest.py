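import numpy as np
import pytest

from selfscreen import AlleleClass, Fish, Genotype, MutantAllele, ScreenConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20160120)


@pytest.fixture
def zygotic_allele():
    return MutantAllele("m", AlleleClass.ZYGOTIC_LETHAL, "curly tail", penetrance=1.0)


@pytest.fixture
def sterile_i_allele():
    return MutantAllele("s", AlleleClass.STERILE_TYPE_I, "maternal effect")


@pytest.fixture
def sterile_ii_allele():
    return MutantAllele("t", AlleleClass.STERILE_TYPE_II, "nonegg layer")


def make_mother(genotype, fish_id="F2-1", expressed=None):
    return Fish(fish_id, "R001", "F2", "R001-F1", genotype,
                expressed_sterile=expressed)


@pytest.fixture
def het_mother():
    return make_mother(Genotype.from_dosages({"m": 1}))


@pytest.fixture
def small_config():
    return ScreenConfig(n_f1_families=5, seed=7)
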