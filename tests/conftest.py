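import numpy as np
import pytest

from holeysim import ExplicitLandscape, Genotype, RussianRouletteLandscape
from holeysim.fixtures import make_five_locus_example
from holeysim.genotypes import iter_all_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240122)


@pytest.fixture(scope="session")
def five_locus_example():
    """Five-locus worked-example landscape and the (pop1, pop2) genotypes."""
    return make_five_locus_example()


@pytest.fixture(scope="session")
def rr_land():
    return RussianRouletteLandscape(L=30, p=0.5, landscape_seed=42)


@pytest.fixture
def all_viable_L6():
    """Fully viable 6-locus binary landscape (everything neutral)."""
    return ExplicitLandscape(6, "binary", inviable=[])


@pytest.fixture
def two_island_L3():
    """Three-locus landscape where only 000 and 111 are viable."""
    inviable = [
        g.sequence for g in iter_all_genotypes(3, "binary")
        if g.sequence not in ("000", "111")
    ]
    return ExplicitLandscape(3, "binary", inviable=inviable)


class ScriptedFolder:
    """StructureProvider stub mapping exact sequences to fixed structures."""

    def __init__(self, table, default=None):
        self.table = dict(table)
        self.default = default
        self.calls = 0

    def fold(self, sequence: str) -> str:
        self.calls += 1
        if sequence in self.table:
            return self.table[sequence]
        if self.default is not None:
            return self.default
        raise KeyError(sequence)


@pytest.fixture
def scripted_folder_cls():
    return ScriptedFolder
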