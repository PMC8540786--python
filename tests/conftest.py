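import numpy as np
import pytest

from ssrpopgen.io import GenotypeTable, IndividualMeta, MarkerDef
from ssrpopgen.simulate import study_shaped_fixture


def make_table(calls, metas=None, locus_names=None):
    """Build a GenotypeTable from a nested list of (a1, a2) pairs.

    ``calls[i][j]`` is the call of individual i at locus j; ``(0, 0)`` is
    missing.
    """
    alleles = np.asarray(calls, dtype=np.int64)
    n, L = alleles.shape[:2]
    if metas is None:
        metas = [IndividualMeta(sample_id=f"S{i + 1}") for i in range(n)]
    loci = [MarkerDef(name=name) for name in (locus_names or [f"L{j + 1}" for j in range(L)])]
    return GenotypeTable(alleles, metas, loci)


@pytest.fixture
def toy_pair():
    """Two individuals, one locus: (100,100) and (100,102)."""
    return make_table([[[100, 100]], [[100, 102]]])


@pytest.fixture
def two_group_metas():
    def build(n_per_group):
        metas = []
        for g, label in enumerate(["A", "B"][: len(n_per_group)]):
            for k in range(n_per_group[g]):
                metas.append(
                    IndividualMeta(
                        sample_id=f"{label}{k + 1}", variety=label, country=label
                    )
                )
        return metas

    return build


@pytest.fixture(scope="session")
def fixture104():
    """Study-shaped synthetic collection (104 individuals x 20 loci)."""
    return study_shaped_fixture(seed=2021)
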