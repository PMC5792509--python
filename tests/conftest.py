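import numpy as np
import pytest

from antcolonykin.matrix import AlleleFrequencies, GenotypeMatrix


def make_matrix(calls, trees=None, species="sp", castes=None, excluded=None):
    """Small GenotypeMatrix from a nested list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        calls=calls,
        ids=np.array([f"i{k}" for k in range(n)], dtype=object),
        species=np.full(n, species, dtype=object),
        tree=np.array(trees if trees is not None
                      else ["t0"] * n, dtype=object),
        caste=np.array(castes if castes is not None
                       else ["worker"] * n, dtype=object),
        loci=np.array([f"l{j}" for j in range(m)], dtype=object),
        excluded=excluded,
    )


@pytest.fixture
def uniform_freqs():
    """Five loci, reference-allele frequency 0.5 everywhere."""
    return AlleleFrequencies(
        p=np.full(5, 0.5), loci=np.array([f"l{j}" for j in range(5)],
                                         dtype=object))


@pytest.fixture
def panel300():
    from antcolonykin.syndata import draw_allele_frequencies

    return draw_allele_frequencies(300, 0.1, 0.5, seed=77)
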