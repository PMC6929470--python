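import numpy as np
import pytest

from omegak.alignment import CodonAlignment
from omegak.genetic_code import SENSE_CODONS
from omegak.model import CodonModel
from omegak.rates import f1x4_frequencies
from omegak.trees import LabelledTree


@pytest.fixture
def uniform_pi():
    return np.ones(61) / 61


@pytest.fixture
def skew_pi():
    return f1x4_frequencies([0.1, 0.2, 0.3, 0.4])


@pytest.fixture
def mixture_model(skew_pi):
    return CodonModel(
        kappa=2.0,
        codon_freqs=skew_pi,
        omega_categories=[(0.2, 0.5), (1.0, 0.3), (2.5, 0.2)],
        k=0.4,
    )


@pytest.fixture
def three_taxon_tree():
    return LabelledTree.from_newick("(A:0.1,(B{test}:0.2,C{test}:0.15){test}:0.05);")


def random_alignment(taxa, n_codons, seed):
    """Random (not tree-generated) codon alignment for oracle tests."""
    rng = np.random.default_rng(seed)
    seqs = [
        "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, n_codons))
        for _ in taxa
    ]
    return CodonAlignment(list(taxa), seqs)


@pytest.fixture
def small_alignment():
    return random_alignment(["A", "B", "C"], 5, seed=7)
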