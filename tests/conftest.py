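import numpy as np
import pytest

from gtpanel.model import MISSING, GenotypeMatrix
from gtpanel.simulate import DriftParams, simulate_temporal_genotypes


def make_matrix(pop_calls, alleles=("A", "C"), loci=None, collections=None):
    """Build a GenotypeMatrix from per-population per-locus call arrays.

    ``pop_calls`` is a list (per collection) of (n, L, 2) arrays of allele
    indices (MISSING allowed).
    """
    blocks = [np.asarray(b, dtype=np.int16) for b in pop_calls]
    n_loci = blocks[0].shape[1]
    loci = loci or [f"l{j}" for j in range(n_loci)]
    individuals, labels = [], []
    for gi, b in enumerate(blocks):
        lab = collections[gi] if collections else gi
        for k in range(b.shape[0]):
            individuals.append(f"p{gi}_i{k}")
            labels.append(lab)
    calls = np.concatenate(blocks, axis=0)
    cats = [list(alleles)] * n_loci if isinstance(alleles[0], str) else [list(a) for a in alleles]
    return GenotypeMatrix(individuals, labels, loci, cats, calls)


@pytest.fixture(scope="session")
def small_temporal_gm():
    """A small default-conditions temporal dataset (shared, read-only)."""
    gm, truth = simulate_temporal_genotypes(DriftParams(n_loci=80, seed=11))
    return gm, truth


def build_panel_for_gm(gm, seed=0, locus_len=150, snp_margin=40):
    """A ready-made primer/probe panel matching a genotype matrix."""
    from gtpanel.simulate import panel_for_genotypes

    return panel_for_genotypes(gm, seed=seed, locus_len=locus_len, snp_margin=snp_margin)
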