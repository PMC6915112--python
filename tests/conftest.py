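"""Shared fixtures: published-table fixtures and random-matrix strategies."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import strategies as st

from pseudohet.model import DNA_BASES, GenotypeMatrix, Locus, read_matrix_tsv

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def table1_matrix() -> GenotypeMatrix:
    """The five representative genotyped loci printed for 8 individuals."""
    return read_matrix_tsv(DATA_DIR / "table1_genotypes.tsv")


@pytest.fixture(scope="session")
def table2_sequences() -> pd.DataFrame:
    """Per-sequence annotation rows expanded from the printed species counts."""
    from pseudohet.classify import expand_annotation_counts

    counts = pd.read_csv(DATA_DIR / "table2_annotation_counts.tsv", sep="\t")
    return expand_annotation_counts(counts)


def make_matrix(codes, individuals=None, scaffold="s1", ref="A", alt="G") -> GenotypeMatrix:
    """Build a matrix from an int code grid with auto-generated loci/ids."""
    codes = np.asarray(codes, dtype=np.int8)
    n_loci, n_ind = codes.shape
    if individuals is None:
        individuals = ["female", "male"] + [f"off{k}" for k in range(n_ind - 2)]
    loci = [Locus(scaffold, i + 1, ref, alt) for i in range(n_loci)]
    return GenotypeMatrix(loci, list(individuals), codes)


@st.composite
def matrices(draw, min_loci=0, max_loci=8, min_ind=2, max_ind=6):
    """Random valid genotype matrices (loci unique, parents first)."""
    n_loci = draw(st.integers(min_loci, max_loci))
    n_ind = draw(st.integers(min_ind, max_ind))
    individuals = [f"ind{j}" for j in range(n_ind)]
    loci = []
    for i in range(n_loci):
        scaffold = f"s{draw(st.integers(1, 3))}"
        ref, alt = draw(
            st.tuples(st.sampled_from(DNA_BASES), st.sampled_from(DNA_BASES)).filter(
                lambda p: p[0] != p[1]
            )
        )
        loci.append(Locus(scaffold, 1000 * (i + 1), ref, alt))
    flat = draw(
        st.lists(st.integers(0, 3), min_size=n_loci * n_ind, max_size=n_loci * n_ind)
    )
    codes = np.array(flat, dtype=np.int8).reshape(n_loci, n_ind)
    return GenotypeMatrix(loci, individuals, codes)
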