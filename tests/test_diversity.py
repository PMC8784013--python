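"""Diversity statistics: frozen arithmetic examples, rarefaction oracle and
ordering invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatpop.diversity import (
    WHOLE_SAMPLE,
    allele_frequencies,
    allelic_richness,
    diversity_summary,
    effective_alleles,
    expected_heterozygosity,
    observed_heterozygosity,
    pic,
    rarefaction_size,
)
from conftest import make_matrix


def test_allele_frequencies_counts():
    G = make_matrix([[(1, 1)], [(1, 2)]])
    cell = allele_frequencies(G).cell(WHOLE_SAMPLE, "L1")
    assert cell.counts == {1: 3, 2: 1}
    assert cell.freqs == {1: 0.75, 2: 0.25}
    assert cell.gene_copies == 4


def test_all_missing_locus_flagged_empty():
    G = make_matrix([[(1, 1), None], [(1, 2), None]])
    cell = allele_frequencies(G).cell(WHOLE_SAMPLE, "L2")
    assert cell.empty
    with pytest.raises(ValueError):
        cell.freqs


def test_missing_genotypes_never_enter_counts():
    G_full = make_matrix([[(1, 2)], [(2, 2)]])
    G_miss = make_matrix([[(1, 2)], [(2, 2)], [None]])
    a = allele_frequencies(G_full).cell(WHOLE_SAMPLE, "L1")
    b = allele_frequencies(G_miss).cell(WHOLE_SAMPLE, "L1")
    assert a.counts == b.counts and a.n_ind == b.n_ind


@pytest.mark.parametrize(
    "freqs,expected",
    [([0.5, 0.5], 2.0), ([1.0], 1.0), ([0.75, 0.25], 1.6)],
)
def test_effective_alleles(freqs, expected):
    assert effective_alleles(freqs) == pytest.approx(expected)


def test_observed_heterozygosity():
    G = make_matrix([[(1, 2)], [(1, 1)]])
    assert observed_heterozygosity(G, np.arange(2), 0) == 0.5
    G_hom = make_matrix([[(1, 1)], [(2, 2)]])
    assert observed_heterozygosity(G_hom, np.arange(2), 0) == 0.0


def test_expected_heterozygosity_forms():
    assert expected_heterozygosity([0.5, 0.5], unbiased=False) == pytest.approx(0.5)
    assert expected_heterozygosity([0.5, 0.5], n_ind=2) == pytest.approx(2 / 3)
    assert expected_heterozygosity([1.0], n_ind=5) == 0.0
    with pytest.raises(ValueError):
        expected_heterozygosity([0.5, 0.5], n_ind=1, unbiased=True)


def _pic_double_sum(p):
    # brute-force Botstein double sum
    s = 1 - sum(x * x for x in p)
    for i, j in itertools.combinations(range(len(p)), 2):
        s -= 2 * p[i] ** 2 * p[j] ** 2
    return s


@pytest.mark.parametrize(
    "freqs,expected",
    [
        ([0.5, 0.5], 0.375),
        ([1.0], 0.0),
        ([0.25] * 4, _pic_double_sum([0.25] * 4)),  # = 0.703125
        ([0.6, 0.3, 0.1], _pic_double_sum([0.6, 0.3, 0.1])),
    ],
)
def test_pic(freqs, expected):
    assert pic(freqs) == pytest.approx(expected, abs=1e-12)


def test_allelic_richness_examples():
    assert allelic_richness([3, 1], 2) == pytest.approx(1.5)
    assert allelic_richness([8], 3) == 1.0
    assert allelic_richness([3, 2, 1], 6) == 3.0  # g = 2N returns Na
    assert allelic_richness([3, 1], 1) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        allelic_richness([3, 1], 5)


def test_allelic_richness_monotone_in_g():
    counts = [5, 3, 1, 1]
    values = [allelic_richness(counts, g) for g in range(1, 11)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


def enumerate_rarefaction(counts, g):
    """Exhaustive oracle: mean number of distinct alleles over all
    C(2N, g) subsamples of the gene-copy pool."""
    pool = [a for a, c in enumerate(counts) for _ in range(c)]
    vals = [len(set(sub)) for sub in itertools.combinations(pool, g)]
    return sum(vals) / len(vals)


@pytest.mark.parametrize("counts", [[3, 1], [2, 2, 1], [4, 2], [1, 1, 1, 1]])
def test_rarefaction_matches_enumeration_small(counts):
    for g in range(1, sum(counts) + 1):
        assert allelic_richness(counts, g) == pytest.approx(
            enumerate_rarefaction(counts, g), abs=1e-12
        )


def test_rarefaction_size_is_min_gene_copies():
    G = make_matrix(
        [[(1, 2)]] * 5 + [[(1, 1)]] * 19, groups=["a"] * 5 + ["b"] * 19
    )
    table = allele_frequencies(G, "pop")
    assert rarefaction_size(table) == 10
    G2 = make_matrix([[(1, 2)], [(1, 1)], [None]], groups=["a", "a", "a"])
    assert rarefaction_size(allele_frequencies(G2, "pop")) == 4


def test_diversity_summary_identical_individuals():
    G = make_matrix([[(1, 2), (3, 3)], [(1, 2), (3, 3)]])
    df = diversity_summary(G)
    assert df.loc["L1", "Na"] == 2.0
    assert df.loc["L2", "Na"] == 1.0
    assert "Average" in df.index and "SD" in df.index


def test_diversity_summary_grouping_mode_columns(togo_like):
    G, _ = togo_like
    df = diversity_summary(G, grouping="phenotype")
    assert list(df.columns) == ["N", "Na", "AR", "Ae", "Ho", "He", "PIC"]
    assert df.loc["Albino", "N"] == 5
    assert ((df["Ae"] <= df["Na"] + 1e-9)).all()


def test_panmictic_no_heterozygote_deficit():
    from msatpop.simulate import make_fixture

    G, _ = make_fixture("panmictic", seed=21)
    df = diversity_summary(G)
    ho, he = df.loc["Average", "Ho"], df.loc["Average", "He"]
    assert abs(ho - he) < 0.03


@given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_pic_he_inequality_chain(raw):
    """PIC <= 1 - sum(p^2) <= unbiased He for any spectrum."""
    p = np.array(raw) / np.sum(raw)
    gene_div = 1 - np.sum(p * p)
    assert pic(p) <= gene_div + 1e-12
    assert gene_div <= expected_heterozygosity(p, n_ind=50) + 1e-12
    ae = effective_alleles(p)
    assert 1 - 1e-9 <= ae <= len(p) + 1e-9
    if np.allclose(p, p[0]):
        assert ae == pytest.approx(len(p))
    elif len(p) > 1:
        assert ae < len(p)
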