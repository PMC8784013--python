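"""Weir-Cockerham estimators: hand-derived components, the algebraic
identity, the independent oracle and permutation behaviour."""

import numpy as np
import pytest

from msatpop.fstats import (
    fis_permutation_test,
    fis_table,
    per_population_fis,
    wc_components,
    wc_fstats,
)
from conftest import make_matrix, random_dataset, wc_oracle


def all_het_dataset():
    # two populations of 10, every individual heterozygous 1/2
    return make_matrix([[(1, 2)]] * 20, groups=["a"] * 10 + ["b"] * 10)


def test_components_hand_example():
    vc = wc_components(all_het_dataset(), "pop", "L1")
    a, b, c = vc.per_allele[1]
    assert c == pytest.approx(0.5)
    assert b == pytest.approx(-0.25)
    assert a == pytest.approx((10 / 10) * (0 - (0.25 - 0 - 0.25) / 9))
    # both alleles are symmetric here
    assert vc.per_allele[2] == pytest.approx(vc.per_allele[1])


def test_all_heterozygote_fis_is_minus_one():
    res = wc_fstats(all_het_dataset(), "pop")
    assert res.per_locus.loc["L1", "f"] == pytest.approx(-1.0)
    assert res.multilocus["f"] == pytest.approx(-1.0)


def test_identical_populations_have_no_differentiation():
    block = [[(1, 1), (1, 2)], [(1, 2), (2, 2)], [(2, 2), (1, 1)]]
    G = make_matrix(block + block, groups=["a"] * 3 + ["b"] * 3)
    res = wc_fstats(G, "pop")
    # zero between-population variance: theta estimate non-positive
    assert res.multilocus["theta"] <= 1e-12


def test_monomorphic_locus_flagged():
    G = make_matrix([[(5, 5)]] * 6, groups=["a"] * 3 + ["b"] * 3)
    vc = wc_components(G, "pop", "L1")
    assert vc.monomorphic and vc.total == 0.0
    with pytest.raises(ValueError, match=">= 2 populations"):
        wc_components(make_matrix([[(1, 2)]], groups=["a"]), "pop", "L1")


def test_fstat_identity_and_oracle_agreement():
    """(1-F) = (1-f)(1-theta) exactly, and the ratios match an independent
    symbol-by-symbol evaluation of the published formulas."""
    rng = np.random.default_rng(42)
    for _ in range(15):
        G = random_dataset(rng)
        res = wc_fstats(G, "pop")
        f, th, F = (res.multilocus[k] for k in ("f", "theta", "F"))
        assert (1 - F) == pytest.approx((1 - f) * (1 - th), abs=1e-12)
        of, oth, oF = wc_oracle(G, "pop")
        assert f == pytest.approx(of, abs=1e-12)
        assert th == pytest.approx(oth, abs=1e-12)
        assert F == pytest.approx(oF, abs=1e-12)
        per = res.per_locus.dropna()
        np.testing.assert_allclose(
            1 - per["F"], (1 - per["f"]) * (1 - per["theta"]), atol=1e-12
        )


def test_multilocus_invariant_to_locus_order():
    rng = np.random.default_rng(7)
    G = random_dataset(rng, n_loci=5)
    res = wc_fstats(G, "pop")
    perm = [3, 0, 4, 1, 2]
    G2 = make_matrix(
        [
            [tuple(G.alleles[i, j]) if G.alleles[i, j, 0] > 0 else None for j in perm]
            for i in range(G.n_individuals)
        ],
        groups=list(G.group_labels("pop")),
    )
    res2 = wc_fstats(G2, "pop")
    for k in ("f", "theta", "F"):
        assert res.multilocus[k] == pytest.approx(res2.multilocus[k], abs=1e-12)


def test_per_population_fis_extremes():
    hwe = make_matrix(
        [[(1, 1)], [(1, 2)], [(1, 2)], [(2, 2)]] * 50, groups=["a"] * 200
    )
    fis = per_population_fis(hwe, "pop")["a"]
    assert abs(fis) < 0.01
    hom = make_matrix([[(1, 1)], [(2, 2)]] * 10, groups=["a"] * 20)
    assert per_population_fis(hom, "pop")["a"] == pytest.approx(1.0)


def test_permutation_extreme_deficit_significant():
    hom = make_matrix([[(1, 1), (3, 3)], [(2, 2), (4, 4)]] * 10, groups=["a"] * 20)
    p = fis_permutation_test(hom, "pop", "a", n_perm=999, seed=1)
    assert p <= 0.01


def test_permutation_invariant_to_allele_relabeling():
    rng = np.random.default_rng(12)
    G = random_dataset(rng, n_pops=1, n_per_pop=20, n_loci=4)
    relabel = {a: 1000 - a for a in range(90, 120)}
    calls = []
    for i in range(G.n_individuals):
        row = []
        for j in range(G.n_loci):
            a, b = G.alleles[i, j]
            row.append(None if a < 0 else (relabel.get(int(a), int(a)),
                                           relabel.get(int(b), int(b))))
        calls.append(row)
    G2 = make_matrix(calls, groups=list(G.group_labels("pop")))
    p1 = fis_permutation_test(G, "pop", "p0", n_perm=300, seed=99)
    p2 = fis_permutation_test(G2, "pop", "p0", n_perm=300, seed=99)
    assert p1 == p2


def test_fis_table_stars(togo_like):
    G, _ = togo_like
    df = fis_table(G, "zone", n_perm=199, seed=0)
    assert set(df.index) == set(G.classes("zone"))
    assert ((df["p_value"] > 0) & (df["p_value"] <= 1)).all()
    # the fixture is built with a strong heterozygote deficit (FIS 0.17)
    assert (df["FIS"] > 0).all()
    assert (df["significant"] == "*").all()


def test_permutation_requires_enough_perms(togo_like):
    G, _ = togo_like
    with pytest.raises(ValueError, match="n_perm"):
        fis_permutation_test(G, "zone", "Atakora", n_perm=10)
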