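"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from msatpop.genotype_io import MISSING, GenotypeMatrix


def make_matrix(calls, groups=None, locus_names=None, grouping_name="pop"):
    """Build a GenotypeMatrix from nested call lists.

    ``calls[i][j]`` is ``(a, b)`` or ``None`` for missing; ``groups[i]`` the
    class of individual i under ``grouping_name``.
    """
    n = len(calls)
    L = len(calls[0])
    alleles = np.full((n, L, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(calls):
        for j, call in enumerate(row):
            if call is not None:
                a, b = call
                alleles[i, j] = sorted((a, b))
    ids = [f"i{i + 1}" for i in range(n)]
    loci = locus_names or [f"L{j + 1}" for j in range(L)]
    groupings = {}
    if groups is not None:
        groupings[grouping_name] = dict(zip(ids, map(str, groups)))
    return GenotypeMatrix(ids, loci, alleles, groupings)


def wc_oracle(G: GenotypeMatrix, grouping: str):
    """Independent symbol-by-symbol Weir-Cockerham estimator.

    Plain scalar loops evaluating the published component formulas directly;
    returns multilocus (f, theta, F) by ratio of summed components.  Kept
    deliberately separate from the package's vector implementation.
    """
    pops = G.population_indices(grouping)
    A_tot = B_tot = C_tot = 0.0
    for j in range(G.n_loci):
        per_pop = []
        for idx in pops.values():
            genos = []
            for i in idx:
                a, b = G.alleles[i, j]
                if a != MISSING:
                    genos.append((int(a), int(b)))
            if genos:
                per_pop.append(genos)
        r = len(per_pop)
        if r < 2:
            continue
        alleles = sorted({a for genos in per_pop for g in genos for a in g})
        if len(alleles) < 2:
            continue
        n_list = [len(g) for g in per_pop]
        nbar = sum(n_list) / r
        n_c = (sum(n_list) - sum(ni * ni for ni in n_list) / sum(n_list)) / (r - 1)
        for allele in alleles:
            p_list, h_list = [], []
            for genos in per_pop:
                ni = len(genos)
                copies = sum((a == allele) + (b == allele) for a, b in genos)
                hets = sum(1 for a, b in genos if a != b and allele in (a, b))
                p_list.append(copies / (2 * ni))
                h_list.append(hets / ni)
            pbar = sum(ni * pi for ni, pi in zip(n_list, p_list)) / sum(n_list)
            s2 = sum(
                ni * (pi - pbar) ** 2 for ni, pi in zip(n_list, p_list)
            ) / ((r - 1) * nbar)
            hbar = sum(ni * hi for ni, hi in zip(n_list, h_list)) / sum(n_list)
            a_c = (nbar / n_c) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b_c = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_c = hbar / 2
            A_tot += a_c
            B_tot += b_c
            C_tot += c_c
    total = A_tot + B_tot + C_tot
    return (
        1 - C_tot / (B_tot + C_tot),
        A_tot / total,
        1 - C_tot / total,
    )


def random_dataset(rng, n_pops=3, n_per_pop=8, n_loci=4, n_alleles=4, missing=0.05):
    """Small random multiallelic dataset for estimator cross-checks."""
    calls, groups = [], []
    for p in range(n_pops):
        freqs = rng.dirichlet(np.ones(n_alleles))
        for _ in range(n_per_pop):
            row = []
            for _j in range(n_loci):
                if rng.random() < missing:
                    row.append(None)
                else:
                    a, b = rng.choice(n_alleles, size=2, p=freqs) + 1
                    row.append((int(a) * 2 + 100, int(b) * 2 + 100))
            calls.append(row)
            groups.append(f"p{p}")
    return make_matrix(calls, groups)


def random_additive_tree(rng, n_leaves):
    """Random binary tree topology with positive branch lengths and its
    exact leaf-to-leaf path-length matrix (the additive-distance oracle)."""
    labels = [f"t{chr(97 + i)}" for i in range(n_leaves)]
    # start from a star over three leaves, then attach the rest by edge split
    nodes = {lab: {} for lab in labels[:3]}
    center = "n0"
    nodes[center] = {}
    edges = {}
    for lab in labels[:3]:
        w = float(rng.uniform(0.1, 2.0))
        edges[(center, lab)] = w
    next_internal = 1
    for lab in labels[3:]:
        edge = list(edges)[rng.integers(len(edges))]
        w = edges.pop(edge)
        u, v = edge
        mid = f"n{next_internal}"
        next_internal += 1
        cut = float(rng.uniform(0.2, 0.8))
        edges[(u, mid)] = w * cut
        edges[(mid, v)] = w * (1 - cut)
        edges[(mid, lab)] = float(rng.uniform(0.1, 2.0))
    # all-pairs path lengths on the tree graph
    adj: dict[str, list[tuple[str, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    D = (D + D.T) / 2.0  # exact symmetry despite float summation order
    np.fill_diagonal(D, 0.0)
    return labels, D


@pytest.fixture(scope="session")
def togo_like():
    from msatpop.simulate import make_fixture

    return make_fixture("togo-like", seed=11)
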