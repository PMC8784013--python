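"""Weir & Cockerham variance-component F-statistics.

Estimates Wright's fixation indices FIS (f), FST (theta) and FIT (F) from the
among-population (a), among-individual-within-population (b) and
within-individual (c) variance components, computed per allele and locus from
sample sizes, allele frequencies and observed heterozygote frequencies.
Multilocus estimates are ratios of summed components (not averages of
per-locus ratios), so the identity ``(1 - F) = (1 - f)(1 - theta)`` holds
exactly wherever all three are defined.

Also provides per-population multilocus FIS (ratio-of-sums of observed to
unbiased expected heterozygosity) and a one-sided permutation test for
heterozygote deficit that shuffles gene copies among individuals within the
population independently at each locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import expected_heterozygosity
from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Summed variance components for one locus.

    ``a``: among populations, ``b``: among individuals within populations,
    ``c``: within individuals (half the average heterozygote frequency);
    ``per_allele`` holds the per-allele triples.  ``c`` is nonnegative;
    ``a`` and ``b`` may be negative.
    """

    locus: str
    a: float
    b: float
    c: float
    per_allele: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    monomorphic: bool = False

    @property
    def total(self) -> float:
        return self.a + self.b + self.c


@dataclass
class FStatsResult:
    """Per-locus and multilocus f (FIS), theta (FST), F (FIT)."""

    per_locus: pd.DataFrame  # index locus; columns f, theta, F, a, b, c
    multilocus: dict[str, float]  # f, theta, F
    components: list[VarianceComponents]

    def to_frame(self) -> pd.DataFrame:
        """Per-locus table with an ``Average`` multilocus row (ratio of sums)."""
        avg = pd.DataFrame(
            [{"f": self.multilocus["f"], "theta": self.multilocus["theta"],
              "F": self.multilocus["F"]}],
            index=["Average"],
        )
        return pd.concat([self.per_locus[["f", "theta", "F"]], avg])


def wc_components(
    G: GenotypeMatrix, grouping: str, locus: str
) -> VarianceComponents:
    """Variance components a, b, c at one locus.

    For each allele A, with r populations of sample sizes ``n_i``, allele
    frequencies ``p_i``, observed frequencies of A-heterozygotes ``h_i``::

        nbar = mean n_i                      (weighted notation below)
        n_c  = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
        pbar = sum n_i p_i / sum n_i
        s^2  = sum n_i (p_i - pbar)^2 / ((r - 1) nbar)
        hbar = sum n_i h_i / sum n_i
        a = (nbar / n_c) [s^2 - (pbar(1-pbar) - (r-1)/r s^2 - hbar/4)/(nbar-1)]
        b = (nbar/(nbar-1)) [pbar(1-pbar) - (r-1)/r s^2 - (2nbar-1)/(4nbar) hbar]
        c = hbar / 2

    Individuals missing at the locus are dropped for this locus only.
    """
    j = G.locus_names.index(locus)
    pops = G.population_indices(grouping)
    n_i, freq_rows, het_rows, alleles_seen = [], [], [], set()
    for pop, idx in pops.items():
        calls = G.alleles[idx, j, :]
        calls = calls[calls[:, 0] > 0]
        if len(calls) == 0:
            continue
        n_i.append(len(calls))
        counts: dict[int, int] = {}
        hets: dict[int, int] = {}
        for a_, b_ in calls:
            counts[int(a_)] = counts.get(int(a_), 0) + 1
            counts[int(b_)] = counts.get(int(b_), 0) + 1
            if a_ != b_:
                hets[int(a_)] = hets.get(int(a_), 0) + 1
                hets[int(b_)] = hets.get(int(b_), 0) + 1
        freq_rows.append(counts)
        het_rows.append(hets)
        alleles_seen.update(counts)
    r = len(n_i)
    if r < 2:
        raise ValueError(
            f"locus {locus}: need >= 2 populations with genotyped individuals"
        )
    if len(alleles_seen) < 2:
        logger.warning("locus %s monomorphic across populations", locus)
        return VarianceComponents(locus, 0.0, 0.0, 0.0, {}, monomorphic=True)

    n = np.array(n_i, dtype=float)
    n_sum = n.sum()
    nbar = n_sum / r
    n_c = (n_sum - np.sum(n * n) / n_sum) / (r - 1)
    per_allele: dict[int, tuple[float, float, float]] = {}
    a_sum = b_sum = c_sum = 0.0
    for allele in sorted(alleles_seen):
        p = np.array([fr.get(allele, 0) / (2 * ni) for fr, ni in zip(freq_rows, n_i)])
        h = np.array([he.get(allele, 0) / ni for he, ni in zip(het_rows, n_i)])
        pbar = float(np.sum(n * p) / n_sum)
        s2 = float(np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n * h) / n_sum)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / n_c * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        per_allele[allele] = (a, b, c)
        a_sum += a
        b_sum += b
        c_sum += c
    return VarianceComponents(locus, a_sum, b_sum, c_sum, per_allele)


def wc_fstats(G: GenotypeMatrix, grouping: str) -> FStatsResult:
    """Per-locus and multilocus Weir-Cockerham f, theta, F.

    Per locus: ``theta = a / (a+b+c)``, ``f = 1 - c/(b+c)``,
    ``F = 1 - c/(a+b+c)`` from components summed over alleles.  Multilocus:
    the same ratios with components additionally summed over loci; loci with
    a zero denominator are excluded from the sums with a warning.
    """
    comps = [wc_components(G, grouping, locus) for locus in G.locus_names]
    rows = []
    A = B = C = 0.0
    for vc in comps:
        if vc.total == 0.0:
            logger.warning("locus %s: zero total variance; excluded", vc.locus)
            rows.append(
                {"locus": vc.locus, "f": np.nan, "theta": np.nan, "F": np.nan,
                 "a": vc.a, "b": vc.b, "c": vc.c}
            )
            continue
        theta = vc.a / vc.total
        f = 1.0 - vc.c / (vc.b + vc.c) if (vc.b + vc.c) != 0 else np.nan
        F = 1.0 - vc.c / vc.total
        rows.append(
            {"locus": vc.locus, "f": f, "theta": theta, "F": F,
             "a": vc.a, "b": vc.b, "c": vc.c}
        )
        A += vc.a
        B += vc.b
        C += vc.c
    per_locus = pd.DataFrame(rows).set_index("locus")
    total = A + B + C
    multilocus = {
        "f": 1.0 - C / (B + C) if (B + C) != 0 else np.nan,
        "theta": A / total if total != 0 else np.nan,
        "F": 1.0 - C / total if total != 0 else np.nan,
    }
    return FStatsResult(per_locus, multilocus, comps)


def _pop_ho_he(G: GenotypeMatrix, idx: np.ndarray) -> tuple[float, float]:
    """Sums over loci of observed and unbiased expected heterozygosity."""
    ho_sum = he_sum = 0.0
    used = 0
    for j in range(G.n_loci):
        calls = G.alleles[idx, j, :]
        calls = calls[calls[:, 0] > 0]
        n = len(calls)
        if n < 2:
            continue
        copies = calls.ravel()
        _, counts = np.unique(copies, return_counts=True)
        p = counts / (2 * n)
        ho_sum += float((calls[:, 0] != calls[:, 1]).mean())
        he_sum += expected_heterozygosity(p, n, unbiased=True)
        used += 1
    if used == 0 or he_sum == 0.0:
        raise ValueError("FIS undefined: no polymorphic locus with data")
    return ho_sum, he_sum


def per_population_fis(G: GenotypeMatrix, grouping: str) -> dict[str, float]:
    """Multilocus within-population FIS = 1 - sum(Ho) / sum(He) per class."""
    out = {}
    for pop, idx in G.population_indices(grouping).items():
        ho, he = _pop_ho_he(G, idx)
        out[pop] = 1.0 - ho / he
    return out


def fis_permutation_test(
    G: GenotypeMatrix,
    grouping: str,
    population: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """One-sided permutation p-value for heterozygote deficit in one class.

    The null shuffles the 2n gene copies among individuals within the
    population, independently per locus (allele frequencies, hence He, are
    invariant; only Ho changes).  ``p = (1 + #{perm FIS >= observed}) /
    (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    idx = G.population_indices(grouping)[population]
    ho_obs, he_sum = _pop_ho_he(G, idx)
    fis_obs = 1.0 - ho_obs / he_sum
    rng = np.random.default_rng(seed)
    ho_perm = np.zeros(n_perm)
    for j in range(G.n_loci):
        calls = G.alleles[idx, j, :]
        calls = calls[calls[:, 0] > 0]
        n = len(calls)
        if n < 2:
            continue
        copies = calls.ravel()
        _, counts = np.unique(copies, return_counts=True)
        if len(counts) < 2:
            continue
        # canonical pool built from the count spectrum: heterozygosity under
        # random pairing depends on labels only through their counts, so this
        # makes the p-value exactly invariant to allele relabeling
        canon = np.repeat(np.arange(len(counts)), np.sort(counts)[::-1])
        # n_perm independent shuffles of the copy pool, paired in order
        pool = np.tile(canon, (n_perm, 1))
        pool = rng.permuted(pool, axis=1).reshape(n_perm, n, 2)
        ho_perm += (pool[:, :, 0] != pool[:, :, 1]).mean(axis=1)
    fis_perm = 1.0 - ho_perm / he_sum
    p = (1 + int(np.sum(fis_perm >= fis_obs - 1e-12))) / (1 + n_perm)
    return float(p)


def fis_table(
    G: GenotypeMatrix,
    grouping: str,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-population FIS with permutation p-values and star annotation."""
    rng = np.random.default_rng(seed)
    rows = []
    for pop, fis in per_population_fis(G, grouping).items():
        p = fis_permutation_test(
            G, grouping, pop, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rows.append(
            {"population": pop, "FIS": fis, "p_value": p,
             "significant": "*" if p < alpha else ""}
        )
    return pd.DataFrame(rows).set_index("population")
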