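"""Per-locus and per-population microsatellite diversity statistics.

Covers allele counts and frequencies, effective number of alleles
(``Ae = 1 / sum(p^2)``), allelic richness by rarefaction, observed
heterozygosity, expected heterozygosity (Nei's unbiased gene diversity by
default), polymorphism information content (Botstein's PIC), and summary
tables of the shape population geneticists publish: per-locus rows for the
whole sample, per-population rows averaged over loci, each with a
mean +/- SD footer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Population label used when all individuals are pooled.
WHOLE_SAMPLE = "all"


@dataclass
class FreqCell:
    """Allele counts for one (population, locus) cell.

    ``n_ind`` counts individuals with a non-missing genotype; ``gene_copies``
    is ``2 * n_ind``; ``counts`` maps allele label -> observed copies.
    """

    n_ind: int
    counts: dict[int, int]

    @property
    def gene_copies(self) -> int:
        return 2 * self.n_ind

    @property
    def freqs(self) -> dict[int, float]:
        if self.n_ind == 0:
            raise ValueError("frequencies undefined for an empty cell")
        g = self.gene_copies
        return {a: c / g for a, c in self.counts.items()}

    @property
    def freq_vector(self) -> np.ndarray:
        return np.array(list(self.freqs.values()))

    @property
    def empty(self) -> bool:
        return self.n_ind == 0


class AlleleFreqTable:
    """Per (population, locus) allele frequency spectra with sample sizes."""

    def __init__(
        self,
        cells: Mapping[tuple[str, str], FreqCell],
        populations: list[str],
        loci: list[str],
    ) -> None:
        self.cells = dict(cells)
        self.populations = populations
        self.loci = loci

    def cell(self, population: str, locus: str) -> FreqCell:
        return self.cells[(population, locus)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (population, locus, allele, count, freq) table."""
        rows = []
        for (pop, locus), cell in self.cells.items():
            if cell.empty:
                continue
            for allele, count in sorted(cell.counts.items()):
                rows.append(
                    {
                        "population": pop,
                        "locus": locus,
                        "allele": allele,
                        "count": count,
                        "freq": count / cell.gene_copies,
                    }
                )
        return pd.DataFrame(rows)


def allele_frequencies(
    G: GenotypeMatrix, grouping: str | None = None
) -> AlleleFreqTable:
    """Tabulate allele counts per (population, locus) from non-missing calls.

    ``grouping=None`` pools all individuals into a single population named
    :data:`WHOLE_SAMPLE`.  Cells where no individual is genotyped are kept
    with ``n_ind = 0`` and flagged with a warning.
    """
    if G.n_individuals == 0 or G.n_loci == 0:
        raise ValueError("genotype matrix is empty")
    if grouping is None:
        pops = {WHOLE_SAMPLE: np.arange(G.n_individuals)}
    else:
        pops = G.population_indices(grouping)
    cells: dict[tuple[str, str], FreqCell] = {}
    miss = G.missing_mask
    for pop, idx in pops.items():
        for j, locus in enumerate(G.locus_names):
            ok = idx[~miss[idx, j]]
            counts: dict[int, int] = {}
            for a in G.alleles[ok, j, :].ravel():
                counts[int(a)] = counts.get(int(a), 0) + 1
            if len(ok) == 0:
                logger.warning("no genotyped individuals for %s at %s", pop, locus)
            cells[(pop, locus)] = FreqCell(len(ok), dict(sorted(counts.items())))
    return AlleleFreqTable(cells, list(pops), list(G.locus_names))


def effective_alleles(freqs: np.ndarray) -> float:
    """Effective number of alleles ``Ae = 1 / sum(p^2)``.

    Equals the allele count for an equifrequent locus and is always between 1
    and the number of alleles.
    """
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    return float(1.0 / np.sum(p * p))


def observed_heterozygosity(G: GenotypeMatrix, individuals: np.ndarray, locus_idx: int) -> float:
    """Fraction of non-missing genotypes with two distinct alleles."""
    calls = G.alleles[individuals, locus_idx, :]
    ok = calls[:, 0] > 0
    if not ok.any():
        raise ValueError("no genotyped individuals at this locus")
    het = calls[ok, 0] != calls[ok, 1]
    return float(het.mean())


def expected_heterozygosity(
    freqs: np.ndarray, n_ind: int | None = None, unbiased: bool = True
) -> float:
    """Gene diversity ``1 - sum(p^2)``, small-sample corrected by default.

    The unbiased form multiplies by ``2n / (2n - 1)`` (Nei's correction for
    sampling 2n gene copies) and requires ``n_ind >= 2``.
    """
    p = np.asarray(freqs, dtype=float)
    h = 1.0 - float(np.sum(p * p))
    if not unbiased:
        return h
    if n_ind is None or n_ind < 2:
        raise ValueError("unbiased He needs n_ind >= 2")
    return 2 * n_ind / (2 * n_ind - 1) * h


def pic(freqs: np.ndarray) -> float:
    """Botstein's polymorphism information content.

    ``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``; the pairwise sum is
    evaluated via ``(sum p^2)^2 - sum p^4``.
    """
    p = np.asarray(freqs, dtype=float)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2 * s2 - s4)


def allelic_richness(counts: np.ndarray, g: int) -> float:
    """Rarefaction allelic richness: expected alleles in ``g`` gene copies.

    With total copies ``2N`` and ``N_a`` copies of allele ``a``,
    ``AR(g) = sum_a [1 - C(2N - N_a, g) / C(2N, g)]`` — the expected number of
    distinct alleles in a random subsample of ``g`` copies drawn without
    replacement.  ``AR(1) = 1`` and ``AR(2N) = Na``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if not 1 <= g <= total:
        raise ValueError(f"rarefaction size g={g} outside [1, {total}]")
    denom = math.comb(total, g)
    ar = 0.0
    for c in counts:
        ar += 1.0 - math.comb(total - int(c), g) / denom
    return ar


def rarefaction_size(table: AlleleFreqTable) -> int:
    """Standard rarefaction size: the smallest gene-copy count of any
    non-empty (population, locus) cell (the FSTAT convention)."""
    sizes = [c.gene_copies for c in table.cells.values() if not c.empty]
    if not sizes:
        raise ValueError("all cells empty; cannot choose a rarefaction size")
    return min(sizes)


def diversity_summary(
    G: GenotypeMatrix,
    grouping: str | None = None,
    unbiased_he: bool = True,
    rarefaction_grouping: str | None = None,
) -> pd.DataFrame:
    """Published-style diversity table.

    With ``grouping=None``: one row per locus over the pooled sample with
    columns ``Na, AR, Ae, Ho, He, PIC`` plus ``Average`` / ``SD`` footer rows
    (SD is the standard deviation of the listed per-locus values).  With a
    grouping: one row per population, each statistic averaged over loci, plus
    an ``N`` column of group sizes.

    ``rarefaction_grouping`` selects which grouping's smallest cell sets the
    rarefaction size ``g`` (defaults to the analysis grouping itself); AR at a
    cell whose gene-copy count is below ``g`` is not computable and is skipped
    from averages with a warning.
    """
    table = allele_frequencies(G, grouping)
    g_table = (
        table
        if rarefaction_grouping is None or rarefaction_grouping == grouping
        else allele_frequencies(G, rarefaction_grouping)
    )
    g = rarefaction_size(g_table)

    if grouping is None:
        rows = []
        for j, locus in enumerate(G.locus_names):
            cell = table.cell(WHOLE_SAMPLE, locus)
            if cell.empty:
                logger.warning("locus %s has no data; skipped", locus)
                continue
            rows.append(
                {
                    "locus": locus,
                    **_cell_stats(G, np.arange(G.n_individuals), j, cell, g, unbiased_he),
                }
            )
        df = pd.DataFrame(rows).set_index("locus")
        footer = pd.DataFrame(
            [df.mean(), df.std(ddof=1)], index=["Average", "SD"]
        )
        df = pd.concat([df, footer])
        df["Na"] = df["Na"].astype(float)
        return df

    pops = G.population_indices(grouping)
    rows = []
    for pop, idx in pops.items():
        per_locus = []
        for j, locus in enumerate(G.locus_names):
            cell = table.cell(pop, locus)
            if cell.empty:
                logger.warning("cell (%s, %s) empty; excluded from averages", pop, locus)
                continue
            per_locus.append(_cell_stats(G, idx, j, cell, g, unbiased_he))
        stats = pd.DataFrame(per_locus).mean()
        rows.append({"population": pop, "N": len(idx), **stats})
    return pd.DataFrame(rows).set_index("population")


def _cell_stats(
    G: GenotypeMatrix,
    idx: np.ndarray,
    locus_idx: int,
    cell: FreqCell,
    g: int,
    unbiased_he: bool,
) -> dict[str, float]:
    p = cell.freq_vector
    counts = np.array(list(cell.counts.values()))
    out = {
        "Na": float(len(cell.counts)),
        "AR": allelic_richness(counts, g) if g <= cell.gene_copies else np.nan,
        "Ae": effective_alleles(p),
        "Ho": observed_heterozygosity(G, idx, locus_idx),
        "He": expected_heterozygosity(p, cell.n_ind, unbiased=unbiased_he)
        if (not unbiased_he or cell.n_ind >= 2)
        else np.nan,
        "PIC": pic(p),
    }
    if np.isnan(out["AR"]):
        logger.warning("cell with %d copies below rarefaction size %d", cell.gene_copies, g)
    return out
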