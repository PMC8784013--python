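"""Nei's unbiased genetic identity and distance between populations.

Per locus, with allele frequencies ``x`` and ``y`` in populations X and Y of
``n_X`` and ``n_Y`` genotyped individuals:

    J_XY   = sum_a x_a y_a
    Jhat_X = (2 n_X sum_a x_a^2 - 1) / (2 n_X - 1)      (unbiased homozygosity)
    Jhat_Y analogous

The identity combines loci by averaging the J-statistics first and taking the
ratio afterwards (the POPGENE convention):

    I = mean_l(J_XY) / sqrt(mean_l(Jhat_X) * mean_l(Jhat_Y)),  D = -ln I.

The small-sample correction can push I above 1 at tiny n; D is then negative
and reported as-is (logged, not clamped).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import allele_frequencies
from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with companion identities.

    Distance diagonal is 0 by convention; identity diagonal is 1.  Masked
    (uncomputable) pairs are NaN.
    """

    labels: list[str]
    distance: np.ndarray
    identity: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise ValueError("labels must be unique")
        for m in (self.distance, self.identity):
            if m.shape != (k, k):
                raise ValueError("matrix shape does not match labels")
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError("matrix must be symmetric")

    def to_frame(self, which: str = "distance") -> pd.DataFrame:
        m = self.distance if which == "distance" else self.identity
        return pd.DataFrame(m, index=self.labels, columns=self.labels)

    def to_triangular_frame(self) -> pd.DataFrame:
        """Published layout: identities above the diagonal, distances below."""
        k = len(self.labels)
        out = np.full((k, k), np.nan)
        iu = np.triu_indices(k, 1)
        il = np.tril_indices(k, -1)
        out[iu] = self.identity[iu]
        out[il] = self.distance[il]
        return pd.DataFrame(out, index=self.labels, columns=self.labels)

    def to_phylip(self, path: str | Path, precision: int = 6) -> None:
        lines = [f"{len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            row = " ".join(f"{d:.{precision}f}" for d in self.distance[i])
            lines.append(f"{lab.replace(' ', '_'):<12s}{row}")
        Path(path).write_text("\n".join(lines) + "\n")


def _pair_stats(
    freqs_x: dict[int, float], freqs_y: dict[int, float], n_x: int, n_y: int
) -> tuple[float, float, float]:
    jxy = sum(px * freqs_y.get(a, 0.0) for a, px in freqs_x.items())
    sx2 = sum(p * p for p in freqs_x.values())
    sy2 = sum(p * p for p in freqs_y.values())
    jx = (2 * n_x * sx2 - 1.0) / (2 * n_x - 1.0)
    jy = (2 * n_y * sy2 - 1.0) / (2 * n_y - 1.0)
    return jxy, jx, jy


def nei_identity(G: GenotypeMatrix, grouping: str, pop_x: str, pop_y: str) -> float:
    """Unbiased genetic identity between two populations.

    Loci typed in only one of the two populations are dropped pairwise; loci
    where the unbiased homozygosity is nonpositive (possible at n = 1..2) are
    excluded with a warning.
    """
    table = allele_frequencies(G, grouping)
    jxy_l, jx_l, jy_l = [], [], []
    for locus in G.locus_names:
        cx, cy = table.cell(pop_x, locus), table.cell(pop_y, locus)
        if cx.empty or cy.empty:
            continue
        if cx.n_ind < 1 or cy.n_ind < 1:
            continue
        jxy, jx, jy = _pair_stats(cx.freqs, cy.freqs, cx.n_ind, cy.n_ind)
        if jx <= 0 or jy <= 0:
            logger.warning(
                "locus %s: nonpositive unbiased homozygosity at small n; excluded",
                locus,
            )
            continue
        jxy_l.append(jxy)
        jx_l.append(jx)
        jy_l.append(jy)
    if not jxy_l:
        raise ValueError(f"no shared typed locus between {pop_x!r} and {pop_y!r}")
    I = float(np.mean(jxy_l) / math.sqrt(np.mean(jx_l) * np.mean(jy_l)))
    if I > 1:
        logger.info("identity %s-%s exceeds 1 (%.4f); distance will be negative",
                    pop_x, pop_y, I)
    return I


def nei_distance(identity: float) -> float:
    """``D = -ln I``; not clamped, so ``I > 1`` yields a negative distance."""
    if identity <= 0:
        raise ValueError(f"identity must be positive, got {identity}")
    return -math.log(identity)


def pairwise_matrix(G: GenotypeMatrix, grouping: str) -> DistanceMatrix:
    """All-pairs Nei identity and distance for one grouping."""
    pops = G.classes(grouping)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    k = len(pops)
    I = np.eye(k)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                ident = nei_identity(G, grouping, pops[i], pops[j])
                dist = nei_distance(ident)
            except ValueError as exc:
                logger.warning("pair (%s, %s) masked: %s", pops[i], pops[j], exc)
                ident = dist = np.nan
            I[i, j] = I[j, i] = ident
            D[i, j] = D[j, i] = dist
    return DistanceMatrix(pops, D, I)
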