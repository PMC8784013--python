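"""Factorial correspondence analysis of individuals coded by allele counts.

Individuals are rows; columns are (locus, allele) pairs holding the number of
copies carried (0/1/2).  Standard correspondence analysis is applied under
the chi-square metric: divide by the grand total, form standardized residuals
``(P_ij - r_i c_j) / sqrt(r_i c_j)``, take the SVD; squared singular values
are the axis inertias (eigenvalues).  Missing loci contribute zero columns
for that row and shrink the row mass (no imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FCAResult:
    """Eigenvalues, principal coordinates and inertia of a CA solution."""

    eigenvalues: np.ndarray  # descending, one per nontrivial axis
    row_coords: pd.DataFrame  # individuals x axes (principal coordinates)
    col_coords: pd.DataFrame  # (locus, allele) columns x axes
    inertia_fractions: np.ndarray

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())


def indicator_matrix(G: GenotypeMatrix) -> pd.DataFrame:
    """Individuals x (locus, allele) allele-copy count matrix.

    Row sums equal twice the number of typed loci of the individual.
    """
    cols: dict[str, np.ndarray] = {}
    for j, locus in enumerate(G.locus_names):
        calls = G.alleles[:, j, :]
        alleles = np.unique(calls[calls > 0])
        for a in alleles:
            cols[f"{locus}.{a}"] = (calls == a).sum(axis=1)
    X = pd.DataFrame(cols, index=G.individual_ids)
    untyped = G.missing_mask.sum(axis=1)
    for i in np.flatnonzero(untyped > 0):
        logger.debug(
            "%s: %d missing loci contribute zero columns",
            G.individual_ids[i],
            untyped[i],
        )
    return X


def correspondence_analysis(X: pd.DataFrame | np.ndarray, n_axes: int = 3) -> FCAResult:
    """Correspondence analysis of a nonnegative count matrix.

    Returns up to ``n_axes`` principal coordinates; eigenvalues and inertia
    fractions are reported for all nontrivial axes.  Axis signs are fixed by
    forcing the largest-magnitude row coordinate positive on each axis.
    """
    if isinstance(X, pd.DataFrame):
        row_names, col_names = list(X.index), list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        row_names = [f"r{i}" for i in range(M.shape[0])]
        col_names = [f"c{j}" for j in range(M.shape[1])]
    if (M < 0).any():
        raise ValueError("count matrix must be nonnegative")
    row_tot = M.sum(axis=1)
    if (row_tot == 0).any():
        bad = row_names[int(np.argmax(row_tot == 0))]
        raise ValueError(f"all-zero row for individual {bad!r}")
    keep = M.sum(axis=0) > 0
    if not keep.all():
        M = M[:, keep]
        col_names = [c for c, k in zip(col_names, keep) if k]

    P = M / M.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    # drop numerically-null axes (CA of a rank-k table has k-1 nontrivial axes)
    nz = s > max(s[0], 1.0) * 1e-10 if s.size else s > 0
    U, s, Vt = U[:, nz], s[nz], Vt[nz]
    eig = s**2
    inertia = eig / eig.sum()

    n_keep = min(n_axes, len(s))
    F = (U / np.sqrt(r)[:, None]) * s  # row principal coordinates
    Gc = (Vt.T / np.sqrt(c)[:, None]) * s
    for ax in range(n_keep):
        i_max = int(np.argmax(np.abs(F[:, ax])))
        if F[i_max, ax] < 0:
            F[:, ax] *= -1
            Gc[:, ax] *= -1
    axes = [f"axis{k + 1}" for k in range(n_keep)]
    return FCAResult(
        eigenvalues=eig,
        row_coords=pd.DataFrame(F[:, :n_keep], index=row_names, columns=axes),
        col_coords=pd.DataFrame(Gc[:, :n_keep], index=col_names, columns=axes),
        inertia_fractions=inertia,
    )


def fca(G: GenotypeMatrix, n_axes: int = 3) -> FCAResult:
    """Correspondence analysis of the genotype matrix's allele-count coding."""
    return correspondence_analysis(indicator_matrix(G), n_axes=n_axes)
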