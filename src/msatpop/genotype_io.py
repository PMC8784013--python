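"""Diploid co-dominant genotype matrices and their file formats.

The canonical in-memory object is :class:`GenotypeMatrix`: individuals x loci,
each cell an unordered pair of positive integer allele labels (microsatellite
fragment sizes in bp) or missing, plus one or more named population groupings
(e.g. plumage phenotype, agroecological zone).

Two text formats are supported:

* GENEPOP (2- or 3-digit allele tokens, ``POP``-separated samples).  GENEPOP
  can carry only a single grouping, so export takes a grouping name.
* a delimited table with an id column, grouping columns and one ``a/b`` column
  per locus.  This is the lossless native format: it carries every grouping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel allele value for a missing genotype (both slots set).
MISSING = -1


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


@dataclass(frozen=True)
class GenepopDialect:
    """Concrete GENEPOP conventions.

    Parameters
    ----------
    digits
        Characters per allele in a genotype token (2 or 3).
    pop_token
        The population separator line (matched case-insensitively).
    """

    digits: int = 3
    pop_token: str = "POP"

    def __post_init__(self) -> None:
        if self.digits not in (2, 3):
            raise ValueError(f"digits must be 2 or 3, got {self.digits}")

    @property
    def missing_allele(self) -> str:
        return "0" * self.digits

    @property
    def token_width(self) -> int:
        return 2 * self.digits


class GenotypeMatrix:
    """Individuals x loci diploid genotype calls with named groupings.

    Parameters
    ----------
    individual_ids
        Ordered unique individual identifiers.
    locus_names
        Ordered unique locus names (e.g. ``GF43``, ``GUJ0066``).
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)``.  A missing
        genotype has both slots equal to :data:`MISSING`; a called genotype
        has two positive allele labels.  Missing is genotype-level only:
        half-calls are coerced to missing on construction with a warning.
    groupings
        Mapping grouping-name -> (individual id -> class label).  Every
        individual must have exactly one class per declared grouping.
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        locus_names: Sequence[str],
        alleles: np.ndarray,
        groupings: Mapping[str, Mapping[str, str]] | None = None,
    ) -> None:
        self.individual_ids = list(individual_ids)
        self.locus_names = list(locus_names)
        alleles = np.asarray(alleles, dtype=np.int64)
        if alleles.shape != (len(self.individual_ids), len(self.locus_names), 2):
            raise ValueError(
                f"alleles shape {alleles.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_names)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("locus names must be unique")
        # half-calls (exactly one missing slot) become fully missing
        half = (alleles == MISSING).sum(axis=2) == 1
        if half.any():
            logger.warning(
                "%d half-called genotypes coerced to missing", int(half.sum())
            )
            alleles = alleles.copy()
            alleles[half] = MISSING
        bad = (alleles != MISSING) & (alleles <= 0)
        if bad.any():
            raise ValueError("allele labels must be positive integers")
        self.alleles = alleles
        self.groupings: dict[str, dict[str, str]] = {}
        for name, mapping in (groupings or {}).items():
            self.set_grouping(name, mapping)

    # -- structure ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def set_grouping(self, name: str, mapping: Mapping[str, str]) -> None:
        missing = [i for i in self.individual_ids if i not in mapping]
        if missing:
            raise ValueError(
                f"grouping {name!r} lacks a class for individuals: {missing[:5]}"
            )
        self.groupings[name] = {i: str(mapping[i]) for i in self.individual_ids}

    def group_labels(self, grouping: str) -> np.ndarray:
        """Class label per individual, in individual order."""
        try:
            mapping = self.groupings[grouping]
        except KeyError:
            raise KeyError(
                f"unknown grouping {grouping!r}; have {sorted(self.groupings)}"
            ) from None
        return np.array([mapping[i] for i in self.individual_ids], dtype=object)

    def classes(self, grouping: str) -> list[str]:
        """Distinct class labels in order of first appearance."""
        labels = self.group_labels(grouping)
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(lab, None)
        return list(seen)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the genotype is missing."""
        return self.alleles[:, :, 0] == MISSING

    def subset(self, individual_idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(individual_idx)
        ids = [self.individual_ids[i] for i in idx]
        groupings = {
            name: {i: mapping[i] for i in ids}
            for name, mapping in self.groupings.items()
        }
        return GenotypeMatrix(ids, self.locus_names, self.alleles[idx], groupings)

    def population_indices(self, grouping: str) -> dict[str, np.ndarray]:
        """Map class label -> integer indices of its individuals."""
        labels = self.group_labels(grouping)
        return {c: np.flatnonzero(labels == c) for c in self.classes(grouping)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.alleles, other.alleles)
            and self.groupings == other.groupings
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x {self.n_loci} loci, "
            f"groupings={sorted(self.groupings)})"
        )


def _sorted_pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

def read_genepop(
    path: str | Path,
    dialect: GenepopDialect = GenepopDialect(),
    grouping_name: str = "pop",
    pop_names: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Parse a GENEPOP file into a :class:`GenotypeMatrix`.

    The POP blocks populate a single grouping named ``grouping_name``; classes
    are named after ``pop_names`` if given, else after the id of the last
    individual in each block (the GENEPOP convention) or ``pop<k>`` when ids
    clash.  All-zero tokens become missing genotypes.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    pop_re = re.compile(rf"^\s*{re.escape(dialect.pop_token)}\s*$", re.IGNORECASE)

    # locus names: every line after the title until the first POP; a single
    # line may carry several comma-separated names
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not pop_re.match(lines[i]):
        locus_names.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"{path}: no {dialect.pop_token} separator found")

    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    block_of: list[int] = []
    block_last_id: list[str] = []
    n_pops = 0
    width = dialect.token_width
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if pop_re.match(line):
            n_pops += 1
            block_last_id.append("")
            continue
        if n_pops == 0:
            raise GenotypeParseError(f"{path}:{lineno}: sample before first POP")
        if "," not in line:
            raise GenotypeParseError(
                f"{path}:{lineno}: expected '<id> , <genotypes>'"
            )
        ind_id, _, rest = line.partition(",")
        ind_id = ind_id.strip()
        tokens = rest.split()
        if len(tokens) != len(locus_names):
            raise GenotypeParseError(
                f"{path}:{lineno}: {len(tokens)} genotype tokens for "
                f"{len(locus_names)} loci"
            )
        calls: list[tuple[int, int]] = []
        for tok, locus in zip(tokens, locus_names):
            if len(tok) != width or not tok.isdigit():
                raise GenotypeParseError(
                    f"{path}:{lineno}: bad genotype token {tok!r} for locus "
                    f"{locus} (expected {width} digits)"
                )
            a, b = int(tok[: dialect.digits]), int(tok[dialect.digits :])
            if a == 0 and b == 0:
                calls.append((MISSING, MISSING))
            elif a == 0 or b == 0:
                logger.warning(
                    "%s:%d: half-called token %r treated as missing",
                    path,
                    lineno,
                    tok,
                )
                calls.append((MISSING, MISSING))
            else:
                calls.append(_sorted_pair(a, b))
        if ind_id in ids:
            raise GenotypeParseError(f"{path}:{lineno}: duplicate individual id {ind_id!r}")
        ids.append(ind_id)
        rows.append(calls)
        block_of.append(n_pops - 1)
        block_last_id[-1] = ind_id

    if not ids:
        raise GenotypeParseError(f"{path}: no individuals")
    if pop_names is not None:
        if len(pop_names) != n_pops:
            raise GenotypeParseError(
                f"{path}: {len(pop_names)} pop_names for {n_pops} POP blocks"
            )
        names = list(pop_names)
    elif len(set(block_last_id)) == n_pops:
        names = block_last_id
    else:
        names = [f"pop{k + 1}" for k in range(n_pops)]

    alleles = np.array(rows, dtype=np.int64)
    grouping = {ind: names[b] for ind, b in zip(ids, block_of)}
    return GenotypeMatrix(ids, locus_names, alleles, {grouping_name: grouping})


def write_genepop(
    G: GenotypeMatrix,
    path: str | Path,
    grouping_name: str,
    dialect: GenepopDialect = GenepopDialect(),
    title: str = "msatpop export",
    remap: bool = False,
) -> dict[str, dict[int, int]] | None:
    """Write one grouping of ``G`` as GENEPOP text.

    Individuals are emitted grouped by class (classes in first-appearance
    order, original order within a class), so the writer is deterministic
    byte-for-byte.  Returns a per-locus relabelling legend when ``remap`` was
    needed, else ``None``.

    Raises
    ------
    ValueError
        if an allele label does not fit the dialect width and ``remap`` is
        False.
    """
    limit = 10 ** dialect.digits
    legend: dict[str, dict[int, int]] | None = None
    alleles = G.alleles
    if (alleles >= limit).any():
        if not remap:
            raise ValueError(
                f"allele labels >= {limit} cannot be written at "
                f"{dialect.digits} digits; pass remap=True"
            )
        legend = {}
        alleles = alleles.copy()
        for j, locus in enumerate(G.locus_names):
            obs = np.unique(alleles[:, j, :])
            obs = obs[obs != MISSING]
            mapping = {int(a): k + 1 for k, a in enumerate(sorted(obs))}
            legend[locus] = mapping
            for old, new in mapping.items():
                alleles[:, j, :][G.alleles[:, j, :] == old] = new

    idx_by_pop = G.population_indices(grouping_name)
    out = [title]
    out.extend(G.locus_names)
    for pop, idx in idx_by_pop.items():
        out.append(dialect.pop_token)
        for i in idx:
            toks = []
            for j in range(G.n_loci):
                a, b = alleles[i, j]
                if a == MISSING:
                    toks.append(dialect.missing_allele * 2)
                else:
                    toks.append(f"{a:0{dialect.digits}d}{b:0{dialect.digits}d}")
            out.append(f"{G.individual_ids[i]} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")
    return legend


# ---------------------------------------------------------------------------
# Delimited tables (lossless native format)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSchema:
    """Column mapping for the tabular genotype format.

    ``locus_cols`` maps locus name -> column holding the ``a/b`` genotype;
    empty/NA cells are missing.  ``grouping_cols`` maps grouping name ->
    column; several groupings may be attached at once.
    """

    id_col: str = "id"
    grouping_cols: Mapping[str, str] = field(default_factory=dict)
    locus_cols: Mapping[str, str] | None = None  # None: every other column
    allele_sep: str = "/"
    delimiter: str = ","


def read_table(path: str | Path, schema: TableSchema = TableSchema()) -> GenotypeMatrix:
    """Read a delimited genotype table into a :class:`GenotypeMatrix`."""
    df = pd.read_csv(path, sep=schema.delimiter, dtype=str)
    if schema.id_col not in df.columns:
        raise GenotypeParseError(f"{path}: missing id column {schema.id_col!r}")
    absent = [c for c in schema.grouping_cols.values() if c not in df.columns]
    if absent:
        raise GenotypeParseError(f"{path}: missing grouping columns {absent}")
    if schema.locus_cols is None:
        reserved = {schema.id_col, *schema.grouping_cols.values()}
        locus_cols = {c: c for c in df.columns if c not in reserved}
    else:
        locus_cols = dict(schema.locus_cols)
    ids = df[schema.id_col].tolist()
    if len(set(ids)) != len(ids):
        raise GenotypeParseError(f"{path}: duplicate individual ids")
    n, L = len(ids), len(locus_cols)
    alleles = np.full((n, L, 2), MISSING, dtype=np.int64)
    for j, (locus, col) in enumerate(locus_cols.items()):
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if not cell or cell.lower() in ("na", "nan"):
                continue
            parts = cell.split(schema.allele_sep)
            if len(parts) != 2:
                raise GenotypeParseError(
                    f"{path}: row {i + 1} locus {locus}: bad genotype {cell!r}"
                )
            try:
                a, b = int(parts[0]), int(parts[1])
            except ValueError:
                raise GenotypeParseError(
                    f"{path}: row {i + 1} locus {locus}: non-integer allele in "
                    f"{cell!r}"
                ) from None
            if a == 0 and b == 0:
                continue
            alleles[i, j] = _sorted_pair(a, b)
    groupings = {
        name: dict(zip(ids, df[col].astype(str)))
        for name, col in schema.grouping_cols.items()
    }
    return GenotypeMatrix(ids, list(locus_cols), alleles, groupings)


def write_table(G: GenotypeMatrix, path: str | Path, allele_sep: str = "/") -> None:
    """Write ``G`` (all groupings) as CSV; inverse of :func:`read_table`."""
    data: dict[str, list[str]] = {"id": G.individual_ids}
    for name in G.groupings:
        data[name] = [G.groupings[name][i] for i in G.individual_ids]
    for j, locus in enumerate(G.locus_names):
        col = []
        for i in range(G.n_individuals):
            a, b = G.alleles[i, j]
            col.append("" if a == MISSING else f"{a}{allele_sep}{b}")
        data[locus] = col
    pd.DataFrame(data).to_csv(path, index=False)


def table_schema_for(G: GenotypeMatrix) -> TableSchema:
    """Schema that reads back a table written by :func:`write_table`."""
    return TableSchema(
        id_col="id",
        grouping_cols={name: name for name in G.groupings},
        locus_cols={locus: locus for locus in G.locus_names},
    )
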