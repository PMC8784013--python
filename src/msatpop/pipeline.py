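"""One-command orchestration of the full microsatellite analysis.

From a genotype file (GENEPOP or tabular) plus a config, reproduce the whole
chain: per-locus and per-population diversity tables, Weir-Cockerham
F-statistics, Nei identity/distance matrices, a Neighbour-Joining tree in
Newick form, FCA coordinates, the Evanno DeltaK table and the cluster
composition table — deterministically under a base seed, with a JSON
manifest recording parameters and seeds.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import best_k, cluster_composition, evanno_delta_k, gibbs_fit, ln_prob_data
from .diversity import diversity_summary
from .fca import fca
from .fstats import fis_table, wc_fstats
from .genotype_io import (
    GenepopDialect,
    GenotypeMatrix,
    TableSchema,
    read_genepop,
    read_table,
)
from .neidist import pairwise_matrix
from .njtree import neighbor_joining

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one full analysis."""

    input_path: str
    input_format: str = "table"  # "table" | "genepop"
    groupings: list[str] = field(default_factory=lambda: ["phenotype", "zone"])
    genepop_digits: int = 3
    genepop_grouping: str = "pop"
    unbiased_he: bool = True
    rarefaction_grouping: str | None = None
    n_perm: int = 999
    nj_clamp_negative: bool = False
    fca_axes: int = 3
    k_range: tuple[int, int] = (2, 6)
    replicates: int = 10
    burnin: int = 5_000
    sweeps: int = 10_000
    alpha_policy: str = "sample"
    seed: int = 0
    output_dir: str = "msatpop-out"


def load_genotypes(cfg: AnalysisConfig) -> GenotypeMatrix:
    if cfg.input_format == "genepop":
        return read_genepop(
            cfg.input_path,
            GenepopDialect(digits=cfg.genepop_digits),
            grouping_name=cfg.genepop_grouping,
        )
    if cfg.input_format == "table":
        schema = TableSchema(grouping_cols={g: g for g in cfg.groupings})
        return read_table(cfg.input_path, schema)
    raise ValueError(f"unknown input format {cfg.input_format!r}")


def run_all(cfg: AnalysisConfig, G: GenotypeMatrix | None = None) -> dict[str, Path]:
    """Run every stage and write the report bundle into ``cfg.output_dir``.

    Results are computed first and written at the end; on a stage failure the
    partially-created output directory is removed and the error re-raised
    with the stage name.
    """
    if G is None:
        G = load_genotypes(cfg)
    for g in cfg.groupings:
        if g not in G.groupings:
            raise ValueError(f"grouping {g!r} not present in the input")
    rng = np.random.default_rng(cfg.seed)
    artifacts: dict[str, pd.DataFrame | str] = {}

    stage = "diversity"
    try:
        artifacts["diversity_per_locus.tsv"] = diversity_summary(
            G,
            grouping=None,
            unbiased_he=cfg.unbiased_he,
            rarefaction_grouping=cfg.rarefaction_grouping or cfg.groupings[0],
        )
        for g in cfg.groupings:
            artifacts[f"diversity_by_{_slug(g)}.tsv"] = diversity_summary(
                G, grouping=g, unbiased_he=cfg.unbiased_he
            )

        stage = "fstats"
        for g in cfg.groupings:
            artifacts[f"fstats_by_{_slug(g)}.tsv"] = wc_fstats(G, g).to_frame()
            artifacts[f"fis_by_{_slug(g)}.tsv"] = fis_table(
                G, g, n_perm=cfg.n_perm, seed=int(rng.integers(2**31))
            )

        stage = "neidist"
        dmat = pairwise_matrix(G, cfg.groupings[0])
        artifacts["nei_triangular.tsv"] = dmat.to_triangular_frame()
        artifacts["nei_distance.tsv"] = dmat.to_frame("distance")
        artifacts["nei_identity.tsv"] = dmat.to_frame("identity")

        stage = "njtree"
        tree = neighbor_joining(dmat, clamp_negative=cfg.nj_clamp_negative)
        artifacts["nj_tree.nwk"] = tree.newick()

        stage = "fca"
        res = fca(G, n_axes=cfg.fca_axes)
        coords = res.row_coords.copy()
        for g in cfg.groupings:
            coords.insert(0, g, G.group_labels(g))
        artifacts["fca_coordinates.tsv"] = coords
        artifacts["fca_inertia.tsv"] = pd.DataFrame(
            {
                "eigenvalue": res.eigenvalues,
                "inertia_fraction": res.inertia_fractions,
            },
            index=[f"axis{i + 1}" for i in range(len(res.eigenvalues))],
        )

        stage = "admixture"
        runs = []
        k_lo, k_hi = cfg.k_range
        for K in range(k_lo, k_hi + 1):
            for rep in range(cfg.replicates):
                runs.append(
                    gibbs_fit(
                        G,
                        K,
                        burnin=cfg.burnin,
                        sweeps=cfg.sweeps,
                        seed=cfg.seed + 1000 * K + rep,
                        alpha_policy=cfg.alpha_policy,
                    )
                )
        # Evanno needs interior points; pad the lower end with K-1 runs
        delta = evanno_delta_k(runs) if k_hi - k_lo >= 2 else None
        if delta is not None:
            artifacts["evanno_delta_k.tsv"] = delta
            chosen = best_k(delta)
        else:
            chosen = k_lo
        rep_runs = [r for r in runs if r.K == chosen]
        run = max(rep_runs, key=ln_prob_data)
        qout = run.Q.copy()
        for g in cfg.groupings:
            qout.insert(0, g, G.group_labels(g))
        artifacts["q_matrix.tsv"] = qout
        artifacts["cluster_composition.tsv"] = cluster_composition(
            run, G, cfg.groupings[-1]
        )
        manifest = {
            "msatpop_version": __version__,
            "config": asdict(cfg),
            "seed": cfg.seed,
            "n_individuals": G.n_individuals,
            "n_loci": G.n_loci,
            "groupings": {g: G.classes(g) for g in cfg.groupings},
            "best_k": int(chosen),
        }
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    outdir = Path(cfg.output_dir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        for name, obj in artifacts.items():
            path = outdir / name
            if isinstance(obj, str):
                path.write_text(obj + "\n")
            else:
                obj.to_csv(path, sep="\t", float_format="%.6g")
            written[name] = path
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        written["manifest.json"] = mpath
    except Exception:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for p in written.values():
                p.unlink(missing_ok=True)
        raise
    return written


def _slug(name: str) -> str:
    return name.replace(" ", "_").lower()


# ---------------------------------------------------------------------------
# Comparison harness against transcribed published tables
# ---------------------------------------------------------------------------

def load_reference_table(name: str) -> pd.DataFrame:
    """Load a transcribed published reference table shipped with the package.

    ``name`` is one of ``table2``, ``table3``, ``table4``.
    """
    fname = f"{name}_reference.tsv"
    with resources.files("msatpop.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col=0)


def compare_tables(
    produced: pd.DataFrame,
    reference: pd.DataFrame,
    tolerances: dict[str, float],
) -> pd.DataFrame:
    """Cell-level comparison of a produced table against a reference.

    Both tables must share index labels and every column named in
    ``tolerances``.  Returns a long-format report with one row per compared
    cell: produced value, reference value, absolute difference and a pass
    flag (``abs diff <= tolerance``).
    """
    missing_cols = [c for c in tolerances if c not in produced.columns or c not in reference.columns]
    if missing_cols:
        raise ValueError(f"schema mismatch: columns {missing_cols} absent")
    common = [i for i in reference.index if i in produced.index]
    if not common:
        raise ValueError("schema mismatch: no shared index labels")
    rows = []
    for idx in common:
        for col, tol in tolerances.items():
            got = float(produced.loc[idx, col])
            want = float(reference.loc[idx, col])
            diff = abs(got - want)
            rows.append(
                {
                    "row": idx,
                    "column": col,
                    "produced": got,
                    "reference": want,
                    "abs_diff": diff,
                    "tolerance": tol,
                    "pass": bool(diff <= tol),
                }
            )
    return pd.DataFrame(rows)
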