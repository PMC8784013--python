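"""Synthetic diploid microsatellite genotypes with known truth.

The generative model is a multiallelic Balding-Nichols hierarchy: ancestral
allele frequencies ``p`` per locus are drawn from a flat Dirichlet; each of
``K`` source populations then draws its own frequencies from
``Dirichlet(p * (1 - F) / F)`` with ``F`` the target FST, so the expected
differentiation is an explicit parameter.  Within-individual inbreeding is an
IBD-copy mixture: with probability ``target_fis`` the second gene copy of a
genotype is an identical-by-descent copy of the first, which gives
``E[FIS] = target_fis`` exactly.  Missingness is completely at random.

Sampling groups either coincide with the source populations (one-hot
ancestry, used for differentiation/label-recovery fixtures) or are
ancestry-blind with individual admixture ``q ~ Dirichlet(alpha * 1_K)``
(used for the study-shaped fixture where plumage phenotype does not track
ancestry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_frequencies",
    "simulate_genotypes",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass
class SimConfig:
    """Parameters of the genotype simulator.

    Parameters
    ----------
    K_ancestral
        Number of unobserved source populations.
    n_loci
        Number of microsatellite loci.
    alleles_per_locus
        Ancestral allele count, one integer for all loci or one per locus.
    target_fst
        Balding-Nichols F in [0, 1): expected differentiation among the
        source populations.  0 means all sources share the ancestral
        frequencies exactly.
    target_fis
        Probability that a genotype's second gene copy is an IBD copy of the
        first; equals the expected within-population FIS.  Must lie in [0, 1].
    admixture_alpha
        Dirichlet concentration for individual ancestry when groups are
        ancestry-blind; large -> admixed, small -> near-discrete.
    n_per_group
        Individuals per sampling group.
    group_names
        Optional class labels (default ``group1..``).
    missing_rate
        Per-genotype missing probability (MCAR).
    seed
        Seed for all randomness; same seed -> byte-identical output.
    group_ancestry
        ``"aligned"``: group g draws purely from source population g (requires
        len(n_per_group) == K_ancestral); ``"admixed"``: ancestry-blind
        Dirichlet(alpha) admixture; ``"auto"`` picks aligned iff the counts
        match.
    """

    K_ancestral: int = 1
    n_loci: int = 10
    alleles_per_locus: int | Sequence[int] = 4
    target_fst: float = 0.0
    target_fis: float = 0.0
    admixture_alpha: float = 1.0
    n_per_group: Sequence[int] = (50,)
    group_names: Sequence[str] | None = None
    missing_rate: float = 0.0
    seed: int = 0
    group_ancestry: str = "auto"

    def __post_init__(self) -> None:
        if self.K_ancestral < 1:
            raise ValueError("K_ancestral must be >= 1")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must lie in [0, 1)")
        if not 0.0 <= self.target_fis <= 1.0:
            raise ValueError(
                "target_fis must lie in [0, 1]: the IBD-copy device cannot "
                "generate heterozygote excess"
            )
        if self.admixture_alpha <= 0:
            raise ValueError("admixture_alpha must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.n_per_group) == 0:
            raise ValueError("n_per_group must be nonempty")
        if self.group_ancestry not in ("auto", "aligned", "admixed"):
            raise ValueError("group_ancestry must be auto|aligned|admixed")
        if self.group_ancestry == "aligned" and len(self.n_per_group) != self.K_ancestral:
            raise ValueError("aligned ancestry needs one group per source population")

    @property
    def allele_counts(self) -> list[int]:
        if isinstance(self.alleles_per_locus, int):
            counts = [self.alleles_per_locus] * self.n_loci
        else:
            counts = list(self.alleles_per_locus)
            if len(counts) != self.n_loci:
                raise ValueError("alleles_per_locus list must match n_loci")
        if any(c < 1 for c in counts):
            raise ValueError("allele counts must be >= 1")
        return counts

    @property
    def aligned(self) -> bool:
        if self.group_ancestry == "aligned":
            return True
        if self.group_ancestry == "admixed":
            return False
        return len(self.n_per_group) == self.K_ancestral

    @property
    def labels(self) -> list[str]:
        if self.group_names is not None:
            if len(self.group_names) != len(self.n_per_group):
                raise ValueError("group_names must match n_per_group")
            return list(self.group_names)
        return [f"group{g + 1}" for g in range(len(self.n_per_group))]


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``ancestral_freqs[l]`` and ``pop_freqs[k][l]`` are frequency vectors per
    locus; ``admixture`` is the n x K matrix of individual ancestry
    proportions; ``group_labels`` the sampling-group label per individual.
    """

    ancestral_freqs: list[np.ndarray]
    pop_freqs: list[list[np.ndarray]]
    admixture: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    group_labels: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.pop_freqs)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ancestral_freqs": [f.tolist() for f in self.ancestral_freqs],
            "pop_freqs": [[f.tolist() for f in pop] for pop in self.pop_freqs],
            "admixture": self.admixture.tolist(),
            "group_labels": self.group_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def simulate_frequencies(cfg: SimConfig) -> SimTruth:
    """Draw ancestral and per-source-population allele frequencies."""
    rng = np.random.default_rng(cfg.seed)
    ancestral: list[np.ndarray] = []
    pop_freqs: list[list[np.ndarray]] = [[] for _ in range(cfg.K_ancestral)]
    F = cfg.target_fst
    for n_alleles in cfg.allele_counts:
        if n_alleles == 1:
            p = np.ones(1)
        else:
            p = rng.dirichlet(np.ones(n_alleles))
            # guard against numerically-zero Dirichlet parameters downstream
            p = np.clip(p, 1e-4, None)
            p /= p.sum()
        ancestral.append(p)
        for k in range(cfg.K_ancestral):
            if F == 0.0 or n_alleles == 1:
                pop_freqs[k].append(p.copy())
            else:
                pop_freqs[k].append(rng.dirichlet(p * (1.0 - F) / F))
    return SimTruth(ancestral, pop_freqs)


def simulate_genotypes(truth: SimTruth, cfg: SimConfig) -> GenotypeMatrix:
    """Sample a genotype matrix from ``truth`` under ``cfg``.

    Allele labels are synthetic fragment sizes ``100 + 2*index`` bp, shared
    across source populations within a locus.
    """
    if truth.K != cfg.K_ancestral:
        raise ValueError("truth inconsistent with cfg: wrong number of populations")
    rng = np.random.default_rng(cfg.seed + 1)
    n = int(sum(cfg.n_per_group))
    L = cfg.n_loci
    K = cfg.K_ancestral
    labels = cfg.labels

    group_of = np.repeat(np.arange(len(cfg.n_per_group)), cfg.n_per_group)
    if cfg.aligned:
        Q = np.zeros((n, K))
        Q[np.arange(n), group_of % K] = 1.0
    else:
        Q = rng.dirichlet(np.full(K, cfg.admixture_alpha), size=n)

    alleles = np.empty((n, L, 2), dtype=np.int64)
    for l in range(L):
        freqs = np.vstack([truth.pop_freqs[k][l] for k in range(K)])  # K x A
        A = freqs.shape[1]
        sizes = 100 + 2 * np.arange(A)
        # first copy: origin then allele
        z1 = _categorical(rng, Q)  # n
        a1 = _categorical(rng, freqs[z1])
        # second copy: IBD copy of the first with prob target_fis
        ibd = rng.random(n) < cfg.target_fis
        z2 = _categorical(rng, Q)
        a2 = _categorical(rng, freqs[z2])
        a2 = np.where(ibd, a1, a2)
        pair = np.sort(np.stack([sizes[a1], sizes[a2]], axis=1), axis=1)
        alleles[:, l, :] = pair
    if cfg.missing_rate > 0:
        drop = rng.random((n, L)) < cfg.missing_rate
        alleles[drop] = MISSING

    ids = [f"ind{i + 1:03d}" for i in range(n)]
    grouping = {ids[i]: labels[group_of[i]] for i in range(n)}
    G = GenotypeMatrix(ids, [f"L{l + 1:02d}" for l in range(L)], alleles, {"group": grouping})
    truth.admixture = Q
    truth.group_labels = [labels[g] for g in group_of]
    return G


def _categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw; ``probs`` is (n, A) or (A,) broadcast."""
    probs = np.atleast_2d(probs)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0]) * cum[:, -1]
    return (u[:, None] >= cum).sum(axis=1)


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

# The study-shaped fixture mirrors the field survey: 94 birds in 7 plumage
# phenotypes (and a 35/59 agroecological-zone split), 18 loci with the
# published per-locus allele counts (mean 6.0/locus), FST 0.012, FIS 0.17,
# three admixed source populations and sporadic missing genotypes.
_TOGO_ALLELE_COUNTS = [4, 3, 7, 25, 7, 2, 2, 3, 4, 4, 8, 4, 7, 5, 5, 7, 4, 7]
_TOGO_LOCI = [
    "GF43", "GUJ0001", "GUJ0059", "GUJ0066", "GF13", "GF5", "GUJ0084",
    "GF30", "GF75", "GF168", "GF12", "GUJ0013", "GF37", "GUJ0086",
    "MCW0222", "GF69", "GF74", "MCW0069",
]
_TOGO_PHENOTYPES = {
    "Albino": 5,
    "Bonaparte": 19,
    "Pearl grey": 19,
    "Lavender": 8,
    "Black pied": 5,
    "Multi-coloured": 18,
    "Royal purple": 20,
}

FIXTURE_NAMES = (
    "togo-like",
    "two-pop-differentiated",
    "panmictic",
    "three-source-admixed",
)


def make_fixture(name: str, seed: int = 0) -> tuple[GenotypeMatrix, SimTruth]:
    """Build a preset simulated dataset.

    ``togo-like``: 94 individuals, 18 loci with the study's allele spectrum,
    7 phenotype + 2 zone groupings, FST=0.012, FIS=0.17, alpha=1.0.
    ``two-pop-differentiated``: 2 sources at FST=0.30, 50 individuals each.
    ``panmictic``: one population, FIS=0.
    ``three-source-admixed``: 3 sources at FST=0.15.
    """
    if name == "togo-like":
        cfg = SimConfig(
            K_ancestral=3,
            n_loci=18,
            alleles_per_locus=_TOGO_ALLELE_COUNTS,
            target_fst=0.012,
            target_fis=0.17,
            admixture_alpha=1.0,
            n_per_group=list(_TOGO_PHENOTYPES.values()),
            group_names=list(_TOGO_PHENOTYPES),
            missing_rate=0.02,
            seed=seed,
            group_ancestry="admixed",
        )
        truth = simulate_frequencies(cfg)
        G = simulate_genotypes(truth, cfg)
        G.groupings["phenotype"] = G.groupings.pop("group")
        # 35 Atakora / 59 Dry Savannah, interleaved across phenotypes
        rng = np.random.default_rng(cfg.seed + 2)
        zone = np.array(["Dry Savannah"] * G.n_individuals, dtype=object)
        zone[rng.choice(G.n_individuals, size=35, replace=False)] = "Atakora"
        G.set_grouping("zone", dict(zip(G.individual_ids, zone)))
        G.locus_names = list(_TOGO_LOCI)
        return G, truth
    if name == "two-pop-differentiated":
        cfg = SimConfig(
            K_ancestral=2,
            n_loci=20,
            alleles_per_locus=6,
            target_fst=0.30,
            target_fis=0.0,
            n_per_group=[50, 50],
            seed=seed,
            group_ancestry="aligned",
        )
    elif name == "panmictic":
        cfg = SimConfig(
            K_ancestral=1,
            n_loci=18,
            alleles_per_locus=6,
            target_fst=0.0,
            target_fis=0.0,
            n_per_group=[94],
            seed=seed,
        )
    elif name == "three-source-admixed":
        cfg = SimConfig(
            K_ancestral=3,
            n_loci=15,
            alleles_per_locus=8,
            target_fst=0.15,
            target_fis=0.0,
            n_per_group=[25, 25, 25],
            seed=seed,
            group_ancestry="aligned",
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; presets: {FIXTURE_NAMES}")
    truth = simulate_frequencies(cfg)
    G = simulate_genotypes(truth, cfg)
    return G, truth
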