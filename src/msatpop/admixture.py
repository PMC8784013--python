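"""Bayesian admixture-model clustering by Gibbs sampling.

The model is the classic no-linkage admixture model with uncorrelated allele
frequencies: each individual ``i`` has ancestry proportions ``q_i`` over ``K``
clusters (Dirichlet(alpha) prior, one alpha shared across clusters), each
cluster ``k`` has its own allele frequencies ``p_{k,l}`` per locus
(Dirichlet(lambda = 1) prior), and each gene copy independently picks an
origin cluster ``z ~ Categorical(q_i)`` and then an allele ``~ p_{z,l}``.

One Gibbs sweep updates, in order: the origin ``z`` of every gene copy, every
``q_i``, every ``p_{k,l}``, and (optionally) alpha by a Metropolis step with
a uniform prior on (0, 10).  Missing genotypes are skipped everywhere.

Model choice across K uses the standard harmonic-style estimator
``LnP(D) = mean(trace) - var(trace)/2`` of the per-sweep complete-data
log-likelihood, summarized over replicate chains by the Evanno
second-order-rate-of-change statistic ``DeltaK``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class AdmixtureRun:
    """Posterior summaries of one chain at one K."""

    K: int
    seed: int
    burnin: int
    sweeps: int
    Q: pd.DataFrame  # individuals x K posterior-mean ancestry
    P: np.ndarray  # K x loci x max-alleles posterior-mean frequencies
    allele_labels: list[np.ndarray]  # per locus, labels of the P columns
    loglik_trace: np.ndarray  # retained per-sweep complete log-likelihood
    alpha_trace: np.ndarray
    alpha_acceptance: float

    @property
    def q_matrix(self) -> np.ndarray:
        return self.Q.to_numpy()


class _CodedGenotypes:
    """Genotypes recoded to dense per-locus allele indices for the sampler."""

    def __init__(self, G: GenotypeMatrix) -> None:
        n, L = G.n_individuals, G.n_loci
        self.labels: list[np.ndarray] = []
        self.valid = ~G.missing_mask  # (n, L)
        self.A1 = np.zeros((n, L), dtype=np.int64)
        self.A2 = np.zeros((n, L), dtype=np.int64)
        for j in range(L):
            calls = G.alleles[:, j, :]
            obs = np.unique(calls[calls > 0])
            self.labels.append(obs)
            lut = {int(a): k for k, a in enumerate(obs)}
            ok = self.valid[:, j]
            self.A1[ok, j] = [lut[int(a)] for a in calls[ok, 0]]
            self.A2[ok, j] = [lut[int(a)] for a in calls[ok, 1]]
        self.n_alleles = np.array([len(lab) for lab in self.labels])
        self.Amax = int(self.n_alleles.max())
        self.allele_ok = np.zeros((L, self.Amax), dtype=bool)
        for j, m in enumerate(self.n_alleles):
            self.allele_ok[j, :m] = True
        self.n, self.L = n, L
        self.lgrid = np.broadcast_to(np.arange(L), (n, L))


def gibbs_fit(
    G: GenotypeMatrix,
    K: int,
    burnin: int = 5_000,
    sweeps: int = 10_000,
    seed: int = 0,
    alpha_policy: str = "sample",
    alpha: float = 1.0,
    lambda_prior: float = 1.0,
) -> AdmixtureRun:
    """Fit the admixture model with ``burnin`` discarded and ``sweeps``
    retained Gibbs sweeps.

    ``alpha_policy`` is ``"sample"`` (Metropolis step, Normal proposal with
    SD ``0.05 * alpha``, uniform prior on (0, 10)) or ``"fixed"``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if burnin < 1 or sweeps < 1:
        raise ValueError("burnin and sweeps must be >= 1")
    if alpha_policy not in ("sample", "fixed"):
        raise ValueError(f"alpha_policy must be 'sample' or 'fixed', got {alpha_policy!r}")
    data = _CodedGenotypes(G)
    if K > int(data.n_alleles.max()):
        logger.warning(
            "K=%d exceeds the largest allele count (%d); empty clusters expected",
            K,
            int(data.n_alleles.max()),
        )
    rng = np.random.default_rng(seed)
    n, L, Amax = data.n, data.L, data.Amax

    Q = np.full((n, K), 1.0 / K)
    P = rng.dirichlet(np.ones(Amax), size=(K, L)) * data.allele_ok
    P /= P.sum(axis=2, keepdims=True)
    a_cur = float(alpha)

    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    trace = np.empty(sweeps)
    alpha_trace = np.empty(sweeps)
    n_acc = n_prop = 0

    def draw_origins(A: np.ndarray) -> np.ndarray:
        # P gathered at the carried allele: (K, n, L)
        W = Q.T[:, :, None] * P[:, data.lgrid, A]
        cum = np.cumsum(W, axis=0)
        u = rng.random((n, L)) * cum[-1]
        return np.minimum((u[None] >= cum).sum(axis=0), K - 1)

    for sweep in range(burnin + sweeps):
        z1 = draw_origins(data.A1)
        z2 = draw_origins(data.A2)

        # ancestry update
        N = np.zeros((n, K))
        for k in range(K):
            N[:, k] = ((z1 == k) & data.valid).sum(axis=1) + (
                (z2 == k) & data.valid
            ).sum(axis=1)
        Qg = rng.gamma(a_cur + N) + 1e-300
        Q = Qg / Qg.sum(axis=1, keepdims=True)

        # cluster frequency update
        C = np.zeros((K, L, Amax))
        for k in range(K):
            for z, A in ((z1, data.A1), (z2, data.A2)):
                m = (z == k) & data.valid
                np.add.at(C[k], (data.lgrid[m], A[m]), 1.0)
        Pg = (rng.gamma(lambda_prior + C) + 1e-300) * data.allele_ok
        P = Pg / Pg.sum(axis=2, keepdims=True)

        if alpha_policy == "sample" and K > 1:
            a_new = rng.normal(a_cur, 0.05 * a_cur)
            n_prop += 1
            if 0.0 < a_new < 10.0:
                slog = float(np.log(Q).sum())
                lp_new = n * (gammaln(K * a_new) - K * gammaln(a_new)) + (a_new - 1) * slog
                lp_cur = n * (gammaln(K * a_cur) - K * gammaln(a_cur)) + (a_cur - 1) * slog
                if np.log(rng.random()) < lp_new - lp_cur:
                    a_cur = float(a_new)
                    n_acc += 1

        if sweep >= burnin:
            t = sweep - burnin
            mix1 = np.einsum("ik,kil->il", Q, P[:, data.lgrid, data.A1])
            mix2 = np.einsum("ik,kil->il", Q, P[:, data.lgrid, data.A2])
            trace[t] = float(
                np.log(mix1[data.valid]).sum() + np.log(mix2[data.valid]).sum()
            )
            alpha_trace[t] = a_cur
            Q_sum += Q
            P_sum += P

    Q_mean = Q_sum / sweeps
    P_mean = P_sum / sweeps
    return AdmixtureRun(
        K=K,
        seed=seed,
        burnin=burnin,
        sweeps=sweeps,
        Q=pd.DataFrame(
            Q_mean, index=G.individual_ids, columns=[f"cluster{k + 1}" for k in range(K)]
        ),
        P=P_mean,
        allele_labels=data.labels,
        loglik_trace=trace,
        alpha_trace=alpha_trace,
        alpha_acceptance=n_acc / n_prop if n_prop else float("nan"),
    )


def ln_prob_data(run: AdmixtureRun) -> float:
    """``LnP(D) = mean(trace) - var(trace) / 2`` over retained sweeps."""
    trace = np.asarray(run.loglik_trace, dtype=float)
    if trace.size < 2:
        raise ValueError("need >= 2 retained sweeps to estimate LnP(D)")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def evanno_delta_k(runs: list[AdmixtureRun]) -> pd.DataFrame:
    """Evanno summary across K.

    Per K: mean and SD of LnP(D) over replicates; for interior K,
    ``L'(K) = Lbar(K) - Lbar(K-1)``,
    ``|L''(K)| = |Lbar(K+1) - 2 Lbar(K) + Lbar(K-1)|`` and
    ``DeltaK = |L''(K)| / SD(K)``.  DeltaK is NaN at boundary K, with fewer
    than 2 replicates, or when the replicate SD is zero (flagged).
    """
    by_k: dict[int, list[float]] = {}
    for run in runs:
        by_k.setdefault(run.K, []).append(ln_prob_data(run))
    ks = sorted(by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) if len(by_k[k]) > 1 else np.nan for k in ks}
    rows = []
    for k in ks:
        lprime = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            lsec = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            if np.isnan(sd[k]) or sd[k] == 0.0:
                logger.warning("K=%d: zero/undefined replicate SD; DeltaK undefined", k)
                dk = np.nan
            else:
                dk = lsec / sd[k]
        else:
            lsec = dk = np.nan
        rows.append(
            {
                "K": k,
                "n_reps": len(by_k[k]),
                "mean_lnp": mean[k],
                "sd_lnp": sd[k],
                "lprime": lprime,
                "lsecond_abs": lsec,
                "delta_k": dk,
            }
        )
    return pd.DataFrame(rows).set_index("K")


def best_k(delta_table: pd.DataFrame) -> int:
    """argmax of DeltaK over the interior K values."""
    dk = delta_table["delta_k"].dropna()
    if dk.empty:
        raise ValueError("DeltaK undefined for every K")
    return int(dk.idxmax())


def cluster_composition(
    run: AdmixtureRun, G: GenotypeMatrix, grouping: str
) -> pd.DataFrame:
    """Group x cluster percentage table from hard max-Q assignments.

    Each individual goes to its highest-ancestry cluster (ties to the lowest
    cluster index, logged); cell (g, k) is the percentage of group g assigned
    to cluster k, so rows sum to 100.
    """
    Qm = run.Q.loc[G.individual_ids].to_numpy()
    assign = Qm.argmax(axis=1)
    ties = (Qm == Qm.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("%d individuals with tied max ancestry assigned to the "
                    "lowest cluster index", int(ties.sum()))
    labels = G.group_labels(grouping)
    groups = G.classes(grouping)
    out = np.zeros((len(groups), run.K))
    for gi, g in enumerate(groups):
        members = labels == g
        for k in range(run.K):
            out[gi, k] = 100.0 * np.sum(assign[members] == k) / members.sum()
    return pd.DataFrame(out, index=groups, columns=list(run.Q.columns))


def align_clusters(Q: np.ndarray, true_labels: np.ndarray) -> np.ndarray:
    """Greedy cluster -> true-class matching; returns the permuted-column Q.

    ``true_labels`` are integer class codes in ``0..K-1``.  Used by recovery
    tests to undo label switching before comparing hard assignments.
    """
    K = Q.shape[1]
    classes = np.unique(true_labels)
    conf = np.zeros((K, K))
    assign = Q.argmax(axis=1)
    for k in range(K):
        for ci, c in enumerate(classes[:K]):
            conf[k, ci] = np.sum((assign == k) & (true_labels == c))
    perm = np.full(K, -1)
    used_rows, used_cols = set(), set()
    for _ in range(K):
        best_val, best_rc = -1.0, None
        for k in range(K):
            if k in used_rows:
                continue
            for ci in range(K):
                if ci in used_cols:
                    continue
                if conf[k, ci] > best_val:
                    best_val, best_rc = conf[k, ci], (k, ci)
        k, ci = best_rc
        perm[ci] = k
        used_rows.add(k)
        used_cols.add(ci)
    return Q[:, perm]
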