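"""Admixture Gibbs sampler, LnP(D) estimator and Evanno summary."""

import numpy as np
import pandas as pd
import pytest

from msatpop.admixture import (
    AdmixtureRun,
    best_k,
    cluster_composition,
    evanno_delta_k,
    gibbs_fit,
    ln_prob_data,
)
from msatpop.simulate import make_fixture
from conftest import make_matrix


def tiny_matrix():
    return make_matrix(
        [[(1, 2), (3, 3)], [(1, 1), (3, 4)], [(2, 2), (4, 4)], [(1, 2), None]],
        groups=["a", "a", "b", "b"],
    )


def fake_run(K, traces):
    n = 3
    return AdmixtureRun(
        K=K, seed=0, burnin=0, sweeps=len(traces),
        Q=pd.DataFrame(np.full((n, K), 1.0 / K)),
        P=np.zeros((K, 1, 1)), allele_labels=[np.array([1])],
        loglik_trace=np.asarray(traces, dtype=float),
        alpha_trace=np.zeros(len(traces)), alpha_acceptance=0.0,
    )


def test_k1_gives_unit_ancestry():
    run = gibbs_fit(tiny_matrix(), K=1, burnin=10, sweeps=20, seed=0,
                    alpha_policy="fixed")
    np.testing.assert_allclose(run.q_matrix, 1.0)
    # P rows are simplexes over the observed alleles
    np.testing.assert_allclose(run.P.sum(axis=2), 1.0, atol=1e-9)


def test_posterior_q_rows_are_simplex():
    run = gibbs_fit(tiny_matrix(), K=3, burnin=20, sweeps=30, seed=1)
    np.testing.assert_allclose(run.q_matrix.sum(axis=1), 1.0, atol=1e-9)
    assert (run.q_matrix >= 0).all()
    assert 0 < run.alpha_trace[-1] < 10


def test_ln_prob_data_examples():
    assert ln_prob_data(fake_run(2, [-50.0, -50.0, -50.0])) == -50.0
    assert ln_prob_data(fake_run(2, [-100.0, -102.0])) == pytest.approx(-102.0)
    with pytest.raises(ValueError):
        ln_prob_data(fake_run(2, [-100.0]))


def test_evanno_arithmetic_example():
    """Means (-5000, -4500, -4400, -4390) with SD(K=2)=10 give DeltaK(2)=40."""
    runs = []
    for K, mean in zip(range(1, 5), (-5000.0, -4500.0, -4400.0, -4390.0)):
        for off in (-10.0, 0.0, 10.0):  # SD over 3 replicates = 10
            runs.append(fake_run(K, [mean + off] * 2))
    table = evanno_delta_k(runs)
    assert table.loc[2, "lprime"] == pytest.approx(500.0)
    assert table.loc[2, "lsecond_abs"] == pytest.approx(400.0)
    assert table.loc[2, "delta_k"] == pytest.approx(40.0)
    assert np.isnan(table.loc[1, "delta_k"]) and np.isnan(table.loc[4, "delta_k"])
    assert best_k(table) == 2


def test_evanno_linear_means_give_zero_delta_k():
    runs = []
    for K, mean in zip(range(1, 4), (-300.0, -200.0, -100.0)):
        for off in (-1.0, 1.0):
            runs.append(fake_run(K, [mean + off] * 2))
    table = evanno_delta_k(runs)
    assert table.loc[2, "delta_k"] == pytest.approx(0.0)


def test_evanno_requires_consecutive_k():
    runs = [fake_run(K, [-10.0, -11.0]) for K in (1, 3, 4)]
    with pytest.raises(ValueError, match="consecutive"):
        evanno_delta_k(runs)


def test_cluster_composition_rows_sum_to_100():
    G = tiny_matrix()
    run = gibbs_fit(G, K=2, burnin=20, sweeps=30, seed=2, alpha_policy="fixed")
    comp = cluster_composition(run, G, "pop")
    np.testing.assert_allclose(comp.sum(axis=1), 100.0)
    assert list(comp.index) == ["a", "b"]


def test_one_dominant_cluster_yields_single_100_column():
    G = tiny_matrix()
    run = gibbs_fit(G, K=2, burnin=20, sweeps=30, seed=3, alpha_policy="fixed")
    Q = run.Q.copy()
    Q.iloc[:, 0] = 0.9
    Q.iloc[:, 1] = 0.1
    run.Q = Q
    comp = cluster_composition(run, G, "pop")
    np.testing.assert_allclose(comp["cluster1"], 100.0)
    np.testing.assert_allclose(comp["cluster2"], 0.0)


def test_summaries_invariant_to_cluster_relabeling():
    G = tiny_matrix()
    run = gibbs_fit(G, K=3, burnin=30, sweeps=50, seed=4, alpha_policy="fixed")
    swapped = AdmixtureRun(
        K=run.K, seed=run.seed, burnin=run.burnin, sweeps=run.sweeps,
        Q=run.Q.iloc[:, [2, 0, 1]].set_axis(run.Q.columns, axis=1),
        P=run.P[[2, 0, 1]], allele_labels=run.allele_labels,
        loglik_trace=run.loglik_trace, alpha_trace=run.alpha_trace,
        alpha_acceptance=run.alpha_acceptance,
    )
    assert ln_prob_data(swapped) == ln_prob_data(run)
    a = cluster_composition(run, G, "pop").to_numpy()
    b = cluster_composition(swapped, G, "pop").to_numpy()
    assert sorted(map(tuple, a.T)) == sorted(map(tuple, b.T))


def test_posterior_q_tracks_truth_on_strong_signal():
    G, truth = make_fixture("two-pop-differentiated", seed=6)
    run = gibbs_fit(G, K=2, burnin=150, sweeps=250, seed=7, alpha_policy="fixed",
                    alpha=0.1)
    q1 = run.q_matrix[:, 0]
    true1 = truth.admixture[:, 0]
    r = abs(np.corrcoef(q1, true1)[0, 1])
    assert r >= 0.9


def test_invalid_arguments():
    with pytest.raises(ValueError, match="alpha_policy"):
        gibbs_fit(tiny_matrix(), K=2, burnin=5, sweeps=5, alpha_policy="bogus")
    with pytest.raises(ValueError):
        gibbs_fit(tiny_matrix(), K=0, burnin=5, sweeps=5)
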