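import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from ssrpopgen.admixture import (
    StructureAdmixture,
    align_runs,
    evanno_delta_k,
    membership_report,
    run_admixture,
)
from ssrpopgen.io import structure_matrix
from ssrpopgen.simulate import SimConfig, simulate


def two_pop_data(seed=11, fst=0.3, n_per_pop=20, n_loci=20):
    cfg = SimConfig(
        n_pops=2, n_per_pop=n_per_pop, n_loci=n_loci, target_fst=fst,
        inbreeding_f=0.0, missing_rate=0.02, alleles_per_locus=(4, 8), seed=seed,
    )
    g, truth = simulate(cfg)
    return structure_matrix(g)[0], truth


def accuracy(labels, true_pops, K):
    C = np.zeros((K, K))
    for a, b in zip(labels, true_pops):
        C[a, b] += 1
    r, c = linear_sum_assignment(-C)
    return C[r, c].sum() / len(labels)


class TestSampler:
    def test_k1_degenerate(self):
        X, _ = two_pop_data(seed=1)
        run = run_admixture(X, K=1, burn_in=100, iterations=1000, seed=0)
        assert np.allclose(run.Q_, 1.0)
        # lnPD tracks the pooled multinomial log-likelihood: posterior draws
        # of P sit below the MLE by O(free parameters / 2), so lnPD must lie
        # in [MLE - 2 * n_params, MLE]
        lnl_hat = 0.0
        n_params = 0
        n, two_l = X.shape
        for j in range(two_l // 2):
            copies = X[:, 2 * j : 2 * j + 2].ravel()
            copies = copies[copies >= 0]
            counts = np.bincount(copies)
            p = counts / counts.sum()
            lnl_hat += float((counts[counts > 0] * np.log(p[counts > 0])).sum())
            n_params += int((counts > 0).sum()) - 1
        assert lnl_hat - 2 * n_params <= run.lnPD_ <= lnl_hat

    def test_two_pop_recovery(self):
        X, truth = two_pop_data(seed=11)
        run = run_admixture(X, K=2, burn_in=500, iterations=4000, seed=3)
        assert run.Q_.max(axis=1).mean() >= 0.9
        assert accuracy(run.labels_, truth.pop_of_individual, 2) >= 0.95

    def test_simplex_validity(self):
        X, _ = two_pop_data(seed=7, n_per_pop=10, n_loci=8)
        run = run_admixture(X, K=3, burn_in=100, iterations=600, seed=1)
        assert np.allclose(run.Q_.sum(axis=1), 1.0, atol=1e-9)
        sums = run.P_.sum(axis=2)
        for l, na in enumerate(run.n_alleles_):
            assert np.allclose(sums[:, l], 1.0, atol=1e-9)
            assert np.all(run.P_[:, l, na:] == 0.0)

    def test_duplicated_individual_gets_same_ancestry(self):
        X, _ = two_pop_data(seed=5)
        X2 = np.vstack([X, X[:1]])
        run = run_admixture(X2, K=2, burn_in=500, iterations=4000, seed=2)
        assert np.allclose(run.Q_[0], run.Q_[-1], atol=0.05)

    def test_parameter_validation(self):
        X, _ = two_pop_data(seed=1, n_per_pop=3, n_loci=4)
        with pytest.raises(ValueError, match="exceeds"):
            run_admixture(X, K=100, burn_in=10, iterations=20)
        with pytest.raises(ValueError):
            StructureAdmixture(n_clusters=0).fit(X)

    def test_sklearn_params_round_trip(self):
        est = StructureAdmixture(n_clusters=4, n_iter=123)
        params = est.get_params()
        assert params["n_clusters"] == 4
        est.set_params(n_clusters=2)
        assert est.n_clusters == 2


class TestAlignment:
    def test_label_swap_realigned(self):
        X, _ = two_pop_data(seed=11, n_per_pop=10, n_loci=10)
        r1 = run_admixture(X, K=2, burn_in=100, iterations=800, seed=4)
        r2 = run_admixture(X, K=2, burn_in=100, iterations=800, seed=4)
        r2.Q_ = r2.Q_[:, ::-1]
        r2.P_ = r2.P_[::-1]
        a1, a2 = align_runs([r1, r2])
        assert np.allclose(a1.Q_, a2.Q_)

    def test_k1_noop(self):
        X, _ = two_pop_data(seed=2, n_per_pop=5, n_loci=6)
        r = run_admixture(X, K=1, burn_in=50, iterations=300, seed=1)
        (a,) = align_runs([r])
        assert np.allclose(a.Q_, r.Q_)

    def test_mixed_k_rejected(self):
        X, _ = two_pop_data(seed=2, n_per_pop=5, n_loci=6)
        r1 = run_admixture(X, K=1, burn_in=50, iterations=300, seed=1)
        r2 = run_admixture(X, K=2, burn_in=50, iterations=300, seed=1)
        with pytest.raises(ValueError, match="share K"):
            align_runs([r1, r2])

    def test_alignment_reduces_disagreement(self):
        X, _ = two_pop_data(seed=11)
        runs = [
            run_admixture(X, K=2, burn_in=300, iterations=2000, seed=s)
            for s in (1, 2, 3)
        ]
        def dist(rs):
            return sum(
                np.abs(a.Q_ - b.Q_).mean()
                for i, a in enumerate(rs)
                for b in rs[i + 1 :]
            )
        aligned = align_runs(runs)
        assert dist(aligned) <= dist(runs) + 1e-12


def fake_run(lnpd):
    r = StructureAdmixture(n_clusters=1)
    r.lnPD_ = lnpd
    return r


class TestEvanno:
    def test_hand_built_table(self):
        # lnPD means {-100, -50, -45, -44} with replicate sd 1
        a = 1 / np.sqrt(2)
        runs = {
            k + 1: [fake_run(v - a), fake_run(v + a)]
            for k, v in enumerate([-100.0, -50.0, -45.0, -44.0])
        }
        df = evanno_delta_k(runs)
        assert df.loc[2, "deltaK"] == pytest.approx(45.0, rel=1e-9)
        assert np.isnan(df.loc[1, "deltaK"]) and np.isnan(df.loc[4, "deltaK"])

    def test_linear_lnpd_gives_zero(self):
        runs = {
            k: [fake_run(-100.0 + 10 * k + d) for d in (-0.5, 0.5)]
            for k in range(1, 5)
        }
        df = evanno_delta_k(runs)
        assert df.loc[2, "deltaK"] == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(0)
        vals = {k: rng.normal(-1000 + 50 * k, 5, size=3) for k in range(1, 6)}
        df1 = evanno_delta_k({k: [fake_run(x) for x in v] for k, v in vals.items()})
        df2 = evanno_delta_k(
            {k: [fake_run(x + 777.0) for x in v] for k, v in vals.items()}
        )
        assert np.allclose(
            df1["deltaK"].dropna().values, df2["deltaK"].dropna().values
        )

    def test_requires_consecutive_ks_and_replicates(self):
        runs = {1: [fake_run(0), fake_run(1)], 3: [fake_run(0), fake_run(1)]}
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k(runs)


class TestMembershipReport:
    def test_identity_q(self):
        r = StructureAdmixture(n_clusters=2)
        r.Q_ = np.eye(2)[[0, 0, 1, 1]]
        rep = membership_report(r, {"A": [0, 1], "B": [2, 3]}, threshold=0.9)
        assert rep["n_above_threshold"] == 4
        assert rep["groups"]["A"]["mean_membership"] == 1.0
        assert rep["admixed_individuals"] == []

    def test_admixed_flagged(self):
        r = StructureAdmixture(n_clusters=2)
        r.Q_ = np.array([[0.5, 0.5], [0.95, 0.05]])
        rep = membership_report(r, {"A": [0, 1]}, threshold=0.9)
        assert rep["admixed_individuals"] == [0]

    def test_counts_match_direct_thresholding(self):
        X, truth = two_pop_data(seed=13)
        run = run_admixture(X, K=2, burn_in=300, iterations=2000, seed=5)
        grouping = {"P1": np.flatnonzero(truth.pop_of_individual == 0),
                    "P2": np.flatnonzero(truth.pop_of_individual == 1)}
        rep = membership_report(run, grouping, threshold=0.9)
        assert rep["n_above_threshold"] == int((run.Q_.max(axis=1) > 0.9).sum())


class TestConvergence:
    def test_likelihood_rises_to_plateau(self):
        """The data log-likelihood improves from early burn-in to the end."""
        X, _ = two_pop_data(seed=21)
        run = run_admixture(X, K=2, burn_in=0, iterations=4000, seed=9)
        trace = run.loglik_trace_
        q = len(trace) // 4
        assert trace[:q].mean() < trace[-q:].mean()
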