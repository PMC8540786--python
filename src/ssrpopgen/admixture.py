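"""Bayesian model-based clustering of multilocus genotypes (admixture model).

The model follows the classic admixture formulation: each of the ``2L``
allele copies of an individual has a latent cluster of origin ``Z``; cluster
``k`` carries per-locus allele frequencies ``P[k, l] ~ Dirichlet(lambda)``;
individual ancestry proportions ``Q[i] ~ Dirichlet(alpha, ..., alpha)`` with
a single symmetric ``alpha`` updated by a Metropolis step under a uniform
prior on ``(0, alpha_max]``. Inference is by Gibbs sampling:

* ``Z | P, Q``: each copy is assigned cluster ``k`` with probability
  proportional to ``Q[i, k] * P[k, l, a]``;
* ``P | Z``: Dirichlet with counts of copies assigned per (cluster, locus,
  allele);
* ``Q | Z``: Dirichlet with per-individual assignment counts.

Missing copies carry no information and are skipped. The data
log-likelihood ``ln P(X | P, Q)`` is recorded on the thinned trace, and the
model evidence is approximated by the usual harmonic-variance estimator
``lnPD = mean(lnL) - var(lnL) / 2`` over the post-burn-in trace. The number
of clusters is chosen over replicate runs with the Evanno delta-K statistic
(second-order rate of change of lnPD across K, normalized by the replicate
standard deviation).

The sampler is exposed as a scikit-learn style estimator operating on the
integer-coded genotype matrix produced by
:func:`ssrpopgen.io.structure_matrix` (shape ``(n, 2L)``, missing ``-9``).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import STRUCTURE_MISSING, GenotypeTable, structure_matrix

__all__ = [
    "StructureAdmixture",
    "run_admixture",
    "align_runs",
    "evanno_delta_k",
    "membership_report",
]


class StructureAdmixture(BaseEstimator):
    """STRUCTURE-style admixture model fitted by Gibbs sampling.

    Parameters
    ----------
    n_clusters:
        Number of ancestral clusters K.
    n_burnin, n_iter:
        Burn-in sweeps discarded before recording, and post-burn-in sweeps.
        The published protocol this mirrors used ``2e5`` / ``1e6``; the
        defaults here are scaled down for desk-scale data.
    thin:
        Record every ``thin``-th sweep.
    alpha_init, alpha_max, alpha_proposal_sd:
        Initial value, uniform-prior upper bound and Metropolis proposal
        standard deviation for the ancestry concentration ``alpha``.
    freq_lambda:
        Dirichlet hyperparameter for cluster allele frequencies.
    random_state:
        Seed for the sampler.

    Attributes
    ----------
    Q_ : ndarray of shape (n, K)
        Posterior-mean ancestry proportions (rows sum to 1).
    P_ : ndarray of shape (K, L, A_max)
        Posterior-mean cluster allele frequencies (simplex per (k, l) over
        each locus's observed alleles).
    labels_ : ndarray of shape (n,)
        Modal-cluster assignment (argmax of ``Q_``).
    loglik_trace_ : ndarray
        Data log-likelihood at every recorded sweep (burn-in included).
    lnPD_ : float
        ``mean - var/2`` evidence approximation over post-burn-in records.
    alpha_ : float
        Posterior-mean ancestry concentration.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_burnin: int = 2_000,
        n_iter: int = 20_000,
        thin: int = 10,
        alpha_init: float = 1.0,
        alpha_max: float = 10.0,
        alpha_proposal_sd: float = 0.05,
        freq_lambda: float = 1.0,
        random_state: int | None = None,
    ) -> None:
        self.n_clusters = n_clusters
        self.n_burnin = n_burnin
        self.n_iter = n_iter
        self.thin = thin
        self.alpha_init = alpha_init
        self.alpha_max = alpha_max
        self.alpha_proposal_sd = alpha_proposal_sd
        self.freq_lambda = freq_lambda
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _flatten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, np.ndarray]:
        """Non-missing copy arrays (individual, locus, allele) + locus sizes."""
        X = np.asarray(X, dtype=np.int64)
        if X.ndim != 2 or X.shape[1] % 2:
            raise ValueError("X must have shape (n, 2 * n_loci)")
        n, two_l = X.shape
        L = two_l // 2
        codes = X.reshape(n, L, 2)
        n_alleles = np.zeros(L, dtype=int)
        for l in range(L):
            vals = codes[:, l, :]
            vals = vals[vals != STRUCTURE_MISSING]
            if vals.size == 0:
                raise ValueError(f"locus {l} entirely missing")
            if vals.min() < 0:
                raise ValueError("allele codes must be >= 0 or -9 for missing")
            n_alleles[l] = vals.max() + 1
        ind, loc, copy = np.where(codes != STRUCTURE_MISSING)
        allele = codes[ind, loc, copy]
        return ind, loc, allele, L, n_alleles

    def fit(self, X, y=None) -> "StructureAdmixture":
        """Run the Gibbs sampler on an integer-coded genotype matrix."""
        K = int(self.n_clusters)
        if K < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_burnin < 0 or self.n_iter <= 0:
            raise ValueError("need n_iter > 0 and n_burnin >= 0")
        ind, loc, allele, L, n_alleles = self._flatten(X)
        n = np.asarray(X).shape[0]
        if K > n:
            raise ValueError(f"n_clusters={K} exceeds {n} individuals")
        rng = np.random.default_rng(self.random_state)
        A = int(n_alleles.max())
        valid = np.zeros((L, A), dtype=bool)
        for l in range(L):
            valid[l, : n_alleles[l]] = True
        # Dirichlet base shapes: lambda on valid allele slots, 0 elsewhere
        # (a Gamma(0) draw is exactly 0, keeping invalid slots at zero mass).
        p_base = np.where(valid, self.freq_lambda, 0.0)

        C = ind.size
        z = rng.integers(0, K, size=C)
        alpha = float(self.alpha_init)

        total = self.n_burnin + self.n_iter
        q_sum = np.zeros((n, K))
        p_sum = np.zeros((K, L, A))
        n_rec = 0
        trace: list[float] = []
        trace_iter: list[int] = []
        post_lnl: list[float] = []
        alpha_sum = 0.0

        flat_la = loc * A + allele  # per-copy index into (L*A) frequency slabs

        for sweep in range(total):
            # P | Z
            counts_p = np.zeros((K, L * A))
            np.add.at(counts_p, (z, flat_la), 1.0)
            gam = rng.standard_gamma(p_base[None, :, :] + counts_p.reshape(K, L, A))
            P = gam / gam.sum(axis=2, keepdims=True)

            # Q | Z
            counts_q = np.zeros((n, K))
            np.add.at(counts_q, (ind, z), 1.0)
            # tiny floor keeps rows valid when a Gamma(alpha) draw underflows
            gq = rng.standard_gamma(alpha + counts_q) + 1e-300
            Q = gq / gq.sum(axis=1, keepdims=True)

            # Z | P, Q
            W = Q[ind, :] * P.reshape(K, L * A)[:, flat_la].T  # (C, K)
            rowsum = W.sum(axis=1)
            cum = np.cumsum(W, axis=1)
            u = rng.random(C) * rowsum
            z = (cum < u[:, None]).sum(axis=1)

            # alpha | Q (Metropolis, symmetric Dirichlet likelihood)
            if K > 1:
                prop = alpha + rng.normal(0.0, self.alpha_proposal_sd)
                if 0.0 < prop <= self.alpha_max:
                    logq = float(np.log(np.clip(Q, 1e-300, None)).sum())
                    def _ll(a: float) -> float:
                        return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * logq
                    if np.log(rng.random()) < _ll(prop) - _ll(alpha):
                        alpha = prop

            if sweep % self.thin == 0:
                lnl = float(np.log(rowsum).sum())
                trace.append(lnl)
                trace_iter.append(sweep)
                if sweep >= self.n_burnin:
                    post_lnl.append(lnl)
                    q_sum += Q
                    p_sum += P
                    alpha_sum += alpha
                    n_rec += 1

        if n_rec == 0:
            raise RuntimeError("no post-burn-in samples recorded; increase n_iter")
        self.n_features_in_ = 2 * L
        self.n_alleles_ = n_alleles
        self.Q_ = q_sum / n_rec
        self.Q_ /= self.Q_.sum(axis=1, keepdims=True)
        P_mean = p_sum / n_rec
        with np.errstate(invalid="ignore"):
            P_mean /= P_mean.sum(axis=2, keepdims=True)
        self.P_ = np.nan_to_num(P_mean)
        self.labels_ = self.Q_.argmax(axis=1)
        self.alpha_ = alpha_sum / n_rec
        self.loglik_trace_ = np.asarray(trace)
        self.loglik_iters_ = np.asarray(trace_iter)
        post = np.asarray(post_lnl)
        self.lnPD_ = float(post.mean() - post.var(ddof=1) / 2.0) if post.size > 1 else float(post.mean())
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    # convenience accessors matching the replicate-run bookkeeping ----------

    @property
    def K(self) -> int:
        return self.n_clusters

    def membership(self) -> np.ndarray:
        check_is_fitted(self, "Q_")
        return self.Q_


def run_admixture(
    g: GenotypeTable | np.ndarray,
    K: int,
    burn_in: int = 2_000,
    iterations: int = 20_000,
    seed: int | None = None,
    **kwargs,
) -> StructureAdmixture:
    """Fit one admixture run on a genotype table (thin wrapper)."""
    X = structure_matrix(g)[0] if isinstance(g, GenotypeTable) else np.asarray(g)
    model = StructureAdmixture(
        n_clusters=K,
        n_burnin=burn_in,
        n_iter=iterations,
        random_state=seed,
        **kwargs,
    )
    return model.fit(X)


def align_runs(runs: Sequence[StructureAdmixture]) -> list[StructureAdmixture]:
    """Resolve label switching across replicate runs of the same K.

    Cluster labels of every run are permuted to maximize Q-matrix agreement
    with the first run (optimal assignment on the Q-column correlation
    cost). Returns shallow copies with permuted ``Q_``, ``P_``, ``labels_``.
    """
    if not runs:
        return []
    K = runs[0].n_clusters
    if any(r.n_clusters != K for r in runs):
        raise ValueError("all runs must share K")
    ref = runs[0].Q_
    aligned = []
    for r in runs:
        cost = -ref.T @ r.Q_  # (K, K); minimize = maximize agreement
        _, perm = linear_sum_assignment(cost)
        out = StructureAdmixture(**r.get_params())
        for attr in (
            "n_features_in_",
            "n_alleles_",
            "alpha_",
            "loglik_trace_",
            "loglik_iters_",
            "lnPD_",
        ):
            setattr(out, attr, getattr(r, attr))
        out.Q_ = r.Q_[:, perm]
        out.P_ = r.P_[perm]
        out.labels_ = out.Q_.argmax(axis=1)
        aligned.append(out)
    return aligned


def evanno_delta_k(runs_by_k: Mapping[int, Sequence[StructureAdmixture]]) -> pd.DataFrame:
    """Evanno delta-K table from replicate runs grouped by K.

    ``deltaK(K) = mean_r |lnPD_r(K+1) - 2 lnPD_r(K) + lnPD_r(K-1)| /
    sd(lnPD(K))``; defined only for interior K with replicate sd > 0 and
    with the same replicate count at K-1, K, K+1 (replicates are paired by
    index). Requires >= 3 consecutive K values with >= 2 replicates each.
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(runs_by_k[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    lnpd = {k: np.asarray([r.lnPD_ for r in runs_by_k[k]]) for k in ks}
    rows = []
    for k in ks:
        vals = lnpd[k]
        row: dict[str, float] = {
            "K": k,
            "mean_lnPD": float(vals.mean()),
            "sd_lnPD": float(vals.std(ddof=1)),
            "Lprime": float("nan"),
            "Lsecond": float("nan"),
            "deltaK": float("nan"),
        }
        if k - 1 in lnpd:
            row["Lprime"] = float((lnpd[k] - lnpd[k - 1]).mean())
        if k - 1 in lnpd and k + 1 in lnpd:
            m = min(len(lnpd[k - 1]), len(lnpd[k]), len(lnpd[k + 1]))
            second = np.abs(lnpd[k + 1][:m] - 2 * lnpd[k][:m] + lnpd[k - 1][:m])
            row["Lsecond"] = float(second.mean())
            sd = row["sd_lnPD"]
            row["deltaK"] = float(second.mean() / sd) if sd > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("K")


def membership_report(
    run: StructureAdmixture,
    grouping: Mapping[str, np.ndarray],
    threshold: float = 0.9,
) -> dict:
    """Ancestry-membership summary against a grouping of individuals.

    Per group: modal cluster (most common argmax), mean membership in that
    cluster, and the count of individuals whose maximum membership exceeds
    ``threshold``; plus the global list of admixed individuals (max
    membership below threshold).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    Q = run.Q_
    qmax = Q.max(axis=1)
    per_group = {}
    for label, idx in grouping.items():
        idx = np.asarray(idx, dtype=int)
        modal = int(np.bincount(Q[idx].argmax(axis=1), minlength=Q.shape[1]).argmax())
        per_group[label] = {
            "modal_cluster": modal,
            "mean_membership": float(Q[idx, modal].mean()),
            "n_above_threshold": int((qmax[idx] > threshold).sum()),
            "n": int(idx.size),
        }
    return {
        "groups": per_group,
        "n_above_threshold": int((qmax > threshold).sum()),
        "admixed_individuals": np.flatnonzero(qmax <= threshold).tolist(),
    }
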