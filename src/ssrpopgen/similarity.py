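"""Band-sharing similarity, UPGMA clustering with bootstrap, and PCoA.

Similarity between two individuals is computed over the bands of loci typed
in *both* individuals (pairwise deletion). With ``a`` = shared presences,
``b``/``c`` = one-sided presences and ``d`` = shared absences:

* simple matching ``(a + d) / (a + b + c + d)`` — used for the genetic
  similarity summaries;
* Dice ``2a / (2a + b + c)`` — used for the UPGMA dendrogram.

The dendrogram is average-linkage (UPGMA) agglomerative clustering on
``D = 1 - S``; node heights are ultrametric leaf depths (half the merge
distance). Bootstrap support resamples loci (not bands) with replacement,
keeping each locus's bands together, and reports the percentage of
replicate trees containing each original clade. Ordination is classical
metric multidimensional scaling (PCoA: Gower double-centering of
``-D^2 / 2`` and eigendecomposition), with negative eigenvalues reported
and never silently retained as axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import BandMatrix, GenotypeTable, to_band_matrix

__all__ = [
    "SimilarityMatrix",
    "Dendrogram",
    "PCoAResult",
    "similarity_matrix",
    "group_similarity_summary",
    "upgma",
    "bootstrap_supports",
    "pcoa",
]

COEFFICIENTS = ("simple_matching", "dice")


@dataclass
class SimilarityMatrix:
    """Square symmetric band-sharing similarity with unit diagonal."""

    labels: list[str]
    S: np.ndarray
    coefficient: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.6f")


@dataclass
class PCoAResult:
    """Principal-coordinate embedding with its eigenvalue spectrum."""

    coordinates: pd.DataFrame  # individuals x retained axes
    eigenvalues: np.ndarray  # full spectrum, descending
    proportion_explained: np.ndarray


def _locus_contributions(
    band: BandMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus pairwise counts for additive similarity assembly.

    Returns ``(A, ONES, NB, M)``: ``A[l]`` the shared-presence matrix of
    locus ``l``'s bands, ``ONES[l, i]`` the band count of individual ``i``
    at ``l``, ``NB[l]`` the number of bands of ``l``, and ``M[l]`` the
    co-typed pair mask.
    """
    n = band.B.shape[0]
    loci = range(len(band.locus_names))
    A = np.zeros((len(band.locus_names), n, n))
    ONES = np.zeros((len(band.locus_names), n))
    NB = np.zeros(len(band.locus_names))
    M = np.zeros((len(band.locus_names), n, n), dtype=bool)
    for l in loci:
        cols = band.band_locus == l
        Bl = band.B[:, cols].astype(float)
        A[l] = Bl @ Bl.T
        ONES[l] = Bl.sum(axis=1)
        NB[l] = int(cols.sum())
        t = band.typed[:, l]
        M[l] = np.outer(t, t)
    return A, ONES, NB, M


def _assemble(
    A: np.ndarray,
    ONES: np.ndarray,
    NB: np.ndarray,
    M: np.ndarray,
    weights: np.ndarray,
    coefficient: str,
) -> np.ndarray:
    """Similarity matrix from per-locus counts with locus multiplicities."""
    w = weights[:, None, None] * M
    a = (w * A).sum(axis=0)
    ones_sum = np.einsum("l,lij,li->ij", weights, M, ONES)
    ones_sum = ones_sum + ones_sum.T
    bc = ones_sum - 2 * a
    total = np.einsum("l,lij->ij", weights * NB, M)
    no_cotyped = (weights[:, None, None] * M).sum(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        if coefficient == "simple_matching":
            d = total - (ones_sum - a)
            S = (a + d) / total
        elif coefficient == "dice":
            S = 2 * a / (2 * a + bc)
        else:
            raise ValueError(f"unknown coefficient {coefficient!r}")
    S[no_cotyped] = np.nan
    np.fill_diagonal(S, 1.0)
    return S


def similarity_matrix(
    b: BandMatrix | GenotypeTable, coefficient: str = "simple_matching"
) -> SimilarityMatrix:
    """Pairwise band-sharing similarity over co-typed loci.

    Pairs with no co-typed locus get NaN with a warning.
    """
    band = to_band_matrix(b) if isinstance(b, GenotypeTable) else b
    if band.B.shape[0] < 2:
        raise ValueError("need >= 2 individuals")
    A, ONES, NB, M = _locus_contributions(band)
    S = _assemble(A, ONES, NB, M, np.ones(len(band.locus_names)), coefficient)
    if np.isnan(S).any():
        warnings.warn(
            "some pairs share no co-typed locus; their similarity is NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return SimilarityMatrix(labels=list(band.labels), S=S, coefficient=coefficient)


def group_similarity_summary(
    S: SimilarityMatrix,
    grouping: Mapping[str, np.ndarray],
    band: BandMatrix | None = None,
    restrict_bands: bool = False,
) -> pd.DataFrame:
    """Per-group similarity summary: within-group mean and all-pair mean.

    ``SM`` is the mean over within-group pairs (NaN for singleton groups);
    ``MGS`` the mean over all pairs involving at least one group member,
    self-pairs excluded. With ``restrict_bands=True`` (requires ``band``)
    the within-group mean is recomputed on a band matrix restricted to
    bands observed inside the group — the convention under which
    within-group similarities are not inflated by absences of bands the
    group never shows.
    """
    rows = []
    n = S.S.shape[0]
    for label, idx in grouping.items():
        idx = np.asarray(idx, dtype=int)
        inside = np.zeros(n, dtype=bool)
        inside[idx] = True
        if idx.size < 2:
            sm_vals = np.array([])
        elif restrict_bands:
            if band is None:
                raise ValueError("restrict_bands=True requires the band matrix")
            sub = _restrict_band_matrix(band, idx)
            A, ONES, NB, M = _locus_contributions(sub)
            Sg = _assemble(A, ONES, NB, M, np.ones(len(sub.locus_names)), S.coefficient)
            iu = np.triu_indices(idx.size, k=1)
            sm_vals = Sg[iu]
        else:
            iu = np.triu_indices(idx.size, k=1)
            sm_vals = S.S[np.ix_(idx, idx)][iu]
        pair_mask = inside[:, None] | inside[None, :]
        np.fill_diagonal(pair_mask, False)
        iu_all = np.triu_indices(n, k=1)
        mgs_vals = S.S[iu_all][pair_mask[iu_all]]
        rows.append(
            {
                "group": label,
                "SM": float(np.nanmean(sm_vals)) if sm_vals.size else float("nan"),
                "SM_se": _safe_sem(sm_vals),
                "MGS": float(np.nanmean(mgs_vals)),
                "MGS_se": _safe_sem(mgs_vals),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def _safe_sem(values: np.ndarray) -> float:
    values = values[np.isfinite(values)] if values.size else values
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def _restrict_band_matrix(band: BandMatrix, idx: np.ndarray) -> BandMatrix:
    """Band matrix of a subset of individuals, columns re-restricted to
    bands observed in that subset."""
    B = band.B[idx]
    keep = B.sum(axis=0) > 0
    return BandMatrix(
        B=B[:, keep],
        bands=[band.bands[k] for k in np.flatnonzero(keep)],
        band_locus=band.band_locus[keep],
        typed=band.typed[idx],
        labels=[band.labels[i] for i in idx],
        locus_names=list(band.locus_names),
    )


# ---------------------------------------------------------------------------
# UPGMA + bootstrap
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Rooted ultrametric UPGMA tree with optional clade supports (%)."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix (merge heights = distances)
    root: TreeNode  # branch lengths on the half-distance (ultrametric) scale
    supports: dict[frozenset, float] | None = None

    def clades(self) -> set[frozenset]:
        """Non-trivial clades (internal nodes below the root)."""
        out: set[frozenset] = set()
        for node in self.root.non_tips(include_self=False):
            out.add(frozenset(tip.name for tip in node.tips()))
        return out

    def to_newick(self, path: str | Path | None = None) -> str:
        tree = self.root.copy()
        if self.supports is not None:
            for node in tree.non_tips(include_self=False):
                clade = frozenset(tip.name for tip in node.tips())
                sup = self.supports.get(clade)
                node.name = f"{sup:.1f}" if sup is not None else None
        nwk = str(tree).strip()
        if path is not None:
            Path(path).write_text(nwk + "\n")
        return nwk


def _tree_from_linkage(Z: np.ndarray, labels: list[str]) -> TreeNode:
    """scipy linkage -> skbio TreeNode with ultrametric heights ``dist/2``."""
    n = len(labels)
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=labels[i]), 0.0) for i in range(n)
    }
    for k, (i, j, dist, _) in enumerate(Z):
        h = dist / 2.0
        ci, hi = nodes.pop(int(i))
        cj, hj = nodes.pop(int(j))
        ci.length = h - hi
        cj.length = h - hj
        nodes[n + k] = (TreeNode(children=[ci, cj]), h)
    (root, _), = nodes.values()
    return root


def upgma(S: SimilarityMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering on ``D = 1 - S``."""
    D = 1.0 - S.S
    if np.isnan(D).any():
        raise ValueError(
            "similarity matrix has missing entries; subset individuals or impute"
        )
    Z = linkage(squareform(D, checks=False), method="average")
    return Dendrogram(
        labels=list(S.labels), linkage=Z, root=_tree_from_linkage(Z, list(S.labels))
    )


def bootstrap_supports(
    g: GenotypeTable,
    reps: int = 1000,
    seed: int | None = None,
    coefficient: str = "dice",
) -> Dendrogram:
    """UPGMA dendrogram with locus-bootstrap clade supports.

    Loci are resampled with replacement per replicate (a locus's bands stay
    together); the support of each original clade is the percentage of
    replicate trees containing it. Reproducible under a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    band = to_band_matrix(g)
    A, ONES, NB, M = _locus_contributions(band)
    L = len(band.locus_names)
    S0 = _assemble(A, ONES, NB, M, np.ones(L), coefficient)
    if np.isnan(S0).any():
        raise ValueError("pairs with no co-typed locus; cannot bootstrap")
    base = upgma(SimilarityMatrix(list(band.labels), S0, coefficient))
    target = base.clades()
    counts = {clade: 0 for clade in target}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        weights = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(float)
        Sb = _assemble(A, ONES, NB, M, weights, coefficient)
        if np.isnan(Sb).any():  # a pair co-typed at none of the drawn loci
            continue
        Zb = linkage(squareform(1.0 - Sb, checks=False), method="average")
        rep_tree = Dendrogram(
            labels=list(band.labels),
            linkage=Zb,
            root=_tree_from_linkage(Zb, list(band.labels)),
        )
        for clade in rep_tree.clades():
            if clade in counts:
                counts[clade] += 1
    base.supports = {c: 100.0 * k / reps for c, k in counts.items()}
    return base


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def pcoa(S: SimilarityMatrix, axes: int = 2) -> PCoAResult:
    """Principal coordinate analysis of ``D = 1 - S``.

    Gower double-centering of ``-D^2/2`` followed by eigendecomposition;
    eigenvalues are reported in full (negative ones included) and axes with
    non-positive eigenvalues are never retained — the result is truncated
    with a warning instead.
    """
    D = 1.0 - S.S
    if np.isnan(D).any():
        raise ValueError("similarity matrix has missing entries")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(
            DistanceMatrix(D, ids=S.labels), method="eigh", dimensions=0
        )
    eigvals = res.eigvals.values
    n_pos = int((eigvals > 1e-10).sum())
    if axes > n_pos:
        warnings.warn(
            f"only {n_pos} axes have positive eigenvalues; truncating from "
            f"{axes} to {n_pos}",
            RuntimeWarning,
            stacklevel=2,
        )
        axes = n_pos
    coords = res.samples.iloc[:, :axes].copy()
    coords.columns = [f"PCo{i + 1}" for i in range(axes)]
    coords.index = S.labels
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=res.proportion_explained.values,
    )
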