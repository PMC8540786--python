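"""Dominant-marker sex prediction and exact-test linkage disequilibrium.

The SCAR119 dominant band is a male-associated marker in dioecious hemp:
band present predicts a male plant, band absent a not-male plant (female or
monoecious, both karyologically XX). Concordance is scored on dioecious
individuals only, since monoecious plants have no male/female phenotype.

Linkage disequilibrium between locus pairs is tested with Fisher's exact
test on the genotypic contingency table: rows/columns are the observed
single-locus genotype classes (unordered allele pairs; the SCAR band is a
two-state dominant pseudo-locus), counted over individuals typed at both
loci. The p-value is the total probability, under fixed margins, of tables
no more probable than the observed one — enumerated exactly when the table
is small, otherwise estimated by Monte-Carlo sampling of fixed-margin
tables (Patefield's algorithm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import random_table

from .io import MISSING, GenotypeTable, IndividualMeta

__all__ = [
    "predict_sex",
    "ld_exact_test",
    "ld_matrix",
    "LDMatrix",
    "LDResult",
    "SCAR_LOCUS",
]

SCAR_LOCUS = "SCAR"


# ---------------------------------------------------------------------------
# Sex prediction
# ---------------------------------------------------------------------------


def predict_sex(g: GenotypeTable | list[IndividualMeta]) -> tuple[pd.DataFrame, float]:
    """Predict sex from the dominant SCAR band and score concordance.

    Returns a per-individual table (band state, prediction, phenotype,
    concordance flag) and the fraction of band-typed *dioecious* individuals
    whose prediction matches their phenotype. Untyped bands are excluded
    from the concordance denominator; a monoecious individual showing the
    band is flagged discordant (the band should be male-specific).
    """
    metas = g.individuals if isinstance(g, GenotypeTable) else list(g)
    rows = []
    agree = total = 0
    for m in metas:
        if m.scar_band == "untyped":
            predicted, concordant = "", None
        else:
            predicted = "male" if m.scar_band == "present" else "not-male"
            if m.sex_phenotype in ("male", "female"):
                ok = (predicted == "male") == (m.sex_phenotype == "male")
                concordant = ok
                total += 1
                agree += ok
            elif m.sex_phenotype == "monoecious":
                # band must be absent in monoecious (XX) plants
                concordant = predicted == "not-male"
            else:
                concordant = None
        rows.append(
            {
                "sample_id": m.sample_id,
                "scar_band": m.scar_band,
                "predicted": predicted,
                "phenotype": m.sex_phenotype,
                "concordant": concordant,
            }
        )
    concordance = agree / total if total else float("nan")
    return pd.DataFrame(rows), concordance


# ---------------------------------------------------------------------------
# Genotype-class codes
# ---------------------------------------------------------------------------


def _genotype_codes(g: GenotypeTable, locus: str) -> np.ndarray:
    """Per-individual genotype-class code at a locus (-1 = untyped).

    For an SSR locus, classes are the distinct observed unordered allele
    pairs; for :data:`SCAR_LOCUS`, the two dominant band states.
    """
    if locus == SCAR_LOCUS:
        states = {"absent": 0, "present": 1}
        return np.array(
            [states.get(m.scar_band, -1) for m in g.individuals], dtype=np.int64
        )
    j = g.locus_index(locus)
    calls = np.sort(g.alleles[:, j, :], axis=1)
    codes = np.full(g.n_individuals, -1, dtype=np.int64)
    typed = calls[:, 0] != MISSING
    if typed.any():
        _, inv = np.unique(calls[typed], axis=0, return_inverse=True)
        codes[typed] = inv
    return codes


def _contingency(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    both = (codes_a >= 0) & (codes_b >= 0)
    a, b = codes_a[both], codes_b[both]
    if a.size == 0:
        return np.zeros((0, 0), dtype=np.int64)
    _, a = np.unique(a, return_inverse=True)
    _, b = np.unique(b, return_inverse=True)
    table = np.zeros((a.max() + 1, b.max() + 1), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    return table


# ---------------------------------------------------------------------------
# Exact and Monte-Carlo r x c Fisher tests
# ---------------------------------------------------------------------------


class _TooManyTables(Exception):
    pass


def _table_count_bound(table: np.ndarray) -> float:
    """Cheap upper bound on the number of tables sharing the margins.

    All cells outside the last row/column are free up to their margin
    minimum; the rest are forced.
    """
    R = table.sum(axis=1)
    C = table.sum(axis=0)
    bound = 1.0
    for i in range(len(R) - 1):
        for j in range(len(C) - 1):
            bound *= min(R[i], C[j]) + 1
            if bound > 1e18:
                return bound
    return bound


def _exact_rxc(table: np.ndarray, max_tables: int) -> float:
    """Exact conditional p-value by depth-first enumeration of all tables
    with the observed margins; raises :class:`_TooManyTables` past the cap."""
    R = table.sum(axis=1)
    C = table.sum(axis=0)
    n = int(table.sum())
    const = gammaln(R + 1).sum() + gammaln(C + 1).sum() - gammaln(n + 1)
    logp_obs = const - gammaln(table + 1).sum()
    r, c = table.shape
    visited = 0
    total_p = 0.0

    def rec(row: int, col: int, row_rem: int, col_rem: np.ndarray, neg_lg: float):
        nonlocal visited, total_p
        if row == r - 1:
            # last row forced by column remainders
            visited += 1
            if visited > max_tables:
                raise _TooManyTables
            logp = const + neg_lg - gammaln(col_rem + 1).sum()
            if logp <= logp_obs + 1e-9:
                total_p += np.exp(logp)
            return
        if col == c - 1:
            v = row_rem
            if v > col_rem[col]:
                return
            col_rem2 = col_rem.copy()
            col_rem2[col] -= v
            rec(row + 1, 0, int(R[row + 1]), col_rem2, neg_lg - gammaln(v + 1))
            return
        # capacity of the remaining cells in this row
        cap_rest = int(col_rem[col + 1 :].sum())
        lo = max(0, row_rem - cap_rest)
        hi = min(row_rem, int(col_rem[col]))
        for v in range(lo, hi + 1):
            col_rem2 = col_rem.copy()
            col_rem2[col] -= v
            rec(row, col + 1, row_rem - v, col_rem2, neg_lg - gammaln(v + 1))

    rec(0, 0, int(R[0]), C.astype(np.int64).copy(), 0.0)
    return min(total_p, 1.0)


def _mc_rxc(
    table: np.ndarray, reps: int, rng: np.random.Generator, batch: int = 10_000
) -> float:
    """Monte-Carlo conditional p-value from fixed-margin table sampling."""
    R = table.sum(axis=1)
    C = table.sum(axis=0)
    stat_obs = gammaln(table + 1).sum()  # larger => less probable table
    dist = random_table(R, C)
    hits = 0
    done = 0
    while done < reps:
        m = min(batch, reps - done)
        sims = dist.rvs(size=m, random_state=rng)
        stats = gammaln(sims + 1).sum(axis=(1, 2))
        hits += int((stats >= stat_obs - 1e-9).sum())
        done += m
    return (1 + hits) / (reps + 1)


@dataclass
class LDResult:
    p_value: float
    method: str  # "exact", "monte_carlo" or "degenerate"
    table: np.ndarray
    n: int  # co-typed individuals


def ld_exact_test(
    g: GenotypeTable,
    locus_a: str,
    locus_b: str,
    mc_reps: int = 100_000,
    seed: int | None = None,
    max_exact: int = 1_000_000,
) -> LDResult:
    """Fisher's exact test of genotypic association between two loci.

    Exact enumeration is used when at most ``max_exact`` tables share the
    observed margins; beyond that a seeded Monte-Carlo estimate with
    ``mc_reps`` fixed-margin tables is returned. A degenerate table (fewer
    than two non-empty rows or columns) yields p = 1 with a warning.
    """
    codes_a = _genotype_codes(g, locus_a)
    codes_b = _genotype_codes(g, locus_b)
    table = _contingency(codes_a, codes_b)
    n = int(table.sum())
    if n < 2:
        raise ValueError(f"{locus_a} x {locus_b}: fewer than 2 co-typed individuals")
    if min(table.shape) < 2 or (table.sum(axis=1) > 0).sum() < 2 or (
        table.sum(axis=0) > 0
    ).sum() < 2:
        warnings.warn(
            f"{locus_a} x {locus_b}: degenerate table (a margin is zero); p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return LDResult(p_value=1.0, method="degenerate", table=table, n=n)
    try:
        if _table_count_bound(table) > max_exact:
            raise _TooManyTables
        p = _exact_rxc(table, max_exact)
        method = "exact"
    except _TooManyTables:
        rng = np.random.default_rng(seed)
        p = _mc_rxc(table, mc_reps, rng)
        method = "monte_carlo"
    return LDResult(p_value=float(p), method=method, table=table, n=n)


@dataclass
class LDMatrix:
    """Symmetric matrix of pairwise LD p-values with significance codes."""

    labels: list[str]
    P: np.ndarray  # NaN on the diagonal

    def stars(self, i: int, j: int) -> str:
        p = self.P[i, j]
        if not np.isfinite(p):
            return ""
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        return ""

    def bonferroni_adjusted(self) -> np.ndarray:
        """Optional family-wise adjustment: p * number of tests, capped at 1."""
        n_tests = np.isfinite(self.P).sum() // 2
        return np.clip(self.P * n_tests, 0.0, 1.0)

    def significant_partners(self, locus: str, alpha: float = 0.01) -> list[str]:
        i = self.labels.index(locus)
        return [
            self.labels[j]
            for j in range(len(self.labels))
            if j != i and np.isfinite(self.P[i, j]) and self.P[i, j] < alpha
        ]

    def to_csv(self, path: str | Path) -> None:
        """Lower triangle: p-values; upper triangle: significance stars."""
        n = len(self.labels)
        out = pd.DataFrame("", index=self.labels, columns=self.labels, dtype=object)
        for i in range(n):
            out.iat[i, i] = "x"
            for j in range(i):
                out.iat[i, j] = f"{self.P[i, j]:.3g}"
                out.iat[j, i] = self.stars(i, j)
        out.to_csv(path)


def ld_matrix(
    g: GenotypeTable,
    mc_reps: int = 100_000,
    seed: int | None = None,
    include_scar: bool = True,
    max_exact: int = 1_000_000,
) -> LDMatrix:
    """All pairwise genotypic LD tests (optionally including the SCAR band).

    Per-pair Monte-Carlo seeds are spawned deterministically from ``seed``,
    so results do not depend on evaluation order.
    """
    labels = ([SCAR_LOCUS] if include_scar else []) + g.locus_names
    n = len(labels)
    P = np.full((n, n), np.nan)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            res = ld_exact_test(
                g,
                labels[i],
                labels[j],
                mc_reps=mc_reps,
                seed=children[k],
                max_exact=max_exact,
            )
            P[i, j] = P[j, i] = res.p_value
            k += 1
    return LDMatrix(labels=labels, P=P)
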