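"""Per-group (variety / country / sex-system) diversity summaries.

Each group row aggregates the single-locus statistics over loci (mean and
standard error across loci), adds band-similarity summaries (within-group
simple matching and mean similarity against the whole collection), and a
group-specific F-statistic triple computed with the group as the single
subpopulation against the pooled collection: ``Hs`` = group expected
heterozygosity, ``Ht`` = total expected heterozygosity, ``Ho`` = group
observed heterozygosity. The ± values are standard errors over loci.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import diversity as dv
from .io import GenotypeTable, to_band_matrix

__all__ = [
    "proportion_polymorphic",
    "population_table",
    "variance_partition",
    "write_population_table",
]


def proportion_polymorphic(g: GenotypeTable, group=None) -> float:
    """Fraction of loci with >= 2 alleles observed within the group.

    Loci untyped in the group count as non-polymorphic.
    """
    idx = (
        np.arange(g.n_individuals) if group is None else np.asarray(group, dtype=int)
    )
    if idx.size == 0:
        raise ValueError("group is empty")
    n_poly = 0
    for locus in g.locus_names:
        try:
            f = dv.allele_frequencies(g, locus, idx, label="group")
        except dv.UntypedLocusError:
            continue
        if f.n_alleles >= 2:
            n_poly += 1
    return n_poly / g.n_loci


def _sem(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def _group_fstats(
    g: GenotypeTable, idx: np.ndarray, unbiased: bool = False
) -> tuple[float, float, float]:
    """Multi-locus (Fis, Fit, Fst) of one group against the pooled total.

    Per locus: Hs = group He, Ht = total He, Ho = group Ho; the multi-locus
    values are ratios of the across-locus means (more stable than averaging
    per-locus ratios and preserving (1-Fis)(1-Fst) = (1-Fit)).
    """
    hos, hss, hts = [], [], []
    for locus in g.locus_names:
        try:
            fg = dv.allele_frequencies(g, locus, idx, label="group")
            ft = dv.allele_frequencies(g, locus)
        except dv.UntypedLocusError:
            continue
        hos.append(dv.observed_heterozygosity(g, locus, idx))
        hss.append(dv.expected_heterozygosity(fg, unbiased=unbiased))
        hts.append(dv.expected_heterozygosity(ft, unbiased=unbiased))
    ho, hs, ht = float(np.mean(hos)), float(np.mean(hss)), float(np.mean(hts))
    if ht <= 0:
        return float("nan"), float("nan"), float("nan")
    fis = (hs - ho) / hs if hs > 0 else float("nan")
    return fis, (ht - ho) / ht, (ht - hs) / ht


def population_table(
    g: GenotypeTable,
    grouping: Mapping[str, np.ndarray] | str = "variety",
    restrict_bands: bool = True,
    unbiased: bool = False,
) -> pd.DataFrame:
    """Per-group descriptive statistics table.

    Columns: N, P (proportion polymorphic loci), I ± se (Shannon), SM ± se
    (% mean within-group simple-matching similarity), MGS ± se (% mean
    simple-matching similarity over all pairs involving the group), No ± se
    (mean observed alleles/locus), Ne ± se (effective alleles), Ho/He/Ha ±
    se, Fis, Fit, Fst (group vs pooled total) and Nm.

    ``restrict_bands=True`` computes the within-group SM on a band matrix
    restricted to the group's own bands (the study convention for the SM
    column); MGS always uses the global band set.
    """
    from .similarity import group_similarity_summary, similarity_matrix

    if isinstance(grouping, str):
        grouping = g.grouping(grouping)
    band = to_band_matrix(g)
    S = similarity_matrix(band, "simple_matching")
    sim = group_similarity_summary(
        S, grouping, band=band, restrict_bands=restrict_bands
    )

    rows = []
    for label, idx in grouping.items():
        idx = np.asarray(idx, dtype=int)
        per_locus: dict[str, list[float]] = {
            k: [] for k in ("I", "No", "Ne", "Ho", "He", "Ha")
        }
        for locus in g.locus_names:
            try:
                f = dv.allele_frequencies(g, locus, idx, label=label)
            except dv.UntypedLocusError:
                for k in per_locus:
                    per_locus[k].append(float("nan"))
                continue
            per_locus["I"].append(dv.shannon_index(f))
            per_locus["No"].append(f.n_alleles)
            per_locus["Ne"].append(dv.effective_alleles(f))
            per_locus["Ho"].append(dv.observed_heterozygosity(g, locus, idx))
            per_locus["He"].append(dv.expected_heterozygosity(f))
            per_locus["Ha"].append(
                dv.expected_heterozygosity(f, unbiased=True)
                if f.n_gene_copies >= 2
                else float("nan")
            )
        fis, fit, fst = _group_fstats(g, idx, unbiased=unbiased)
        row: dict[str, object] = {
            "group": label,
            "N": idx.size,
            "P": proportion_polymorphic(g, idx),
        }
        for k, vals in per_locus.items():
            arr = np.asarray(vals, dtype=float)
            row[k] = float(np.nanmean(arr))
            row[f"{k}_se"] = _sem(arr)
        row["SM"] = sim.loc[label, "SM"]
        row["SM_se"] = sim.loc[label, "SM_se"]
        row["MGS"] = sim.loc[label, "MGS"]
        row["MGS_se"] = sim.loc[label, "MGS_se"]
        row["Fis"], row["Fit"], row["Fst"] = fis, fit, fst
        row["Nm"] = dv.gene_flow(fst)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def variance_partition(
    g: GenotypeTable, grouping: Mapping[str, np.ndarray] | str = "variety"
) -> tuple[float, float]:
    """(percent among groups, percent within groups) from per-group Fst.

    The among-group fraction is the unweighted mean of the per-group
    fixation indices (each group against the pooled total); the within
    fraction is its complement. Both are returned as percentages.
    """
    if isinstance(grouping, str):
        grouping = g.grouping(grouping)
    if len(grouping) < 2:
        raise ValueError("need >= 2 groups")
    fsts = [
        _group_fstats(g, np.asarray(idx, dtype=int))[2] for idx in grouping.values()
    ]
    among = float(np.nanmean(fsts)) * 100.0
    return among, 100.0 - among


def write_population_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the per-group summary with ``value ± se`` formatting."""
    out = pd.DataFrame(index=df.index)
    out["N"] = df["N"]
    out["P"] = df["P"].map(lambda v: f"{v:.2f}")
    for col, scale in [
        ("I", 1), ("SM", 100), ("MGS", 100), ("No", 1), ("Ne", 1),
        ("Ho", 1), ("He", 1), ("Ha", 1),
    ]:
        out[col] = [
            f"{v * scale:.2f} ± {se * scale:.2f}"
            for v, se in zip(df[col], df[f"{col}_se"])
        ]
    for col in ("Fis", "Fit", "Fst", "Nm"):
        out[col] = df[col].map(lambda v: f"{v:.2f}")
    out.to_csv(path)
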