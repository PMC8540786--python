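"""Private-allele screening across grouping schemes.

An allele is *private* to a group when it reaches at least ``min_freq``
(default 5%) of the group's non-missing gene copies and has exactly zero
observed copies in every other group. Frequencies are gene-copy based: a
single heterozygous carrier in a group with ``n`` typed individuals has
frequency ``1 / (2 n)``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeTable

__all__ = ["find_private_alleles", "private_allele_summary"]


def _group_allele_counts(
    g: GenotypeTable, locus_idx: int, idx: np.ndarray
) -> tuple[dict[int, int], int]:
    calls = g.alleles[idx, locus_idx, :]
    copies = calls[calls != MISSING]
    sizes, counts = np.unique(copies, return_counts=True)
    return {int(s): int(c) for s, c in zip(sizes, counts)}, int(copies.size)


def find_private_alleles(
    g: GenotypeTable,
    grouping: Mapping[str, np.ndarray] | str,
    min_freq: float = 0.05,
    scheme: str | None = None,
) -> pd.DataFrame:
    """List alleles private to a single group.

    Returns a DataFrame with columns ``scheme, group, locus, allele,
    frequency`` — one row per (locus, allele) reaching ``min_freq`` in
    exactly one group and absent (zero copies) from all others.
    """
    if not 0.0 < min_freq <= 1.0:
        raise ValueError("min_freq must be in (0, 1]")
    if isinstance(grouping, str):
        scheme = scheme or grouping
        grouping = g.grouping(grouping)
    if len(grouping) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for j, locus in enumerate(g.locus_names):
        per_group = {
            label: _group_allele_counts(g, j, np.asarray(idx, dtype=int))
            for label, idx in grouping.items()
        }
        all_alleles = sorted({a for counts, _ in per_group.values() for a in counts})
        for allele in all_alleles:
            carriers = [label for label, (c, _) in per_group.items() if allele in c]
            if len(carriers) != 1:
                continue
            label = carriers[0]
            counts, n_copies = per_group[label]
            freq = counts[allele] / n_copies
            if freq >= min_freq:
                rows.append(
                    {
                        "scheme": scheme or "custom",
                        "group": label,
                        "locus": locus,
                        "allele": allele,
                        "frequency": freq,
                    }
                )
    return pd.DataFrame(rows, columns=["scheme", "group", "locus", "allele", "frequency"])


def private_allele_summary(
    records: pd.DataFrame,
    g: GenotypeTable,
    grouping: Mapping[str, np.ndarray] | str,
) -> pd.DataFrame:
    """Per-group rollup of a private-allele listing.

    Columns: number of private alleles, total distinct alleles observed in
    the group, min/max private frequency and the count with frequency
    <= 10%.
    """
    if isinstance(grouping, str):
        grouping = g.grouping(grouping)
    rows = []
    for label, idx in grouping.items():
        idx = np.asarray(idx, dtype=int)
        total_alleles = 0
        for j in range(g.n_loci):
            counts, _ = _group_allele_counts(g, j, idx)
            total_alleles += len(counts)
        sub = records[records["group"] == label]
        freqs = sub["frequency"].to_numpy()
        rows.append(
            {
                "group": label,
                "n_private": len(sub),
                "total_group_alleles": total_alleles,
                "min_freq": float(freqs.min()) if freqs.size else float("nan"),
                "max_freq": float(freqs.max()) if freqs.size else float("nan"),
                "n_freq_le_10pct": int((freqs <= 0.10).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("group")
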