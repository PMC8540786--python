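"""Synthetic SSR genotype generation with known population-genetic truth.

Two generators are provided:

* :func:`simulate` — a generic hierarchical generator: ancestral allele
  frequencies per locus are symmetric-Dirichlet; population frequencies
  follow the Balding–Nichols parameterization ``Dirichlet(p * (1 - F) / F)``
  so the differentiation target ``F`` (Fst) is an explicit, recoverable
  parameter; genotypes are drawn with probability ``inbreeding_f`` of
  autozygosity (both copies identical by descent) and independent draws
  otherwise. Optional null alleles (a designated allele that fails to
  amplify: heterozygous carriers look homozygous, null homozygotes look
  missing), missing data, admixed individuals and a dominant sex band fully
  linked to maleness complete the study-like structure.

* :func:`study_shaped_fixture` — a 104-individual, 20-locus dataset in the
  exact variety/country/sex layout of the hemp core collection, calibrated
  locus-by-locus to the published panel summary (allele count, top allele
  frequency, gene diversity, inbreeding and fixation index), with every
  calibrated allele guaranteed observed.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .io import GenotypeTable, IndividualMeta, MarkerDef
from .study import STUDY_LOCUS_CALIBRATION, STUDY_MARKERS, study_individuals

__all__ = ["SimConfig", "SimTruth", "simulate", "study_shaped_fixture"]


@dataclass
class SimConfig:
    """Configuration of the generic genotype generator."""

    n_pops: int = 8
    n_per_pop: int | Sequence[int] = 50
    n_loci: int = 100
    alleles_per_locus: tuple[int, int] = (3, 28)
    target_fst: float = 0.15
    inbreeding_f: float = 0.3
    missing_rate: float = 0.02
    null_allele_rate: float = 0.0
    sex_model: str | Sequence[str] = "dioecious"
    admixed: Sequence[tuple[int, Sequence[float]]] = ()
    seed: int | None = None

    def pop_sizes(self) -> list[int]:
        if isinstance(self.n_per_pop, int):
            return [self.n_per_pop] * self.n_pops
        sizes = list(self.n_per_pop)
        if len(sizes) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        return sizes

    def sex_models(self) -> list[str]:
        models = (
            [self.sex_model] * self.n_pops
            if isinstance(self.sex_model, str)
            else list(self.sex_model)
        )
        if len(models) != self.n_pops:
            raise ValueError("sex_model length must equal n_pops")
        for m in models:
            if m not in ("dioecious", "monoecious"):
                raise ValueError(f"unknown sex model {m!r}")
        return models

    def validate(self) -> None:
        lo, hi = self.alleles_per_locus
        if lo < 2 or hi < lo:
            raise ValueError("alleles_per_locus must satisfy 2 <= min <= max")
        for rate in (self.missing_rate, self.null_allele_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must be in [0, 1]")
        if self.n_pops < 1 or self.n_loci < 1:
            raise ValueError("need at least one population and one locus")


@dataclass
class SimTruth:
    """Generating parameters recorded alongside a simulated table."""

    target_fst: float
    inbreeding_f: float
    membership: np.ndarray  # (n, n_pops) mixing proportions
    pop_of_individual: np.ndarray  # modal source population
    allele_sizes: list[np.ndarray]  # per locus
    ancestral_freqs: list[np.ndarray]
    pop_freqs: list[np.ndarray]  # per locus, (n_pops, n_alleles)
    null_allele: list[int | None]  # per locus: null allele size or None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_fst": self.target_fst,
            "inbreeding_f": self.inbreeding_f,
            "membership": self.membership.tolist(),
            "pop_of_individual": self.pop_of_individual.tolist(),
            "allele_sizes": [a.tolist() for a in self.allele_sizes],
            "ancestral_freqs": [a.tolist() for a in self.ancestral_freqs],
            "pop_freqs": [a.tolist() for a in self.pop_freqs],
            "null_allele": self.null_allele,
        }
        Path(path).write_text(json.dumps(payload))


def _draw_genotypes(
    rng: np.random.Generator,
    membership: np.ndarray,  # (n, n_pops)
    pop_freqs: np.ndarray,  # (n_pops, n_alleles)
    inbreeding_f: float,
) -> np.ndarray:
    """Unordered allele-index pairs (n, 2) for one locus."""
    n = membership.shape[0]
    out = np.empty((n, 2), dtype=np.int64)
    n_alleles = pop_freqs.shape[1]
    for i in range(n):
        w = membership[i]
        if inbreeding_f > 0 and rng.random() < inbreeding_f:
            src = rng.choice(len(w), p=w)
            a = rng.choice(n_alleles, p=pop_freqs[src])
            out[i] = (a, a)
        else:
            for c in range(2):
                src = rng.choice(len(w), p=w)
                out[i, c] = rng.choice(n_alleles, p=pop_freqs[src])
    return out


def simulate(config: SimConfig, seed: int | None = None) -> tuple[GenotypeTable, SimTruth]:
    """Generate a genotype table under a known hierarchical model.

    ``seed`` overrides ``config.seed`` when given. Returns the table and a
    :class:`SimTruth` record of the generating parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.pop_sizes()
    sex_models = config.sex_models()
    n = sum(sizes)
    P = config.n_pops

    pop_of = np.repeat(np.arange(P), sizes)
    membership = np.zeros((n, P))
    membership[np.arange(n), pop_of] = 1.0
    for i, props in config.admixed:
        props = np.asarray(props, dtype=float)
        if props.size != P or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError(f"admixed proportions for individual {i} invalid")
        membership[i] = props

    lo, hi = config.alleles_per_locus
    loci: list[MarkerDef] = []
    allele_sizes: list[np.ndarray] = []
    anc_freqs: list[np.ndarray] = []
    pop_freqs: list[np.ndarray] = []
    null_allele: list[int | None] = []
    F = config.target_fst
    for l in range(config.n_loci):
        n_alleles = int(rng.integers(lo, hi + 1))
        motif_len = int(rng.choice([2, 3]))
        base = int(rng.integers(80, 320))
        sizes_l = base + motif_len * np.arange(n_alleles)
        anc = rng.dirichlet(np.ones(n_alleles))
        if config.null_allele_rate > 0:
            # designate the last allele as non-amplifying at the target rate
            anc[-1] = config.null_allele_rate
            anc[:-1] *= (1.0 - config.null_allele_rate) / anc[:-1].sum()
            null_allele.append(int(sizes_l[-1]))
        else:
            null_allele.append(None)
        if F > 0:
            pf = rng.dirichlet(np.maximum(anc, 1e-9) * (1.0 - F) / F, size=P)
        else:
            pf = np.tile(anc, (P, 1))
        loci.append(MarkerDef(name=f"LOC{l + 1}", motif=f"(CT){n_alleles}"))
        allele_sizes.append(sizes_l)
        anc_freqs.append(anc)
        pop_freqs.append(pf)

    alleles = np.zeros((n, config.n_loci, 2), dtype=np.int64)
    for l in range(config.n_loci):
        pairs = _draw_genotypes(rng, membership, pop_freqs[l], config.inbreeding_f)
        calls = allele_sizes[l][pairs]
        if null_allele[l] is not None:
            is_null = calls == null_allele[l]
            both_null = is_null.all(axis=1)
            one_null = is_null.any(axis=1) & ~both_null
            # heterozygous carriers look homozygous for the amplifying allele
            visible = np.where(is_null[one_null, 0], calls[one_null, 1], calls[one_null, 0])
            calls[one_null, 0] = visible
            calls[one_null, 1] = visible
            calls[both_null] = 0
        alleles[:, l, :] = calls
    if config.missing_rate > 0:
        drop = rng.random((n, config.n_loci)) < config.missing_rate
        alleles[drop] = 0

    metas: list[IndividualMeta] = []
    i = 0
    for p, (size, model) in enumerate(zip(sizes, sex_models)):
        for k in range(size):
            if model == "dioecious":
                sex = "male" if k % 2 == 0 else "female"
            else:
                sex = "monoecious"
            metas.append(
                IndividualMeta(
                    sample_id=f"POP{p + 1}-{k + 1}",
                    variety=f"POP{p + 1}",
                    country="SIM",
                    sex_phenotype=sex,
                    scar_band="present" if sex == "male" else "absent",
                )
            )
            i += 1

    table = GenotypeTable(alleles, metas, loci)
    truth = SimTruth(
        target_fst=F,
        inbreeding_f=config.inbreeding_f,
        membership=membership,
        pop_of_individual=pop_of,
        allele_sizes=allele_sizes,
        ancestral_freqs=anc_freqs,
        pop_freqs=pop_freqs,
        null_allele=null_allele,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Study-shaped fixture
# ---------------------------------------------------------------------------


def _calibrated_frequencies(
    n_alleles: int, p_max: float, he_target: float
) -> np.ndarray:
    """Pooled allele frequencies with given top frequency and gene diversity.

    The top allele gets ``p_max``; the remaining mass decays geometrically
    with the ratio solved so that ``1 - sum p^2`` matches ``he_target``
    (clipped to the attainable range).
    """
    if n_alleles == 1:
        return np.array([1.0])
    rest = 1.0 - p_max
    m = n_alleles - 1

    def tail(r: float) -> np.ndarray:
        w = r ** np.arange(m)
        return rest * w / w.sum()

    def he(r: float) -> float:
        q = tail(r)
        return 1.0 - p_max**2 - float(np.sum(q**2))

    lo, hi = 1e-4, 1.0
    if he_target >= he(hi):
        r = hi
    elif he_target <= he(lo):
        r = lo
    else:
        r = brentq(lambda x: he(x) - he_target, lo, hi, xtol=1e-12)
    return np.concatenate([[p_max], tail(r)])


def study_shaped_fixture(seed: int | None = None) -> GenotypeTable:
    """Synthetic dataset in the exact layout of the hemp core collection.

    104 individuals in the published 11-variety/country/sex layout, typed at
    the 20-locus panel with allele-size ladders inside each marker's
    expected fragment range. Per locus, pooled allele frequencies match the
    published top-allele frequency and gene diversity; varieties are
    differentiated by a Balding–Nichols draw at the published per-locus
    fixation index, and within-variety genotypes carry the published
    per-locus inbreeding coefficient as autozygosity probability. After
    sampling, every calibrated allele is guaranteed to be observed at least
    once (unobserved rare alleles are injected by converting single copies
    of the locally most common allele), so the total allele count and the
    per-locus allele counts of the panel summary are reproduced exactly.
    No calls are missing.
    """
    rng = np.random.default_rng(seed)
    metas = study_individuals()
    n = len(metas)
    varieties = [m.variety for m in metas]
    var_labels = list(dict.fromkeys(varieties))
    var_idx = {v: np.flatnonzero(np.array(varieties) == v) for v in var_labels}
    r = len(var_labels)

    alleles = np.zeros((n, len(STUDY_MARKERS), 2), dtype=np.int64)
    for j, marker in enumerate(STUDY_MARKERS):
        na, p_max, he, fis, fst = STUDY_LOCUS_CALIBRATION[marker.name]
        lo, hi = marker.expected_size_range
        step = marker.motif_length or 2
        ladder = np.arange(lo, hi + 1, step)
        if ladder.size < na:  # motif-consistent ladder too short: densify
            ladder = np.arange(lo, hi + 1)
        pick = np.unique(np.linspace(0, ladder.size - 1, na).round().astype(int))
        sizes = ladder[pick] if pick.size == na else ladder[:na]
        freqs = _calibrated_frequencies(na, p_max, he)
        order = rng.permutation(na)
        sizes_by_freq = sizes[order]  # random size <-> frequency assignment

        F = float(np.clip(fst, 0.02, 0.9))
        pf = rng.dirichlet(np.maximum(freqs, 1e-9) * (1.0 - F) / F, size=r)
        f_auto = float(np.clip(fis, 0.0, 1.0))
        for v, vi in enumerate(var_labels):
            idx = var_idx[vi]
            p = pf[v]
            for i in idx:
                if rng.random() < f_auto:
                    a = rng.choice(na, p=p)
                    pair = (a, a)
                else:
                    pair = (rng.choice(na, p=p), rng.choice(na, p=p))
                alleles[i, j, :] = sizes_by_freq[list(pair)]
        # guarantee every calibrated allele is observed at least once
        observed = set(np.unique(alleles[:, j, :]))
        for a, size in enumerate(sizes_by_freq):
            if int(size) in observed:
                continue
            vals, counts = np.unique(alleles[:, j, :], return_counts=True)
            modal = vals[counts.argmax()]
            carriers, slots = np.where(alleles[:, j, :] == modal)
            # prefer heterozygous carriers so the injection leaves the
            # heterozygote count (hence Ho and Fis) unchanged
            het = alleles[carriers, j, 0] != alleles[carriers, j, 1]
            if het.any():
                carriers, slots = carriers[het], slots[het]
            k = rng.integers(0, carriers.size)
            alleles[carriers[k], j, slots[k]] = size
            observed.add(int(size))
    return GenotypeTable(alleles, metas, list(STUDY_MARKERS))
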