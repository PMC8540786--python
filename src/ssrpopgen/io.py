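"""Genotype data model and tabular I/O.

The central container is :class:`GenotypeTable`: a diploid, codominant
genotype matrix (individuals x loci, two allele sizes in bp per call, 0 =
missing) together with per-individual metadata (variety, country, sex
phenotype, dominant SCAR band) and per-locus marker definitions.

Two on-disk dialects are supported for genotype calls:

``wide``
    GenAlEx-like CSV with two columns per locus (``LOCUS.1``, ``LOCUS.2``)
    and ``0`` for missing alleles.
``long``
    One row per (sample, locus) call: ``sample_id,locus,allele1,allele2``.

A STRUCTURE-format export (two rows per individual, alleles recoded to
consecutive integers per locus, missing ``-9``) is provided for the
admixture machinery and for interoperability.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerDef",
    "IndividualMeta",
    "GenotypeTable",
    "BandMatrix",
    "GenotypeParseError",
    "GenotypeValidationError",
    "read_genotypes",
    "write_genotypes",
    "read_metadata",
    "write_metadata",
    "to_band_matrix",
    "export_structure",
    "structure_matrix",
]

MISSING = 0  #: in-memory sentinel for a missing allele (GenAlEx convention)
STRUCTURE_MISSING = -9  #: missing sentinel in STRUCTURE export

SEX_PHENOTYPES = ("male", "female", "monoecious")
SCAR_STATES = ("present", "absent", "untyped")


class GenotypeParseError(ValueError):
    """Malformed genotype/metadata file content."""


class GenotypeValidationError(ValueError):
    """Structurally valid file but inconsistent data."""


@dataclass(frozen=True)
class MarkerDef:
    """Definition of one SSR marker locus.

    Only ``name`` is required; the remaining fields mirror a marker-panel
    table (genomic coordinates, expected fragment-size range, multiplex
    group, fluorescent dye, annealing temperature and repeat motif).
    """

    name: str
    chromosome: str = ""
    start: int | None = None
    end: int | None = None
    expected_size_range: tuple[int, int] | None = None
    multiplex_id: int | None = None
    dye: str = ""
    annealing_temp: float | None = None
    motif: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise GenotypeValidationError("marker name must be non-empty")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise GenotypeValidationError(
                f"marker {self.name}: start {self.start} > end {self.end}"
            )
        if self.expected_size_range is not None:
            lo, hi = self.expected_size_range
            if not lo < hi:
                raise GenotypeValidationError(
                    f"marker {self.name}: expected size range {lo}-{hi} is empty"
                )
        if self.multiplex_id is not None and self.multiplex_id not in (1, 2, 3, 4):
            raise GenotypeValidationError(
                f"marker {self.name}: multiplex_id must be in 1-4"
            )

    @property
    def motif_length(self) -> int:
        """Length of the repeat unit parsed from e.g. ``(AAT)10`` (0 if unknown)."""
        m = re.match(r"\(([ACGT]+)\)", self.motif)
        return len(m.group(1)) if m else 0


@dataclass(frozen=True)
class IndividualMeta:
    """Per-individual metadata: variety, origin, sex phenotype, SCAR band."""

    sample_id: str
    variety: str = ""
    country: str = ""
    sex_phenotype: str = ""  # "", "male", "female" or "monoecious"
    scar_band: str = "untyped"  # "present", "absent" or "untyped"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise GenotypeValidationError("sample_id must be non-empty")
        if self.sex_phenotype and self.sex_phenotype not in SEX_PHENOTYPES:
            raise GenotypeValidationError(
                f"{self.sample_id}: unknown sex phenotype {self.sex_phenotype!r}"
            )
        if self.scar_band not in SCAR_STATES:
            raise GenotypeValidationError(
                f"{self.sample_id}: unknown SCAR band state {self.scar_band!r}"
            )

    @property
    def sex_system(self) -> str:
        """``dioecious`` (male/female), ``monoecious`` or ``""`` if unknown."""
        if self.sex_phenotype in ("male", "female"):
            return "dioecious"
        if self.sex_phenotype == "monoecious":
            return "monoecious"
        return ""


class GenotypeTable:
    """Diploid codominant genotype calls for a set of individuals and loci.

    Parameters
    ----------
    alleles:
        Integer array of shape ``(n_individuals, n_loci, 2)`` holding allele
        fragment sizes in bp. A call is missing iff both entries are 0;
        partially missing calls are rejected.
    individuals:
        Ordered :class:`IndividualMeta` records (order is preserved in every
        derived table and matrix).
    loci:
        Ordered :class:`MarkerDef` records.
    """

    def __init__(
        self,
        alleles: np.ndarray,
        individuals: Sequence[IndividualMeta],
        loci: Sequence[MarkerDef],
    ) -> None:
        alleles = np.asarray(alleles, dtype=np.int64)
        if alleles.ndim != 3 or alleles.shape[2] != 2:
            raise GenotypeValidationError(
                f"alleles must have shape (n, L, 2), got {alleles.shape}"
            )
        if alleles.shape[0] != len(individuals) or alleles.shape[1] != len(loci):
            raise GenotypeValidationError(
                "alleles shape does not match individuals/loci lists"
            )
        if (alleles < 0).any():
            raise GenotypeValidationError("allele sizes must be non-negative")
        half_missing = (alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            i, l = np.argwhere(half_missing)[0]
            raise GenotypeValidationError(
                f"call ({individuals[i].sample_id}, {loci[l].name}) has exactly "
                "one missing allele; a call must be fully typed or fully missing"
            )
        ids = [m.sample_id for m in individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise GenotypeValidationError(f"duplicate sample_ids: {dup}")
        names = [m.name for m in loci]
        if len(set(names)) != len(names):
            raise GenotypeValidationError("duplicate locus names")
        # variety -> country must be a function
        var_country: dict[str, str] = {}
        for m in individuals:
            if m.variety and m.country:
                prev = var_country.setdefault(m.variety, m.country)
                if prev != m.country:
                    raise GenotypeValidationError(
                        f"variety {m.variety} mapped to both {prev} and {m.country}"
                    )
        self.alleles = alleles
        self.individuals = list(individuals)
        self.loci = list(loci)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.individuals]

    @property
    def locus_names(self) -> list[str]:
        return [m.name for m in self.loci]

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array, True where the call is missing."""
        return self.alleles[:, :, 0] == MISSING

    def typed_mask(self) -> np.ndarray:
        return ~self.missing_mask()

    def subset(self, individual_idx: Iterable[int]) -> "GenotypeTable":
        idx = np.asarray(list(individual_idx), dtype=int)
        return GenotypeTable(
            self.alleles[idx], [self.individuals[i] for i in idx], self.loci
        )

    def grouping(self, scheme: str) -> dict[str, np.ndarray]:
        """Partition individuals by ``variety``, ``country`` or ``sex_system``.

        Returns an ordered mapping group label -> individual index array;
        individuals with an empty label under the scheme are skipped.
        Order of first appearance is preserved.
        """
        key = {
            "variety": lambda m: m.variety,
            "country": lambda m: m.country,
            "sex_system": lambda m: m.sex_system,
        }.get(scheme)
        if key is None:
            raise ValueError(f"unknown grouping scheme {scheme!r}")
        groups: dict[str, list[int]] = {}
        for i, m in enumerate(self.individuals):
            label = key(m)
            if label:
                groups.setdefault(label, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            np.array_equal(self.alleles, other.alleles)
            and self.individuals == other.individuals
            and self.loci == other.loci
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeTable({self.n_individuals} individuals x "
            f"{self.n_loci} loci)"
        )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def _meta_from_row(row: Mapping[str, object]) -> IndividualMeta:
    def get(name: str) -> str:
        val = row.get(name, "")
        return "" if val is None or (isinstance(val, float) and np.isnan(val)) else str(val)

    scar = get("scar") or get("scar_band") or "untyped"
    return IndividualMeta(
        sample_id=get("sample_id"),
        variety=get("variety"),
        country=get("country"),
        sex_phenotype=get("sex") or get("sex_phenotype"),
        scar_band=scar,
    )


def read_metadata(path: str | Path) -> list[IndividualMeta]:
    """Read an individual-metadata CSV (sample_id, variety, country, sex, scar)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise GenotypeParseError(f"{path}: metadata CSV lacks a sample_id column")
    return [_meta_from_row(row) for _, row in df.iterrows()]


def write_metadata(individuals: Sequence[IndividualMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in individuals],
            "variety": [m.variety for m in individuals],
            "country": [m.country for m in individuals],
            "sex": [m.sex_phenotype for m in individuals],
            "scar": [m.scar_band for m in individuals],
        }
    ).to_csv(path, index=False)


def _parse_allele(value: object, where: str) -> int:
    try:
        a = int(value)
    except (TypeError, ValueError):
        raise GenotypeParseError(f"{where}: allele {value!r} is not an integer")
    if a < 0:
        raise GenotypeParseError(f"{where}: negative allele size {a}")
    return a


def read_genotypes(
    path: str | Path,
    dialect: str = "wide",
    metadata: str | Path | Sequence[IndividualMeta] | None = None,
    loci: Sequence[MarkerDef] | None = None,
) -> GenotypeTable:
    """Read a genotype CSV into a validated :class:`GenotypeTable`.

    ``metadata`` may be a metadata CSV path or a pre-built list of
    :class:`IndividualMeta`; unmatched samples get bare metadata records.
    ``loci`` optionally supplies full marker definitions (matched by name).
    """
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise GenotypeParseError(f"{path}: first column must be sample_id")
        cols = list(df.columns[1:])
        if len(cols) % 2:
            raise GenotypeParseError(f"{path}: odd number of allele columns")
        locus_names: list[str] = []
        for c1, c2 in zip(cols[::2], cols[1::2]):
            n1 = c1.rsplit(".", 1)
            n2 = c2.rsplit(".", 1)
            if len(n1) != 2 or len(n2) != 2 or n1[0] != n2[0]:
                raise GenotypeParseError(
                    f"{path}: columns {c1!r},{c2!r} are not a LOCUS.1/LOCUS.2 pair"
                )
            locus_names.append(n1[0])
        samples = [str(s) for s in df["sample_id"]]
        n, L = len(samples), len(locus_names)
        alleles = np.zeros((n, L, 2), dtype=np.int64)
        for j in range(L):
            for k in range(2):
                col = df[cols[2 * j + k]]
                for i, v in enumerate(col):
                    alleles[i, j, k] = _parse_allele(
                        v, f"{path} line {i + 2}, column {cols[2 * j + k]}"
                    )
    elif dialect == "long":
        df = pd.read_csv(path)
        required = {"sample_id", "locus", "allele1", "allele2"}
        if not required.issubset(df.columns):
            raise GenotypeParseError(
                f"{path}: long dialect needs columns {sorted(required)}"
            )
        samples = list(dict.fromkeys(str(s) for s in df["sample_id"]))
        locus_names = list(dict.fromkeys(str(l) for l in df["locus"]))
        s_idx = {s: i for i, s in enumerate(samples)}
        l_idx = {l: j for j, l in enumerate(locus_names)}
        alleles = np.zeros((len(samples), len(locus_names), 2), dtype=np.int64)
        for r, row in enumerate(df.itertuples(index=False)):
            i, j = s_idx[str(row.sample_id)], l_idx[str(row.locus)]
            where = f"{path} line {r + 2}"
            alleles[i, j, 0] = _parse_allele(row.allele1, where)
            alleles[i, j, 1] = _parse_allele(row.allele2, where)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if metadata is None:
        metas = [IndividualMeta(sample_id=s) for s in samples]
    else:
        records = (
            read_metadata(metadata)
            if isinstance(metadata, (str, Path))
            else list(metadata)
        )
        by_id = {m.sample_id: m for m in records}
        metas = [by_id.get(s, IndividualMeta(sample_id=s)) for s in samples]

    if loci is None:
        marker_defs = [MarkerDef(name=n) for n in locus_names]
    else:
        by_name = {m.name: m for m in loci}
        marker_defs = [by_name.get(n, MarkerDef(name=n)) for n in locus_names]

    return GenotypeTable(alleles, metas, marker_defs)


def write_genotypes(g: GenotypeTable, path: str | Path, dialect: str = "wide") -> None:
    """Write genotype calls to CSV (inverse of :func:`read_genotypes`)."""
    path = Path(path)
    if dialect == "wide":
        data: dict[str, object] = {"sample_id": g.sample_ids}
        for j, name in enumerate(g.locus_names):
            data[f"{name}.1"] = g.alleles[:, j, 0]
            data[f"{name}.2"] = g.alleles[:, j, 1]
        pd.DataFrame(data).to_csv(path, index=False)
    elif dialect == "long":
        rows = []
        for i, sid in enumerate(g.sample_ids):
            for j, name in enumerate(g.locus_names):
                rows.append(
                    (sid, name, g.alleles[i, j, 0], g.alleles[i, j, 1])
                )
        pd.DataFrame(
            rows, columns=["sample_id", "locus", "allele1", "allele2"]
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_marker_panel(loci: Sequence[MarkerDef], path: str | Path) -> None:
    """Write a marker-panel CSV (name, chromosome, coordinates, size range...)."""
    pd.DataFrame(
        {
            "locus": [m.name for m in loci],
            "chromosome": [m.chromosome for m in loci],
            "start": [m.start for m in loci],
            "end": [m.end for m in loci],
            "size_min": [m.expected_size_range[0] if m.expected_size_range else None for m in loci],
            "size_max": [m.expected_size_range[1] if m.expected_size_range else None for m in loci],
            "multiplex": [m.multiplex_id for m in loci],
            "dye": [m.dye for m in loci],
            "annealing_temp": [m.annealing_temp for m in loci],
            "motif": [m.motif for m in loci],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Band (presence/absence) matrix
# ---------------------------------------------------------------------------


@dataclass
class BandMatrix:
    """Binary individuals x bands matrix; a band is a (locus, allele-size) pair.

    ``B[i, b] == 1`` iff individual ``i`` carries at least one copy of band
    ``b``. ``typed[i, l]`` masks loci missing in an individual so that
    similarity coefficients can use pairwise deletion over co-typed loci.
    """

    B: np.ndarray  # (n, n_bands) uint8
    bands: list[tuple[str, int]]  # (locus name, allele size), column order
    band_locus: np.ndarray  # (n_bands,) locus index of each band
    typed: np.ndarray  # (n, L) bool
    labels: list[str]
    locus_names: list[str]

    @property
    def n_bands(self) -> int:
        return self.B.shape[1]


def to_band_matrix(g: GenotypeTable) -> BandMatrix:
    """Binarize codominant calls into band presence/absence.

    Heterozygotes contribute two 1s at their locus, homozygotes one; missing
    calls leave all of the locus's bands 0 and are recorded in the typed mask.
    Every returned band is observed in at least one individual.
    """
    bands: list[tuple[str, int]] = []
    band_locus: list[int] = []
    cols: list[np.ndarray] = []
    for j, name in enumerate(g.locus_names):
        calls = g.alleles[:, j, :]
        observed = np.unique(calls[calls != MISSING])
        for size in observed:
            cols.append((calls == size).any(axis=1).astype(np.uint8))
            bands.append((name, int(size)))
            band_locus.append(j)
    B = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((g.n_individuals, 0), dtype=np.uint8)
    )
    return BandMatrix(
        B=B,
        bands=bands,
        band_locus=np.asarray(band_locus, dtype=int),
        typed=g.typed_mask(),
        labels=g.sample_ids,
        locus_names=list(g.locus_names),
    )


# ---------------------------------------------------------------------------
# STRUCTURE format
# ---------------------------------------------------------------------------


def structure_matrix(g: GenotypeTable) -> tuple[np.ndarray, list[dict[int, int]]]:
    """Integer-recode genotypes for the admixture machinery.

    Returns ``(X, maps)`` where ``X`` has shape ``(n, 2 * L)`` with columns
    ``[locus0_copy0, locus0_copy1, locus1_copy0, ...]``, alleles recoded to
    0-based consecutive integers per locus and missing encoded as ``-9``;
    ``maps[l]`` maps allele size -> code for locus ``l``.
    """
    n, L = g.n_individuals, g.n_loci
    X = np.full((n, 2 * L), STRUCTURE_MISSING, dtype=np.int64)
    maps: list[dict[int, int]] = []
    for j in range(L):
        calls = g.alleles[:, j, :]
        observed = np.unique(calls[calls != MISSING])
        amap = {int(a): c for c, a in enumerate(observed)}
        maps.append(amap)
        for k in range(2):
            col = calls[:, k]
            typed = col != MISSING
            X[typed, 2 * j + k] = np.array(
                [amap[int(a)] for a in col[typed]], dtype=np.int64
            )
    return X, maps


def export_structure(g: GenotypeTable, path: str | Path) -> Path:
    """Write a STRUCTURE-style text file (two rows per individual).

    Alleles are recoded to consecutive 1-based integers per locus, missing is
    ``-9``. The recode map is persisted alongside as ``<path>.recode.json``
    (locus -> {size: code}) so the export is invertible.
    """
    path = Path(path)
    X, maps = structure_matrix(g)
    with open(path, "w") as fh:
        fh.write("\t".join(["sample"] + g.locus_names) + "\n")
        for i, sid in enumerate(g.sample_ids):
            for k in range(2):
                row = [
                    str(X[i, 2 * j + k] + 1 if X[i, 2 * j + k] >= 0 else STRUCTURE_MISSING)
                    for j in range(g.n_loci)
                ]
                fh.write("\t".join([sid] + row) + "\n")
    recode = {
        name: {str(size): code + 1 for size, code in amap.items()}
        for name, amap in zip(g.locus_names, maps)
    }
    recode_path = path.with_name(path.name + ".recode.json")
    with open(recode_path, "w") as fh:
        json.dump(recode, fh, indent=1, sort_keys=True)
    return path
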