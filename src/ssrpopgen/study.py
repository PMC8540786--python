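"""Published marker panel and collection layout of the hemp variety study.

These constants describe the genotyping design the package was built around:
a core collection of 104 *Cannabis sativa* individuals from 11 European hemp
varieties (dioecious southern varieties, monoecious northern ones) typed at
20 nuclear SSR loci organized in four multiplexes, plus the dominant SCAR119
male-associated band. They serve two purposes: concrete marker/metadata
defaults for I/O round-trips, and the calibration targets used by
:func:`ssrpopgen.simulate.study_shaped_fixture` to generate a synthetic
dataset with the same per-locus allele counts, allele-frequency profile,
differentiation and inbreeding as the published panel summary.
"""

from __future__ import annotations

from .io import IndividualMeta, MarkerDef

__all__ = [
    "STUDY_MARKERS",
    "STUDY_LAYOUT",
    "STUDY_LOCUS_CALIBRATION",
    "VARIETY_COUNTRY",
    "study_individuals",
]

# name, chromosome, start, end, (size_min, size_max), multiplex, dye, Ta, motif
_MARKER_ROWS = [
    ("SSR_6-3", "6", 35062092, 35062261, (180, 200), 1, "M13", 55, "(AAT)10"),
    ("SSR_2-2", "2", 27019093, 27019345, (250, 270), 1, "M13", 55, "(TGA)12"),
    ("SSR_X-1", "X", 12090959, 12091352, (390, 450), 1, "M13", 55, "(TC)40"),
    ("SSR_4-2", "4", 38738240, 38738472, (230, 260), 1, "PAN1", 55, "(AT)17"),
    ("SSR_2-3", "2", 49240375, 49240744, (350, 410), 1, "PAN1", 55, "(GA)22"),
    ("SSR_7-3", "7", 51776452, 51776692, (230, 280), 1, "PAN2", 55, "(CT)22"),
    ("SSR_3-3", "3", 59258629, 59258880, (250, 300), 1, "PAN3", 55, "(AG)21"),
    ("SSR_2-1", "2", 15695145, 15695388, (240, 260), 2, "M13", 55, "(AAT)11"),
    ("SSR_4-1", "4", 3414697, 3414947, (230, 270), 2, "PAN1", 55, "(ATA)21"),
    ("SSR_8-2", "8", 13924026, 13924199, (180, 220), 2, "PAN2", 55, "(CT)21"),
    ("SSR_5-2", "5", 34558385, 34558643, (250, 300), 2, "PAN2", 55, "(CT)32"),
    ("SSR_6-1", "6", 3764859, 3765058, (200, 270), 2, "PAN3", 55, "(AT)17"),
    ("SSR_X-3", "X", 71305129, 71305410, (280, 350), 2, "PAN3", 55, "(TC)41"),
    ("SSR_1-4", "1", 86039144, 86039328, (180, 220), 3, "M13", 55, "(TTA)17"),
    ("SSR_3-1", "3", 12247530, 12247829, (300, 340), 3, "M13", 55, "(TC)32"),
    ("SSR_8-4", "8", 50925135, 50925396, (280, 330), 3, "PAN1", 55, "(TC)22"),
    ("SSR_9-4", "9", 58895568, 58895670, (110, 150), 4, "PAN1", 57, "(CT)16"),
    ("SSR_1-1", "1", 12756851, 12757030, (180, 220), 4, "PAN1", 57, "(TC)33"),
    ("SSR_5-5", "5", 82565436, 82565719, (270, 290), 4, "PAN2", 57, "(GA)18"),
    ("SSR_6-4", "6", 63517285, 63517456, (170, 180), 4, "PAN3", 57, "(CT)30"),
]

#: The 20-locus SSR panel, in panel order.
STUDY_MARKERS: list[MarkerDef] = [
    MarkerDef(
        name=name,
        chromosome=chrom,
        start=start,
        end=end,
        expected_size_range=size_range,
        multiplex_id=multiplex,
        dye=dye,
        annealing_temp=float(ta),
        motif=motif,
    )
    for name, chrom, start, end, size_range, multiplex, dye, ta, motif in _MARKER_ROWS
]

#: Collection layout: variety -> (country, n_male, n_female, n_monoecious).
STUDY_LAYOUT: dict[str, tuple[str, int, int, int]] = {
    "ITA1": ("Italy", 7, 3, 0),
    "ITA2": ("Italy", 4, 5, 0),
    "ITA3": ("Italy", 2, 8, 0),
    "HUN1": ("Hungary", 6, 5, 0),
    "HUN2": ("Hungary", 5, 5, 0),
    "FIN": ("Finland", 3, 8, 0),
    "NED": ("Netherlands", 0, 0, 13),
    "POL": ("Poland", 0, 0, 8),
    "FRA1": ("France", 0, 0, 10),
    "FRA2": ("France", 0, 0, 9),
    "FRA3": ("France", 0, 0, 3),
}

VARIETY_COUNTRY: dict[str, str] = {v: c for v, (c, *_) in STUDY_LAYOUT.items()}

#: Published per-locus panel summary used as calibration targets:
#: locus -> (Na, p_max, He, Fis, Fst). Na is the observed allele count,
#: p_max the frequency of the most common allele, He Nei's gene diversity
#: over the pooled collection, Fis the within-variety inbreeding coefficient
#: and Fst the among-variety fixation index.
STUDY_LOCUS_CALIBRATION: dict[str, tuple[int, float, float, float, float]] = {
    "SSR_6-3": (7, 0.54, 0.62, 0.00, 0.22),
    "SSR_2-2": (7, 0.55, 0.63, 0.16, 0.25),
    "SSR_X-1": (28, 0.13, 0.92, 0.42, 0.07),
    "SSR_4-2": (11, 0.43, 0.74, 0.73, 0.10),
    "SSR_2-3": (24, 0.25, 0.89, 0.18, 0.08),
    "SSR_7-3": (17, 0.21, 0.89, 0.03, 0.07),
    "SSR_3-3": (23, 0.20, 0.91, 0.19, 0.09),
    "SSR_2-1": (7, 0.77, 0.38, 0.74, 0.37),
    "SSR_4-1": (11, 0.70, 0.50, 0.68, 0.13),
    "SSR_8-2": (20, 0.17, 0.91, 0.07, 0.10),
    "SSR_5-2": (21, 0.14, 0.92, 0.67, 0.17),
    "SSR_6-1": (14, 0.18, 0.88, 0.64, 0.14),
    "SSR_X-3": (25, 0.13, 0.93, 0.31, 0.10),
    "SSR_1-4": (8, 0.62, 0.59, 0.16, 0.06),
    "SSR_3-1": (15, 0.16, 0.90, 0.45, 0.14),
    "SSR_8-4": (17, 0.16, 0.90, 0.56, 0.12),
    "SSR_9-4": (17, 0.23, 0.89, 0.35, 0.09),
    "SSR_1-1": (18, 0.23, 0.88, 0.63, 0.15),
    "SSR_5-5": (8, 0.70, 0.49, 0.86, 0.21),
    "SSR_6-4": (3, 0.67, 0.47, 0.29, 0.17),
}


def study_individuals() -> list[IndividualMeta]:
    """Metadata records for the 104-individual collection layout.

    Sample ids are ``<VARIETY>-<k>``; within each dioecious variety males
    come first (matching the layout counts), and the SCAR119 band is present
    exactly in males.
    """
    metas: list[IndividualMeta] = []
    for variety, (country, n_male, n_female, n_mono) in STUDY_LAYOUT.items():
        sexes = ["male"] * n_male + ["female"] * n_female + ["monoecious"] * n_mono
        for k, sex in enumerate(sexes, start=1):
            metas.append(
                IndividualMeta(
                    sample_id=f"{variety}-{k}",
                    variety=variety,
                    country=country,
                    sex_phenotype=sex,
                    scar_band="present" if sex == "male" else "absent",
                )
            )
    return metas
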