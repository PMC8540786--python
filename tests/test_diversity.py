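import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrpopgen.diversity import (
    AlleleFreqs,
    UntypedLocusError,
    allele_frequencies,
    effective_alleles,
    expected_heterozygosity,
    f_statistics,
    gene_flow,
    locus_table,
    observed_heterozygosity,
    pic,
    pic_label,
    shannon_index,
)

from conftest import make_table


def freqs(*p, n=100):
    return AlleleFreqs("L", "G", {100 + 2 * i: v for i, v in enumerate(p)}, n)


class TestSingleLocusFormulas:
    """Closed-form oracles computed by hand."""

    def test_allele_frequencies_hand_count(self, toy_pair):
        f = allele_frequencies(toy_pair, "L1")
        assert f.freqs == {100: 0.75, 102: 0.25}
        assert f.n_gene_copies == 4

    def test_monomorphic_group(self):
        g = make_table([[[100, 100]], [[100, 100]]])
        f = allele_frequencies(g, "L1")
        assert f.freqs == {100: 1.0}

    def test_untyped_locus_raises(self):
        g = make_table([[[0, 0]]])
        with pytest.raises(UntypedLocusError):
            allele_frequencies(g, "L1")

    def test_observed_heterozygosity(self, toy_pair):
        assert observed_heterozygosity(toy_pair, "L1") == 0.5
        g = make_table([[[100, 100]], [[102, 102]]])
        assert observed_heterozygosity(g, "L1") == 0.0

    @pytest.mark.parametrize(
        "p,expected",
        [((0.75, 0.25), 0.375), ((1.0,), 0.0), ((0.25,) * 4, 0.75)],
    )
    def test_expected_heterozygosity(self, p, expected):
        assert expected_heterozygosity(freqs(*p)) == pytest.approx(expected, abs=1e-12)

    def test_unbiased_he_factor(self):
        f = freqs(0.75, 0.25, n=4)
        assert expected_heterozygosity(f, unbiased=True) == pytest.approx(
            0.375 * 4 / 3, abs=1e-12
        )

    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.75, 0.25), 0.3046875),  # 1 - 0.625 - 2*(0.75*0.25)^2
            ((1.0,), 0.0),
        ],
    )
    def test_pic(self, p, expected):
        assert pic(freqs(*p)) == pytest.approx(expected, abs=1e-12)

    def test_pic_labels(self):
        assert pic_label(0.6) == "highly informative"
        assert pic_label(0.4) == "reasonably informative"
        assert pic_label(0.0) == "uninformative"

    @pytest.mark.parametrize(
        "p,expected", [((0.5, 0.5), 2.0), ((0.75, 0.25), 1.6), ((1.0,), 1.0)]
    )
    def test_effective_alleles(self, p, expected):
        assert effective_alleles(freqs(*p)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "p,expected",
        [
            ((1.0,), 0.0),
            ((0.5, 0.5), math.log(2)),
            ((0.75, 0.25), -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))),
        ],
    )
    def test_shannon_index(self, p, expected):
        assert shannon_index(freqs(*p)) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=10).map(
            lambda xs: tuple(x / sum(xs) for x in xs)
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_pic_bounded_by_he_and_ne_by_na(self, p):
        f = freqs(*p)
        assert pic(f) <= expected_heterozygosity(f) + 1e-12
        assert 1.0 - 1e-12 <= effective_alleles(f) <= len(p) + 1e-12


class TestGeneFlow:
    @pytest.mark.parametrize("fst,nm", [(0.2, 1.0), (1.0, 0.0), (0.5, 0.25)])
    def test_island_model_formula(self, fst, nm):
        assert gene_flow(fst) == pytest.approx(nm, abs=1e-12)

    def test_undefined_for_nonpositive_fst(self):
        assert math.isnan(gene_flow(0.0))
        assert math.isnan(gene_flow(-0.1))


def brute_force_fstats(g, grouping):
    """Independent from-scratch evaluation of Ho-bar, Hs, Ht on plain dicts."""
    stats = []
    for idx in grouping.values():
        copies, het, n = Counter(), 0, 0
        for i in idx:
            a, b = g.alleles[i, 0, :]
            if a == 0:
                continue
            n += 1
            het += a != b
            copies[a] += 1
            copies[b] += 1
        if n:
            total = sum(copies.values())
            p = {k: v / total for k, v in copies.items()}
            stats.append((n, p, het / n))
    N = sum(s[0] for s in stats)
    ho = sum(s[0] / N * s[2] for s in stats)
    hs = sum(s[0] / N * (1 - sum(v**2 for v in s[1].values())) for s in stats)
    pooled = Counter()
    for n, p, _ in stats:
        for k, v in p.items():
            pooled[k] += n / N * v
    ht = 1 - sum(v**2 for v in pooled.values())
    return (hs - ho) / hs, (ht - ho) / ht, (ht - hs) / ht


class TestFStatistics:
    def test_complete_fixation(self):
        g = make_table(
            [[[100, 100]], [[100, 100]], [[102, 102]], [[102, 102]]]
        )
        grouping = {"A": [0, 1], "B": [2, 3]}
        fs = f_statistics(g, "L1", grouping)
        assert fs.fst == pytest.approx(1.0, abs=1e-12)
        assert fs.fit == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_group_has_zero_fst(self):
        calls = [[[100, 102]], [[100, 100]], [[100, 102]], [[100, 100]]]
        g = make_table(calls)
        fs = f_statistics(g, "L1", {"A": [0, 1], "B": [2, 3]})
        assert fs.fst == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([100, 102, 104], size=(4, 1, 2))
        g = make_table(calls)
        grouping = {"A": [0, 1], "B": [2, 3]}
        fs = f_statistics(g, "L1", grouping)
        fis, fit, fst = brute_force_fstats(g, grouping)
        assert fs.fis == pytest.approx(fis, abs=1e-12)
        assert fs.fit == pytest.approx(fit, abs=1e-12)
        assert fs.fst == pytest.approx(fst, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("unbiased", [False, True])
    def test_wright_identity(self, seed, unbiased):
        """(1 - Fis)(1 - Fst) == (1 - Fit) when computed from one Ho/Hs/Ht."""
        rng = np.random.default_rng(seed)
        calls = rng.choice([100, 102, 104, 106], size=(12, 1, 2))
        g = make_table(calls)
        grouping = {"A": range(4), "B": range(4, 8), "C": range(8, 12)}
        fs = f_statistics(g, "L1", grouping, unbiased=unbiased)
        assert (1 - fs.fis) * (1 - fs.fst) == pytest.approx(1 - fs.fit, abs=1e-10)


class TestLocusTable:
    def test_monomorphic_locus_row(self):
        g = make_table(
            [[[100, 100]], [[100, 100]], [[100, 100]], [[100, 100]]],
            metas=None,
        )
        grouping = {"A": [0, 1], "B": [2, 3]}
        df = locus_table(g, grouping)
        row = df.iloc[0]
        assert row["Na"] == 1
        assert row["He"] == 0 and row["PIC"] == 0 and row["I"] == 0

    def test_mean_sd_block(self, fixture104):
        df = locus_table(fixture104, grouping="variety")
        assert list(df["locus"].iloc[-2:]) == ["Mean", "St. Dev."]
        data = df.iloc[:-2]
        assert len(data) == 20
        assert data["Na"].sum() == 301
        # per-locus invariants on real-size data
        assert (data["PIC"] <= data["He"] + 1e-12).all()
        assert (data["Ne"] <= data["Na"] + 1e-12).all()
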