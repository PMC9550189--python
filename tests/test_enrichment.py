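import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from syntevo.core import Interval, ValidationError
from syntevo.enrichment import (
    WindowTable,
    assign_gene_regions,
    association_test,
    classify_windows,
    compare_gene_lengths,
    gene_density_per_mam,
    make_windows,
    reportable_repeat_classes,
    tally_features,
)
from syntevo.features import EBR
from syntevo.simulate import AnnotationBundle
from tests._oracles import rank_sum_u


def bundle_of(genes=(), repeats=None, tads=(), compartments=(), gaps=(), cens=()):
    return AnnotationBundle(
        genes=list(genes),
        repeats=repeats or {},
        tads=list(tads),
        compartments=list(compartments),
        gaps=list(gaps),
        centromeres=list(cens),
    )


class TestMakeWindows:
    def test_plain_tiling(self):
        wt = make_windows({"c": 1_000_000}, 10_000)
        assert len(wt.retained()) == 100
        assert not wt.df["partial"].any()

    def test_gap_majority_removes_window(self):
        wt = make_windows({"c": 30_000}, 10_000, gaps=[Interval("c", 10_000, 16_000)])
        df = wt.df
        assert df.loc[1, "retained"] == False  # 60% gap
        assert df.loc[0, "retained"] and df.loc[2, "retained"]

    def test_half_gap_is_kept(self):
        wt = make_windows({"c": 20_000}, 10_000, gaps=[Interval("c", 0, 5_000)])
        assert wt.df.loc[0, "retained"]  # exactly 50% is not >50%

    def test_centromere_abutting_boundary_retained(self):
        # half-open: centromere ending exactly at the window start overlaps 0 bp
        wt = make_windows({"c": 30_000}, 10_000,
                          centromeres=[Interval("c", 0, 10_000)])
        assert not wt.df.loc[0, "retained"]
        assert wt.df.loc[1, "retained"]

    def test_partial_last_window_flagged(self):
        wt = make_windows({"c": 25_000}, 10_000)
        assert wt.df.loc[2, "partial"]
        assert wt.df.loc[2, "end"] == 25_000


class TestClassifyWindows:
    def test_containment_rule(self):
        wt = make_windows({"c": 100_000}, 10_000)
        out = classify_windows(
            wt,
            mshsbs=[Interval("c", 20_000, 50_000)],
            ebrs=[EBR(Interval("c", 60_000, 75_000), "x", reuse=True)],
        )
        df = out.df
        assert list(df.loc[2:4, "region_class"]) == ["msHSB"] * 3
        assert df.loc[5, "region_class"] == "other"  # straddles msHSB end? no: 50k..60k between
        assert df.loc[6, "region_class"] == "EBR"
        assert df.loc[6, "reuse_class"] == "reuse"
        assert df.loc[7, "region_class"] == "other"  # 70-80k straddles EBR end

    def test_overlapping_regions_rejected(self):
        wt = make_windows({"c": 100_000}, 10_000)
        with pytest.raises(ValidationError):
            classify_windows(
                wt,
                mshsbs=[Interval("c", 0, 50_000)],
                ebrs=[EBR(Interval("c", 40_000, 60_000), "x")],
            )

    def test_counts_match_per_bp_brute_force(self):
        rng = random.Random(4)
        width = 10
        L = 500
        regions = []
        pos = 0
        while pos < L - 40:
            start = pos + rng.randint(5, 20)
            end = start + rng.randint(5, 60)
            if end > L:
                break
            regions.append((start, min(end, L)))
            pos = end
        half = len(regions) // 2
        mshsbs = [Interval("c", s, e) for s, e in regions[:half]]
        ebrs = [EBR(Interval("c", s, e), "x") for s, e in regions[half:]]
        wt = classify_windows(make_windows({"c": L}, width), mshsbs, ebrs)
        for row in wt.df.itertuples():
            expected = "other"
            for iv in mshsbs:
                if row.start >= iv.start and row.end <= iv.end:
                    expected = "msHSB"
            for e in ebrs:
                if row.start >= e.interval.start and row.end <= e.interval.end:
                    expected = "EBR"
            assert row.region_class == expected


class TestTallies:
    def test_empty_tracks_all_zero(self):
        wt = make_windows({"c": 50_000}, 10_000)
        out = tally_features(wt, bundle_of())
        assert (out.df["gene_count"] == 0).all()
        assert (out.df["compartment"] == "ND").all()
        assert not out.df["tad_present"].any()

    def test_gene_spanning_two_windows_counted_once(self):
        wt = make_windows({"c": 30_000}, 10_000)
        out = tally_features(wt, bundle_of(genes=[Interval("c", 8_000, 14_000)]))
        assert list(out.df["gene_count"]) == [1, 0, 0]
        assert list(out.df["gene_bases"]) == [2_000, 4_000, 0]

    def test_compartment_transition_label(self):
        comps = [(Interval("c", 0, 5_000), "A"), (Interval("c", 5_000, 20_000), "B")]
        wt = make_windows({"c": 20_000}, 10_000)
        out = tally_features(wt, bundle_of(compartments=comps))
        assert list(out.df["compartment"]) == ["A/B", "B"]

    def test_tally_conservation_against_per_bp_oracle(self):
        rng = random.Random(7)
        L, width = 400, 20
        repeats = {
            "rep": [
                Interval("c", s, min(L, s + rng.randint(1, 30)))
                for s in rng.sample(range(L - 5), 12)
            ]
        }
        wt = make_windows({"c": L}, width)
        out = tally_features(wt, bundle_of(repeats=repeats))
        cover = np.zeros(L)
        for iv in repeats["rep"]:
            cover[iv.start : iv.end] += 1
        per_window = [cover[s : s + width].sum() for s in range(0, L, width)]
        assert list(out.df["rep_bases"]) == per_window


class TestComparisons:
    def test_identical_groups_not_significant(self):
        g = {"a": [10.0] * 20 + [20.0] * 20, "b": [10.0] * 20 + [20.0] * 20}
        (out,) = compare_gene_lengths(g)
        assert out.p_value > 0.9
        assert out.median_a == out.median_b

    def test_statistic_matches_rank_sum_enumeration(self):
        rng = random.Random(9)
        for _ in range(20):
            xs = [rng.randint(0, 30) for _ in range(rng.randint(2, 8))]
            ys = [rng.randint(0, 30) for _ in range(rng.randint(2, 8))]
            (out,) = compare_gene_lengths({"a": xs, "b": ys})
            assert out.statistic == pytest.approx(rank_sum_u(xs, ys))

    def test_small_group_skipped(self):
        out = compare_gene_lengths({"a": [1.0], "b": [1.0, 2.0, 3.0]})
        assert out[0].skipped

    def test_bonferroni_over_pairs(self):
        rng = np.random.default_rng(0)
        groups = {k: list(rng.normal(10, 1, 30)) for k in "abc"}
        out = compare_gene_lengths(groups)
        assert len(out) == 3
        for c in out:
            assert c.p_corrected == pytest.approx(min(1.0, c.p_value * 3))


class TestAssociation:
    def test_equal_proportions_odds_ratio_one(self):
        pres = {"a": np.array([True, False] * 50), "b": np.array([True, False] * 50)}
        (out,) = association_test(pres)
        assert out.odds_ratio == pytest.approx(1.0)

    def test_textbook_cross_product(self):
        a = np.array([False] * 30 + [True] * 70)
        b = np.array([False] * 10 + [True] * 90)
        (out,) = association_test({"a": a, "b": b})
        assert out.odds_ratio == pytest.approx(27 / 7)
        # hand computation of sum((O-E)^2/E) for [[30,70],[10,90]]
        assert out.statistic == pytest.approx(12.5)
        assert out.p_value == pytest.approx(stats.chi2.sf(12.5, 1))

    def test_zero_cell_gets_haldane_correction(self):
        a = np.array([False] * 10 + [True] * 10)
        b = np.array([True] * 20)
        (out,) = association_test({"a": a, "b": b})
        assert out.or_corrected
        assert np.isfinite(out.odds_ratio)


class TestGeneDensity:
    def test_density_arithmetic(self):
        out = gene_density_per_mam(
            {"m1": 190, "m2": 100, "m3": 120}, {"m1": 10_000_000, "m2": 10_000_000, "m3": 10_000_000}
        )
        assert out.set_index("chrom").loc["m1", "density_per_mbp"] == pytest.approx(19.0)

    def test_uniform_density_not_significant(self):
        rng = np.random.default_rng(5)
        counts = {f"m{i}": int(c) for i, c in enumerate(rng.poisson(100, 8))}
        lengths = {k: 10_000_000 for k in counts}
        out = gene_density_per_mam(counts, lengths)
        assert not out["significant"].any()

    def test_planted_dense_chromosome_flagged(self):
        counts = {f"m{i}": 100 + i for i in range(9)}
        counts["hot"] = 300
        lengths = {k: 10_000_000 for k in counts}
        out = gene_density_per_mam(counts, lengths)
        flagged = set(out.loc[out["significant"], "chrom"])
        assert flagged == {"hot"}

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            gene_density_per_mam({"a": 1, "b": 1, "c": 1}, {"a": 0, "b": 1, "c": 1})


class TestRepeatReporting:
    def test_sparse_subclass_suppressed(self):
        df = pd.DataFrame(
            {
                "retained": [True] * 4,
                "region_class": ["EBR", "EBR", "msHSB", "msHSB"],
                "dense_bases": [500.0, 300.0, 200.0, 100.0],
                "sparse_bases": [10.0, 5.0, 0.0, 2.0],
            }
        )
        wt = WindowTable(10_000, df)
        assert reportable_repeat_classes(wt) == ["dense"]
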