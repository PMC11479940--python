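"""TPM/median-of-ratios normalization, intron retention, links, readthrough."""

import math

import numpy as np
import pandas as pd
import pytest

from svakit.expression import (
    CountTable,
    FeatureError,
    count_reads_in_features,
    detect_readthrough,
    intron_retention,
    link_elements_to_genes,
    size_factors_median_ratios,
    tpm,
)
from svakit.io import AnnotationRecord, BedRecord
from svakit.profiles import AlignmentRecord, CoverageTrack


def table(counts: dict, lengths: dict, kinds=None, groups=None) -> CountTable:
    df = pd.DataFrame(counts)
    return CountTable(
        counts=df,
        lengths=pd.Series(lengths),
        kinds=pd.Series(kinds or {f: "gene" for f in df.index}),
        groups=pd.Series(groups or {s: "g" for s in df.columns}),
    )


class TestTPM:
    def test_single_feature_gets_the_whole_million(self):
        t = table({"s": pd.Series({"f": 7})}, {"f": 500})
        assert tpm(t).loc["f", "s"] == pytest.approx(1e6)

    def test_hand_computed_two_feature_example(self):
        t = table({"s": pd.Series({"a": 10, "b": 10})}, {"a": 1000, "b": 2000})
        out = tpm(t)
        assert out.loc["a", "s"] == pytest.approx(666_666.67, rel=1e-6)
        assert out.loc["b", "s"] == pytest.approx(333_333.33, rel=1e-6)

    def test_all_zero_sample_yields_zero_not_nan(self):
        t = table({"s": pd.Series({"a": 0, "b": 0})}, {"a": 100, "b": 200})
        assert (tpm(t)["s"] == 0).all()

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        counts = {f"s{j}": pd.Series({f"f{i}": int(rng.integers(0, 500)) for i in range(30)})
                  for j in range(4)}
        lengths = {f"f{i}": int(rng.integers(200, 5000)) for i in range(30)}
        out = tpm(table(counts, lengths))
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-6)


class TestSizeFactors:
    def test_identical_samples_have_unit_factors(self):
        t = table({"a": pd.Series({"f1": 10, "f2": 20}), "b": pd.Series({"f1": 10, "f2": 20})},
                  {"f1": 100, "f2": 100})
        assert np.allclose(size_factors_median_ratios(t), 1.0)

    def test_doubled_sample_gives_inverse_sqrt2_pair(self):
        counts = {"a": pd.Series({f"f{i}": 10 * (i + 1) for i in range(9)})}
        counts["b"] = counts["a"] * 2
        t = table(counts, {f"f{i}": 100 for i in range(9)})
        factors = size_factors_median_ratios(t)
        assert factors["a"] == pytest.approx(1 / math.sqrt(2))
        assert factors["b"] == pytest.approx(math.sqrt(2))
        assert factors["b"] / factors["a"] == pytest.approx(2.0)

    def test_scaling_one_sample_scales_its_relative_factor(self):
        # size factors are defined up to a common scale (the geometric-mean
        # reference absorbs part of the change), so equivariance holds for
        # factor ratios
        rng = np.random.default_rng(1)
        base = {f"s{j}": pd.Series({f"f{i}": int(rng.integers(5, 200)) for i in range(20)})
                for j in range(3)}
        lengths = {f"f{i}": 100 for i in range(20)}
        f0 = size_factors_median_ratios(table(base, lengths))
        scaled = {k: (v * 3 if k == "s1" else v) for k, v in base.items()}
        f1 = size_factors_median_ratios(table(scaled, lengths))
        assert f1["s1"] / f1["s0"] == pytest.approx(3 * f0["s1"] / f0["s0"])
        assert f1["s2"] / f1["s0"] == pytest.approx(f0["s2"] / f0["s0"])

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(2)
        counts = {f"s{j}": pd.Series({f"f{i}": int(rng.integers(0, 300)) for i in range(50)})
                  for j in range(6)}
        lengths = {f"f{i}": 100 for i in range(50)}
        t = table(counts, lengths)
        factors = size_factors_median_ratios(t)
        mat = t.counts.to_numpy(dtype=float)
        keep = (mat > 0).all(axis=1)
        ref = np.array([math.exp(np.mean([math.log(x) for x in row])) for row in mat[keep]])
        for j, sample in enumerate(t.counts.columns):
            expected = float(np.median(mat[keep, j] / ref))
            assert factors[sample] == pytest.approx(expected)

    def test_no_universally_nonzero_feature_is_an_error(self):
        t = table({"a": pd.Series({"f1": 0, "f2": 5}), "b": pd.Series({"f1": 5, "f2": 0})},
                  {"f1": 100, "f2": 100})
        with pytest.raises(ValueError):
            size_factors_median_ratios(t)


def retention_table(intron_dko_mean, exon_dko_mean):
    counts = {}
    for name, group, intron, exon in (
        ("c1", "control", 40, 100), ("c2", "control", 40, 100),
        ("k1", "dko", intron_dko_mean, exon_dko_mean),
        ("k2", "dko", intron_dko_mean, exon_dko_mean),
    ):
        counts[name] = pd.Series({"gene": 1000, "intron": intron, "exon": exon})
    return CountTable(
        counts=pd.DataFrame(counts),
        lengths=pd.Series({"gene": 2000, "intron": 1000, "exon": 500}),
        kinds=pd.Series({"gene": "gene", "intron": "intron", "exon": "exon"}),
        groups=pd.Series({"c1": "control", "c2": "control", "k1": "dko", "k2": "dko"}),
    )


class TestIntronRetention:
    def test_equal_groups_have_unit_ratios_and_no_flags(self):
        t = retention_table(40, 100)
        r = intron_retention(t, "intron", "exon", ("control", "dko"))
        assert r.intron_ratio == pytest.approx(1.0)
        assert r.exon_ratio == pytest.approx(1.0)
        assert not r.intron_up and not r.exon_down

    def test_planted_threefold_intron_and_halved_exon(self):
        t = retention_table(120, 50)
        r = intron_retention(t, "intron", "exon", ("control", "dko"))
        assert 2.5 <= r.intron_ratio <= 3.5
        assert 0.4 <= r.exon_ratio <= 0.6
        assert r.intron_up and r.exon_down

    def test_zero_intron_counts_give_missing_ratio(self):
        t = retention_table(0, 100)
        t.counts.loc["intron"] = 0
        r = intron_retention(t, "intron", "exon", ("control", "dko"))
        assert math.isnan(r.intron_ratio)

    def test_absent_feature_error_names_it(self):
        t = retention_table(40, 100)
        with pytest.raises(FeatureError, match="nosuch"):
            intron_retention(t, "nosuch", "exon", ("control", "dko"))


def gene(chrom, start, end, strand, gene_id):
    return AnnotationRecord(chrom, "t", "gene", start, end, ".", strand, ".",
                            {"gene_id": gene_id})


class TestGeneLinks:
    def test_tss_at_ten_kilobases_is_linked(self):
        el = BedRecord("c", 100_000, 101_500, "e", ".", "+")
        links = link_elements_to_genes([el], [gene("c", 111_500, 120_000, "+", "g")])
        assert len(links) == 1
        assert links[0].distance == 10_000

    def test_tss_below_minimum_excluded(self):
        el = BedRecord("c", 100_000, 101_500, "e", ".", "+")
        assert link_elements_to_genes([el], [gene("c", 102_501, 110_000, "+", "g")]) == []

    def test_tss_beyond_maximum_excluded(self):
        el = BedRecord("c", 100_000, 101_500, "e", ".", "+")
        assert link_elements_to_genes([el], [gene("c", 161_502, 170_000, "+", "g")]) == []

    def test_minus_strand_tss_is_the_gene_end(self):
        el = BedRecord("c", 100_000, 101_500, "e", ".", "+")
        links = link_elements_to_genes([el], [gene("c", 50_000, 95_000, "-", "g")])
        assert len(links) == 1
        assert links[0].distance == 100_000 - (95_000 - 1)
        assert links[0].side == "upstream"  # element past the TSS against transcription

    def test_translation_invariance(self):
        el = BedRecord("c", 100_000, 101_500, "e", ".", "+")
        g = gene("c", 111_500, 120_000, "+", "g")
        base = link_elements_to_genes([el], [g])
        shift = 12_345
        el2 = BedRecord("c", el.start + shift, el.end + shift, "e", ".", "+")
        g2 = gene("c", g.start + shift, g.end + shift, "+", "g")
        moved = link_elements_to_genes([el2], [g2])
        assert [(l.distance, l.side) for l in moved] == [(l.distance, l.side) for l in base]

    def test_links_sorted_by_distance(self):
        el = BedRecord("c", 100_000, 101_500, "e", ".", "+")
        genes = [gene("c", 131_501, 140_000, "+", "far"), gene("c", 106_501, 110_000, "+", "near")]
        links = link_elements_to_genes([el], genes)
        assert [l.gene_id for l in links] == ["near", "far"]


class TestReadthrough:
    annotation = [gene("c", 20_001, 30_000, "-", "g")]
    element = BedRecord("c", 31_000, 32_500, "e", ".", "+")

    def test_zero_coverage_beyond_element_gives_zero_extent(self):
        empty = CoverageTrack({})
        call = detect_readthrough(empty, empty, self.element, self.annotation)
        assert call.extent == 0

    def test_planted_antisense_readthrough_recovered(self):
        plus = CoverageTrack({"c": [(32_500, 34_500, 4.0)]})
        minus = CoverageTrack({})
        call = detect_readthrough(plus, minus, self.element, self.annotation)
        assert 1_800 <= call.extent <= 2_200
        assert call.direction == "antisense"  # '+' signal vs the minus-strand gene
        assert call.side == "right"

    def test_gap_bridged_under_max_gap(self):
        plus = CoverageTrack({"c": [(32_500, 33_000, 3.0), (33_100, 33_600, 3.0)]})
        minus = CoverageTrack({})
        call = detect_readthrough(plus, minus, self.element, self.annotation, max_gap=200)
        assert call.extent == 33_600 - 32_500
        short = detect_readthrough(plus, minus, self.element, self.annotation, max_gap=50)
        assert short.extent == 500

    def test_extent_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 4, size=3_000)
        plus = CoverageTrack({"c": [(32_500 + i, 32_501 + i, float(v))
                                    for i, v in enumerate(vals)]})
        minus = CoverageTrack({})
        extents_cov = [
            detect_readthrough(plus, minus, self.element, self.annotation,
                               min_coverage=c, max_gap=50).extent
            for c in (0.5, 1.0, 2.0, 3.5)
        ]
        assert extents_cov == sorted(extents_cov, reverse=True)
        extents_gap = [
            detect_readthrough(plus, minus, self.element, self.annotation,
                               min_coverage=2.0, max_gap=g).extent
            for g in (0, 20, 100, 400)
        ]
        assert extents_gap == sorted(extents_gap)


def test_count_reads_in_features_overlap_rule():
    reads = [AlignmentRecord("r1", "c", 90, 20), AlignmentRecord("r2", "c", 300, 50),
             AlignmentRecord("r3", "x", 100, 50)]
    features = [BedRecord("c", 100, 200, "f1"), BedRecord("c", 250, 400, "f2")]
    counts = count_reads_in_features(reads, features)
    assert counts["f1"] == 1 and counts["f2"] == 1
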