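"""The seeded generator: determinism, planted truth and file validity."""

import dataclasses
import warnings

import numpy as np
import pytest

from svakit import catalog, methylation, profiles
from svakit.io import read_bed, read_bedgraph, read_fasta, read_gtf
from svakit.synthetic import (
    InvalidConfigError,
    SimConfig,
    simulate_genome_with_elements,
    simulate_methylation_and_counts,
    simulate_signal_and_alignments,
    write_fixture,
)


class TestConfig:
    def test_element_longer_than_chromosome_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(chrom_length=20_000, element_length_range=(1_200, 2_400)).validate()

    def test_fraction_bounds_enforced(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(methylation_high=1.2).validate()
        with pytest.raises(InvalidConfigError):
            SimConfig(noise_rate=0.3).validate()


class TestGenome:
    def test_no_elements_requested_gives_empty_bed(self):
        sim = simulate_genome_with_elements(SimConfig(seed=1, n_fixed_elements=0))
        assert sim.elements == []
        assert sim.truth.elements == []

    def test_fixed_copy_range_plants_exactly_that_many_hexamers(self):
        sim = simulate_genome_with_elements(SimConfig(seed=1, hexamer_copies_range=(40, 40)))
        for el in sim.truth.elements:
            seq = sim.genome[el.chromosome][el.start:el.end]
            assert seq.startswith("CCCTCT" * 40)
            assert not seq.startswith("CCCTCT" * 41)
            # string-count oracle on the head region
            assert seq[: 6 * 41].count("CCCTCT") == 40

    def test_same_seed_reproduces_identical_genome(self):
        cfg = SimConfig(seed=3)
        a = simulate_genome_with_elements(cfg)
        b = simulate_genome_with_elements(cfg)
        assert a.genome == b.genome
        assert a.truth == b.truth

    def test_planted_elements_retrievable_by_slicing(self, genome_sim):
        for el in genome_sim.truth.elements:
            assert genome_sim.genome[el.chromosome][el.start:el.end] == el.sequence

    def test_planted_insertions_retrievable_from_augmented_genome(self, genome_sim):
        from svakit.augment import Insertion, augment_genome

        plan = [Insertion(i.chromosome, i.position, i.sequence, i.label)
                for i in genome_sim.truth.insertions]
        augmented, cmap = augment_genome(genome_sim.genome, plan)
        for ins in genome_sim.truth.insertions:
            end = cmap.lift_point(ins.chromosome, ins.position)
            start = end - len(ins.sequence)
            assert augmented[ins.chromosome][start:end] == ins.sequence

    def test_elements_carry_at_least_twenty_cpgs(self, genome_sim):
        for el in genome_sim.truth.elements:
            assert el.sequence.count("CG") >= 20

    def test_annotation_has_a_multiexon_gene_per_chromosome(self, genome_sim):
        genes = [r for r in genome_sim.annotation if r.feature == "gene"]
        chroms = {f"chr{i + 1}" for i in range(3)}
        assert {g.chrom for g in genes} == chroms
        for chrom in chroms:
            exons = [r for r in genome_sim.annotation
                     if r.feature == "exon" and r.chrom == chrom]
            assert len(exons) >= 2

    def test_an_intron_overlaps_a_planted_insertion(self, genome_sim):
        introns = [r for r in genome_sim.annotation if r.feature == "intron"]
        intronic = [i for i in genome_sim.truth.insertions if i.intronic]
        assert intronic
        for ins in intronic:
            assert any(
                r.chrom == ins.chromosome and r.start0 <= ins.position < r.end0
                for r in introns
            )


class TestSignal:
    def boundary_vs_background(self, cfg):
        sim = simulate_genome_with_elements(cfg)
        signal = simulate_signal_and_alignments(cfg, sim.elements, sim.truth)
        track = profiles.CoverageTrack.from_bedgraph_dict(signal.track)
        ratios = []
        for el in sim.elements:
            if el.name not in sim.truth.enriched_element_ids:
                continue
            arr = track.per_base(el.chrom, cfg.chrom_length)
            boundary = np.r_[arr[el.start - 1000:el.start + 1000],
                             arr[el.end - 1000:el.end + 1000]]
            background = arr[2_000:12_000]  # far from any element
            ratios.append(boundary.mean() / background.mean())
        return ratios

    def test_null_enrichment_gives_unit_ratio(self):
        ratios = self.boundary_vs_background(SimConfig(seed=2, boundary_enrichment=1.0))
        assert all(0.9 <= r <= 1.1 for r in ratios)

    def test_planted_fivefold_enrichment_measured_by_direct_averaging(self):
        ratios = self.boundary_vs_background(SimConfig(seed=2, boundary_enrichment=5.0))
        assert ratios
        assert all(4.0 <= r <= 6.0 for r in ratios)

    def test_spikein_count_passthrough(self, genome_sim, sim_config):
        cfg = dataclasses.replace(sim_config, spikein_reads=10_000)
        signal = simulate_signal_and_alignments(cfg, genome_sim.elements, genome_sim.truth)
        assert signal.spikein_aligned == 10_000

    def test_sam_records_carry_tags(self, genome_sim, sim_config):
        signal = simulate_signal_and_alignments(sim_config, genome_sim.elements,
                                                genome_sim.truth)
        assert all(r.number_of_hits >= 1 and r.mismatches >= 0 for r in signal.sam_records)
        assert any(r.number_of_hits > 1 for r in signal.sam_records)


class TestMethylationAndCounts:
    def test_degenerate_rates_give_fully_methylated_control(self):
        cfg = SimConfig(seed=4, methylation_high=1.0, noise_rate=0.0)
        sim = simulate_genome_with_elements(cfg)
        meth = simulate_methylation_and_counts(cfg, sim.elements, sim.truth)
        control = meth.calls[meth.calls["condition"] == "control"]
        assert (control["log_lik_ratio"] > 0).all()

    def test_demethylated_elements_near_planted_low_rate(self):
        cfg = SimConfig(seed=5, methylation_low=0.1, noise_rate=0.0)
        sim = simulate_genome_with_elements(cfg)
        meth = simulate_methylation_and_counts(cfg, sim.elements, sim.truth)
        binarized = methylation.binarize_calls(meth.calls)
        kd = binarized.calls[binarized.calls["condition"] == "knockdown"]
        for el in sim.elements:
            summary = methylation.element_methylation(kd, el)
            if el.name in sim.truth.demethylated_element_ids:
                assert abs(summary.mean_methylation - 0.1) <= 0.05
            else:
                assert summary.mean_methylation > 0.8

    def test_counts_table_has_all_feature_kinds(self, sim_config, genome_sim):
        meth = simulate_methylation_and_counts(sim_config, genome_sim.elements,
                                               genome_sim.truth)
        assert set(meth.counts.kinds.unique()) == {"gene", "intron", "exon", "TE"}
        assert set(meth.counts.groups.unique()) == {"control", "double_kd"}


class TestFixtureFiles:
    def test_fixture_parses_with_package_readers_without_warnings(self, tmp_path):
        cfg = SimConfig(seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            paths, truth = write_fixture(cfg, tmp_path / "fx")
            genome = read_fasta(paths["genome"])
            elements = read_bed(paths["elements"])
            annotation = read_gtf(paths["annotation"])
            calls = catalog.read_insertion_table(paths["insertions"])
            track = profiles.CoverageTrack.from_bedgraph_dict(read_bedgraph(paths["signal"]))
            alignments = profiles.read_sam(paths["alignments"])
            meth_calls = methylation.read_call_table(paths["methylation"])
        assert len(genome) == cfg.n_chromosomes
        assert len(elements) == cfg.n_fixed_elements
        assert len(calls) == len(truth.insertions) + len(truth.decoy_rows)
        assert len(alignments) > 0
        assert not meth_calls.empty
        assert track.chrom_extent("chr1") == cfg.chrom_length
        assert any(r.feature == "gene" for r in annotation)

    def test_fixture_is_byte_identical_across_runs(self, tmp_path):
        cfg = SimConfig(seed=8)
        paths_a, _ = write_fixture(cfg, tmp_path / "a")
        paths_b, _ = write_fixture(cfg, tmp_path / "b")
        for key in paths_a:
            with open(paths_a[key], "rb") as fa, open(paths_b[key], "rb") as fb:
                assert fa.read() == fb.read(), key

    def test_insertion_table_quality_fields_on_percent_scale(self, tmp_path):
        paths, truth = write_fixture(SimConfig(seed=9), tmp_path / "fx")
        first = open(paths["insertions"]).readlines()[1].split("\t")
        header = open(paths["insertions"]).readline().split("\t")
        unmap = float(first[header.index("UnmapCover")])
        assert unmap > 1.0  # printed as a percentage, reader normalizes
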