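"""Deterministic, seeded generator of every input the pipeline consumes.

The generator emulates the data modalities of an SVA-silencing study on a
miniature multi-chromosome genome: planted SVA-like elements (a (CCCTCT)n
hexamer head followed by a GC-rich VNTR-like body), a truth set of
non-reference insertions with TLDR-style quality fields (plus decoy calls
that fail the conventional filters), repressive-mark coverage enriched at
element boundaries with a yeast spike-in read count, per-CpG per-read
methylation calls under a methylated control and a demethylated knockdown
condition, gene/intron/exon/TE count tables with a planted intron-retention
effect, and stranded readthrough coverage extending from one activated
element.  Identical configurations (same seed) reproduce byte-identical
output files; every planted feature is recorded in a :class:`TruthSet` for
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import pysam

from .expression import CountTable
from .io import AnnotationRecord, BedRecord, write_bed, write_bedgraph, write_fasta, write_gtf
from .profiles import AlignmentRecord

FLANK = 10_000  # profiling flank; elements keep this much clear on each side
_CHROM_MARGIN = FLANK + 2_000


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome and its data modalities.

    Defaults mirror the conditions of the emulated experiments: elements
    longer than 1 kbp with 10 kbp flanks, a CCCTCT hexamer head in the
    copy-number range of patient alleles, a GC-rich body, strong boundary
    enrichment of the repressive mark, near-complete methylation in the
    control and near-complete loss in the knockdown, and a 3-fold planted
    intron-retention effect with halved downstream-exon output.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 120_000
    n_fixed_elements: int = 6
    n_polymorphic_insertions: int = 6
    element_length_range: tuple[int, int] = (1_200, 2_400)
    hexamer_copies_range: tuple[int, int] = (35, 50)
    vntr_gc_fraction: float = 0.72
    boundary_enrichment: float = 5.0
    methylation_high: float = 0.95
    methylation_low: float = 0.10
    noise_rate: float = 0.02
    spikein_reads: int = 10_000
    reads_per_cpg: int = 12
    intron_fold: float = 3.0
    exon_fold: float = 0.5
    readthrough_extent: int = 2_000

    def validate(self) -> None:
        for name in ("vntr_gc_fraction", "methylation_high", "methylation_low"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.noise_rate <= 0.2:
            raise InvalidConfigError("noise_rate must lie in [0, 0.2]")
        lo, hi = self.element_length_range
        if not 1_000 < lo <= hi:
            raise InvalidConfigError("element lengths must satisfy 1000 < min <= max")
        if self.chrom_length <= hi + 2 * FLANK:
            raise InvalidConfigError(
                f"chromosome length {self.chrom_length} cannot hold an element of "
                f"{hi} bases plus two {FLANK}-base flanks"
            )
        clo, chi = self.hexamer_copies_range
        if not 1 <= clo <= chi:
            raise InvalidConfigError("hexamer copy range must satisfy 1 <= min <= max")
        if min(self.n_chromosomes, self.chrom_length) <= 0:
            raise InvalidConfigError("need at least one chromosome of positive length")
        if min(self.n_fixed_elements, self.n_polymorphic_insertions, self.spikein_reads) < 0:
            raise InvalidConfigError("counts must be >= 0")


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


# ---------------------------------------------------------------------------
# truth


@dataclass(frozen=True)
class PlantedElement:
    element_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    subfamily: str
    hexamer_copies: int
    sequence: str


@dataclass(frozen=True)
class PlantedInsertion:
    label: str
    chromosome: str
    position: int  # 0-based insert-before point
    sequence: str
    subfamily: str
    hexamer_copies: int
    sample_ids: frozenset[str]
    intronic: bool
    unmap_cover: float
    te_match: float
    span_reads: int


@dataclass
class TruthSet:
    """Ground truth planted by the generator, for recovery tests."""

    elements: list[PlantedElement]
    insertions: list[PlantedInsertion]  # calls that survive the default filters
    decoy_rows: list[dict]  # insertion-table rows that must be filtered out
    enriched_element_ids: frozenset[str]
    demethylated_element_ids: frozenset[str]
    readthrough_element_id: str | None
    readthrough_extent: int
    intron_fold: float
    exon_fold: float
    target_intron_id: str | None
    target_exon_id: str | None

    @property
    def planted_insertions(self) -> list[tuple[str, int, str, str]]:
        return [(i.chromosome, i.position, i.sequence, i.subfamily) for i in self.insertions]

    @property
    def planted_hexamer_copies(self) -> dict[str, int]:
        return {e.element_id: e.hexamer_copies for e in self.elements}

    def to_json(self, path) -> None:
        def default(obj):
            if isinstance(obj, frozenset):
                return sorted(obj)
            raise TypeError(type(obj))

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, default=default, indent=1)


# ---------------------------------------------------------------------------
# sequence construction

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_element_sequence(
    rng: np.random.Generator, length: int, hexamer_copies: int, gc_fraction: float,
    min_cpgs: int = 20,
) -> str:
    """(CCCTCT)n head + GC-biased body with at least ``min_cpgs`` CpG sites.

    Body bases are sampled independently with P(G or C) = ``gc_fraction``;
    if the sampled body happens to carry fewer than ``min_cpgs`` CpG
    dinucleotides, CG pairs are planted at evenly spaced body offsets.
    """
    head = "CCCTCT" * hexamer_copies
    body_len = length - len(head)
    if body_len < 2 * min_cpgs:
        raise InvalidConfigError(
            f"element of {length} bases cannot hold {hexamer_copies} hexamer "
            f"copies plus a body with {min_cpgs} CpGs"
        )
    p_gc = gc_fraction / 2.0
    probs = [(1 - gc_fraction) / 2, p_gc, p_gc, (1 - gc_fraction) / 2]
    body = list("".join(_BASES[rng.choice(4, size=body_len, p=probs)]))
    # the body must not continue the hexamer run in phase, or the planted
    # copy number would be ambiguous
    body[:4] = list("AGGA")
    if "".join(body).count("CG") < min_cpgs:
        for offset in np.linspace(4, body_len - 2, min_cpgs).astype(int):
            body[offset], body[offset + 1] = "C", "G"
    return head + "".join(body)


# ---------------------------------------------------------------------------
# stage 1: genome, elements, annotation


class GenomeSim(NamedTuple):
    genome: dict[str, str]
    elements: list[BedRecord]
    annotation: list[AnnotationRecord]
    truth: TruthSet


_GENE_START = 15_000
_EXON_LEN = 500
_INTRON1_LEN = 4_000
_INTRON2_LEN = 2_000
_ELEMENT_REGION_START = 35_000


def _gene_model(chrom: str, index: int) -> tuple[list[AnnotationRecord], dict[str, tuple[int, int]]]:
    """One multi-exon gene per chromosome (1-based GTF records)."""
    strand = "+" if index % 2 == 0 else "-"
    gene_id = f"gene_{chrom}"
    e1 = (_GENE_START, _GENE_START + _EXON_LEN)
    i1 = (e1[1], e1[1] + _INTRON1_LEN)
    e2 = (i1[1], i1[1] + _EXON_LEN)
    i2 = (e2[1], e2[1] + _INTRON2_LEN)
    e3 = (i2[1], i2[1] + _EXON_LEN)
    spans = {
        f"{gene_id}_exon1": e1,
        f"{gene_id}_intron1": i1,
        f"{gene_id}_exon2": e2,
        f"{gene_id}_intron2": i2,
        f"{gene_id}_exon3": e3,
    }
    records = [
        AnnotationRecord(chrom, "svakit_sim", "gene", _GENE_START + 1, e3[1], ".", strand, ".",
                         {"gene_id": gene_id}),
        AnnotationRecord(chrom, "svakit_sim", "transcript", _GENE_START + 1, e3[1], ".", strand,
                         ".", {"gene_id": gene_id, "transcript_id": f"{gene_id}.t1"}),
    ]
    for name, (s, e) in spans.items():
        feature = "exon" if "exon" in name else "intron"
        records.append(
            AnnotationRecord(chrom, "svakit_sim", feature, s + 1, e, ".", strand, ".",
                             {"gene_id": gene_id, "transcript_id": f"{gene_id}.t1",
                              "feature_id": name})
        )
    return records, spans


def simulate_genome_with_elements(config: SimConfig) -> GenomeSim:
    """Generate the genome FASTA, element BED, gene GTF and truth set."""
    config.validate()
    rng = _rng(config, 1)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    genome = {c: _random_dna(rng, config.chrom_length) for c in chrom_names}

    # annotation: one multi-exon gene per chromosome
    annotation: list[AnnotationRecord] = []
    intron1_span: dict[str, tuple[int, int]] = {}
    for idx, chrom in enumerate(chrom_names):
        records, spans = _gene_model(chrom, idx)
        annotation.extend(records)
        intron1_span[chrom] = spans[f"gene_{chrom}_intron1"]

    # fixed elements, round-robin over chromosomes
    lo, hi = config.element_length_range
    spacing = hi + 2 * FLANK + 1_000
    elements: list[BedRecord] = []
    planted: list[PlantedElement] = []
    for i in range(config.n_fixed_elements):
        chrom = chrom_names[i % config.n_chromosomes]
        slot = i // config.n_chromosomes
        start = _ELEMENT_REGION_START + slot * spacing + int(rng.integers(0, 400))
        length = int(rng.integers(lo, hi + 1))
        if start + length + _CHROM_MARGIN > config.chrom_length:
            raise InvalidConfigError(
                f"{config.n_fixed_elements} elements of up to {hi} bases do not fit "
                f"on {config.n_chromosomes} chromosomes of {config.chrom_length} bases"
            )
        clo, chi = config.hexamer_copies_range
        copies = int(rng.integers(clo, chi + 1))
        seq = make_element_sequence(rng, length, copies, config.vntr_gc_fraction)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        subfamily = "SVA_E" if i % 2 == 0 else "SVA_F"
        element_id = f"{subfamily}.{chrom}.{slot}"
        left = genome[chrom][:start]
        if left.endswith("T"):  # would extend the hexamer run out of phase 0
            left = left[:-1] + "A"
        genome[chrom] = left + seq + genome[chrom][start + length:]
        elements.append(BedRecord(chrom, start, start + length, element_id, ".", strand))
        planted.append(PlantedElement(element_id, chrom, start, start + length, strand,
                                      subfamily, copies, seq))

    # polymorphic insertions (non-reference: not in the FASTA), plus decoys
    samples = ("XNPC1", "CNPC1")
    insertions: list[PlantedInsertion] = []
    per_chrom_count = {c: 0 for c in chrom_names}
    for i in range(config.n_polymorphic_insertions):
        chrom = chrom_names[i % config.n_chromosomes]
        intronic = per_chrom_count[chrom] == 0
        if intronic:
            s, e = intron1_span[chrom]
            position = (s + e) // 2
        else:
            position = 25_000 + per_chrom_count[chrom] * 1_500 + int(rng.integers(0, 400))
        per_chrom_count[chrom] += 1
        length = int(rng.integers(lo, hi + 1))
        clo, chi = config.hexamer_copies_range
        copies = int(rng.integers(clo, chi + 1))
        seq = make_element_sequence(rng, length, copies, config.vntr_gc_fraction)
        if i % 3 == 2:  # private to one sample
            sample_ids = frozenset({samples[i % 2]})
        else:
            sample_ids = frozenset(samples)
        insertions.append(
            PlantedInsertion(
                label=f"ins_{chrom}_{per_chrom_count[chrom] - 1}",
                chromosome=chrom,
                position=position,
                sequence=seq,
                subfamily="SVA_E" if i % 2 == 0 else "SVA_F",
                hexamer_copies=copies,
                sample_ids=sample_ids,
                intronic=intronic,
                unmap_cover=float(np.round(rng.uniform(0.85, 0.98), 3)),
                te_match=float(np.round(rng.uniform(0.85, 0.99), 3)),
                span_reads=int(rng.integers(3, 13)),
            )
        )

    decoys: list[dict] = []
    if config.n_polymorphic_insertions:
        decoy_specs = [
            {"unmap": 0.70, "match": 0.90, "span": 5, "length": lo},      # low UnmapCover
            {"unmap": 0.92, "match": 0.91, "span": 2, "length": lo},      # too few reads
            {"unmap": 0.93, "match": 0.92, "span": 6, "length": 800},     # too short
        ]
        for k, spec in enumerate(decoy_specs):
            chrom = chrom_names[k % config.n_chromosomes]
            seq = make_element_sequence(rng, max(spec["length"], 700), 20,
                                        config.vntr_gc_fraction, min_cpgs=5)[: spec["length"]]
            decoys.append(
                {
                    "chromosome": chrom,
                    "start": 28_000 + 900 * k,
                    "end": 28_000 + 900 * k,
                    "subfamily": "SVA_F",
                    "consensus": seq,
                    "UnmapCover": spec["unmap"],
                    "TEMatch": spec["match"],
                    "span_reads": spec["span"],
                    "samples": samples[k % 2],
                }
            )

    element_ids = [e.element_id for e in planted]
    enriched = frozenset(element_ids[:-1]) if len(element_ids) > 1 else frozenset(element_ids)
    demethylated = frozenset(element_ids[::2])
    readthrough_id = element_ids[0] if element_ids else None
    target_chrom = next((i.chromosome for i in insertions if i.intronic), None)
    truth = TruthSet(
        elements=planted,
        insertions=insertions,
        decoy_rows=decoys,
        enriched_element_ids=enriched,
        demethylated_element_ids=demethylated,
        readthrough_element_id=readthrough_id,
        readthrough_extent=config.readthrough_extent,
        intron_fold=config.intron_fold,
        exon_fold=config.exon_fold,
        target_intron_id=f"gene_{target_chrom}_intron1" if target_chrom else None,
        target_exon_id=f"gene_{target_chrom}_exon2" if target_chrom else None,
    )
    return GenomeSim(genome, elements, annotation, truth)


def insertion_table_rows(truth: TruthSet, percent_scale: bool = True) -> pd.DataFrame:
    """TLDR-style insertion table (truth insertions + decoy rows).

    ``percent_scale`` prints the two quality fractions as 0-100
    percentages, the way caller output is usually formatted.
    """
    rows = []
    for ins in truth.insertions:
        rows.append(
            {
                "chromosome": ins.chromosome,
                "start": ins.position,
                "end": ins.position,
                "subfamily": ins.subfamily,
                "consensus": ins.sequence,
                "UnmapCover": ins.unmap_cover,
                "TEMatch": ins.te_match,
                "span_reads": ins.span_reads,
                "samples": ",".join(sorted(ins.sample_ids)),
            }
        )
    rows.extend(truth.decoy_rows)
    df = pd.DataFrame(rows).sort_values(["chromosome", "start"], kind="stable")
    if percent_scale:
        df["UnmapCover"] = (df["UnmapCover"] * 100).round(1)
        df["TEMatch"] = (df["TEMatch"] * 100).round(1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage 2: boundary-enriched signal + minimal alignments + spike-in

_SIGNAL_BIN = 50


class SignalSim(NamedTuple):
    track: dict[str, list[tuple[int, int, float]]]
    sam_records: list[AlignmentRecord]
    spikein_aligned: int


def simulate_signal_and_alignments(
    config: SimConfig, elements: list[BedRecord], truth: TruthSet
) -> SignalSim:
    """Boundary-enriched bedGraph, minimal tagged SAM records and spike-in count.

    Enriched elements carry ``boundary_enrichment``-fold signal in the
    +/-1 kbp windows around both element boundaries relative to the
    genome-wide background (mean 1).
    """
    config.validate()
    rng = _rng(config, 2)
    chrom_lengths: dict[str, int] = {}
    for el in elements:
        chrom_lengths[el.chrom] = max(chrom_lengths.get(el.chrom, 0), config.chrom_length)
    for i in range(config.n_chromosomes):
        chrom_lengths.setdefault(f"chr{i + 1}", config.chrom_length)

    enriched = {el.name: el for el in elements if el.name in truth.enriched_element_ids}
    track: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in sorted(chrom_lengths):
        n = chrom_lengths[chrom]
        n_bins = (n + _SIGNAL_BIN - 1) // _SIGNAL_BIN
        values = np.maximum(rng.normal(1.0, config.noise_rate, size=n_bins), 1e-3) \
            if config.noise_rate > 0 else np.ones(n_bins)
        boundary_bins: set[int] = set()
        for el in enriched.values():
            if el.chrom != chrom:
                continue
            for edge in (el.start, el.end):
                lo = max(0, (edge - 1_000)) // _SIGNAL_BIN
                hi = min(n, edge + 1_000) // _SIGNAL_BIN
                boundary_bins.update(range(lo, hi))
        if boundary_bins:
            values[sorted(boundary_bins)] *= config.boundary_enrichment
        track[chrom] = [
            (b * _SIGNAL_BIN, min(n, (b + 1) * _SIGNAL_BIN), float(np.round(values[b], 6)))
            for b in range(n_bins)
        ]

    sam_records: list[AlignmentRecord] = []
    read_no = 0
    for chrom in sorted(chrom_lengths):
        for _ in range(40):
            start = int(rng.integers(0, chrom_lengths[chrom] - 150))
            nh = 1 if rng.random() < 0.75 else int(rng.integers(2, 6))
            nm = int(rng.binomial(100, 0.02))
            primary = rng.random() >= 0.1
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            sam_records.append(
                AlignmentRecord(
                    read_id=f"read{read_no}", chromosome=chrom, start=start,
                    aligned_length=100, number_of_hits=nh, mismatches=nm,
                    is_primary=primary, strand=strand,
                )
            )
            read_no += 1
    return SignalSim(track, sam_records, config.spikein_reads)


def write_sam(records: list[AlignmentRecord], chrom_lengths: dict[str, int], path) -> None:
    """Write minimal single-end SAM records with NH and NM tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_id = tid[rec.chromosome]
            a.reference_start = rec.start
            a.mapping_quality = 60
            a.cigarstring = f"{rec.aligned_length}M"
            a.query_sequence = "A" * rec.aligned_length
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if not rec.is_primary:
                flag |= 256
            a.flag = flag
            a.set_tag("NH", rec.number_of_hits)
            a.set_tag("NM", rec.mismatches)
            out.write(a)


# ---------------------------------------------------------------------------
# stage 3: methylation calls + count table


class MethylationSim(NamedTuple):
    calls: pd.DataFrame
    counts: CountTable


_CALL_COLUMNS = ["chromosome", "strand", "position", "read_id", "log_lik_ratio",
                 "sample", "condition"]
_MAX_CPGS_PER_ELEMENT = 40


def _cpg_positions(element: PlantedElement) -> np.ndarray:
    seq = element.sequence
    sites = np.array([i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"], dtype=int)
    if len(sites) > _MAX_CPGS_PER_ELEMENT:
        idx = np.linspace(0, len(sites) - 1, _MAX_CPGS_PER_ELEMENT).astype(int)
        sites = sites[idx]
    return element.start + sites


def simulate_methylation_and_counts(
    config: SimConfig, elements: list[BedRecord], truth: TruthSet
) -> MethylationSim:
    """Per-read per-CpG methylation calls and a gene/intron/exon/TE count table.

    Control calls are methylated at ``methylation_high``; in the knockdown
    condition, elements in the truth's demethylated set drop to
    ``methylation_low``.  LLR magnitudes are drawn in [2.5, 10] so the
    standard binarization threshold of 2 is unambiguous; ``noise_rate``
    flips states.  The count table plants an ``intron_fold`` increase of
    the target intron and an ``exon_fold`` change of its downstream exon in
    the double-knockdown group, and upregulates demethylated TE loci.
    """
    config.validate()
    rng = _rng(config, 3)
    rows = {c: [] for c in _CALL_COLUMNS}
    for element in truth.elements:
        positions = _cpg_positions(element)
        for condition in ("control", "knockdown"):
            p = config.methylation_high
            if condition == "knockdown" and element.element_id in truth.demethylated_element_ids:
                p = config.methylation_low
            p_eff = p * (1 - config.noise_rate) + (1 - p) * config.noise_rate
            n_sites = len(positions)
            states = rng.random((n_sites, config.reads_per_cpg)) < p_eff
            magnitudes = rng.uniform(2.5, 10.0, size=(n_sites, config.reads_per_cpg))
            for s in range(n_sites):
                for r in range(config.reads_per_cpg):
                    rows["chromosome"].append(element.chromosome)
                    rows["strand"].append(element.strand)
                    rows["position"].append(int(positions[s]))
                    rows["read_id"].append(f"{condition}_{element.element_id}_r{r}")
                    sign = 1.0 if states[s, r] else -1.0
                    rows["log_lik_ratio"].append(float(np.round(sign * magnitudes[s, r], 3)))
                    rows["sample"].append(condition)
                    rows["condition"].append(condition)
    calls = pd.DataFrame(rows, columns=_CALL_COLUMNS)

    # count table
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    features: list[tuple[str, str, int]] = []  # (id, kind, length)
    for chrom in chrom_names:
        gid = f"gene_{chrom}"
        features.append((gid, "gene", 3 * _EXON_LEN))
        for name, kind, length in (
            (f"{gid}_exon1", "exon", _EXON_LEN),
            (f"{gid}_intron1", "intron", _INTRON1_LEN),
            (f"{gid}_exon2", "exon", _EXON_LEN),
            (f"{gid}_intron2", "intron", _INTRON2_LEN),
            (f"{gid}_exon3", "exon", _EXON_LEN),
        ):
            features.append((name, kind, length))
    for element in truth.elements:
        features.append((element.element_id, "TE", element.end - element.start))

    base_mean = {"gene": 600.0, "exon": 150.0, "intron": 80.0, "TE": 5.0}
    group_of = {}
    sample_names = []
    for g, label in (("control", "control"), ("dko", "double_kd")):
        for r in range(1, 5):
            name = f"{g}_rep{r}"
            sample_names.append(name)
            group_of[name] = label

    data = {}
    for sample in sample_names:
        double_kd = group_of[sample] == "double_kd"
        col = []
        for fid, kind, _length in features:
            mean = base_mean[kind]
            if double_kd:
                if fid == truth.target_intron_id:
                    mean *= truth.intron_fold
                elif fid == truth.target_exon_id:
                    mean *= truth.exon_fold
                elif kind == "TE" and fid in truth.demethylated_element_ids:
                    mean *= 8.0
            col.append(rng.poisson(mean))
        data[sample] = col
    index = [fid for fid, _, _ in features]
    counts = CountTable(
        counts=pd.DataFrame(data, index=index),
        lengths=pd.Series({fid: length for fid, _, length in features}),
        kinds=pd.Series({fid: kind for fid, kind, _ in features}),
        groups=pd.Series(group_of),
    )
    return MethylationSim(calls, counts)


# ---------------------------------------------------------------------------
# stage 4: stranded readthrough tracks


def simulate_readthrough_tracks(
    config: SimConfig,
    elements: list[BedRecord],
    truth: TruthSet,
    annotation: list[AnnotationRecord],
) -> tuple[dict, dict]:
    """Stranded coverage with one planted antisense readthrough.

    The truth's readthrough element gains ``readthrough_extent`` bases of
    coverage extending from its downstream boundary on the strand opposite
    to its chromosome's gene.
    """
    plus: dict[str, list[tuple[int, int, float]]] = {}
    minus: dict[str, list[tuple[int, int, float]]] = {}
    target = next((el for el in elements if el.name == truth.readthrough_element_id), None)
    if target is not None:
        gene_strand = next(
            (r.strand for r in annotation if r.feature == "gene" and r.chrom == target.chrom),
            "+",
        )
        interval = (target.end, target.end + truth.readthrough_extent, 5.0)
        (minus if gene_strand == "+" else plus)[target.chrom] = [interval]
    return plus, minus


# ---------------------------------------------------------------------------
# fixture directory


def write_fixture(config: SimConfig, outdir) -> tuple[dict[str, str], TruthSet]:
    """Emit the complete synthetic input tree; returns paths and the truth set."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, elements, annotation, truth = simulate_genome_with_elements(config)
    signal = simulate_signal_and_alignments(config, elements, truth)
    meth = simulate_methylation_and_counts(config, elements, truth)
    plus, minus = simulate_readthrough_tracks(config, elements, truth, annotation)

    paths = {name: str(outdir / fname) for name, fname in {
        "genome": "genome.fa",
        "elements": "elements.bed",
        "annotation": "annotation.gtf",
        "insertions": "insertions.tsv",
        "signal": "signal.bedgraph",
        "alignments": "alignments.sam",
        "spikein": "spikein.txt",
        "methylation": "methylation.tsv",
        "counts": "counts.tsv",
        "samples": "samples.tsv",
        "readthrough_plus": "readthrough_plus.bedgraph",
        "readthrough_minus": "readthrough_minus.bedgraph",
        "truth": "truth.json",
    }.items()}

    write_fasta(genome, paths["genome"])
    write_bed(elements, paths["elements"])
    write_gtf(annotation, paths["annotation"])
    insertion_table_rows(truth).to_csv(paths["insertions"], sep="\t", index=False)
    write_bedgraph(signal.track, paths["signal"])
    write_sam(signal.sam_records, {c: len(s) for c, s in genome.items()}, paths["alignments"])
    with open(paths["spikein"], "w") as fh:
        fh.write(f"{signal.spikein_aligned}\n")
    meth.calls.to_csv(paths["methylation"], sep="\t", index=False)
    meth.counts.to_tsv(paths["counts"], paths["samples"])
    write_bedgraph(plus, paths["readthrough_plus"])
    write_bedgraph(minus, paths["readthrough_minus"])
    truth.to_json(paths["truth"])
    return paths, truth
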