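"""Feature quantification, normalization and cis-effect detection.

Counts of reads per feature (genes, introns, exons, transposon loci) are
normalized either as approximate TPM — counts per kilobase of feature
length, rescaled so every sample sums to one million — or with
median-of-ratios size factors (each sample's median ratio of counts to the
per-feature geometric-mean reference).  On top of the normalized table the
module quantifies intron retention (intron up / downstream-exon down),
links elements to nearby genes by TSS distance (the conventional window is
2-50 kbp), and detects readthrough transcription extending from an element
boundary into its flank on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationRecord, BedRecord
from .profiles import CoverageTrack

FEATURE_KINDS = ("gene", "intron", "exon", "TE")


class FeatureError(KeyError):
    pass


@dataclass
class CountTable:
    """Features x samples counts with lengths, kinds and sample groups."""

    counts: pd.DataFrame  # index: feature ids; columns: sample ids
    lengths: pd.Series  # per feature, bases
    kinds: pd.Series  # per feature, one of FEATURE_KINDS
    groups: pd.Series  # per sample, group label

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        self.kinds = self.kinds.reindex(self.counts.index)
        self.groups = self.groups.reindex(self.counts.columns)
        if (self.lengths <= 0).any():
            raise ValueError("feature lengths must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def to_tsv(self, counts_path, samples_path) -> None:
        out = self.counts.copy()
        out.insert(0, "kind", self.kinds)
        out.insert(1, "length", self.lengths)
        out.index.name = "feature_id"
        out.to_csv(counts_path, sep="\t")
        pd.DataFrame({"sample": self.groups.index, "group": self.groups.values}).to_csv(
            samples_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountTable":
        df = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(
            counts=df.drop(columns=["kind", "length"]),
            lengths=df["length"],
            kinds=df["kind"],
            groups=pd.Series(samples["group"].values, index=samples["sample"].values),
        )


def tpm(table: CountTable) -> pd.DataFrame:
    """Approximate TPM: per-kilobase rates rescaled to one million per sample.

    Effective length is the feature length itself (no fragment-length
    correction).  A sample with all-zero counts yields all-zero TPMs.
    """
    rates = table.counts.div(table.lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    out = rates.div(totals.replace(0, np.nan), axis=1) * 1e6
    return out.fillna(0.0)


def size_factors_median_ratios(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors.

    The per-feature reference is the geometric mean across samples
    (features with any zero count are excluded); each sample's factor is
    the median over features of count/reference.
    """
    counts = table.counts.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no feature has nonzero counts in every sample")
    logs = np.log(counts[nonzero])
    reference = np.exp(logs.mean(axis=1))
    ratios = counts[nonzero] / reference[:, None]
    return pd.Series(np.median(ratios, axis=0), index=table.counts.columns, name="size_factor")


@dataclass
class IntronRetentionResult:
    intron_id: str
    exon_id: str
    groups: tuple[str, str]
    intron_tpm_means: dict[str, float]
    exon_tpm_means: dict[str, float]
    intron_ratio: float  # group2 / group1; NaN when undefined
    exon_ratio: float
    intron_up: bool
    exon_down: bool


def intron_retention(
    table: CountTable, intron_id: str, exon_id: str, groups: tuple[str, str]
) -> IntronRetentionResult:
    """Intron-retention summary between two sample groups.

    Reports group mean TPM of the retained intron and a downstream exon,
    their between-group ratios (second group over first), and direction
    flags raised when the two ratios cross 1 in opposite directions (intron
    up and exon down — the expression signature of intron retention with
    reduced downstream output).
    """
    for fid in (intron_id, exon_id):
        if fid not in table.counts.index:
            raise FeatureError(f"feature {fid!r} absent from the count table")
    tpms = tpm(table)

    def group_mean(fid: str, group: str) -> float:
        samples = table.samples_in_group(group)
        if not samples:
            raise ValueError(f"no samples in group {group!r}")
        return float(tpms.loc[fid, samples].mean())

    g1, g2 = groups
    intron_means = {g: group_mean(intron_id, g) for g in groups}
    exon_means = {g: group_mean(exon_id, g) for g in groups}

    def ratio(means: dict[str, float]) -> float:
        return means[g2] / means[g1] if means[g1] > 0 else float("nan")

    intron_ratio = ratio(intron_means)
    exon_ratio = ratio(exon_means)
    flags = np.isfinite(intron_ratio) and np.isfinite(exon_ratio) \
        and intron_ratio > 1.0 and exon_ratio < 1.0
    return IntronRetentionResult(
        intron_id=intron_id,
        exon_id=exon_id,
        groups=(g1, g2),
        intron_tpm_means=intron_means,
        exon_tpm_means=exon_means,
        intron_ratio=intron_ratio,
        exon_ratio=exon_ratio,
        intron_up=bool(flags),
        exon_down=bool(flags),
    )


# ---------------------------------------------------------------------------
# element-to-gene linkage


@dataclass
class GeneLink:
    element_id: str
    gene_id: str
    distance: int  # element edge to gene TSS, bases
    side: str  # element upstream/downstream of the TSS in the gene's frame
    same_strand: bool


def _gene_tss(gene: AnnotationRecord) -> int:
    """0-based TSS: gene start on '+', gene end on '-'."""
    return gene.start0 if gene.strand == "+" else gene.end0 - 1


def link_elements_to_genes(
    elements: list[BedRecord],
    annotation: list[AnnotationRecord],
    min_distance: int = 2000,
    max_distance: int = 50000,
) -> list[GeneLink]:
    """Link each element to genes whose TSS lies within a distance window.

    Distance is measured from the nearest element edge to the TSS (0 when
    the TSS falls inside the element); links outside
    [min_distance, max_distance] are dropped; output is sorted by distance.
    """
    if min_distance > max_distance:
        raise ValueError("min_distance must be <= max_distance")
    genes = [r for r in annotation if r.feature == "gene"]
    links = []
    for el in elements:
        for gene in genes:
            if gene.chrom != el.chrom:
                continue
            tss = _gene_tss(gene)
            if el.start <= tss < el.end:
                distance = 0
            elif tss < el.start:
                distance = el.start - tss
            else:
                distance = tss - (el.end - 1)
            if not min_distance <= distance <= max_distance:
                continue
            element_left_of_tss = el.end <= tss or (distance == 0 and el.start < tss)
            if gene.strand == "+":
                side = "upstream" if element_left_of_tss else "downstream"
            else:
                side = "downstream" if element_left_of_tss else "upstream"
            links.append(
                GeneLink(
                    element_id=el.name,
                    gene_id=gene.attributes.get("gene_id", f"{gene.chrom}:{gene.start}"),
                    distance=distance,
                    side=side,
                    same_strand=el.strand == gene.strand,
                )
            )
    links.sort(key=lambda l: (l.distance, l.element_id, l.gene_id))
    return links


# ---------------------------------------------------------------------------
# readthrough detection


@dataclass
class ReadthroughCall:
    element_id: str
    direction: str  # sense/antisense relative to the overlapped/nearest gene
    strand: str  # strand of the extended signal
    side: str  # left/right of the element in genomic coordinates
    extent: int  # bases of contiguous transcribed flank
    mean_coverage: float


def _extent_outward(arr: np.ndarray, boundary: int, step: int,
                    min_coverage: float, max_gap: int) -> tuple[int, float]:
    """Walk outward from an element boundary bridging short gaps."""
    pos = boundary
    last_covered = None
    gap = 0
    n = len(arr)
    while 0 <= pos < n:
        if arr[pos] >= min_coverage:
            last_covered = pos
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
        pos += step
    if last_covered is None:
        return 0, 0.0
    extent = abs(last_covered - boundary) + 1
    lo, hi = (boundary, last_covered) if step > 0 else (last_covered, boundary)
    return extent, float(arr[lo:hi + 1].mean())


def detect_readthrough(
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    element: BedRecord,
    annotation: list[AnnotationRecord],
    min_coverage: float = 1.0,
    max_gap: int = 100,
) -> ReadthroughCall:
    """Detect readthrough transcription extending from an element boundary.

    On each strand and on each side of the element, the extent of
    contiguous coverage >= ``min_coverage`` (bridging gaps of at most
    ``max_gap`` bases) is measured outward from the element boundary; the
    longest extension wins.  The call is labeled antisense when the
    extended strand is opposite to that of the overlapped (else nearest)
    gene on the element's chromosome.
    """
    genes = [r for r in annotation if r.feature == "gene" and r.chrom == element.chrom]

    def gene_strand() -> str:
        for g in genes:
            if g.start0 < element.end and element.start < g.end0:
                return g.strand
        if genes:
            nearest = min(
                genes,
                key=lambda g: min(abs(g.start0 - element.end), abs(element.start - g.end0)),
            )
            return nearest.strand
        return element.strand

    best = ReadthroughCall(element.name, "sense", element.strand, "right", 0, 0.0)
    for strand, track in (("+", plus_track), ("-", minus_track)):
        n = max(track.chrom_extent(element.chrom), element.end + 1)
        arr = track.per_base(element.chrom, n)
        for side, boundary, step in (("left", element.start - 1, -1), ("right", element.end, +1)):
            extent, mean_cov = _extent_outward(arr, boundary, step, min_coverage, max_gap)
            if extent > best.extent:
                best = ReadthroughCall(element.name, "", strand, side, extent, mean_cov)
    reference_strand = gene_strand()
    best.direction = "antisense" if best.strand != reference_strand else "sense"
    return best


# ---------------------------------------------------------------------------
# fixture-grade overlap counting


def count_reads_in_features(alignments, features: list[BedRecord]) -> pd.Series:
    """Count alignments overlapping each feature by >= 1 base.

    A deliberately minimal interval-overlap counter for building fixtures;
    a read overlapping several features is counted in each.
    """
    counts = {}
    for feat in features:
        c = 0
        for aln in alignments:
            if aln.chromosome != feat.chrom:
                continue
            if aln.start < feat.end and aln.start + aln.aligned_length > feat.start:
                c += 1
        counts[feat.name] = c
    return pd.Series(counts, dtype=int)
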