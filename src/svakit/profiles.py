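"""Alignment filtering, spike-in scaling and repeat-boundary signal profiles.

Repeats are profiled through their unique flanking context: a scale-regions
matrix rescales each element body to a fixed number of bins and attaches
fixed-width flank bins (defaults: 1 kbp body, 10 kbp flanks, 50 bp bins),
after which boundary enrichment — e.g. of the repressive H3K9me3 mark over
element edges — can be read off as the ratio of boundary to distal-flank
signal.  Samples profiled with an exogenous (yeast) spike-in are rescaled by
``1e4 / aligned_spikein_reads`` before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .io import BedRecord


class SpikeInError(ValueError):
    """No spike-in reads: the scale factor is undefined."""


# ---------------------------------------------------------------------------
# alignment records


@dataclass
class AlignmentRecord:
    """Minimal single-end alignment with hit-count and mismatch tags."""

    read_id: str
    chromosome: str
    start: int
    aligned_length: int
    number_of_hits: int = 1
    mismatches: int = 0
    is_primary: bool = True
    strand: str = "+"

    def __post_init__(self):
        if self.aligned_length <= 0:
            raise ValueError("aligned_length must be > 0")
        if self.mismatches > self.aligned_length:
            raise ValueError("mismatches cannot exceed aligned length")
        if self.number_of_hits < 1:
            raise ValueError("number_of_hits must be >= 1")

    @property
    def mismatch_rate(self) -> float:
        return self.mismatches / self.aligned_length


def read_sam(path) -> list[AlignmentRecord]:
    """Read a SAM file into :class:`AlignmentRecord` objects (NH/NM tags)."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chromosome=aln.reference_name,
                    start=aln.reference_start,
                    aligned_length=aln.query_alignment_length or aln.infer_query_length() or 1,
                    number_of_hits=aln.get_tag("NH") if aln.has_tag("NH") else 1,
                    mismatches=aln.get_tag("NM") if aln.has_tag("NM") else 0,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return records


def filter_alignments(
    records: list[AlignmentRecord],
    max_mismatch_rate: float = 0.03,
    unique_only: bool = True,
) -> list[AlignmentRecord]:
    """Unique-mapping, mismatch-bounded primary alignments.

    Keeps primary records with at most ``max_mismatch_rate`` mismatches per
    aligned base (inclusive, mirroring an aligner's maximum-allowed-value
    semantics) and, if ``unique_only``, a single reported hit.
    """
    kept = []
    for rec in records:
        if not rec.is_primary:
            continue
        if unique_only and rec.number_of_hits != 1:
            continue
        if rec.mismatch_rate > max_mismatch_rate:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# spike-in scaling

SPIKEIN_NUMERATOR = 1e4  # scale factor = 1e4 per aligned spike-in read


@dataclass(frozen=True)
class SpikeInStats:
    aligned_reads: int
    scale_factor: float


def spikein_scale_factor(aligned_spikein_reads: int) -> SpikeInStats:
    """Spike-in scale factor, ``1e4 / aligned_spikein_reads``."""
    if aligned_spikein_reads < 0:
        raise ValueError("aligned spike-in read count must be >= 0")
    if aligned_spikein_reads == 0:
        raise SpikeInError("zero aligned spike-in reads; scale factor undefined")
    return SpikeInStats(aligned_spikein_reads, SPIKEIN_NUMERATOR / aligned_spikein_reads)


# ---------------------------------------------------------------------------
# coverage tracks


@dataclass
class CoverageTrack:
    """Per-chromosome sorted, non-overlapping intervals with values.

    Positions not covered by any interval have value 0.
    """

    intervals: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, ivs in self.intervals.items():
            prev_end = -1
            for start, end, value in ivs:
                if start < prev_end:
                    raise ValueError(f"overlapping intervals on {chrom}")
                if end <= start or not np.isfinite(value) or value < 0:
                    raise ValueError(f"invalid interval ({start}, {end}, {value}) on {chrom}")
                prev_end = end

    @classmethod
    def from_bedgraph_dict(cls, track: dict[str, list[tuple[int, int, float]]]) -> "CoverageTrack":
        return cls({c: sorted(v) for c, v in track.items()})

    def chrom_extent(self, chrom: str) -> int:
        ivs = self.intervals.get(chrom, [])
        return ivs[-1][1] if ivs else 0

    def per_base(self, chrom: str, length: int | None = None) -> np.ndarray:
        """Expand one chromosome to a dense per-base value array."""
        n = length if length is not None else self.chrom_extent(chrom)
        arr = np.zeros(n, dtype=float)
        for start, end, value in self.intervals.get(chrom, []):
            arr[start:min(end, n)] = value
        return arr

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: [(s, e, v * factor) for s, e, v in ivs] for c, ivs in self.intervals.items()}
        )


# ---------------------------------------------------------------------------
# scale-regions matrices


@dataclass
class ProfileMatrix:
    """Elements x bins matrix: fixed flank bins around a rescaled body."""

    element_ids: list[str]
    values: np.ndarray  # shape (n_elements, n_bins); NaN = off-chromosome
    bin_size: int
    body: int
    flank: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.bin_size

    @property
    def n_body_bins(self) -> int:
        return self.body // self.bin_size

    def column_means(self) -> np.ndarray:
        """Missing-aware column means (off-chromosome bins excluded)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)

    def to_tsv(self, path) -> None:
        import json

        header = json.dumps({"bin_size": self.bin_size, "body": self.body, "flank": self.flank})
        with open(path, "w") as fh:
            fh.write(f"#{header}\n")
            for eid, row in zip(self.element_ids, self.values):
                cells = "\t".join("nan" if np.isnan(v) else f"{v:.10g}" for v in row)
                fh.write(f"{eid}\t{cells}\n")

    @classmethod
    def from_tsv(cls, path) -> "ProfileMatrix":
        import json

        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("#"))
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(ids, np.array(rows, dtype=float), meta["bin_size"], meta["body"], meta["flank"])


def _mean_over(cumsum: np.ndarray, arr: np.ndarray, a: float, b: float) -> float:
    """Mean of the per-base step function over the real interval [a, b)."""

    def integral(x: float) -> float:
        i = int(np.floor(x))
        base = cumsum[min(i, len(arr))]
        frac = x - i
        if frac > 0 and 0 <= i < len(arr):
            base += frac * arr[i]
        return base

    return (integral(b) - integral(a)) / (b - a)


def scale_regions_matrix(
    track: CoverageTrack,
    elements: list[BedRecord],
    body: int = 1000,
    flank: int = 10000,
    bin_size: int = 50,
    min_element_length: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> ProfileMatrix:
    """Scale-regions signal matrix over elements (5'->3' of each element).

    Only elements with length strictly greater than ``min_element_length``
    get a row.  The body is rescaled to ``body/bin_size`` bins by
    length-weighted averaging; flank bins are raw fixed-width averages.
    Minus-strand rows are reversed so columns read 5'->3' of the element.
    Flank bins outside the chromosome are NaN.
    """
    if body % bin_size or flank % bin_size:
        raise ValueError("body and flank must be multiples of bin_size")
    n_flank = flank // bin_size
    n_body = body // bin_size
    n_cols = 2 * n_flank + n_body

    dense: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def chrom_arrays(chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in dense:
            size = (chrom_sizes or {}).get(chrom, track.chrom_extent(chrom))
            arr = track.per_base(chrom, size)
            dense[chrom] = (arr, np.concatenate([[0.0], np.cumsum(arr)]))
        return dense[chrom]

    ids, rows = [], []
    for el in elements:
        if el.length <= min_element_length:
            continue
        arr, cumsum = chrom_arrays(el.chrom)
        size = len(arr)
        row = np.empty(n_cols)
        # upstream flank (genomic left), fixed bins
        for k in range(n_flank):
            a = el.start - flank + k * bin_size
            b = a + bin_size
            row[k] = np.nan if (a < 0 or b > size) else _mean_over(cumsum, arr, a, b)
        # body, rescaled bins
        for k in range(n_body):
            a = el.start + k * el.length / n_body
            b = el.start + (k + 1) * el.length / n_body
            row[n_flank + k] = _mean_over(cumsum, arr, min(a, size), min(b, size)) \
                if b <= size else np.nan
        # downstream flank
        for k in range(n_flank):
            a = el.end + k * bin_size
            b = a + bin_size
            row[n_flank + n_body + k] = np.nan if (a < 0 or b > size) \
                else _mean_over(cumsum, arr, a, b)
        if el.strand == "-":
            row = row[::-1]
        ids.append(el.name)
        rows.append(row)

    values = np.array(rows, dtype=float) if rows else np.empty((0, n_cols))
    return ProfileMatrix(ids, values, bin_size, body, flank)


def boundary_enrichment(matrix: ProfileMatrix, window: int = 1000) -> dict[str, float]:
    """Per-element ratio of boundary signal to distal-flank signal.

    Boundary = bins within ``window`` bases on either side of each
    body/flank junction; distal = the outermost ``window`` of each flank.
    Elements with zero (or entirely missing) distal signal get NaN.
    """
    if window > matrix.flank:
        raise ValueError("window cannot exceed the flank length")
    w = max(1, window // matrix.bin_size)
    nf, nb = matrix.n_flank_bins, matrix.n_body_bins
    n_cols = matrix.values.shape[1]
    boundary_cols = np.r_[
        max(0, nf - w):min(n_cols, nf + min(w, nb)),
        max(nf, nf + nb - min(w, nb)):min(n_cols, nf + nb + w),
    ]
    distal_cols = np.r_[0:min(w, nf), n_cols - min(w, nf):n_cols]

    ratios: dict[str, float] = {}
    for eid, row in zip(matrix.element_ids, matrix.values):
        with np.errstate(invalid="ignore"):
            b = np.nanmean(row[boundary_cols])
            d = np.nanmean(row[distal_cols])
        ratios[eid] = float("nan") if (not np.isfinite(d) or d == 0) else float(b / d)
    return ratios
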