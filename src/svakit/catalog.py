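"""Non-reference transposon insertion calls: parsing, filtering, comparison.

Long-read insertion callers (TLDR-style) report, per candidate insertion, the
fraction of the inserted consensus covered by transposon sequence
(``UnmapCover``), the similarity of that sequence to the subfamily consensus
(``TEMatch``) and the number of reads spanning the event (``span-reads``).
High-confidence calls are obtained by thresholding those three quality fields
plus the insertion length; the conventional cutoffs are UnmapCover >= 80%,
TEMatch >= 80%, at least 3 spanning reads, and length strictly greater than
1 kbp.

The call's ``start`` is interpreted as the 0-based reference position *before*
which the consensus is inserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .io import BedRecord, FormatError, write_bed


@dataclass
class InsertionCall:
    """One TLDR-style non-reference insertion call."""

    chromosome: str
    start: int
    end: int
    subfamily: str
    consensus: str
    unmap_cover: float
    te_match: float
    span_reads: int
    sample_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(f"insertion start {self.start} > end {self.end}")
        if not self.consensus:
            raise FormatError("insertion with empty consensus sequence")
        for name, value in (("unmap_cover", self.unmap_cover), ("te_match", self.te_match)):
            if not 0.0 <= value <= 1.0:
                raise FormatError(f"{name}={value} outside [0, 1]")
        if self.span_reads < 0:
            raise FormatError("span_reads must be >= 0")

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class FilterThresholds:
    """Quality thresholds applied to insertion calls.

    Defaults are the conventional long-read insertion-call cutoffs:
    UnmapCover and TEMatch of at least 80%, a minimum of three spanning
    reads, and length strictly greater than 1 kbp.
    """

    min_unmap_cover: float = 0.80
    min_te_match: float = 0.80
    min_span_reads: int = 3
    min_length: int = 1000
    allowed_subfamilies: frozenset[str] = frozenset()

    def __post_init__(self):
        if min(self.min_unmap_cover, self.min_te_match, self.min_span_reads, self.min_length) < 0:
            raise ValueError("thresholds must be >= 0")


#: column-name aliases, matched case-insensitively after stripping ``_-. #``
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "chromosome": ("chromosome", "chrom", "chr", "seqname"),
    "start": ("start", "pos", "position"),
    "end": ("end", "stop"),
    "subfamily": ("subfamily", "family", "tefamily", "te"),
    "consensus": ("consensus", "seq", "sequence", "insseq"),
    "unmap_cover": ("unmapcover", "unmap_cover"),
    "te_match": ("tematch", "te_match"),
    "span_reads": ("spanreads", "span_reads", "span"),
    "sample_ids": ("sampleids", "samples", "sample", "samplereads"),
}

_MANDATORY = ("chromosome", "start", "end", "subfamily", "consensus",
              "unmap_cover", "te_match", "span_reads")


def _canon(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def _resolve_columns(columns, aliases) -> dict[str, str]:
    canon_to_real = {_canon(c): c for c in columns}
    mapping = {}
    for canonical, names in aliases.items():
        for name in names:
            if _canon(name) in canon_to_real:
                mapping[canonical] = canon_to_real[_canon(name)]
                break
    return mapping


def _as_fraction(value: float) -> float:
    """Accept a percentage column printed as either 0-1 or 0-100."""
    return value / 100.0 if value > 1.0 else value


def read_insertion_table(path, aliases: dict | None = None) -> list[InsertionCall]:
    """Read a TLDR-style tab-separated insertion table.

    Percentage columns are accepted on either the 0-1 or the 0-100 scale and
    normalized to fractions.  A missing mandatory column raises
    :class:`FormatError` naming the column; a non-numeric quality field raises
    :class:`FormatError` with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = _resolve_columns(df.columns, aliases or DEFAULT_ALIASES)
    for canonical in _MANDATORY:
        if canonical not in mapping:
            raise FormatError(f"insertion table is missing a '{canonical}' column")

    calls = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            unmap = _as_fraction(float(row[mapping["unmap_cover"]]))
            match = _as_fraction(float(row[mapping["te_match"]]))
            span = int(float(row[mapping["span_reads"]]))
            start = int(row[mapping["start"]])
            end = int(row[mapping["end"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric quality field on line {line_no}: {exc}") from None
        samples: frozenset[str] = frozenset()
        if "sample_ids" in mapping and isinstance(row[mapping["sample_ids"]], str):
            samples = frozenset(s for s in row[mapping["sample_ids"]].split(",") if s)
        calls.append(
            InsertionCall(
                chromosome=str(row[mapping["chromosome"]]),
                start=start,
                end=end,
                subfamily=str(row[mapping["subfamily"]]),
                consensus=str(row[mapping["consensus"]]),
                unmap_cover=unmap,
                te_match=match,
                span_reads=span,
                sample_ids=samples,
            )
        )
    return calls


def write_insertion_table(calls: list[InsertionCall], path) -> None:
    rows = [
        {
            "chromosome": c.chromosome,
            "start": c.start,
            "end": c.end,
            "subfamily": c.subfamily,
            "consensus": c.consensus,
            "UnmapCover": c.unmap_cover,
            "TEMatch": c.te_match,
            "span_reads": c.span_reads,
            "samples": ",".join(sorted(c.sample_ids)),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def passes(call: InsertionCall, thresholds: FilterThresholds) -> bool:
    if call.unmap_cover < thresholds.min_unmap_cover:
        return False
    if call.te_match < thresholds.min_te_match:
        return False
    if call.span_reads < thresholds.min_span_reads:
        return False
    if call.length <= thresholds.min_length:  # strictly greater than
        return False
    if thresholds.allowed_subfamilies and call.subfamily not in thresholds.allowed_subfamilies:
        return False
    return True


def filter_insertions(
    calls: list[InsertionCall], thresholds: FilterThresholds = FilterThresholds()
) -> list[InsertionCall]:
    """Keep calls satisfying every threshold, preserving input order."""
    return [c for c in calls if passes(c, thresholds)]


@dataclass
class SharedPrivatePartition:
    """Insertion events partitioned by presence across samples.

    Each event is the list of ``(sample, call)`` pairs grouped into it.
    """

    shared: list[list[tuple[str, InsertionCall]]]
    private: list[list[tuple[str, InsertionCall]]]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_private(self) -> int:
        return len(self.private)


def shared_and_private(
    calls_by_sample: dict[str, list[InsertionCall]], tolerance: int = 50
) -> SharedPrivatePartition:
    """Partition calls from several samples into shared and private events.

    Two calls in different samples are the same event iff they lie on the
    same chromosome, belong to the same subfamily and their starts differ by
    at most ``tolerance`` bases (breakpoint jitter of long-read calls).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    tagged = [
        (call.chromosome, call.subfamily, call.start, sample, call)
        for sample, calls in calls_by_sample.items()
        for call in calls
    ]
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))

    events: list[list[tuple[str, InsertionCall]]] = []
    prev_key = None
    for chrom, subfam, start, sample, call in tagged:
        if prev_key is not None and prev_key[:2] == (chrom, subfam) and start - prev_key[2] <= tolerance:
            events[-1].append((sample, call))
        else:
            events.append([(sample, call)])
        prev_key = (chrom, subfam, start)

    shared = [ev for ev in events if len({s for s, _ in ev}) >= 2]
    private = [ev for ev in events if len({s for s, _ in ev}) < 2]
    return SharedPrivatePartition(shared=shared, private=private)


def calls_to_bed(calls: list[InsertionCall]) -> list[BedRecord]:
    """Export calls as BED with the subfamily in the name field."""
    return [
        BedRecord(chrom=c.chromosome, start=c.start, end=c.end, name=c.subfamily)
        for c in calls
    ]


def write_calls_bed(calls: list[InsertionCall], path) -> None:
    write_bed(calls_to_bed(calls), path)
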