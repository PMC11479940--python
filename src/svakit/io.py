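"""Readers and writers for the plain-text genomic formats used throughout.

Every interval is 0-based half-open internally; GTF (1-based inclusive) is
converted to and from that convention at this boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not conform to the expected format."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED


@dataclass
class BedRecord:
    """One BED interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise FormatError(f"invalid BED interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line with fewer than 3 fields: {line!r}")
            rec = BedRecord(
                chrom=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
                name=parts[3] if len(parts) > 3 else ".",
                score=parts[4] if len(parts) > 4 else ".",
                strand=parts[5] if len(parts) > 5 else ".",
            )
            records.append(rec)
    return records


def write_bed(records: list[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class AnnotationRecord:
    """One GTF feature line (1-based, inclusive coordinates)."""

    chrom: str
    source: str
    feature: str
    start: int
    end: int
    score: str = "."
    strand: str = "."
    frame: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"invalid GTF interval {self.chrom}:{self.start}-{self.end} ({self.feature})"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def start0(self) -> int:
        """0-based inclusive start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end."""
        return self.end

    def attribute_text(self) -> str:
        return " ".join(f'{k} "{v}";' for k, v in self.attributes.items())


def parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path) -> list[AnnotationRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"GTF line with fewer than 9 fields: {line!r}")
            records.append(
                AnnotationRecord(
                    chrom=parts[0],
                    source=parts[1],
                    feature=parts[2],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    score=parts[5],
                    strand=parts[6],
                    frame=parts[7],
                    attributes=parse_gtf_attributes(parts[8]),
                )
            )
    return records


def write_gtf(records: list[AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.source}\t{r.feature}\t{r.start}\t{r.end}\t"
                f"{r.score}\t{r.strand}\t{r.frame}\t{r.attribute_text()}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path) -> dict[str, list[tuple[int, int, float]]]:
    """Read a bedGraph into ``{chrom: [(start, end, value), ...]}`` (sorted)."""
    track: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            track.setdefault(chrom, []).append((int(start), int(end), float(value)))
    for chrom in track:
        track[chrom].sort()
    return track


def write_bedgraph(track: dict[str, list[tuple[int, int, float]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in track:
            for start, end, value in track[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# generic tables


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
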