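"""Insertion-augmented genome construction and exact coordinate liftover.

A set of non-reference insertions is spliced into a reference genome with
insert-before semantics: an insertion at 0-based position ``p`` is placed
between bases ``p-1`` and ``p`` (equivalently, after the 1-based base ``p``).
The splice is recorded in a :class:`CoordinateMap`, a piecewise-offset
bidirectional mapping between reference and augmented coordinates, which also
drives annotation liftover: features wholly downstream of inserted bases are
shifted, features spanning an insertion point are stretched (the insertion
becomes internal to the feature — the situation of an intronic transposon
insertion), and features upstream are untouched.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, replace

from .io import AnnotationRecord

logger = logging.getLogger(__name__)


class AugmentError(ValueError):
    """Invalid insertion plan for the given genome."""


@dataclass(frozen=True)
class Insertion:
    """One planned insertion: ``sequence`` goes before 0-based ``position``."""

    chromosome: str
    position: int
    sequence: str
    label: str = "."


@dataclass
class ChromosomeMap:
    """Sorted splice records for one chromosome.

    ``entries[i] = (reference_breakpoint, cumulative_offset, inserted_length,
    label)`` where ``cumulative_offset`` is the total number of bases inserted
    at or before that breakpoint (prefix sums of the inserted lengths).
    """

    entries: list[tuple[int, int, int, str]]

    def __post_init__(self):
        breakpoints = [e[0] for e in self.entries]
        if breakpoints != sorted(set(breakpoints)):
            raise AugmentError("breakpoints must be strictly increasing")
        running = 0
        for bp, cum, length, _ in self.entries:
            running += length
            if cum != running:
                raise AugmentError("cumulative offsets must be prefix sums of lengths")

    @property
    def total_inserted(self) -> int:
        return self.entries[-1][1] if self.entries else 0

    def lift_point(self, position: int) -> int:
        """Reference -> augmented for a non-inserted 0-based position."""
        idx = bisect.bisect_right([e[0] for e in self.entries], position)
        return position + (self.entries[idx - 1][1] if idx else 0)

    def project_point(self, position: int):
        """Augmented -> reference.

        Returns ``(reference_position, status, label)`` where status is
        ``"unique"`` off inserted segments and ``"inside_insertion"`` (with
        the insertion's label, reference position = the insertion point)
        inside one.
        """
        offset_before = 0
        for bp, cum, length, label in self.entries:
            seg_start = bp + offset_before
            if position < seg_start:
                return position - offset_before, "unique", None
            if position < seg_start + length:
                return bp, "inside_insertion", label
            offset_before = cum
        return position - offset_before, "unique", None


@dataclass
class CoordinateMap:
    """Per-chromosome piecewise-offset maps for one augmentation."""

    chromosomes: dict[str, ChromosomeMap]

    def lift_point(self, chromosome: str, position: int) -> int:
        cmap = self.chromosomes.get(chromosome)
        return cmap.lift_point(position) if cmap else position

    def project_point(self, chromosome: str, position: int):
        cmap = self.chromosomes.get(chromosome)
        if cmap is None:
            return position, "unique", None
        return cmap.project_point(position)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\treference_breakpoint\tcumulative_offset\tinserted_length\tlabel\n")
            for chrom, cmap in self.chromosomes.items():
                for bp, cum, length, label in cmap.entries:
                    fh.write(f"{chrom}\t{bp}\t{cum}\t{length}\t{label}\n")

    @classmethod
    def from_tsv(cls, path) -> "CoordinateMap":
        chroms: dict[str, list] = {}
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                chrom, bp, cum, length, label = line.rstrip("\n").split("\t")
                chroms.setdefault(chrom, []).append((int(bp), int(cum), int(length), label))
        return cls({c: ChromosomeMap(sorted(v)) for c, v in chroms.items()})


def augment_genome(
    genome: dict[str, str], plan: list[Insertion]
) -> tuple[dict[str, str], CoordinateMap]:
    """Splice every planned insertion into the genome.

    The augmented sequence is independent of application order; insertions
    are validated (in bounds, at most one per position) and applied in a
    single linear pass per chromosome.
    """
    by_chrom: dict[str, list[Insertion]] = {}
    for ins in plan:
        if ins.chromosome not in genome:
            raise AugmentError(f"insertion {ins.label!r}: unknown chromosome {ins.chromosome!r}")
        length = len(genome[ins.chromosome])
        if not 0 <= ins.position <= length:
            raise AugmentError(
                f"insertion {ins.label!r} at {ins.chromosome}:{ins.position} "
                f"is outside [0, {length}]"
            )
        by_chrom.setdefault(ins.chromosome, []).append(ins)

    augmented: dict[str, str] = {}
    maps: dict[str, ChromosomeMap] = {}
    for chrom, seq in genome.items():
        insertions = sorted(by_chrom.get(chrom, []), key=lambda i: i.position)
        positions = [i.position for i in insertions]
        if len(set(positions)) != len(positions):
            dup = next(p for p in positions if positions.count(p) > 1)
            raise AugmentError(f"two insertions at {chrom}:{dup}")
        if not insertions:
            augmented[chrom] = seq
            continue
        pieces = []
        entries = []
        cursor = 0
        cumulative = 0
        for ins in insertions:
            pieces.append(seq[cursor:ins.position])
            pieces.append(ins.sequence)
            cursor = ins.position
            cumulative += len(ins.sequence)
            entries.append((ins.position, cumulative, len(ins.sequence), ins.label))
        pieces.append(seq[cursor:])
        augmented[chrom] = "".join(pieces)
        maps[chrom] = ChromosomeMap(entries)
    return augmented, CoordinateMap(maps)


def stitch_at_breakpoint(
    genome: dict[str, str], chromosome: str, breakpoint: int, insert: str, label: str = "stitch"
) -> tuple[dict[str, str], CoordinateMap]:
    """Concatenate ``chrom[1..breakpoint] + insert + chrom[breakpoint+1..end]``.

    ``breakpoint`` is the 1-based last base of the left segment, so this is
    a single insert-before splice at 0-based position ``breakpoint``.
    """
    if chromosome not in genome:
        raise AugmentError(f"unknown chromosome {chromosome!r}")
    if not 1 <= breakpoint < len(genome[chromosome]):
        raise AugmentError(
            f"breakpoint {breakpoint} outside [1, {len(genome[chromosome]) - 1}]"
        )
    return augment_genome(genome, [Insertion(chromosome, breakpoint, insert, label)])


def lift_annotation(
    records: list[AnnotationRecord], cmap: CoordinateMap
) -> list[AnnotationRecord]:
    """Lift 1-based GTF features onto the augmented genome.

    A feature upstream of all insertions is unchanged; one downstream of k
    inserted bases shifts by k; one spanning an insertion point keeps its
    (shifted) start and absorbs the internal insertion into its end.
    """
    lifted = []
    for rec in records:
        chrom_map = cmap.chromosomes.get(rec.chrom)
        if chrom_map is None:
            logger.warning("chromosome %s absent from coordinate map; %s feature passed through",
                           rec.chrom, rec.feature)
            lifted.append(replace(rec, attributes=dict(rec.attributes)))
            continue
        new_start = chrom_map.lift_point(rec.start0) + 1
        new_end = chrom_map.lift_point(rec.end0 - 1) + 1
        lifted.append(replace(rec, start=new_start, end=new_end,
                              attributes=dict(rec.attributes)))
    return lifted


def project_to_reference(cmap: CoordinateMap, chromosome: str, position: int):
    """Augmented -> reference projection for one 0-based position.

    Returns ``(reference_position, status, label)``; status is ``"unique"``
    off inserted segments and ``"inside_insertion"`` inside one, in which
    case the reference position is the insertion point.
    """
    if position < 0:
        raise AugmentError(f"position {position} out of range")
    return cmap.project_point(chromosome, position)
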