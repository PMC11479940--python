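"""Consensus building and noise-tolerant tandem-motif run estimation.

The hexamer head of an SVA is a tandem (CCCTCT)n run whose copy number is
clinically meaningful (it is polymorphic and inversely associated with age
at onset in X-linked dystonia parkinsonism).  Copy number is estimated from
a per-locus read consensus by aligning the sequence against an unbounded
tandem concatenation of the motif with a wraparound local dynamic program:
matches score +1 and every edit (substitution, insertion or deletion) costs
``(1 - max_noise) / max_noise``, so a segment attains a positive score
exactly when its edit-noise is below ``max_noise`` (the conventional noise
ceiling is 20%).  Matching is phase-agnostic — a run may begin and end at
any position within the motif — and partial terminal copies contribute
fractionally to the copy estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_SYMBOL_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}

#: a reported run must span at least this many motif copies
MIN_COPIES = 2.0


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# column-majority consensus


def column_consensus(alignment: list[str], min_depth: int = 1) -> str:
    """Plurality consensus of a gapped multiple alignment of reads.

    Per column, the plurality symbol among {A, C, G, T, -} is emitted; a
    plurality gap deletes the column (so the consensus incorporates
    deletions), columns covered by fewer than ``min_depth`` reads emit N,
    and ties break by the fixed order A < C < G < T < deletion.
    """
    if not alignment:
        raise AlignmentError("empty alignment")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    width = len(alignment[0])
    if any(len(read) != width for read in alignment):
        raise AlignmentError("aligned reads must all have equal length")

    out = []
    for col in range(width):
        counts: dict[str, int] = {}
        for read in alignment:
            sym = read[col].upper()
            if sym in _SYMBOL_ORDER:
                counts[sym] = counts.get(sym, 0) + 1
        depth = sum(counts.values())
        if depth < min_depth:
            out.append("N")
            continue
        winner = min(counts, key=lambda s: (-counts[s], _SYMBOL_ORDER[s]))
        if winner != "-":
            out.append(winner)
    return "".join(out)


# ---------------------------------------------------------------------------
# wraparound tandem-run finding


@dataclass
class RepeatRun:
    """One tandem-motif run on a sequence (0-based half-open coordinates)."""

    start: int
    end: int
    motif: str
    copy_estimate: float
    matches: int
    mismatches_plus_indels: int

    @property
    def identity(self) -> float:
        total = self.matches + self.mismatches_plus_indels
        return self.matches / total if total else float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start


def _best_wraparound_run(seq: str, motif: str, penalty: float):
    """Best-scoring local alignment of ``seq`` against cyclic ``motif``.

    Returns ``(score, start, end, matches, edits, consumed)`` where
    ``consumed`` counts motif positions spanned (copies * len(motif)), or
    ``None`` when no positive-scoring segment exists.  Deletion moves are
    resolved with two relaxation passes per row, which suffices because a
    full cycle of deletions is always score-decreasing.
    """
    n, m = len(seq), len(motif)
    NEG = float("-inf")
    # state per (i, j): score, start, matches, edits, consumed
    H = [[NEG] * m for _ in range(n + 1)]
    S = [[0] * m for _ in range(n + 1)]
    M = [[0] * m for _ in range(n + 1)]
    E = [[0] * m for _ in range(n + 1)]
    C = [[0] * m for _ in range(n + 1)]

    best = (0.0, 0, 0, 0, 0, 0)
    for i in range(1, n + 1):
        base = seq[i - 1]
        Hp, Sp, Mp, Ep, Cp = H[i - 1], S[i - 1], M[i - 1], E[i - 1], C[i - 1]
        Hi, Si, Mi, Ei, Ci = H[i], S[i], M[i], E[i], C[i]
        for j in range(m):
            jm1 = j - 1 if j else m - 1
            # diagonal (consume one seq base + one motif position), with
            # the option of starting a fresh run here
            prev = Hp[jm1]
            if prev > 0:
                fr_val, fr_s, fr_m, fr_e, fr_c = prev, Sp[jm1], Mp[jm1], Ep[jm1], Cp[jm1]
            else:
                fr_val, fr_s, fr_m, fr_e, fr_c = 0.0, i - 1, 0, 0, 0
            if base == motif[j]:
                val = fr_val + 1.0
                Hi[j], Si[j], Mi[j], Ei[j], Ci[j] = val, fr_s, fr_m + 1, fr_e, fr_c + 1
            else:
                val = fr_val - penalty
                Hi[j], Si[j], Mi[j], Ei[j], Ci[j] = val, fr_s, fr_m, fr_e + 1, fr_c + 1
            # insertion in the sequence (extra base, phase unchanged)
            if Hp[j] != NEG and Hp[j] - penalty > Hi[j]:
                Hi[j] = Hp[j] - penalty
                Si[j], Mi[j], Ei[j], Ci[j] = Sp[j], Mp[j], Ep[j] + 1, Cp[j]
        # deletions (skip motif positions) — two passes handle wraparound
        for _ in range(2):
            for j in range(m):
                jm1 = j - 1 if j else m - 1
                if Hi[jm1] != NEG and Hi[jm1] - penalty > Hi[j]:
                    Hi[j] = Hi[jm1] - penalty
                    Si[j], Mi[j], Ei[j], Ci[j] = Si[jm1], Mi[jm1], Ei[jm1] + 1, Ci[jm1] + 1
        for j in range(m):
            if Hi[j] > best[0]:
                best = (Hi[j], Si[j], i, Mi[j], Ei[j], Ci[j])
    if best[0] <= 0:
        return None
    score, start, end, matches, edits, consumed = best
    return score, start, end, matches, edits, consumed


def find_motif_run(
    sequence: str,
    motif: str,
    max_noise: float = 0.2,
    min_length: int = 0,
) -> list[RepeatRun]:
    """Find maximal tandem runs of ``motif`` with edit-noise below ``max_noise``.

    Runs are located by wraparound local alignment (unit edit costs), must
    span at least :data:`MIN_COPIES` motif copies and at least
    ``min_length`` bases, and are reported non-overlapping, 5'->3'.
    ``copy_estimate`` counts aligned motif positions divided by the motif
    length, so partial terminal copies count fractionally.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0 <= max_noise < 0.5:
        raise ValueError("max_noise must lie in [0, 0.5)")
    sequence = sequence.upper()
    motif = motif.upper()
    penalty = (1.0 - max_noise) / max_noise if max_noise > 0 else float("inf")

    m = len(motif)
    runs: list[RepeatRun] = []

    def search(seq: str, offset: int) -> None:
        if len(seq) < 2 * m:
            return
        hit = _best_wraparound_run(seq, motif, penalty)
        if hit is None:
            return
        _, start, end, matches, edits, consumed = hit
        if consumed / m >= MIN_COPIES and (end - start) >= min_length:
            runs.append(
                RepeatRun(
                    start=offset + start,
                    end=offset + end,
                    motif=motif,
                    copy_estimate=consumed / m,
                    matches=matches,
                    mismatches_plus_indels=edits,
                )
            )
        search(seq[:start], offset)
        search(seq[end:], offset + end)

    search(sequence, 0)
    runs.sort(key=lambda r: r.start)
    return runs


# ---------------------------------------------------------------------------
# hexamer reporting

HEXAMER_MOTIF = "CCCTCT"


@dataclass
class HexamerReport:
    consensus: str
    runs: list[RepeatRun]
    copies: int | None  # rounded copy count of the longest run; None if no run


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def hexamer_report(
    alignment: list[str],
    motif: str = HEXAMER_MOTIF,
    min_depth: int = 1,
    max_noise: float = 0.2,
    min_length: int = 0,
) -> HexamerReport:
    """Consensus + tandem-run estimation for one repeat locus.

    The headline copy count is the half-up-rounded copy estimate of the
    longest run (ties broken 5'-most); if no run is found, no count is
    fabricated.
    """
    consensus = column_consensus(alignment, min_depth=min_depth)
    runs = find_motif_run(consensus, motif, max_noise=max_noise, min_length=min_length)
    if not runs:
        return HexamerReport(consensus, [], None)
    longest = max(runs, key=lambda r: (r.length, -r.start))
    return HexamerReport(consensus, runs, round_half_up(longest.copy_estimate))
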