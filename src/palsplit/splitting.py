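"""Palindrome detection and recursive read splitting.

A read carrying a WGA palindrome aligns strongly to its own reverse
complement.  The correction procedure detects the best such alignment,
splits the read at the center of the palindrome, and recurses on both
halves until no detectable palindrome remains — so nested palindromes
(a fragment folded more than once) are resolved into all their copies.
No base is ever edited: the emitted and discarded fragments tile the
input read exactly.  Fragments shorter than a minimum length (default
50 bp) are discarded rather than emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import (
    FilterThresholds,
    ResourceLimitError,
    ScoringScheme,
    clean_sequence,
    passes_filters,
    reverse_complement,
    sw_align,
)
from .seqio import fragment_id

logger = logging.getLogger("palsplit")


@dataclass
class Read:
    """A sequence record with optional qualities and provenance.

    ``origin`` locates this sequence inside the original input read as
    ``(parent_id, start, end)`` with 0-based half-open coordinates; an
    unsplit input read has origin ``(id, 0, len(seq))``.
    """

    id: str
    seq: str
    qual: str | None = None
    origin: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if self.origin is None:
            self.origin = (self.id, 0, len(self.seq))
        pid, start, end = self.origin
        if end - start != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: origin interval [{start},{end}) does not "
                f"match sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CorrectionParams:
    """Parameters of the correction procedure.

    min_len
        Minimum emitted fragment length in bases; shorter fragments
        (including never-split short input reads) are discarded.
    max_iterations
        Safety cap on split events per input read.  Real read sets show up
        to ~15 splits per read; the cap only guards against pathological
        input.
    max_align_length
        Reads longer than this are passed through uncorrected with a
        warning (the alignment matrix is quadratic in read length).
    """

    min_len: int = 50
    max_iterations: int = 64
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    max_align_length: int = 100_000

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class CorrectionResult:
    """Outcome of correcting one input read.

    ``fragments`` and ``discarded`` are ordered left-to-right in input
    coordinates; their in-order concatenation reproduces the input
    sequence exactly.  ``iterations`` counts split events;
    ``split_positions`` records each split as ``((start, end), pos)`` in
    original-read coordinates.
    """

    input_id: str
    input_length: int
    fragments: list[Read] = field(default_factory=list)
    discarded: list[Read] = field(default_factory=list)
    iterations: int = 0
    split_positions: list[tuple[tuple[int, int], int]] = field(default_factory=list)

    @property
    def is_palindromic(self) -> bool:
        """True iff at least one split was performed."""
        return self.iterations >= 1

    def to_record(self) -> "CorrectionRecord":
        return CorrectionRecord(
            input_id=self.input_id,
            input_length=self.input_length,
            iterations=self.iterations,
            fragment_lengths=[len(r) for r in self.fragments],
            discarded_lengths=[len(r) for r in self.discarded],
            split_points=[pos for _iv, pos in self.split_positions],
        )


@dataclass(frozen=True)
class CorrectionRecord:
    """Length-level summary of one CorrectionResult (what the stats need)."""

    input_id: str
    input_length: int
    iterations: int
    fragment_lengths: list[int]
    discarded_lengths: list[int]
    split_points: list[int]


_RECORD_COLUMNS = ("read_id", "input_length", "iterations",
                   "fragment_lengths", "discarded_lengths", "split_points")


def write_records(records, path) -> None:
    """Per-read correction records as TSV (list fields comma-separated)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_RECORD_COLUMNS) + "\n")
        for rec in records:
            rec = rec.to_record() if hasattr(rec, "to_record") else rec
            fh.write(
                f"{rec.input_id}\t{rec.input_length}\t{rec.iterations}\t"
                f"{','.join(map(str, rec.fragment_lengths))}\t"
                f"{','.join(map(str, rec.discarded_lengths))}\t"
                f"{','.join(map(str, rec.split_points))}\n"
            )


def read_records(path) -> list[CorrectionRecord]:
    """Read back a record TSV written by :func:`write_records`."""
    def ints(cell: str) -> list[int]:
        return [int(x) for x in cell.split(",")] if cell else []

    records: list[CorrectionRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _RECORD_COLUMNS:
            raise ValueError(f"unrecognized record file header in {path}")
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            records.append(CorrectionRecord(
                input_id=cells[0], input_length=int(cells[1]),
                iterations=int(cells[2]), fragment_lengths=ints(cells[3]),
                discarded_lengths=ints(cells[4]), split_points=ints(cells[5]),
            ))
    return records


# ---------------------------------------------------------------------------
# Detection

def detect_split(read: Read, params: CorrectionParams | None = None) -> int | None:
    """Locate the palindrome center of *read*, or None if no palindrome.

    Aligns the read against its reverse complement.  If the best hit
    passes the filters, the target interval is mapped back to read
    coordinates (the second arm), and the split position is the floor
    midpoint of the union of the two arm intervals — n/2 for a perfect
    palindrome, the junction point for an embedded one.  The returned
    position always satisfies ``0 < pos < len(read)``; a degenerate
    boundary position is reported as "no split".
    """
    if params is None:
        params = CorrectionParams()
    n = len(read.seq)
    if n < 2:
        return None
    try:
        hit = sw_align(read.seq, reverse_complement(read.seq),
                       params.scoring, max_length=params.max_align_length)
    except ResourceLimitError as exc:
        logger.warning("read %s left uncorrected: %s", read.id, exc)
        return None
    if not passes_filters(hit, n, params.thresholds, params.scoring):
        return None
    # arm 1 is the query interval; arm 2 is the target interval mirrored
    # back onto the read: target position j corresponds to read position
    # n - 1 - j, so [t_start, t_end) maps to [n - t_end, n - t_start).
    lo = min(hit.q_start, n - hit.t_end)
    hi = max(hit.q_end, n - hit.t_start)
    pos = (lo + hi) // 2
    if pos <= 0 or pos >= n:
        return None
    return pos


def split_read(read: Read, pos: int) -> tuple[Read, Read]:
    """Split *read* into ``read[0:pos]`` and ``read[pos:]``.

    Qualities are split at the same position; origin intervals and ids
    stay in the coordinate frame of the original input read.
    """
    n = len(read.seq)
    if not 0 < pos < n:
        raise ValueError(f"split position {pos} outside (0, {n})")
    pid, start, _end = read.origin
    mid = start + pos
    left = Read(
        id=fragment_id(pid, start, mid),
        seq=read.seq[:pos],
        qual=read.qual[:pos] if read.qual is not None else None,
        origin=(pid, start, mid),
    )
    right = Read(
        id=fragment_id(pid, mid, _end),
        seq=read.seq[pos:],
        qual=read.qual[pos:] if read.qual is not None else None,
        origin=(pid, mid, _end),
    )
    return left, right


def correct_read(read: Read, params: CorrectionParams | None = None) -> CorrectionResult:
    """Recursively split *read* until no detectable palindrome remains.

    Depth-first, left child first; each leaf fragment is emitted if it is
    at least ``min_len`` bases long and discarded otherwise.  The
    concatenation of emitted plus discarded fragments, in input order,
    equals the input sequence byte for byte.
    """
    if params is None:
        params = CorrectionParams()
    result = CorrectionResult(input_id=read.id, input_length=len(read.seq))
    if len(read.seq) == 0:
        return result
    stack = [read]
    capped = False
    while stack:
        seg = stack.pop()
        pos = None
        if result.iterations < params.max_iterations:
            pos = detect_split(seg, params)
        elif not capped:
            capped = True
            logger.warning(
                "read %s: max_iterations=%d reached; emitting remaining "
                "fragments unsplit", read.id, params.max_iterations)
        if pos is None:
            if len(seg) >= params.min_len:
                result.fragments.append(seg)
            else:
                result.discarded.append(seg)
            continue
        result.iterations += 1
        _pid, start, end = seg.origin
        result.split_positions.append(((start, end), start + pos))
        left, right = split_read(seg, pos)
        stack.append(right)
        stack.append(left)
    result.fragments.sort(key=lambda r: r.origin[1])
    result.discarded.sort(key=lambda r: r.origin[1])
    return result


def correct_set(reads, params: CorrectionParams | None = None,
                strict_alphabet: bool = True, on_error: str = "abort"):
    """Apply :func:`correct_read` to a stream of reads.

    Yields ``(fragments, CorrectionResult)`` pairs in input order.
    ``on_error`` controls handling of malformed records: ``"abort"``
    re-raises, ``"skip"`` logs a warning and continues.
    """
    if params is None:
        params = CorrectionParams()
    for read in reads:
        try:
            cleaned = clean_sequence(read.seq, strict=strict_alphabet)
            if cleaned != read.seq:
                read = Read(read.id, cleaned, read.qual, read.origin)
            result = correct_read(read, params)
        except (ValueError, KeyError) as exc:
            if on_error == "skip":
                logger.warning("skipping malformed record %s: %s", read.id, exc)
                continue
            raise
        yield result.fragments, result
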