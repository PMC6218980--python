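"""Local alignment of a read against its reverse complement.

Artificial palindromes created during whole-genome amplification show up as
a read containing a fragment immediately followed by its own reverse
complement.  Such a read produces a strong Smith-Waterman local alignment
when aligned against its reverse-complement sequence; a plain read does
not.  This module provides the exact Smith-Waterman aligner (linear gap
model), the scoring scheme, and the hit filter that decides whether an
alignment constitutes a detectable palindrome.

The aligner is exact: it fills the full dynamic-programming matrix and
returns an optimal local alignment with a traceback.  Memory is quadratic
in sequence length, so a configurable cap (default 100 kb) guards against
runaway allocations on very long reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

logger = logging.getLogger("palsplit")

# ---------------------------------------------------------------------------
# Alphabet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

#: numeric codes: A=0 C=1 G=2 T=3 N=4.  N never matches anything (incl. N).
_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


class AlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T, N}."""


class ResourceLimitError(RuntimeError):
    """Sequence exceeds the configured alignment length cap."""


def clean_sequence(seq: str, strict: bool = True) -> str:
    """Uppercase *seq* and validate its alphabet.

    In strict mode any character outside {A,C,G,T,N} raises
    :class:`AlphabetError`; in lenient mode such characters are mapped to N.
    """
    up = seq.upper()
    if set(up) <= _VALID:
        return up
    bad = sorted(set(up) - _VALID)
    if strict:
        raise AlphabetError(
            f"sequence contains non-IUPAC characters {bad!r}; "
            "allowed alphabet is A, C, G, T, N (pass strict=False to map to N)"
        )
    return "".join(c if c in _VALID else "N" for c in up)


def reverse_complement(seq: str, strict: bool = True) -> str:
    """Reverse complement of a DNA sequence over {A,C,G,T,N}.

    N complements to N.  Applying the function twice returns the input
    (after uppercasing).
    """
    return clean_sequence(seq, strict=strict).translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an already-validated sequence as int8 codes for the DP kernel."""
    codes = _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise AlphabetError("sequence must be cleaned before encoding")
    return codes


# ---------------------------------------------------------------------------
# Parameters

@dataclass(frozen=True)
class ScoringScheme:
    """Smith-Waterman scoring parameters (linear gap model).

    Defaults are the settings used for palindrome detection in long
    error-rich reads: match +3, mismatch −4, gap −3 per gap column.
    """

    match: int = 3
    mismatch: int = -4
    gap: int = -3

    def __post_init__(self) -> None:
        if not (self.match > 0 and self.mismatch < 0 and self.gap < 0):
            raise ValueError(
                "require match > 0, mismatch < 0, gap < 0; got "
                f"match={self.match}, mismatch={self.mismatch}, gap={self.gap}"
            )


@dataclass(frozen=True)
class FilterThresholds:
    """Hit-acceptance thresholds for a self-vs-reverse-complement alignment.

    A hit is accepted only if it clears all five ratios (see
    :func:`passes_filters`).  With the defaults the operative criterion is
    ``score >= read_length`` (base_score 1.0); the four 0.01 thresholds are
    permissive guards.
    """

    filter_factor: float = 0.01
    query_coverage: float = 0.01
    query_identity: float = 0.01
    relative_score: float = 0.01
    base_score: float = 1.0

    def __post_init__(self) -> None:
        for name in ("filter_factor", "query_coverage", "query_identity",
                     "relative_score", "base_score"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LocalAlignment:
    """One best local alignment between a query and a target.

    Coordinates are 0-based half-open.  ``q_*`` index the query (the read),
    ``t_*`` the target (the read's reverse complement).  ``columns`` counts
    all alignment columns including gap columns; ``matches`` counts
    identical columns.  An empty alignment (no positive-scoring cell) has
    score 0 and columns 0.
    """

    score: int = 0
    q_start: int = 0
    q_end: int = 0
    t_start: int = 0
    t_end: int = 0
    matches: int = 0
    columns: int = 0
    #: CIGAR-like path of ('M'|'I'|'D') ops, one per column; 'M' consumes
    #: both sequences, 'I' the query only, 'D' the target only.
    path: str = field(default="", compare=False, repr=False)

    @property
    def is_empty(self) -> bool:
        return self.columns == 0


# ---------------------------------------------------------------------------
# DP kernel

@njit(cache=True)
def _sw_fill(q: np.ndarray, t: np.ndarray, match: int, mismatch: int,
             gap: int) -> np.ndarray:  # pragma: no cover - jitted
    n, m = q.shape[0], t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            if qi == t[j - 1] and qi < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] + mismatch
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            if best < 0:
                best = 0
            H[i, j] = best
    return H


def _traceback(H: np.ndarray, q: np.ndarray, t: np.ndarray, i: int, j: int,
               scoring: ScoringScheme) -> LocalAlignment:
    """Trace one optimal path ending at cell (i, j).

    Ties inside the path prefer diagonal, then up (gap in target), then
    left, which keeps the traceback deterministic.
    """
    ops: list[str] = []
    matches = 0
    end_i, end_j = i, j
    score = int(H[i, j])
    while H[i, j] > 0:
        h = H[i, j]
        is_match = q[i - 1] == t[j - 1] and q[i - 1] < 4
        sub = scoring.match if is_match else scoring.mismatch
        if i > 0 and j > 0 and H[i - 1, j - 1] + sub == h:
            ops.append("M")
            if is_match:
                matches += 1
            i -= 1
            j -= 1
        elif i > 0 and H[i - 1, j] + scoring.gap == h:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    return LocalAlignment(
        score=score, q_start=i, q_end=end_i, t_start=j, t_end=end_j,
        matches=matches, columns=len(ops), path="".join(ops),
    )


#: safety cap on the number of equal-scoring end cells examined for tie-break
_MAX_TIE_CELLS = 256


def sw_align(query: str, target: str, scoring: ScoringScheme | None = None,
             max_length: int = 100_000) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of *query* against *target*.

    Returns the best-scoring local alignment with a full traceback; a score
    of 0 is returned as an empty alignment.  N aligned to anything
    (including N) scores as a mismatch.  Among equal-scoring optima, the
    hit with the smallest ``q_start``, then smallest ``t_start``, is
    returned.

    Raises :class:`ResourceLimitError` if either sequence exceeds
    *max_length* — the DP matrix is quadratic in sequence length.
    """
    if scoring is None:
        scoring = ScoringScheme()
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    if len(query) > max_length or len(target) > max_length:
        raise ResourceLimitError(
            f"sequence length exceeds alignment cap of {max_length} bases "
            f"(query {len(query)}, target {len(target)}); the DP matrix is "
            "quadratic in read length"
        )
    q = encode(clean_sequence(query))
    t = encode(clean_sequence(target))
    H = _sw_fill(q, t, scoring.match, scoring.mismatch, scoring.gap)
    best = int(H.max())
    if best == 0:
        return LocalAlignment()
    ends = np.argwhere(H == best)
    hit: LocalAlignment | None = None
    for i, j in ends[:_MAX_TIE_CELLS]:
        cand = _traceback(H, q, t, int(i), int(j), scoring)
        key = (cand.q_start, cand.t_start, cand.q_end, cand.t_end)
        if hit is None or key < (hit.q_start, hit.t_start, hit.q_end, hit.t_end):
            hit = cand
    assert hit is not None
    return hit


def rescore_path(aln: LocalAlignment, query: str, target: str,
                 scoring: ScoringScheme) -> int:
    """Re-score an alignment's traceback path column by column.

    Used as a consistency check: the result must equal ``aln.score``.
    """
    q = clean_sequence(query)
    t = clean_sequence(target)
    i, j = aln.q_start, aln.t_start
    score = 0
    for op in aln.path:
        if op == "M":
            a, b = q[i], t[j]
            score += scoring.match if (a == b and a != "N") else scoring.mismatch
            i += 1
            j += 1
        elif op == "I":
            score += scoring.gap
            i += 1
        else:
            score += scoring.gap
            j += 1
    return score


# ---------------------------------------------------------------------------
# Hit filter

def passes_filters(hit: LocalAlignment, read_length: int,
                   thresholds: FilterThresholds | None = None,
                   scoring: ScoringScheme | None = None) -> bool:
    """Decide whether *hit* constitutes a detectable palindrome.

    All five criteria must hold:

    * ``score >= filter_factor * match * read_length`` — fraction of the
      maximum attainable score;
    * ``(q_end - q_start) / read_length >= query_coverage`` — aligned
      fraction of the read;
    * ``matches / columns >= query_identity`` — identical fraction of
      aligned columns;
    * ``score / columns >= relative_score`` — score per alignment column;
    * ``score / read_length >= base_score`` — score per read base.

    Empty alignments always fail.  With the default thresholds the last
    criterion (base_score 1.0) is the operative one: a hit must score at
    least the read length, which random non-palindromic reads essentially
    never reach.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    if scoring is None:
        scoring = ScoringScheme()
    if hit.columns == 0 or read_length <= 0:
        return False
    if hit.score < thresholds.filter_factor * scoring.match * read_length:
        return False
    if (hit.q_end - hit.q_start) / read_length < thresholds.query_coverage:
        return False
    if hit.matches / hit.columns < thresholds.query_identity:
        return False
    if hit.score / hit.columns < thresholds.relative_score:
        return False
    if hit.score / read_length < thresholds.base_score:
        return False
    return True
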