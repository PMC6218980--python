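"""Simulation of WGA-like palindromic chimeric reads with ground truth.

During whole-genome amplification the polymerase can re-elongate along an
already synthesized product, yielding a fragment immediately followed by
its own reverse complement; repeated events nest, so k full-length folds
produce 2^k copies of the original fragment.  The simulator models this
as a fold operator (prefix + reverse complement of the prefix) applied to
random templates, followed by an indel-rich long-read error model.  Every
simulated read is paired with its ground truth (fold points, arm
intervals, and the true split targets projected through the error-model
coordinate map), so detection and splitting are testable end to end
without any external data.

Default error rates (substitution 0.01, insertion 0.08, deletion 0.03,
~12% total, indel-dominated) emulate early PacBio chemistry; long-read
error rates of 11–38% have been reported, and all rates are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .align import reverse_complement
from .splitting import CorrectionResult, Read

_BASES = "ACGT"


@dataclass(frozen=True)
class ErrorModel:
    """Per-base independent error model with a fixed RNG seed.

    Each template base is deleted with probability ``del_rate``,
    substituted (to a different base) with probability ``sub_rate``, and
    followed by a random inserted base with probability ``ins_rate``.
    Identical seeds give identical output.
    """

    sub_rate: float = 0.01
    ins_rate: float = 0.08
    del_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sub_rate + self.del_rate > 1:
            raise ValueError("sub_rate + del_rate must be <= 1 "
                             "(they are exclusive per-base events)")

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass
class SimTruth:
    """Ground truth for one simulated read.

    fold_points
        Breakpoint of each folding event, in pre-error coordinates (the
        k-th full-length fold has breakpoint 2^(k-1) × template length).
    arm_intervals
        Intervals covering the chimera's copies; k full-length folds give
        2^k intervals tiling the pre-error read.
    true_splits_posterror
        All internal arm boundaries projected through the error-model
        coordinate map — the positions a perfect correction would split
        at.  For a single fold this is the projected fold point.
    """

    template_id: str
    fold_points: list[int] = field(default_factory=list)
    arm_intervals: list[tuple[int, int]] = field(default_factory=list)
    true_splits_posterror: list[int] = field(default_factory=list)
    is_palindromic: bool = False


def random_template(length: int, gc: float = 0.5,
                    rng: np.random.Generator | int | None = None) -> str:
    """I.i.d. random DNA of *length* bases with P(G) + P(C) = *gc*."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])


def fold(seq: str, breakpoint: int | None = None) -> str:
    """One polymerase re-elongation event: prefix + rc(prefix).

    With *breakpoint* b (default: full length), returns
    ``seq[:b] + reverse_complement(seq[:b])`` — a perfect palindrome of
    length 2b.  Repeated full-length folds nest, producing 2^k copies of
    the original fragment.
    """
    if breakpoint is None:
        breakpoint = len(seq)
    if not 1 <= breakpoint <= len(seq):
        raise ValueError(f"breakpoint {breakpoint} outside [1, {len(seq)}]")
    prefix = seq[:breakpoint]
    return prefix + reverse_complement(prefix)


def apply_errors(seq: str, model: ErrorModel,
                 rng: np.random.Generator | None = None) -> tuple[str, list[int]]:
    """Mutate *seq* under *model*; return (mutated, coordinate map).

    The coordinate map is a monotone list of length ``len(seq) + 1``
    projecting pre-error positions onto the mutated sequence:
    ``cmap[0] == 0`` and ``cmap[len(seq)]`` equals the output length.
    Insertions land after the base they follow; substitutions always
    change the base.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    out: list[str] = []
    cmap: list[int] = []
    n = len(seq)
    # one uniform draw decides delete/substitute/keep; an independent draw
    # decides a trailing insertion
    events = rng.random(n)
    ins = rng.random(n) < model.ins_rate
    for i, base in enumerate(seq):
        cmap.append(len(out))
        u = events[i]
        if u < model.del_rate:
            pass
        elif u < model.del_rate + model.sub_rate:
            choices = [b for b in _BASES if b != base]
            out.append(choices[rng.integers(3)] if base in _BASES else
                       _BASES[rng.integers(4)])
        else:
            out.append(base)
        if ins[i]:
            out.append(_BASES[rng.integers(4)])
    cmap.append(len(out))
    return "".join(out), cmap


def simulate_readset(
    n_reads: int,
    palindromic_fraction: float = 0.5,
    template_length: int = 500,
    folds: int = 1,
    model: ErrorModel | None = None,
    gc: float = 0.5,
) -> tuple[list[Read], list[SimTruth]]:
    """Simulate a read population with a known palindromic fraction.

    Exactly ``round(n_reads * palindromic_fraction)`` reads are chimeric
    (each built by *folds* full-length fold events on its own random
    template); the rest are plain error-laden templates.  Which indices
    are chimeric is a seeded permutation, so the assignment is
    deterministic per seed.  Returns parallel lists of reads and truths.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if model is None:
        model = ErrorModel()
    rng = np.random.default_rng(model.seed)
    n_pal = round(n_reads * palindromic_fraction)
    pal_idx = set(rng.permutation(n_reads)[:n_pal].tolist())
    reads: list[Read] = []
    truths: list[SimTruth] = []
    for i in range(n_reads):
        rid = f"sim_{i:05d}"
        template = random_template(template_length, gc, rng)
        truth = SimTruth(template_id=rid)
        seq = template
        if i in pal_idx:
            truth.is_palindromic = True
            for _ in range(folds):
                truth.fold_points.append(len(seq))
                seq = fold(seq)
            n_arms = 2 ** folds
            arm = template_length
            truth.arm_intervals = [(k * arm, (k + 1) * arm) for k in range(n_arms)]
        else:
            truth.arm_intervals = [(0, template_length)]
        mutated, cmap = apply_errors(seq, model, rng)
        if truth.is_palindromic:
            arm = template_length
            truth.true_splits_posterror = [
                cmap[k * arm] for k in range(1, 2 ** folds)
            ]
        reads.append(Read(id=rid, seq=mutated))
        truths.append(truth)
    return reads, truths


def write_truth(truths: Iterable[SimTruth], path: str | Path) -> None:
    """Tab-separated ground-truth table: one row per simulated read."""
    with open(path, "w") as fh:
        fh.write("read_id\tis_palindromic\tfold_points\ttrue_splits_posterror\n")
        for t in truths:
            fh.write(
                f"{t.template_id}\t{int(t.is_palindromic)}\t"
                f"{','.join(map(str, t.fold_points))}\t"
                f"{','.join(map(str, t.true_splits_posterror))}\n"
            )


@dataclass
class EvaluationReport:
    """Read-level detection and split-position accuracy on a simulation.

    ``precision`` is None (reported "n/a") when no read was flagged.
    ``split_recall`` is the fraction of true post-error split points with
    some predicted split within ±tolerance bases.
    """

    n_reads: int
    n_true_palindromic: int
    true_positives: int
    false_positives: int
    false_negatives: int
    n_true_splits: int
    n_matched_splits: int
    tolerance: int

    @property
    def precision(self) -> float | None:
        flagged = self.true_positives + self.false_positives
        return self.true_positives / flagged if flagged else None

    @property
    def recall(self) -> float:
        return (self.true_positives / self.n_true_palindromic
                if self.n_true_palindromic else 0.0)

    @property
    def false_positive_rate(self) -> float:
        n_neg = self.n_reads - self.n_true_palindromic
        return self.false_positives / n_neg if n_neg else 0.0

    @property
    def split_recall(self) -> float:
        return (self.n_matched_splits / self.n_true_splits
                if self.n_true_splits else 0.0)


def evaluate(results: Sequence[CorrectionResult], truths: Sequence[SimTruth],
             tolerance: int = 10) -> EvaluationReport:
    """Score correction results against simulation ground truth.

    Results and truths must be aligned by read id; a mismatch is an
    error.  A read counts as flagged iff at least one split was
    performed; a true split point is matched if some predicted split lies
    within ±tolerance bases of it.
    """
    if len(results) != len(truths):
        raise ValueError(
            f"{len(results)} results vs {len(truths)} truths")
    tp = fp = fn = 0
    n_true_splits = n_matched = 0
    for res, truth in zip(results, truths):
        if res.input_id != truth.template_id:
            raise ValueError(
                f"id mismatch: result {res.input_id!r} vs truth "
                f"{truth.template_id!r}")
        flagged = res.is_palindromic
        if truth.is_palindromic and flagged:
            tp += 1
        elif truth.is_palindromic:
            fn += 1
        elif flagged:
            fp += 1
        predicted = [pos for _iv, pos in res.split_positions]
        for true_pos in truth.true_splits_posterror:
            n_true_splits += 1
            if any(abs(p - true_pos) <= tolerance for p in predicted):
                n_matched += 1
    return EvaluationReport(
        n_reads=len(results),
        n_true_palindromic=tp + fn,
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        n_true_splits=n_true_splits,
        n_matched_splits=n_matched,
        tolerance=tolerance,
    )
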