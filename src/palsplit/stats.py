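"""Read-set summaries: correction statistics, GC profile, reports.

Desk-scale analogs of the summaries one reports for a palindrome
correction run: how many reads carried detectable palindromes, average
read lengths before and after correction, how many fragments were
discarded, and the distribution of split iterations per read.  The GC
profile lets one verify that splitting reads leaves the base composition
of the set unchanged (correction removes no information, it only cuts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("palsplit")


@dataclass
class SummaryStats:
    """Aggregate statistics of one correction run.

    ``mean_len_out`` averages over emitted reads only (discarded
    fragments are excluded, as in the usual before/after tables).
    """

    n_reads_in: int = 0
    mean_len_in: float = 0.0
    n_reads_with_palindromes: int = 0
    pct_with_palindromes: float = 0.0
    n_reads_out: int = 0
    mean_len_out: float = 0.0
    n_discarded: int = 0
    iteration_histogram: dict[int, int] = field(default_factory=dict)


def summarize_correction(records: Sequence) -> SummaryStats:
    """Aggregate per-read correction records into a SummaryStats.

    Accepts :class:`~palsplit.splitting.CorrectionResult` objects or the
    length-level :class:`~palsplit.splitting.CorrectionRecord` rows read
    back from a record TSV.  A read counts as "with palindromes" iff at
    least one split was performed (iterations >= 1).  An empty record
    list yields all-zero stats.
    """
    stats = SummaryStats()
    in_lengths: list[int] = []
    out_lengths: list[int] = []
    for rec in records:
        rec = rec.to_record() if hasattr(rec, "to_record") else rec
        stats.n_reads_in += 1
        in_lengths.append(rec.input_length)
        if rec.iterations >= 1:
            stats.n_reads_with_palindromes += 1
        out_lengths.extend(rec.fragment_lengths)
        stats.n_discarded += len(rec.discarded_lengths)
        stats.iteration_histogram[rec.iterations] = (
            stats.iteration_histogram.get(rec.iterations, 0) + 1)
    stats.n_reads_out = len(out_lengths)
    if in_lengths:
        stats.mean_len_in = float(np.mean(in_lengths))
        stats.pct_with_palindromes = (
            100.0 * stats.n_reads_with_palindromes / stats.n_reads_in)
    if out_lengths:
        stats.mean_len_out = float(np.mean(out_lengths))
    return stats


def gc_fraction(seq: str) -> float | None:
    """GC fraction of one sequence, excluding N from both numerator and
    denominator; None for an all-N (or empty) sequence."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return None
    return (seq.count("G") + seq.count("C")) / acgt


def gc_profile(reads: Iterable, n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Binned density of per-read GC fractions over [0, 1].

    Returns ``(bin_edges, masses)`` with ``masses.sum() == 1`` (unless no
    read had a defined GC fraction).  All-N reads are excluded with a
    warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    fractions = []
    for read in reads:
        frac = gc_fraction(read.seq)
        if frac is None:
            logger.warning("read %s has no A/C/G/T bases; excluded from "
                           "GC profile", read.id)
            continue
        fractions.append(frac)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(fractions, bins=edges)
    total = counts.sum()
    masses = counts / total if total else counts.astype(float)
    return edges, masses


def write_report(stats: SummaryStats, path: str | Path) -> None:
    """Write *stats* in JSON and TSV form.

    *path* is a base path: ``{path}.json`` and ``{path}.tsv`` are
    written (an existing ``.json``/``.tsv`` suffix is stripped first).
    Field names are exactly the SummaryStats names; histogram keys are
    serialized sorted ascending.
    """
    base = Path(path)
    if base.suffix in {".json", ".tsv"}:
        base = base.with_suffix("")
    hist = {str(k): stats.iteration_histogram[k]
            for k in sorted(stats.iteration_histogram)}
    payload = {
        "n_reads_in": stats.n_reads_in,
        "mean_len_in": stats.mean_len_in,
        "n_reads_with_palindromes": stats.n_reads_with_palindromes,
        "pct_with_palindromes": stats.pct_with_palindromes,
        "n_reads_out": stats.n_reads_out,
        "mean_len_out": stats.mean_len_out,
        "n_discarded": stats.n_discarded,
        "iteration_histogram": hist,
    }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    with open(base.with_suffix(".tsv"), "w") as fh:
        for key, value in payload.items():
            if key == "iteration_histogram":
                value = ",".join(f"{k}:{v}" for k, v in hist.items())
            fh.write(f"{key}\t{value}\n")


def read_report(path: str | Path) -> SummaryStats:
    """Read back a JSON report written by :func:`write_report`."""
    base = Path(path)
    if base.suffix != ".json":
        base = base.with_suffix(".json")
    with open(base) as fh:
        payload = json.load(fh)
    hist = {int(k): v for k, v in payload.pop("iteration_histogram").items()}
    return SummaryStats(iteration_histogram=hist, **payload)
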