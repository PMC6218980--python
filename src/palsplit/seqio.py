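"""Streaming FASTA/FASTQ readers and writers, plus fragment naming.

Parsing and formatting are delegated to Biopython's SeqIO; this module
adds format auto-detection, transparent gzip by extension, uppercasing on
ingest, and the provenance-preserving fragment-id convention
``{parent_id}:{start}-{end}`` (0-based half-open coordinates, always in
the frame of the original input read, so nested splits never nest
suffixes).
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .splitting import Read

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn", ".mfa"}
_FASTQ_EXT = {".fq", ".fastq"}

#: Sanger / Phred+33 quality encoding
_PHRED_OFFSET = 33


class SeqFormatError(ValueError):
    """Malformed or unrecognizable sequence file."""


def detect_format(path: str | Path) -> str:
    """Return ``"fasta"`` or ``"fastq"`` for *path*.

    Decided by extension where possible (``.gz`` is stripped first),
    otherwise by sniffing the first non-blank character of the content
    ('>' FASTA, '@' FASTQ).
    """
    p = Path(path)
    suffixes = [s.lower() for s in p.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes:
        if suffixes[-1] in _FASTA_EXT:
            return "fasta"
        if suffixes[-1] in _FASTQ_EXT:
            return "fastq"
    with _open_text(p, "rt") as fh:
        for line in fh:
            if line.strip():
                if line[0] == ">":
                    return "fasta"
                if line[0] == "@":
                    return "fastq"
                break
    raise SeqFormatError(f"cannot determine sequence format of {p}")


def _open_text(path: str | Path, mode: str) -> io.TextIOBase:
    p = Path(path)
    if p.suffix.lower() == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def read_seqs(path: str | Path, fmt: str | None = None) -> Iterator["Read"]:
    """Yield :class:`~palsplit.splitting.Read` records from a file.

    Sequences are uppercased on ingest; FASTQ qualities are carried as
    Phred+33 strings.  Records are yielded in file order.  A malformed
    FASTQ record raises :class:`SeqFormatError` naming the record.
    """
    from .splitting import Read

    if fmt is None:
        fmt = detect_format(path)
    with _open_text(path, "rt") as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                seq = str(rec.seq).upper()
                qual = None
                if fmt == "fastq":
                    phred = rec.letter_annotations["phred_quality"]
                    qual = "".join(chr(q + _PHRED_OFFSET) for q in phred)
                yield Read(id=rec.id, seq=seq, qual=qual)
        except ValueError as exc:
            raise SeqFormatError(f"malformed {fmt} record in {path}: {exc}") from exc


def write_seqs(reads: Iterable["Read"], path: str | Path,
               fmt: str | None = None, fill_quality: str | None = None) -> int:
    """Write reads to *path*; returns the number of records written.

    Format defaults to the extension of *path*.  Writing FASTQ from
    quality-less reads raises unless *fill_quality* gives a constant
    quality character to use.  Round-trip stable with :func:`read_seqs`.
    """
    if fmt is None:
        fmt = detect_format_for_write(path)
    count = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.seq), id=read.id, description="")
            if fmt == "fastq":
                qual = read.qual
                if qual is None:
                    if fill_quality is None:
                        raise SeqFormatError(
                            f"read {read.id!r} has no qualities; cannot write "
                            "FASTQ without a fill-quality character"
                        )
                    qual = fill_quality * len(read.seq)
                rec.letter_annotations["phred_quality"] = [
                    ord(c) - _PHRED_OFFSET for c in qual
                ]
            SeqIO.write(rec, fh, fmt)
            count += 1
    return count


def detect_format_for_write(path: str | Path) -> str:
    """Like :func:`detect_format` but by extension only (file may not exist)."""
    p = Path(path)
    suffixes = [s.lower() for s in p.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes:
        if suffixes[-1] in _FASTA_EXT:
            return "fasta"
        if suffixes[-1] in _FASTQ_EXT:
            return "fastq"
    raise SeqFormatError(f"cannot determine output format from extension of {p}")


def fragment_id(parent_id: str, start: int, end: int) -> str:
    """Provenance-preserving fragment identifier.

    ``{parent_id}:{start}-{end}`` with 0-based half-open coordinates in
    the original input read.  Because coordinates always refer to the
    original frame, nested splits compose flatly instead of nesting
    suffixes.
    """
    if not 0 <= start < end:
        raise ValueError(f"invalid fragment interval [{start}, {end})")
    return f"{parent_id}:{start}-{end}"


def parse_fragment_id(frag_id: str) -> tuple[str, int, int]:
    """Inverse of :func:`fragment_id` (used for conservation checks)."""
    head, _, coords = frag_id.rpartition(":")
    start_s, _, end_s = coords.partition("-")
    try:
        return head, int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"not a fragment id: {frag_id!r}") from exc
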