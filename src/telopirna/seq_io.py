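"""Small-RNA sequence I/O: adapter clipping, length filtering, read collapsing.

Small-RNA libraries arrive as FASTQ/FASTA of raw reads that still carry the
3' sequencing adapter.  The preprocessing contract is: clip the adapter
(leftmost match wins), keep reads of at least 19 nt, and collapse identical
sequences into one record with a multiplicity.  The *total* number of reads
entering the library (the sum of multiplicities) is kept as the
reads-per-million normalization denominator for every downstream statistic.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "InputError",
    "SmallRNARead",
    "Library",
    "clip_adapter",
    "length_filter",
    "collapse",
    "read_sequences",
    "preprocess",
    "write_collapsed_fasta",
    "length_histogram",
]

DNA_ALPHABET = frozenset("ACGTN")

#: Minimum retained read length after clipping ("> 18 nt" filter).
MIN_LENGTH = 19
#: Cloning band of the libraries this pipeline models (19-29 nt); reads
#: longer than the band are kept in the Library but flagged downstream.
MAX_BAND_LENGTH = 29


class InputError(ValueError):
    """Invalid user input (bad sequence characters, impossible config...)."""


@dataclass(frozen=True)
class SmallRNARead:
    """A clipped, length-filtered read with collapse multiplicity."""

    read_id: str
    seq: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if set(self.seq) - DNA_ALPHABET:
            raise InputError(f"non-ACGTN characters in read {self.read_id!r}")
        if self.multiplicity < 1:
            raise InputError("multiplicity must be >= 1")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def in_band(self) -> bool:
        """True if the read lies in the 19-29 nt cloning band."""
        return MIN_LENGTH <= self.length <= MAX_BAND_LENGTH


@dataclass
class Library:
    """Collapsed read set plus the RPM normalization denominator.

    ``total_reads`` is the number of sequenced reads *before* mapping
    (sum of multiplicities), the denominator for per-million scaling.
    """

    reads: list[SmallRNARead]
    total_reads: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_reads != sum(r.multiplicity for r in self.reads):
            raise InputError("total_reads must equal the sum of multiplicities")
        if self.reads and self.total_reads <= 0:
            raise InputError("total_reads must be positive")

    def by_id(self) -> dict[str, SmallRNARead]:
        return {r.read_id: r for r in self.reads}


def _mismatches(a: str, b: str) -> int:
    # N never matches anything, including another N.
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def clip_adapter(
    raw_seq: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> str | None:
    """Remove a 3' adapter; return the insert, or None if no match is found.

    A match is a prefix of the adapter aligned at offset ``i`` of the read,
    covering ``min(len(adapter), len(raw_seq) - i)`` bases, with at least
    ``min_overlap`` bases overlapping and a mismatch fraction at most
    ``max_mismatch_rate``.  The leftmost matching offset wins and the read
    prefix before it is returned (possibly empty).  N counts as a mismatch.
    """
    if not adapter:
        raise InputError("adapter must be non-empty")
    if min_overlap < 4:
        raise InputError("min_overlap must be >= 4")
    raw_seq = raw_seq.upper()
    adapter = adapter.upper()
    if set(raw_seq) - DNA_ALPHABET or set(adapter) - DNA_ALPHABET:
        raise InputError("non-ACGTN characters in read or adapter")
    n = len(raw_seq)
    for i in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - i)
        if overlap < min_overlap:
            break
        mm = _mismatches(raw_seq[i : i + overlap], adapter[:overlap])
        if mm <= max_mismatch_rate * overlap:
            return raw_seq[:i]
    return None


def length_filter(
    reads: Iterable[SmallRNARead], min_length: int = MIN_LENGTH
) -> list[SmallRNARead]:
    """Keep reads with length >= ``min_length`` (default 19, i.e. > 18 nt).

    No upper bound is applied here; the piRNA/siRNA class partition happens
    in the statistics layer.
    """
    return [r for r in reads if r.length >= min_length]


def collapse(reads: Iterable[SmallRNARead], metadata: dict | None = None) -> Library:
    """Merge identical sequences, summing multiplicities.

    Collapsed ids are ``seq<k>`` in order of first appearance; the incoming
    total read count (sum of multiplicities) is conserved as
    ``Library.total_reads``.
    """
    counts: Counter[str] = Counter()
    order: list[str] = []
    for r in reads:
        if r.seq not in counts:
            order.append(r.seq)
        counts[r.seq] += r.multiplicity
    collapsed = [
        SmallRNARead(read_id=f"seq{k}", seq=s, multiplicity=counts[s])
        for k, s in enumerate(order)
    ]
    return Library(
        reads=collapsed,
        total_reads=sum(counts.values()),
        metadata=dict(metadata or {}),
    )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: Path) -> Literal["fastq", "fasta"]:
    name = path.name[: -len(".gz")] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    raise InputError(f"cannot infer sequence format from {path.name!r}")


def read_sequences(path: str | Path) -> Iterator[SmallRNARead]:
    """Stream reads from FASTA/FASTQ (optionally gzipped).

    Qualities are parsed but ignored.  A trailing ``_xN`` in the record id is
    interpreted as a collapse multiplicity (the conventional collapsed-FASTA
    encoding), so collapsed files round-trip.
    """
    path = Path(path)
    fmt = _sniff_format(path)
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            mult = 1
            rid = rec.id
            if "_x" in rid:
                stem, _, tail = rid.rpartition("_x")
                if tail.isdigit():
                    rid, mult = stem, int(tail)
            yield SmallRNARead(read_id=rid, seq=str(rec.seq).upper(), multiplicity=mult)


def preprocess(
    raw_seqs: Iterable[tuple[str, str]],
    adapter: str | None,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    unclipped_policy: Literal["drop", "keep"] = "drop",
    min_length: int = MIN_LENGTH,
    metadata: dict | None = None,
) -> Library:
    """Clip -> length-filter -> collapse a stream of ``(id, sequence)`` pairs.

    With ``adapter=None`` reads are assumed pre-clipped.  ``unclipped_policy``
    controls reads in which the adapter is not found: ``"drop"`` (default;
    the libraries modelled here were fully adapter-clipped) or ``"keep"``.
    """
    kept: list[SmallRNARead] = []
    for rid, seq in raw_seqs:
        seq = seq.upper()
        if adapter is not None:
            insert = clip_adapter(seq, adapter, min_overlap, max_mismatch_rate)
            if insert is None:
                if unclipped_policy == "drop":
                    continue
                insert = seq
            seq = insert
        if len(seq) >= min_length:
            kept.append(SmallRNARead(read_id=rid, seq=seq))
    return collapse(kept, metadata=metadata)


def write_collapsed_fasta(library: Library, path: str | Path) -> None:
    """Write collapsed reads as FASTA with the ``>id_xN`` multiplicity tag."""
    with open(path, "wt") as out:
        for r in library.reads:
            out.write(f">{r.read_id}_x{r.multiplicity}\n{r.seq}\n")


def length_histogram(library: Library) -> pd.DataFrame:
    """Multiplicity-weighted read-length histogram as a tidy table."""
    counts: Counter[int] = Counter()
    for r in library.reads:
        counts[r.length] += r.multiplicity
    rows = [{"length": k, "count": counts[k]} for k in sorted(counts)]
    return pd.DataFrame(rows, columns=["length", "count"])
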