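"""Ungapped, strand-aware short-read alignment with a small mismatch budget.

Reads are placed on every reference at every offset on both strands and a
hit is reported wherever the Hamming distance is within the budget k
(0 <= k <= 3).  Minus-strand placements compare the reverse complement of
the read against the reference plus strand; the hit's ``five_prime_pos`` is
then the *end* of the interval minus one, because the biological 5' end of
a minus-strand read sits at the right edge of its plus-strand footprint.

The implementation vectorizes the scan with numpy sliding windows, but its
semantics are exactly the exhaustive per-offset Hamming comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seq_io import InputError, Library, SmallRNARead

__all__ = [
    "Reference",
    "ReferenceSet",
    "AlignmentHit",
    "revcomp",
    "map_read",
    "map_library",
    "classify_uniqueness",
    "assign_weights",
    "mapping_summary",
    "hits_to_bed",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Encoding: read N -> 4, reference N -> 5, so N never matches anything.
_READ_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_REF_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str, code: Mapping[str, int]) -> np.ndarray:
    try:
        return np.fromiter((code[c] for c in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:
        raise InputError(f"non-ACGTN character {exc.args[0]!r} in sequence") from exc


@dataclass(frozen=True)
class Reference:
    ref_id: str
    seq: str
    kind: Literal["telomeric_element", "transgene", "control"] = "telomeric_element"

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputError(f"reference {self.ref_id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


class ReferenceSet:
    """Ordered set of references with cached numeric encodings."""

    def __init__(self, references: Iterable[Reference]):
        self.references: dict[str, Reference] = {}
        self._encoded: dict[str, np.ndarray] = {}
        for ref in references:
            if ref.ref_id in self.references:
                raise InputError(f"duplicate ref_id {ref.ref_id!r}")
            self.references[ref.ref_id] = ref
            self._encoded[ref.ref_id] = _encode(ref.seq.upper(), _REF_CODE)
        if not self.references:
            raise InputError("empty ReferenceSet")

    def __iter__(self):
        return iter(self.references.values())

    def __getitem__(self, ref_id: str) -> Reference:
        return self.references[ref_id]

    def __len__(self) -> int:
        return len(self.references)

    def encoded(self, ref_id: str) -> np.ndarray:
        return self._encoded[ref_id]


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped placement; interval is 0-based half-open on the plus strand."""

    read_id: str
    ref_id: str
    strand: Literal["+", "-"]
    start: int
    end: int
    mismatches: int
    multiplicity: int = 1
    first_base: str = "N"  # 5' base of the read as sequenced
    weight: float = field(default=1.0, compare=False)

    @property
    def five_prime_pos(self) -> int:
        """Reference coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def read_length(self) -> int:
        return self.end - self.start


def _scan_one_strand(
    read_codes: np.ndarray, ref_codes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Offsets and mismatch counts of placements with <= k mismatches."""
    L = read_codes.size
    if L > ref_codes.size:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = sliding_window_view(ref_codes, L)
    mism = (windows != read_codes).sum(axis=1)
    keep = np.flatnonzero(mism <= k)
    return keep, mism[keep]


def map_read(
    read: SmallRNARead,
    refs: ReferenceSet,
    k: int = 0,
    mode: Literal["all_hits", "best_stratum"] = "all_hits",
) -> list[AlignmentHit]:
    """All placements of one read on both strands with <= k mismatches.

    ``best_stratum`` keeps only hits with the minimum observed mismatch
    count.  Hits are ordered by (ref_id, strand, start); '+' sorts before
    '-'.  A read longer than a reference simply yields no hits there.
    """
    if not 0 <= k <= 3:
        raise InputError("mismatch budget k must be in 0..3")
    fwd = _encode(read.seq, _READ_CODE)
    rev = _encode(revcomp(read.seq), _READ_CODE)
    hits: list[AlignmentHit] = []
    for ref in refs:
        ref_codes = refs.encoded(ref.ref_id)
        for strand, codes in (("+", fwd), ("-", rev)):
            offsets, mism = _scan_one_strand(codes, ref_codes, k)
            for s, m in zip(offsets.tolist(), mism.tolist()):
                hits.append(
                    AlignmentHit(
                        read_id=read.read_id,
                        ref_id=ref.ref_id,
                        strand=strand,
                        start=s,
                        end=s + read.length,
                        mismatches=m,
                        multiplicity=read.multiplicity,
                        first_base=read.seq[0] if read.seq else "N",
                    )
                )
    if mode == "best_stratum" and hits:
        best = min(h.mismatches for h in hits)
        hits = [h for h in hits if h.mismatches == best]
    hits.sort(key=lambda h: (h.ref_id, h.strand, h.start))
    return hits


def map_library(
    library: Library,
    refs: ReferenceSet,
    k: int = 0,
    mode: Literal["all_hits", "best_stratum"] = "all_hits",
    chunk_size: int = 512,
) -> dict[str, list[AlignmentHit]]:
    """Map every collapsed read; returns hits grouped by read_id.

    Reads are batched by length so each (reference, length) window matrix is
    built once; results are identical to per-read :func:`map_read`.
    Unmapped reads appear with an empty hit list.
    """
    if not 0 <= k <= 3:
        raise InputError("mismatch budget k must be in 0..3")
    hits_by_read: dict[str, list[AlignmentHit]] = {r.read_id: [] for r in library.reads}
    by_length: dict[int, list[SmallRNARead]] = {}
    for r in library.reads:
        by_length.setdefault(r.length, []).append(r)
    for ref in refs:
        ref_codes = refs.encoded(ref.ref_id)
        for L, reads in by_length.items():
            if L == 0 or L > ref_codes.size:
                continue
            windows = sliding_window_view(ref_codes, L)
            for strand in ("+", "-"):
                seqs = [r.seq if strand == "+" else revcomp(r.seq) for r in reads]
                mat = np.zeros((len(reads), L), dtype=np.uint8)
                for i, s in enumerate(seqs):
                    mat[i] = _encode(s, _READ_CODE)
                for lo in range(0, len(reads), chunk_size):
                    chunk = mat[lo : lo + chunk_size]
                    mism = (chunk[:, None, :] != windows[None, :, :]).sum(axis=2)
                    rows, offsets = np.nonzero(mism <= k)
                    for i, s in zip(rows.tolist(), offsets.tolist()):
                        r = reads[lo + i]
                        hits_by_read[r.read_id].append(
                            AlignmentHit(
                                read_id=r.read_id,
                                ref_id=ref.ref_id,
                                strand=strand,
                                start=s,
                                end=s + L,
                                mismatches=int(mism[i, s]),
                                multiplicity=r.multiplicity,
                                first_base=r.seq[0],
                            )
                        )
    for rid, hits in hits_by_read.items():
        if mode == "best_stratum" and hits:
            best = min(h.mismatches for h in hits)
            hits = [h for h in hits if h.mismatches == best]
        hits.sort(key=lambda h: (h.ref_id, h.strand, h.start))
        hits_by_read[rid] = hits
    return hits_by_read


def classify_uniqueness(
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
) -> dict[str, Literal["unique", "multi", "unmapped"]]:
    """Label each read unique (exactly one placement anywhere), multi, or unmapped."""
    out: dict[str, Literal["unique", "multi", "unmapped"]] = {}
    for rid, hits in hits_by_read.items():
        out[rid] = "unmapped" if not hits else ("unique" if len(hits) == 1 else "multi")
    return out


def assign_weights(
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
    weight_mode: Literal["fractional", "count_all"] = "fractional",
) -> list[AlignmentHit]:
    """Flatten hits, attaching a per-hit aggregation weight.

    ``fractional`` (default): each read distributes its multiplicity evenly
    over its placements, so totals are conserved.  ``count_all``: a read
    contributes its full multiplicity to every placement — the convention
    for per-element profiles of multi-copy families, where a read is shown
    on each element it matches.
    """
    out: list[AlignmentHit] = []
    for hits in hits_by_read.values():
        n = len(hits)
        for h in hits:
            w = h.multiplicity / n if weight_mode == "fractional" else float(h.multiplicity)
            out.append(replace(h, weight=w))
    return out


def mapping_summary(hits_by_read: Mapping[str, Sequence[AlignmentHit]]) -> dict:
    """Multiplicity-weighted totals: sequenced, mapped, unique, multi."""
    labels = classify_uniqueness(hits_by_read)
    mult = {
        rid: (hits[0].multiplicity if hits else 1)
        for rid, hits in hits_by_read.items()
    }
    total_mapped = sum(m for r, m in mult.items() if labels[r] != "unmapped")
    return {
        "reads_total_unique_seqs": len(hits_by_read),
        "mapped": total_mapped,
        "unique": sum(m for r, m in mult.items() if labels[r] == "unique"),
        "multi": sum(m for r, m in mult.items() if labels[r] == "multi"),
    }


def hits_to_bed(hits: Iterable[AlignmentHit]) -> str:
    """Headerless BED6-like TSV: ref, start, end, read_id, mismatches, strand."""
    lines = [
        f"{h.ref_id}\t{h.start}\t{h.end}\t{h.read_id}\t{h.mismatches}\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
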