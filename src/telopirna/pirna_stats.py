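"""Cluster-characterization statistics from alignments.

Everything a dual-strand piRNA cluster is recognized by:

* RPM normalization — counts scaled to a one-million-read library, against
  the number of *sequenced* reads (not mapped reads);
* strand-resolved coverage profiles — 5'-end counts in fixed windows
  (default 30 bp) along a reference;
* the read-length partition into piRNAs (24-29 nt), siRNAs (21 nt) and the
  remainder;
* 1U bias — the multiplicity-weighted fraction of 24-29-nt reads whose 5'
  base is uridine (T in the sequenced DNA);
* the ping-pong signature — sense/antisense 5'-overlap spectrum with a
  Z-score peak at overlap 10 when the amplification loop is active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapper import AlignmentHit, Reference
from .seq_io import InputError

__all__ = [
    "PIRNA_LENGTHS",
    "SIRNA_LENGTH",
    "CoverageProfile",
    "LengthSpectrum",
    "PingPongProfile",
    "rpm_normalize",
    "coverage_profile",
    "partition_classes",
    "u1_bias",
    "length_spectrum",
    "pingpong_profile",
]

PIRNA_LENGTHS = range(24, 30)  # 24-29 nt inclusive
SIRNA_LENGTH = 21
SPECTRUM_LENGTHS = range(19, 30)


def rpm_normalize(count: float, total_reads: int) -> float:
    """Scale a count to reads-per-million of the sequenced library."""
    if total_reads <= 0:
        raise InputError("total_reads must be positive for RPM normalization")
    return count * 1_000_000 / total_reads


@dataclass
class CoverageProfile:
    ref_id: str
    strand: Literal["+", "-"]
    window_size: int
    values: np.ndarray  # RPM per window
    normalization_denominator: int

    @property
    def n_windows(self) -> int:
        return int(self.values.size)


def coverage_profile(
    hits: Iterable[AlignmentHit],
    ref: Reference,
    strand: Literal["+", "-"],
    total_reads: int,
    window_size: int = 30,
    mode: Literal["five_prime", "pileup"] = "five_prime",
) -> CoverageProfile:
    """Windowed, RPM-normalized coverage of one strand of one reference.

    Default counts each hit once, in the window containing its 5' end
    (read-count semantics); ``pileup`` spreads the hit weight over every
    window its interval touches, proportionally to the overlap in bp.
    """
    if window_size < 1:
        raise InputError("window_size must be >= 1")
    n_windows = math.ceil(len(ref) / window_size)
    raw = np.zeros(n_windows, dtype=float)
    for h in hits:
        if h.ref_id != ref.ref_id or h.strand != strand:
            continue
        if mode == "five_prime":
            raw[h.five_prime_pos // window_size] += h.weight
        else:
            for w in range(h.start // window_size, (h.end - 1) // window_size + 1):
                lo = max(h.start, w * window_size)
                hi = min(h.end, (w + 1) * window_size)
                raw[w] += h.weight * (hi - lo) / h.read_length
    return CoverageProfile(
        ref_id=ref.ref_id,
        strand=strand,
        window_size=window_size,
        values=rpm_normalize(raw, total_reads),
        normalization_denominator=total_reads,
    )


def partition_classes(
    hits: Iterable[AlignmentHit],
) -> dict[str, list[AlignmentHit]]:
    """Split hits by read length: piRNA (24-29 nt), siRNA (21 nt), other."""
    out: dict[str, list[AlignmentHit]] = {"piRNA": [], "siRNA": [], "other": []}
    for h in hits:
        if h.read_length in PIRNA_LENGTHS:
            out["piRNA"].append(h)
        elif h.read_length == SIRNA_LENGTH:
            out["siRNA"].append(h)
        else:
            out["other"].append(h)
    return out


def u1_bias(hits: Iterable[AlignmentHit], strand: Literal["+", "-"]) -> float | None:
    """Weighted fraction of 24-29-nt reads on ``strand`` starting with U.

    Returns None (reported downstream as NA) when no eligible read exists —
    absence of data, not absence of bias.
    """
    num = den = 0.0
    for h in hits:
        if h.strand != strand or h.read_length not in PIRNA_LENGTHS:
            continue
        den += h.weight
        if h.first_base == "T":
            num += h.weight
    return None if den == 0 else num / den


@dataclass
class LengthSpectrum:
    """Per-strand RPM by read length (19-29 nt) plus per-strand 1U fractions."""

    ref_id: str
    rpm: pd.DataFrame  # index: length 19..29; columns: "+", "-"
    u1_fraction: dict[str, float | None]
    normalization_denominator: int


def length_spectrum(
    hits: Iterable[AlignmentHit], ref_id: str, total_reads: int
) -> LengthSpectrum:
    hits = [h for h in hits if h.ref_id == ref_id]
    table = pd.DataFrame(
        0.0, index=list(SPECTRUM_LENGTHS), columns=["+", "-"]
    ).rename_axis("length")
    for h in hits:
        if h.read_length in SPECTRUM_LENGTHS:
            table.loc[h.read_length, h.strand] += h.weight
    return LengthSpectrum(
        ref_id=ref_id,
        rpm=table.map(lambda c: rpm_normalize(c, total_reads)),
        u1_fraction={s: u1_bias(hits, s) for s in ("+", "-")},
        normalization_denominator=total_reads,
    )


@dataclass
class PingPongProfile:
    """Sense/antisense 5'-overlap spectrum with Z-scores.

    ``overlaps`` runs 1..max_overlap; ``z`` is computed against the mean/sd
    of the background bins (all overlaps except the signal bin when
    ``background_excludes_signal``).  ``degenerate`` is set when the profile
    is uninformative (one strand absent, or zero background sd) — z is then
    all zeros by convention.
    """

    overlaps: np.ndarray
    pair_counts: np.ndarray
    z: np.ndarray
    signal_bin: int = 10
    background_excludes_signal: bool = True
    degenerate: bool = False

    @property
    def argmax_overlap(self) -> int:
        return int(self.overlaps[int(np.argmax(self.z))])

    def z_at(self, o: int) -> float:
        return float(self.z[int(np.flatnonzero(self.overlaps == o)[0])])


def pingpong_profile(
    hits: Iterable[AlignmentHit],
    max_overlap: int = 30,
    signal_bin: int = 10,
    background_excludes_signal: bool = True,
) -> PingPongProfile:
    """5'-overlap pair spectrum of 24-29-nt reads on one reference.

    For a plus-strand 5' end at s and a minus-strand 5' end at a, the
    overlap is o = a - s + 1, so a canonical ping-pong pair scores o = 10.
    Reads are collapsed to weighted 5'-position classes and pair counts are
    products of class weights (not all-vs-all read pairs), which is exact
    and avoids a quadratic blowup at deep positions.
    """
    plus: dict[int, float] = {}
    minus: dict[int, float] = {}
    ref_ids = set()
    for h in hits:
        if h.read_length not in PIRNA_LENGTHS:
            continue
        ref_ids.add(h.ref_id)
        side = plus if h.strand == "+" else minus
        side[h.five_prime_pos] = side.get(h.five_prime_pos, 0.0) + h.weight
    if len(ref_ids) > 1:
        raise InputError("pingpong_profile expects hits from a single reference")
    overlaps = np.arange(1, max_overlap + 1)
    counts = np.zeros(max_overlap, dtype=float)
    degenerate = False
    if not plus or not minus:
        degenerate = True
    else:
        for s, w in plus.items():
            for o in overlaps:
                wm = minus.get(s + int(o) - 1)
                if wm is not None:
                    counts[o - 1] += w * wm
    if background_excludes_signal:
        bg = counts[overlaps != signal_bin]
    else:
        bg = counts
    sd = float(np.std(bg, ddof=1)) if bg.size > 1 else 0.0
    if degenerate or sd == 0.0:
        z = np.zeros_like(counts)
        degenerate = True
    else:
        z = (counts - float(np.mean(bg))) / sd
    return PingPongProfile(
        overlaps=overlaps,
        pair_counts=counts,
        z=z,
        signal_bin=signal_bin,
        background_excludes_signal=background_excludes_signal,
        degenerate=degenerate,
    )
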