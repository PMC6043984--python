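"""Small-RNA library simulator with known ground truth.

Emulates the statistical structure the cluster statistics assume: a mixture
of 24-29-nt piRNAs (tunable 1U bias; a tunable fraction emitted as
sense/antisense partner pairs whose 5' ends overlap by exactly 10 nt),
21-nt siRNAs, and background degradation fragments (19-29 nt), all drawn
from a reference sequence, with optional per-base substitution errors.

The 1U bias is planted by *position selection*: the first-base class of
each primary piRNA is drawn with probability ``u1_prob`` and the read is
then sampled from reference positions whose strand base matches that class.
Error-free reads are therefore exact substrings and map at a mismatch
budget of zero, which is what makes full-pipeline parameter recovery exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mapper import Reference, revcomp
from .seq_io import InputError, SmallRNARead

__all__ = ["SimConfig", "SimulatedRead", "simulate_library", "write_fastq", "truth_table"]

_BASES = np.array(list("ACGT"))

#: Default piRNA length distribution over 24..29 nt, peaked at 25-26 nt as
#: in Drosophila ovarian libraries.
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    24: 0.12, 25: 0.28, 26: 0.28, 27: 0.18, 28: 0.09, 29: 0.05,
}


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq: str
    cls: str  # "pirna" | "sirna" | "background"
    ref_id: str
    strand: str
    five_prime_pos: int
    partner_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.seq)

    def as_read(self) -> SmallRNARead:
        return SmallRNARead(read_id=self.read_id, seq=self.seq)


@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    Defaults model a productive dual-strand telomeric cluster: mostly
    piRNAs with a strong 1U bias on both strands, a moderate planted
    ping-pong fraction, a 21-nt siRNA component, and degradation
    background.
    """

    reference: Reference
    n_reads: int = 10_000
    pirna_fraction: float = 0.70
    sirna_fraction: float = 0.15
    background_fraction: float = 0.15
    pingpong_fraction: float = 0.30
    u1_prob: float = 0.75
    strand_ratio: float = 0.5  # plus-strand share of non-partner reads
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        fr = (self.pirna_fraction, self.sirna_fraction, self.background_fraction)
        if any(not 0 <= f <= 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise InputError("class fractions must lie in [0,1] and sum to 1")
        if self.n_reads <= 0:
            raise InputError("n_reads must be positive")
        if not 0 <= self.pingpong_fraction <= 1:
            raise InputError("pingpong_fraction must lie in [0,1]")
        if self.pingpong_fraction > 0 and self.strand_ratio in (0.0, 1.0):
            raise InputError(
                "pingpong pairs need both strands; strand_ratio must be in (0,1)"
            )
        if not 0 <= self.u1_prob <= 1 or not 0 <= self.strand_ratio <= 1:
            raise InputError("u1_prob and strand_ratio must lie in [0,1]")
        lengths = sorted(self.length_distribution)
        if not lengths or any(L not in range(24, 30) for L in lengths):
            raise InputError("piRNA length distribution must cover lengths in 24..29")
        if abs(sum(self.length_distribution.values()) - 1.0) > 1e-9:
            raise InputError("length distribution must sum to 1")
        max_len = max(29, max(lengths))
        if len(self.reference) <= max_len + 10:
            raise InputError("reference must be longer than max read length + 10")
        if not 0 <= self.error_rate < 1:
            raise InputError("error_rate must lie in [0,1)")


class _StrandSampler:
    """Uniform sampling of 5' positions conditioned on the 5' base class."""

    def __init__(self, ref_seq: str):
        arr = np.frombuffer(ref_seq.encode(), dtype="S1")
        # plus-strand 5' base at s is ref[s]; minus-strand 5' base at a is
        # the complement of ref[a], which is T iff ref[a] == A.
        self.pos = {
            ("+", True): np.flatnonzero(arr == b"T"),
            ("+", False): np.flatnonzero(arr != b"T"),
            ("-", True): np.flatnonzero(arr == b"A"),
            ("-", False): np.flatnonzero(arr != b"A"),
        }

    def draw(
        self, rng: np.random.Generator, strand: str, want_u1: bool, lo: int, hi: int
    ) -> int:
        """A 5' position in [lo, hi] with the requested first-base class."""
        cand = self.pos[(strand, want_u1)]
        cand = cand[(cand >= lo) & (cand <= hi)]
        if cand.size == 0:  # fall back to any valid position
            cand = np.arange(lo, hi + 1)
        return int(cand[rng.integers(cand.size)])


def _extract(ref_seq: str, strand: str, five_prime: int, length: int) -> str:
    if strand == "+":
        return ref_seq[five_prime : five_prime + length]
    return revcomp(ref_seq[five_prime - length + 1 : five_prime + 1])


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(choices.size)]
    return "".join(arr)


def simulate_library(config: SimConfig) -> list[SimulatedRead]:
    """Draw one library; a fixed seed gives a byte-identical result.

    A single Generator seeded from ``config.seed`` drives every choice, in a
    fixed order, so the output is reproducible bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ref = config.reference
    ref_seq = ref.seq.upper()
    n_ref = len(ref_seq)
    sampler = _StrandSampler(ref_seq)

    n_pi = round(config.n_reads * config.pirna_fraction)
    n_si = round(config.n_reads * config.sirna_fraction)
    n_bg = config.n_reads - n_pi - n_si
    n_paired = round(config.pingpong_fraction * n_pi)
    n_paired -= n_paired % 2  # whole pairs only
    n_pairs = n_paired // 2

    lengths = np.array(sorted(config.length_distribution))
    probs = np.array([config.length_distribution[L] for L in lengths], dtype=float)
    probs /= probs.sum()

    def draw_len() -> int:
        return int(lengths[rng.choice(lengths.size, p=probs)])

    reads: list[SimulatedRead] = []
    idx = 0

    def rid() -> str:
        nonlocal idx
        idx += 1
        return f"sim{config.seed}_{idx:06d}"

    # --- ping-pong pairs: driver 5' at s (+) and partner 5' at s+9 (-) ---
    for _ in range(n_pairs):
        driver_plus = rng.random() < config.strand_ratio
        L1, L2 = draw_len(), draw_len()
        want_u1 = rng.random() < config.u1_prob
        if driver_plus:
            # need s+L1 <= n_ref and partner interval start s+9-L2+1 >= 0
            lo, hi = max(0, L2 - 10), n_ref - max(L1, 10)
            s = sampler.draw(rng, "+", want_u1, lo, hi)
            a = s + 9
            d = SimulatedRead(rid(), _extract(ref_seq, "+", s, L1), "pirna",
                              ref.ref_id, "+", s)
            p = SimulatedRead(rid(), _extract(ref_seq, "-", a, L2), "pirna",
                              ref.ref_id, "-", a, partner_id=d.read_id)
        else:
            # driver on minus strand with 5' at a; partner plus 5' at a-9
            lo, hi = max(L1 - 1, 9), min(n_ref - 1, (n_ref - L2) + 9)
            a = sampler.draw(rng, "-", want_u1, lo, hi)
            s = a - 9
            d = SimulatedRead(rid(), _extract(ref_seq, "-", a, L1), "pirna",
                              ref.ref_id, "-", a)
            p = SimulatedRead(rid(), _extract(ref_seq, "+", s, L2), "pirna",
                              ref.ref_id, "+", s, partner_id=d.read_id)
        reads.extend([d, p])

    # --- unpaired primary piRNAs ---
    for _ in range(n_pi - 2 * n_pairs):
        L = draw_len()
        strand = "+" if rng.random() < config.strand_ratio else "-"
        want_u1 = rng.random() < config.u1_prob
        lo, hi = (0, n_ref - L) if strand == "+" else (L - 1, n_ref - 1)
        fp = sampler.draw(rng, strand, want_u1, lo, hi)
        reads.append(SimulatedRead(rid(), _extract(ref_seq, strand, fp, L),
                                   "pirna", ref.ref_id, strand, fp))

    # --- 21-nt siRNAs: exact substrings, no 1U constraint ---
    for _ in range(n_si):
        strand = "+" if rng.random() < config.strand_ratio else "-"
        if strand == "+":
            fp = int(rng.integers(0, n_ref - 21 + 1))
        else:
            fp = int(rng.integers(20, n_ref))
        reads.append(SimulatedRead(rid(), _extract(ref_seq, strand, fp, 21),
                                   "sirna", ref.ref_id, strand, fp))

    # --- background degradation fragments, 19-29 nt, either strand ---
    for _ in range(n_bg):
        L = int(rng.integers(19, 30))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            fp = int(rng.integers(0, n_ref - L + 1))
        else:
            fp = int(rng.integers(L - 1, n_ref))
        reads.append(SimulatedRead(rid(), _extract(ref_seq, strand, fp, L),
                                   "background", ref.ref_id, strand, fp))

    if config.error_rate > 0:
        reads = [
            SimulatedRead(r.read_id, _apply_errors(r.seq, config.error_rate, rng),
                          r.cls, r.ref_id, r.strand, r.five_prime_pos, r.partner_id)
            for r in reads
        ]
    return reads


def truth_table(reads: Sequence[SimulatedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "class": [r.cls for r in reads],
            "ref": [r.ref_id for r in reads],
            "strand": [r.strand for r in reads],
            "five_prime_pos": [r.five_prime_pos for r in reads],
            "length": [r.length for r in reads],
            "partner_id": [r.partner_id or "" for r in reads],
        }
    )


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path, seed: int) -> None:
    """FASTQ with dummy qualities; the seed is recorded in every header."""
    with open(path, "wt") as out:
        for r in reads:
            out.write(f"@{r.read_id} seed={seed} class={r.cls}\n{r.seq}\n+\n{'I' * r.length}\n")
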