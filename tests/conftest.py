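import numpy as np
import pytest

from telopirna.mapper import Reference, ReferenceSet

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def reference_5kb():
    r = np.random.default_rng(101)
    return Reference("ref5k", random_dna(r, 5000))


@pytest.fixture
def refset_5kb(reference_5kb):
    return ReferenceSet([reference_5kb])


def hamming_hits_oracle(seq: str, ref_seq: str, k: int):
    """Exhaustive per-offset Hamming scan on both strands (independent oracle).

    Returns a set of (strand, start, mismatches).  Written with plain string
    slicing so it shares no code with the vectorized implementation.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(seq))
    out = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for start in range(len(ref_seq) - L + 1):
            mm = 0
            for a, b in zip(s, ref_seq[start : start + L]):
                if a != b or a == "N" or b == "N":
                    mm += 1
                    if mm > k:
                        break
            if mm <= k:
                out.add((strand, start, mm))
    return out
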