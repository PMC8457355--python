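"""Small DNA/quality helpers shared across modules.

Sequences are plain upper-case ``str`` over ACGT (IUPAC codes are carried
through verbatim but never expanded).  Batched read data is held as 2-D
``uint8`` arrays of ASCII codes, which is what the vectorised merger and
demultiplexer operate on.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")

PHRED_OFFSET = 33


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random ACGT string."""
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently at ``rate``; never to itself."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        choices = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in np.nonzero(hit)[0]:
            alts = choices[choices != arr[i]]
            arr[i] = rng.choice(alts)
    return arr.tobytes().decode()


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def quals_to_string(quals: np.ndarray) -> str:
    return (np.asarray(quals, dtype=np.uint8) + PHRED_OFFSET).tobytes().decode()


def string_to_quals(qual_string: str) -> np.ndarray:
    return np.frombuffer(qual_string.encode(), dtype=np.uint8).astype(np.int64) - PHRED_OFFSET


def phred_error_prob(quals: np.ndarray) -> np.ndarray:
    """Per-base error probability 10^(-Q/10)."""
    return np.power(10.0, -np.asarray(quals, dtype=float) / 10.0)
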