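"""Small DNA-string helpers shared by the simulator and the mapper."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte-level complement table for uint8-encoded ASCII sequence
_COMP_TABLE = np.arange(256, dtype=np.uint8)
for a, b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP_TABLE[a] = b


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """ASCII bytes of the sequence as a uint8 array."""
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[arr][::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    return decode(encode("ACGT")[rng.integers(0, 4, size=length)])
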