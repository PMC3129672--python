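"""Nucleotide encoding helpers shared by the bias and simulate modules.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, padding beyond
transcript ends) is the sentinel 4 and is treated as uninformative wherever
it appears in a bias window.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0,C=1,G=2,T=3,other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement encoded bases; the sentinel 4 maps to itself."""
    out = codes.copy()
    valid = codes < 4
    out[valid] = 3 - codes[valid]
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT_STR)[::-1]
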