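"""Small nucleotide-sequence helpers shared across the package.

All sequences are uppercase DNA strings over {A, C, G, T, N}.  The
numeric encoding (A=0, C=1, G=2, T=3, N=4) is shared by the folding
and specificity engines.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _b, _i in _CODE.items():
    _ENCODE_LUT[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an int8 array (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run in *seq*."""
    best = run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        if run > best:
            best = run
    return best


def validate_bases(seq: str, allow_n: bool = True) -> None:
    allowed = set(BASES if allow_n else BASES[:4])
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"sequence contains invalid bases: {sorted(bad)}")
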