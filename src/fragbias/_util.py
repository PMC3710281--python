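"""Shared low-level helpers: sequence encoding, reverse complement, Phred strings."""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np

log = logging.getLogger("fragbias")

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte value -> base code (A=0, C=1, G=2, T=3, everything else 255)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode one sequence as uint8 codes (A=0, C=1, G=2, T=3, other=255)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_seqs(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 code matrix.

    Raises ValueError on empty input or unequal lengths.
    """
    if len(seqs) == 0:
        raise ValueError("no sequences given")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must all have the same length")
    flat = _CODE_LUT[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)]
    return flat.reshape(len(seqs), length)


def phred_to_string(quals: Iterable[int]) -> str:
    """Encode integer Phred scores as a Phred+33 ASCII string."""
    return "".join(chr(q + 33) for q in quals)


def string_to_phred(s: str) -> list[int]:
    """Decode a Phred+33 ASCII string into integer scores."""
    return [ord(c) - 33 for c in s]
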