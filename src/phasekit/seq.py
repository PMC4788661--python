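"""Tiny sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
#: length of a plant 21-nt phasiRNA and hence the phasing period
PHASE = 21
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, *, what: str = "sequence") -> None:
    """Raise ValueError unless *seq* is a non-empty string over {A,C,G,T}."""
    if not seq or set(seq) - set(DNA):
        raise ValueError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")


def encode(seq: str) -> np.ndarray:
    """Byte-encode a DNA string as a uint8 array for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
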