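"""Shared sequence helpers: alphabets, complements, IUPAC expansion, encoding."""

from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"

# IUPAC nucleotide one-letter codes and the concrete bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Base -> small integer; anything outside ACGT encodes as 4 (treated as N).
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ParseError(ValueError):
    """Raised on malformed input files; message carries location context."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def is_iupac(seq: str) -> bool:
    return all(c in IUPAC_CODES for c in seq.upper())


def check_probability_vector(v, name: str = "frequencies", tol: float = 1e-9) -> np.ndarray:
    vec = np.asarray(v, dtype=float)
    if vec.shape != (4,):
        raise ValidationError(f"{name} must be a 4-vector, got shape {vec.shape}")
    if np.any(vec < 0):
        raise ValidationError(f"{name} must be non-negative")
    if abs(vec.sum() - 1.0) > tol:
        raise ValidationError(f"{name} must sum to 1 (got {vec.sum():.12f})")
    return vec
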