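"""Low-level sequence utilities: encoding, IUPAC algebra, sliding-window scoring.

Conventions used everywhere in the package:

* base order is A, C, G, T (indices 0..3) in every matrix and lookup table;
* coordinates are 0-based, half-open;
* strand "+" means the motif as stored matches the forward strand.
"""

from __future__ import annotations

import re

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# IUPAC symbol -> frozenset of allowed bases
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
# base-set -> IUPAC symbol
SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# byte-level translation table for fast encoding; unknown/ambiguous bases -> 4
_ENC = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC symbols handled)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_intersect(a: str, b: str) -> str | None:
    """IUPAC symbol for the intersection of two symbols, or None if empty."""
    s = IUPAC_SETS[a] & IUPAC_SETS[b]
    if not s:
        return None
    return SET_TO_IUPAC[s]


def validate_iupac(text: str) -> None:
    """Raise ValueError naming the first offending position if not IUPAC."""
    if not text:
        raise ValueError("empty IUPAC string")
    for i, ch in enumerate(text):
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC symbol {ch!r} at position {i}")


def iupac_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC pattern into a regex over ACGT text."""
    validate_iupac(pattern)
    parts = []
    for ch in pattern:
        s = sorted(IUPAC_SETS[ch])
        parts.append(s[0] if len(s) == 1 else "[" + "".join(s) + "]")
    return re.compile("".join(parts))


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into int8 codes A,C,G,T -> 0..3; others -> 4."""
    return _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def encode_many(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) int8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal length")
    buf = np.frombuffer("".join(seqs).upper().encode("ascii"), dtype=np.uint8)
    return _ENC[buf].reshape(len(seqs), L)


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (code 4 renders as N)."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.int8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on encoded arrays (last axis); N (4) stays 4."""
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    return comp[codes][..., ::-1]


def window_scores(codes: np.ndarray, lut: np.ndarray) -> np.ndarray:
    """Sliding-window additive scores of encoded sequences under a column LUT.

    Parameters
    ----------
    codes : (n, L) or (L,) int8 array, values 0..4 (4 = ambiguous).
    lut : (m, 5) float array; lut[j, b] is the contribution of base code b at
        motif column j.  Column 4 holds the ambiguous-base contribution.

    Returns
    -------
    (n, L - m + 1) (or (L - m + 1,)) float array of window scores.
    """
    single = codes.ndim == 1
    c = np.atleast_2d(codes)
    n, L = c.shape
    m = lut.shape[0]
    if L < m:
        out = np.empty((n, 0))
        return out[0] if single else out
    W = L - m + 1
    out = np.zeros((n, W), dtype=np.float64)
    for j in range(m):
        out += lut[j][c[:, j:j + W]]
    return out[0] if single else out
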