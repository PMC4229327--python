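"""Small shared helpers: DNA encoding, complements, hashing."""

from __future__ import annotations

import hashlib

import numpy as np

# IUPAC nucleotide one-letter codes (uppercase).
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

_BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT (and friends) as uint8; non-ACGT bases map to 255."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; any non-ACGT code renders as N."""
    lut = np.full(256, ord("N"), dtype=np.uint8)
    lut[:4] = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
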