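"""Low-level sequence utilities shared across modules.

Sequences are plain upper-case DNA strings; coordinates are 0-based
half-open throughout the library.  The numpy encodings here back the
k-mer seeding and codon scanning used by the detection and ORF modules.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A=0 C=1 G=2 T=3, anything else = 4 (invalid inside k-mers/codons)
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

# 64-entry codon id -> amino acid (ascii), '*' for stop
_AA64 = np.full(64, ord("X"), dtype=np.uint8)
_CODON_OF_ID = [""] * 64


def _codon_id(codon: str) -> int:
    a, b, c = (int(_BASE_CODE[ord(x)]) for x in codon)
    return a * 16 + b * 4 + c


for _codon, _aa in _STANDARD.forward_table.items():
    _AA64[_codon_id(_codon)] = ord(_aa)
    _CODON_OF_ID[_codon_id(_codon)] = _codon
for _codon in _STANDARD.stop_codons:
    _AA64[_codon_id(_codon)] = ord("*")
    _CODON_OF_ID[_codon_id(_codon)] = _codon

START_CODON_ID = _codon_id("ATG")
STOP_CODON_IDS = frozenset(_codon_id(c) for c in _STANDARD.stop_codons)

# amino acid -> list of codons (for encoding proteins back to DNA)
CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD.forward_table.items():
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_FOR_AA:
    CODONS_FOR_AA[_aa].sort()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A0 C1 G2 T3, other 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; windows containing non-ACGT get -1."""
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = windows.astype(np.int64) @ powers
    bad = np.convolve((codes >= 4).astype(np.int64), np.ones(k, dtype=np.int64))[
        k - 1 : k - 1 + n
    ]
    vals[bad > 0] = -1
    return vals


def codon_ids(codes: np.ndarray, frame: int) -> np.ndarray:
    """Codon ids (0..63, or -1 for codons containing non-ACGT) for a frame."""
    sub = codes[frame:]
    m = (sub.shape[0] // 3) * 3
    if m == 0:
        return np.empty(0, dtype=np.int64)
    trip = sub[:m].reshape(-1, 3).astype(np.int64)
    ids = trip[:, 0] * 16 + trip[:, 1] * 4 + trip[:, 2]
    ids[(trip >= 4).any(axis=1)] = -1
    return ids


def translate_ids(ids: np.ndarray) -> str:
    """Translate an array of codon ids to a protein string ('*' = stop)."""
    valid = np.where(ids >= 0, ids, 0)
    aas = _AA64[valid]
    aas = np.where(ids >= 0, aas, ord("X")).astype(np.uint8)
    return aas.tobytes().decode("ascii")


def translate(seq: str) -> str:
    """Translate an in-frame DNA string (length multiple of 3 not required;
    trailing partial codon ignored)."""
    return translate_ids(codon_ids(encode(seq), 0))


def encode_protein(protein: str, rng: np.random.Generator) -> str:
    """Back-translate a protein to DNA, drawing a codon per residue."""
    parts = []
    for aa in protein:
        choices = CODONS_FOR_AA[aa]
        parts.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(parts)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_protein(length: int, rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, len(aas), size=length))
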