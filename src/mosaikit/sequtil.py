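"""Nucleotide sequence helpers.

Sequences are held internally as uint8 arrays with the encoding
A=0, C=1, G=2, T=3; strings only appear at the FASTA boundary.
"""

from __future__ import annotations

import numpy as np

ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)

# standard genetic code, codon -> amino acid (one letter; '*' = stop)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


def encode(seq: str | bytes) -> np.ndarray:
    """String/bytes -> uint8 codes; non-ACGT become 255."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    out = np.full(len(codes), ord("N"), dtype=np.uint8)
    valid = codes < 4
    out[valid] = ALPHABET[codes[valid]]
    return out.tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def random_sequence(rng: np.random.Generator, length: int, gc_content: float = 0.5) -> np.ndarray:
    """Random sequence with the requested expected GC fraction."""
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must lie in [0, 1]")
    if length <= 0:
        raise ValueError("length must be positive")
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    return rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)


def mutate_positions(
    rng: np.random.Generator, codes: np.ndarray, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Substitute each position independently with probability ``rate``.

    Returns (new sequence, positions substituted).  The replacement base is
    drawn uniformly from the three alternatives, so every flagged position
    really differs from the input.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("substitution rate must lie in [0, 1]")
    out = codes.copy()
    if rate == 0.0:
        return out, np.empty(0, dtype=np.int64)
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    shift = rng.integers(1, 4, size=len(hits)).astype(np.uint8)
    out[hits] = (out[hits] + shift) % 4
    return out, hits


def translate(cds: str) -> str:
    """Translate an in-frame CDS string (standard code)."""
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))
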