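"""Shared nucleotide-sequence helpers.

Sequences are handled uppercase. DNA (T) and RNA (U) spellings are accepted
interchangeably; pairing logic treats T and U as the same base.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")
_TO_DNA = str.maketrans("Uu", "Tt")
_TO_RNA = str.maketrans("Tt", "Uu")

DNA_BASES = "ACGT"

# integer encoding used by the folding kernels: A=0, C=1, G=2, T/U=3
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def to_dna(seq: str) -> str:
    return seq.upper().translate(_TO_DNA)


def to_rna(seq: str) -> str:
    return seq.upper().translate(_TO_RNA)


def complement(base: str) -> str:
    return base.upper().translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def is_valid(seq: str, allow_n: bool = False) -> bool:
    allowed = set("ACGTU") | ({"N"} if allow_n else set())
    return all(b in allowed for b in seq.upper())


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as int8 codes (A=0, C=1, G=2, T/U=3)."""
    try:
        return np.array([_CODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


def pairs_with(a: str, b: str, wobble: bool = True) -> bool:
    """Watson-Crick (and optionally G:U wobble) pairing between two bases."""
    a, b = to_dna(a), to_dna(b)
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    return (a, b) in wc or (wobble and (a, b) in gu)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_BASES), size=length))
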