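"""Small DNA-string helpers shared across the package.

Sequences are plain uppercase Python strings over A/C/G/T/N. ``N`` is an
ambiguity placeholder and never matches any motif.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return set(seq) <= DNA_ALPHABET


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings, with optional early exit."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d
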