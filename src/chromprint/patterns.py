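"""Segregation patterns and their mirror (phase-flip) algebra.

A segregation pattern records, for every offspring of a cross, which
genotype class it shows at a locus: ``A``/``B`` are the two homozygous
(or phase) classes, ``H`` is heterozygous, and ``-`` is missing.  Because
grandparental phase is usually unknown, a pattern and its *mirror*
(``A`` and ``B`` swapped, ``H``/``-`` fixed) are indistinguishable and are
treated as one equivalence class.  The canonical representative of a class
is the lexicographic minimum of the pattern and its mirror.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ABH-"
_MIRROR = str.maketrans("AB", "BA")


def mirror(pattern: str) -> str:
    """Return the phase-flipped pattern (A<->B; H and - unchanged)."""
    return pattern.translate(_MIRROR)


def canonical(pattern: str) -> str:
    """Canonical representative: min(pattern, mirror(pattern))."""
    m = mirror(pattern)
    return pattern if pattern <= m else m


def is_canonical(pattern: str) -> bool:
    return pattern <= mirror(pattern)


def validate(pattern: str) -> None:
    bad = set(pattern) - set(ALPHABET)
    if bad:
        raise ValueError(f"invalid pattern symbols: {sorted(bad)!r}")


def hamming(p1: str, p2: str, *, skip_missing: bool = True) -> int:
    """Hamming distance; positions missing in either pattern are skipped."""
    if len(p1) != len(p2):
        raise ValueError("patterns differ in length")
    if skip_missing:
        return sum(a != b for a, b in zip(p1, p2) if a != "-" and b != "-")
    return sum(a != b for a, b in zip(p1, p2))


def mirror_distance(p1: str, p2: str) -> int:
    """Minimum Hamming distance over the mirror equivalence classes."""
    return min(hamming(p1, p2), hamming(p1, mirror(p2)))


def recombination_fraction(p1: str, p2: str) -> tuple[float, int, int]:
    """Mirror-aware recombination fraction between two patterns.

    Offspring are informative when both patterns carry an ``A`` or ``B``
    call.  Returns ``(rf, recombinants, informative)`` with
    ``rf = min(d, n - d) / n`` where *d* is the Hamming distance over
    informative offspring; the ``min`` absorbs the unknown relative phase
    of the two patterns.  ``n == 0`` yields ``(nan, 0, 0)``.
    """
    if len(p1) != len(p2):
        raise ValueError("patterns differ in length")
    d = 0
    n = 0
    for a, b in zip(p1, p2):
        if a in "AB" and b in "AB":
            n += 1
            if a != b:
                d += 1
    if n == 0:
        return float("nan"), 0, 0
    d = min(d, n - d)
    return d / n, d, n


def patterns_to_matrix(patterns: list[str]) -> np.ndarray:
    """Encode patterns as an int8 matrix (A=0, B=1, H=2, -=3)."""
    lut = np.full(128, 3, dtype=np.int8)
    for i, c in enumerate(ALPHABET):
        lut[ord(c)] = i
    arr = np.frombuffer("".join(patterns).encode(), dtype=np.uint8)
    return lut[arr].reshape(len(patterns), -1)
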