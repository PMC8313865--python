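"""Small DNA sequence helpers shared across the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, allow_n: bool = False) -> bool:
    alphabet = DNA_ALPHABET_N if allow_n else DNA_ALPHABET
    return bool(seq) and set(seq) <= alphabet


def minimal_rotation(unit: str) -> str:
    """Lexicographically smallest rotation of ``unit``."""
    doubled = unit + unit
    return min(doubled[i : i + len(unit)] for i in range(len(unit)))


def primitive_unit(unit: str) -> str:
    """Shortest string whose tandem repetition equals ``unit``.

    ``ACAC`` reduces to ``AC``; a primitive unit is returned unchanged.
    """
    n = len(unit)
    for size in range(1, n + 1):
        if n % size == 0 and unit[:size] * (n // size) == unit:
            return unit[:size]
    return unit


def is_primitive(unit: str) -> bool:
    return primitive_unit(unit) == unit


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature proxy: 2(A+T) + 4(G+C)."""
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def max_homopolymer(seq: str) -> int:
    best = run = 0
    prev = None
    for base in seq:
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


def find_motif(seq: str, motif: str) -> list[int]:
    """All (overlapping) start positions of ``motif`` in ``seq``.

    Matching is literal: an ``N`` (randomized base) never matches, i.e.
    motifs are sought in the designed sequence only.
    """
    hits = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1
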