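"""RNA secondary structure: base-pair maximisation and template threading.

Folding here is deliberately simple and fully checkable: a Nussinov-style
maximum-cardinality nested pairing under Watson-Crick + G·U rules, plus
threading of a sequence onto a fixed canonical 5S rRNA five-helix template.
The threading score counts how many template pairs the sequence can still
form, which is the question that matters for a 5S variant: do its
substitutions break the conserved helices or fall into loops?
"""

from __future__ import annotations

from dataclasses import dataclass, field

_PAIRABLE = {
    ("A", "T"), ("T", "A"),
    ("A", "U"), ("U", "A"),
    ("C", "G"), ("G", "C"),
    ("G", "T"), ("T", "G"),
    ("G", "U"), ("U", "G"),
}


def can_pair(x: str, y: str) -> bool:
    """Watson-Crick or G·U wobble (DNA or RNA alphabet)."""
    return (x, y) in _PAIRABLE


@dataclass(frozen=True)
class StructureModel:
    """A nested (pseudoknot-free) set of base pairs on a gene of given length.

    Pairs are 1-based gene positions ``(i, j)`` with ``i + min_loop < j``;
    each position occurs in at most one pair and pairs never cross.
    """

    length: int
    pairs: frozenset[tuple[int, int]]
    min_loop: int = 3

    def __post_init__(self) -> None:
        used: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) outside gene 1..{self.length}")
            if j - i <= self.min_loop:
                raise ValueError(f"pair ({i},{j}) violates min_loop={self.min_loop}")
            if i in used or j in used:
                raise ValueError(f"position in more than one pair: ({i},{j})")
            used.update((i, j))
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                i1, j1 = plist[a]
                i2, j2 = plist[b]
                if i1 < i2 < j1 < j2:
                    raise ValueError(f"crossing pairs ({i1},{j1}) and ({i2},{j2})")

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)


def fold_nussinov(sequence: str, min_loop: int = 3) -> StructureModel:
    """Maximum-cardinality nested pairing (WC + G·U, hairpin >= min_loop).

    Traceback is deterministic: pairing ``(i, j)`` is preferred over leaving
    ``j`` unpaired, which is preferred over bifurcation at the smallest
    split point.
    """
    s = sequence.upper()
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    if n < min_loop + 2:  # too short to form any pair
        return StructureModel(n, frozenset(), min_loop)
    # N[i][j]: max pairs on s[i..j], 0-based inclusive
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i][j - 1]  # j unpaired
            if can_pair(s[i], s[j]) and j - i > min_loop:
                cand = (N[i + 1][j - 1] if i + 1 <= j - 1 else 0) + 1
                if cand > best:
                    best = cand
            for k in range(i + 1, j - min_loop):  # (k, j) pair needs j - k > min_loop
                if can_pair(s[k], s[j]):
                    cand = N[i][k - 1] + N[k + 1][j - 1] + 1
                    if cand > best:
                        best = cand
            N[i][j] = best

    pairs: set[tuple[int, int]] = set()

    def trace(i: int, j: int) -> None:
        while i < j:
            if N[i][j] == 0:
                return
            if can_pair(s[i], s[j]) and j - i > min_loop and N[i][j] == (
                (N[i + 1][j - 1] if i + 1 <= j - 1 else 0) + 1
            ):
                pairs.add((i + 1, j + 1))
                i, j = i + 1, j - 1
                continue
            if N[i][j] == N[i][j - 1]:
                j -= 1
                continue
            for k in range(i + 1, j - min_loop):
                if can_pair(s[k], s[j]) and N[i][j] == (
                    N[i][k - 1] + N[k + 1][j - 1] + 1
                ):
                    pairs.add((k + 1, j + 1))
                    trace(i, k - 1)
                    i, j = k + 1, j - 1
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")

    trace(0, n - 1)
    return StructureModel(n, frozenset(pairs), min_loop)


def thread_template(sequence: str, template: StructureModel) -> int:
    """Count template pairs whose bases in ``sequence`` remain pairable."""
    if len(sequence) != template.length:
        raise ValueError(
            f"sequence length {len(sequence)} != template length {template.length}"
        )
    s = sequence.upper()
    return sum(1 for i, j in template.pairs if can_pair(s[i - 1], s[j - 1]))


def compare_structures(a: StructureModel, b: StructureModel) -> int:
    """Size of the symmetric difference of the two pair sets."""
    if a.length != b.length:
        raise ValueError("structures are over genes of different lengths")
    return len(a.pairs ^ b.pairs)


# Canonical five-helix 5S rRNA layout used for threading, on a 119-nt gene.
# Helix bounds follow the standard 5S architecture (helix I closing the
# molecule; helices II/III and IV/V on the two arms); loop positions include
# the diagnostic region landmarks at 2, 23 and 112, which sit unpaired.
_HELICES = [
    (3, 9, 113, 119),     # helix I
    (14, 22, 60, 68),     # helix II
    (26, 33, 49, 56),     # helix III
    (70, 77, 97, 104),    # helix IV
    (79, 85, 90, 96),     # helix V
]


def canonical_fives_template(length: int = 119) -> StructureModel:
    """The default canonical 5S rRNA pairing template (five nested helices)."""
    if length != 119:
        raise ValueError("the built-in template is defined for a 119-nt gene")
    pairs = set()
    for i0, i1, j0, j1 in _HELICES:
        assert i1 - i0 == j1 - j0
        for off in range(i1 - i0 + 1):
            pairs.add((i0 + off, j1 - off))
    return StructureModel(length, frozenset(pairs))
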