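"""Pairwise alignment: affine-gap local (Smith–Waterman) and global (Gotoh).

These are the workhorses behind the homology scan and the consensus
machinery.  Traceback is deterministic: at every cell the diagonal move is
preferred, then the vertical (gap in the second sequence), then the
horizontal, so identical inputs always yield identical alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import fill_global, fill_local

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string onto codes 0-3 (A,C,G,T); anything else -> 4.

    Code 4 (N and ambiguity codes) never matches, including against itself.
    """
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; a gap of length L costs ``-(open + (L-1)*ext)``."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("need gap_open <= gap_extend <= 0")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """An alignment of ``a[a_start:a_end]`` with ``b[b_start:b_end]``.

    ``ops`` is a string over {=, X, I, D}: match, mismatch, insertion
    (consumes ``a`` only) and deletion (consumes ``b`` only).
    """

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    ops: str

    @property
    def n_columns(self) -> int:
        return len(self.ops)

    @property
    def n_matches(self) -> int:
        return self.ops.count("=")

    @property
    def n_errors(self) -> int:
        """Mismatches plus gap columns."""
        return len(self.ops) - self.n_matches

    @property
    def identity(self) -> float:
        """Percent matching columns over all alignment columns."""
        return 100.0 * self.n_matches / len(self.ops) if self.ops else 0.0


def _traceback_local(a, b, scoring, best, best_i, best_j, H, E, F) -> AlignmentResult:
    ops: list[str] = []
    i, j = best_i, best_j
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = scoring.match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else scoring.mismatch
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + s:
                ops.append("=" if s == scoring.match else "X")
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in b: consume a[i-1]
            ops.append("I")
            if F[i, j] == H[i - 1, j] + scoring.gap_open:
                state = "H"
            i -= 1
        else:  # E, gap in a: consume b[j-1]
            ops.append("D")
            if E[i, j] == H[i, j - 1] + scoring.gap_open:
                state = "H"
            j -= 1
    ops.reverse()
    return AlignmentResult(int(best), i, best_i, j, best_j, "".join(ops))


def smith_waterman_local(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal local alignment of two nucleotide strings.

    Returns a zero-score, empty alignment when nothing scores positively
    (e.g. no common residue).
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    ca, cb = encode(a), encode(b)
    best, bi, bj, H, E, F = fill_local(
        ca, cb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best == 0:
        return AlignmentResult(0, 0, 0, 0, 0, "")
    return _traceback_local(ca, cb, scoring, best, bi, bj, H, E, F)


def global_align(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> tuple[int, str, str]:
    """End-to-end (Needleman–Wunsch/Gotoh) alignment.

    Returns ``(score, aligned_a, aligned_b)`` with ``-`` marking gaps.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    ca, cb = encode(a), encode(b)
    H, E, F = fill_global(
        ca, cb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    i, j = len(a), len(b)
    out_a: list[str] = []
    out_b: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0:
                s = scoring.match if (ca[i - 1] == cb[j - 1] and ca[i - 1] < 4) else scoring.mismatch
                if H[i, j] == H[i - 1, j - 1] + s:
                    out_a.append(a[i - 1])
                    out_b.append(b[j - 1])
                    i -= 1
                    j -= 1
                    continue
            if i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            if F[i, j] == H[i - 1, j] + scoring.gap_open:
                state = "H"
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            if E[i, j] == H[i, j - 1] + scoring.gap_open:
                state = "H"
            j -= 1
    score = int(H[len(a), len(b)])
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def pairwise_identity(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Percent identity over the columns of the global alignment."""
    _, aln_a, aln_b = global_align(a, b, scoring)
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    return 100.0 * matches / len(aln_a)
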