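"""Low-level strand-aware scanners.

Two primitives: mismatch-bounded DnaA-box matching (Hamming distance against
a possibly IUPAC-degenerate motif) and detection of maximal runs of N-A-N
trinucleotides (DnaA-trios) in each of the three reading phases.

Coordinates returned here are 0-based offsets on the *scanned* strand: for
``strand == "-"`` the scan runs over the reverse complement of the input and
offsets refer to that reverse-complemented string.  A hit at scanned offset
``s`` of length ``L`` maps back to forward offset ``len(seq) - s - L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CONSENSUS_TRIO, IUPAC_DNA, TrioScoring, revcomp, validate_motif

__all__ = ["BoxHit", "TrioArray", "find_box_hits", "find_trio_arrays", "score_trios"]


@dataclass(frozen=True)
class BoxHit:
    """A mismatch-bounded DnaA-box match.

    ``start`` is the 0-based offset on the scanned strand; ``observed`` is the
    matched substring of that strand; ``mismatches`` is the Hamming distance
    to ``motif`` under the wildcard rules (an ambiguity code in the motif
    matches its IUPAC expansion; an N in the sequence matches nothing).
    """

    start: int
    strand: str
    motif: str
    observed: str
    mismatches: int

    @property
    def end(self) -> int:
        """0-based exclusive end on the scanned strand."""
        return self.start + len(self.motif)


@dataclass(frozen=True)
class TrioArray:
    """A maximal run of consecutive N-A-N trinucleotides in one phase.

    ``trios`` are the 3-mers in scanned-strand 5'->3' order; with the box
    upstream of the run this is also box-proximal-first order.  Maximality
    means the same-phase 3-mer immediately before and after the run each
    violate N-A-N or run off the sequence.
    """

    start: int
    strand: str
    trios: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.trios)

    @property
    def end(self) -> int:
        return self.start + 3 * len(self.trios)


def _oriented(sequence: str, strand: str) -> str:
    if strand == "+":
        return sequence
    if strand == "-":
        return revcomp(sequence)
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def find_box_hits(sequence: str, motif: str, max_mm: int, strand: str = "+") -> list[BoxHit]:
    """All windows within ``max_mm`` Hamming mismatches of ``motif``.

    Every window of length ``len(motif)`` on the scanned strand is tested;
    overlapping hits are all reported, sorted by start.  A motif longer than
    the sequence yields an empty list.
    """
    motif = validate_motif(motif)
    seq = _oriented(sequence, strand)
    n, m = len(seq), len(motif)
    if m > n:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    nwin = n - m + 1
    mm = np.zeros(nwin, dtype=np.int64)
    for j, code in enumerate(motif):
        allowed = np.array([ord(b) for b in IUPAC_DNA[code]], dtype=np.uint8)
        mm += ~np.isin(arr[j : j + nwin], allowed)
    starts = np.nonzero(mm <= max_mm)[0]
    return [
        BoxHit(int(s), strand, motif, seq[int(s) : int(s) + m], int(mm[s])) for s in starts
    ]


def _is_trio(seq: str, i: int) -> bool:
    # N-A-N with no ambiguity allowed in the sequence itself
    return seq[i + 1] == "A" and "N" not in seq[i : i + 3]


def find_trio_arrays(sequence: str, strand: str = "+") -> list[TrioArray]:
    """Maximal N-A-N runs in each of the three reading phases.

    Runs from different phases may overlap; within one phase runs are
    disjoint and maximal.  Sorted by start offset.
    """
    seq = _oriented(sequence, strand)
    n = len(seq)
    runs: list[TrioArray] = []
    for phase in range(3):
        i = phase
        while i + 3 <= n:
            if _is_trio(seq, i):
                j = i
                while j + 3 <= n and _is_trio(seq, j):
                    j += 3
                runs.append(
                    TrioArray(i, strand, tuple(seq[k : k + 3] for k in range(i, j, 3)))
                )
                i = j
            else:
                i += 3
    runs.sort(key=lambda r: r.start)
    return runs


def score_trios(array: TrioArray, scheme: TrioScoring | None = None) -> float:
    """Score a trio run under a scoring scheme (default: consensus-weighted).

    The default scheme rewards both run length and consensus content: each
    trio equal to the consensus TAG contributes ``w_full`` (3.0), any other
    N-A-N trio ``w_partial`` (1.0).
    """
    if array.count < 1:
        raise ValueError("cannot score an empty trio array")
    scheme = scheme or TrioScoring()
    if scheme.scheme == "count":
        return float(array.count)
    if scheme.scheme == "consensus_weighted":
        return float(
            sum(scheme.w_full if t == CONSENSUS_TRIO else scheme.w_partial for t in array.trios)
        )
    # matrix: per-position base weights, summed over all trios
    assert scheme.matrix is not None
    total = 0.0
    for trio in array.trios:
        for pos, base in enumerate(trio):
            total += float(scheme.matrix[pos].get(base, 0.0))
    return total
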