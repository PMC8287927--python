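"""Shared test helpers: brute-force oracles and deterministic origin builders.

The oracles deliberately use different algorithms from the library (direct
per-window counting; phase-chunked run assembly) so agreement is evidence,
not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from busscan import OriginRecord, revcomp
from busscan.records import IUPAC_DNA
from busscan.simulate import inert_background, mutated_box

DEFAULT_MOTIF = "TTATCCACA"
LONG_MOTIF = "TTATCCACAGGT"


# ---------------------------------------------------------------- oracles


def brute_box_hits(sequence: str, motif: str, max_mm: int, strand: str = "+"):
    """All (start, mismatches) pairs by direct per-window counting."""
    s = sequence if strand == "+" else revcomp(sequence)
    m = len(motif)
    out = []
    for i in range(len(s) - m + 1):
        mm = sum(1 for a, b in zip(s[i : i + m], motif) if a not in IUPAC_DNA[b])
        if mm <= max_mm:
            out.append((i, mm))
    return out


def brute_trio_runs(sequence: str, strand: str = "+"):
    """All (start, trios) maximal N-A-N runs by phase-chunking the sequence."""
    s = sequence if strand == "+" else revcomp(sequence)
    out = []
    for phase in range(3):
        chunks = [
            (phase + 3 * k, s[phase + 3 * k : phase + 3 * k + 3])
            for k in range((len(s) - phase) // 3)
        ]
        current: list[tuple[int, str]] = []
        for start, chunk in chunks + [(-1, "")]:
            ok = len(chunk) == 3 and chunk[1] == "A" and "N" not in chunk
            if ok:
                current.append((start, chunk))
            elif current:
                out.append((current[0][0], tuple(c for _, c in current)))
                current = []
    return sorted(out, key=lambda r: r[0])


# ----------------------------------------------------- deterministic builds


def single_box_origin(
    mismatches: int = 0,
    spacer: int = 13,
    n_trios: int = 5,
    motif: str = DEFAULT_MOTIF,
    origin_id: str = "constructed",
    flank: int = 30,
):
    """Inert-background origin with one planted box + spacer + consensus trios.

    Returns (record, layout) where layout holds 0-based plus-strand offsets.
    """
    box = mutated_box(motif, mismatches)
    seq = (
        inert_background(flank)
        + box
        + inert_background(spacer, 3)
        + "TAG" * n_trios
        + inert_background(flank, 7)
    )
    layout = {
        "box_start": flank,
        "trio_start": flank + len(motif) + spacer,
        "spacer": spacer,
        "n_trios": n_trios,
    }
    return OriginRecord(id=origin_id, sequence=seq, box_motif=motif), layout


def tandem_origin(
    box1_mm: int = 0,
    box2_mm: int = 3,
    interbox_gap: int = 2,
    trio_gap: int = 4,
    n_trios: int = 5,
    motif: str = DEFAULT_MOTIF,
    origin_id: str = "constructed-tandem",
    flank: int = 30,
):
    """Anchor box + gap + second box + gap + consensus trios on inert background."""
    seq = (
        inert_background(flank)
        + mutated_box(motif, box1_mm)
        + inert_background(interbox_gap, 3)
        + mutated_box(motif, box2_mm)
        + inert_background(trio_gap, 6)
        + "TAG" * n_trios
        + inert_background(flank, 9)
    )
    layout = {
        "box1_start": flank,
        "box2_start": flank + len(motif) + interbox_gap,
        "trio_start": flank + 2 * len(motif) + interbox_gap + trio_gap,
        "spacer": interbox_gap + len(motif) + trio_gap,
    }
    return OriginRecord(id=origin_id, sequence=seq, box_motif=motif), layout


def multi_module_origin(modules, motif: str = DEFAULT_MOTIF, origin_id: str = "multi", sep: int = 30):
    """Several well-separated single-box modules in one origin.

    ``modules`` is a list of (mismatches, spacer, n_trios) tuples, planted
    left to right with ``sep`` bp of inert background between them (wide
    enough that no box can pair with a neighbouring module's trios).
    """
    parts = [inert_background(sep)]
    offsets = []
    pos = sep
    for mm, spacer, n_trios in modules:
        box = mutated_box(motif, mm)
        chunk = box + inert_background(spacer, 3) + "TAG" * n_trios
        parts.append(chunk)
        offsets.append(pos)
        pos += len(chunk)
        parts.append(inert_background(sep, 7))
        pos += sep
    return OriginRecord(id=origin_id, sequence="".join(parts), box_motif=motif), offsets


def random_dna(rng: np.random.Generator, length: int, n_frac: float = 0.0) -> str:
    bases = np.array(list("ACGTN"))
    p_n = n_frac
    p = [(1 - p_n) / 4] * 4 + [p_n]
    return "".join(rng.choice(bases, size=length, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
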