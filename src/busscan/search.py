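"""The BUS search proper: candidate enumeration and the screening cascade.

A BUS (basal unwinding system) module is one or two DnaA-boxes, a short
spacer, and a run of at least three N-A-N DnaA-trios.  The search has two
steps: (1) locate a first DnaA-box within 0-16 bp upstream of a qualifying
trio run; (2) look for a second, less conserved box either downstream of the
first (inside the spacer) or immediately upstream of it (gap <= 3 bp).  When
an upstream second box is strictly more conserved than the first, it becomes
the reference box and the spacer is recounted from it — the only way the
reported spacer can exceed 16 bp.

Screening then reduces the candidates of one origin to a single call by
three filters applied in a fixed order: highest trio score, then fewest
mismatches in the sole/more-conserved box, then spacer closest to 13 bp.
Residual ties are broken deterministically (plus strand first, then smallest
reference-box offset) and reported via ``tie_count``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import OriginRecord, SearchParams
from .scan import BoxHit, TrioArray, find_box_hits, find_trio_arrays, score_trios

__all__ = ["BusCandidate", "BusResult", "enumerate_candidates", "screen_candidates", "search_origin"]

_SCORE_TOL = 1e-9


@dataclass(frozen=True)
class BusCandidate:
    """One (box, optional second box, spacer, trio run) module.

    ``box1`` is the first-located box; ``box2`` the optional secondary.
    ``reference_box`` names which of the two anchors the spacer ("box1" or
    "box2"); ``spacer`` counts the bases strictly between the reference
    box's 3' end and the first trio.  ``primary_mismatches`` is the mismatch
    count of the sole box, or of the more conserved box of a tandem pair.
    All offsets are 0-based on the scanned strand.
    """

    box1: BoxHit
    box2: BoxHit | None
    reference_box: str
    spacer: int
    trios: TrioArray
    strand: str
    trio_score: float
    primary_mismatches: int

    @property
    def tandem(self) -> bool:
        return self.box2 is not None

    @property
    def reference(self) -> BoxHit:
        return self.box1 if self.reference_box == "box1" else self.box2  # type: ignore[return-value]

    @property
    def secondary(self) -> BoxHit | None:
        if self.box2 is None:
            return None
        return self.box2 if self.reference_box == "box1" else self.box1

    def _key(self) -> tuple:
        sec = self.secondary
        return (self.strand, self.reference.start, -1 if sec is None else sec.start, self.trios.start)


@dataclass(frozen=True)
class BusResult:
    """Outcome of searching one origin: at most one retained BUS call."""

    origin_id: str
    found: bool
    retained: BusCandidate | None
    tie_count: int
    candidates_considered: int
    organism: str = ""
    lineage: tuple[str, ...] = ()
    sequence_length: int = 0

    @property
    def phylum(self) -> str:
        return self.lineage[0] if self.lineage else "unclassified"


def _best_secondary(
    box1: BoxHit, run: TrioArray, hits: list[BoxHit], params: SearchParams
) -> BoxHit | None:
    """Pick the secondary box for a (box1, trio run) pair, if any.

    Two admissible windows: fully inside the spacer (downstream of box1), or
    immediately upstream of box1 with a gap of at most ``max_interbox_gap``.
    Among admissible hits the fewest mismatches wins; ties prefer the
    downstream (in-module) placement, then the hit closest to box1.
    """
    admissible: list[tuple[int, int, int, BoxHit]] = []
    for h in hits:
        if h.start == box1.start:
            continue
        if h.start >= box1.end and h.end <= run.start:
            # downstream, inside the spacer interval
            admissible.append((h.mismatches, 0, h.start - box1.end, h))
        elif h.end <= box1.start and box1.start - h.end <= params.max_interbox_gap:
            admissible.append((h.mismatches, 1, box1.start - h.end, h))
    if not admissible:
        return None
    admissible.sort(key=lambda t: (t[0], t[1], t[2]))
    return admissible[0][3]


def enumerate_candidates(origin: OriginRecord, params: SearchParams) -> list[BusCandidate]:
    """All BUS candidates of one origin, both strands, deduplicated.

    Returns an empty list for unsearchable origins.  Candidates are sorted
    by (strand, reference start, trio start) for reproducibility; screening
    is order-invariant regardless.
    """
    if not origin.searchable(params.min_trios):
        return []
    motif = origin.box_motif
    cap_first = params.cap_first_located(motif)
    cap_sole = params.cap_sole(motif)
    cap_primary = params.cap_primary_tandem(motif)
    scoring = params.trio_scoring
    strands = ("+", "-") if params.both_strands else ("+",)

    out: dict[tuple, BusCandidate] = {}
    for strand in strands:
        all_hits = find_box_hits(origin.sequence, motif, params.max_mm_secondary, strand)
        first_boxes = [h for h in all_hits if h.mismatches <= cap_first]
        if not first_boxes:
            continue
        runs = [
            r
            for r in find_trio_arrays(origin.sequence, strand)
            if r.count >= params.min_trios
        ]
        for run in runs:
            run_score = None
            for b1 in first_boxes:
                spacer1 = run.start - b1.end
                if spacer1 < 0 or spacer1 > params.max_spacer:
                    continue
                if run_score is None:
                    run_score = score_trios(run, scoring)
                b2 = _best_secondary(b1, run, all_hits, params)
                if b2 is not None and min(b1.mismatches, b2.mismatches) > cap_primary:
                    b2 = None  # pair exceeds the tandem primary cap; try as sole
                if b2 is None:
                    if b1.mismatches > cap_sole:
                        continue
                    cand = BusCandidate(
                        box1=b1,
                        box2=None,
                        reference_box="box1",
                        spacer=spacer1,
                        trios=run,
                        strand=strand,
                        trio_score=run_score,
                        primary_mismatches=b1.mismatches,
                    )
                else:
                    upstream = b2.end <= b1.start
                    takeover = upstream and b2.mismatches < b1.mismatches
                    reference = "box2" if takeover else "box1"
                    spacer = run.start - b2.end if takeover else spacer1
                    primary = min(b1.mismatches, b2.mismatches)
                    cand = BusCandidate(
                        box1=b1,
                        box2=b2,
                        reference_box=reference,
                        spacer=spacer,
                        trios=run,
                        strand=strand,
                        trio_score=run_score,
                        primary_mismatches=primary,
                    )
                out.setdefault(cand._key(), cand)
    return sorted(out.values(), key=lambda c: (c.strand, c.reference.start, c.trios.start))


def _tiebreak_key(cand: BusCandidate) -> tuple:
    return (
        0 if cand.strand == "+" else 1,
        cand.reference.start,
        cand.trios.start,
        -1 if cand.secondary is None else cand.secondary.start,
    )


def screen_candidates(
    candidates: list[BusCandidate], params: SearchParams, origin: OriginRecord | None = None
) -> BusResult:
    """Reduce candidates to one retained call via the three-filter cascade.

    Filters, in order: (1) keep the highest trio score; (2) keep the fewest
    primary mismatches; (3) keep the spacer closest to ``preferred_spacer``
    (13 bp).  ``tie_count`` counts the survivors of filter 3; the retained
    call is the survivor first in the deterministic tie-break order.
    """
    origin_id = origin.id if origin is not None else ""
    organism = origin.organism if origin is not None else ""
    lineage = origin.lineage if origin is not None else ()
    seq_len = len(origin.sequence) if origin is not None else 0
    if not candidates:
        return BusResult(origin_id, False, None, 0, 0, organism, lineage, seq_len)

    survivors = list(candidates)
    best_score = max(c.trio_score for c in survivors)
    survivors = [c for c in survivors if c.trio_score >= best_score - _SCORE_TOL]
    best_mm = min(c.primary_mismatches for c in survivors)
    survivors = [c for c in survivors if c.primary_mismatches == best_mm]
    best_dev = min(abs(c.spacer - params.preferred_spacer) for c in survivors)
    survivors = [c for c in survivors if abs(c.spacer - params.preferred_spacer) == best_dev]

    retained = min(survivors, key=_tiebreak_key)
    return BusResult(
        origin_id,
        True,
        retained,
        len(survivors),
        len(candidates),
        organism,
        lineage,
        seq_len,
    )


def search_origin(origin: OriginRecord, params: SearchParams | None = None) -> BusResult:
    """Enumerate then screen: the full per-origin BUS search."""
    params = params or SearchParams()
    return screen_candidates(enumerate_candidates(origin, params), params, origin)
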