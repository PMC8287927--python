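"""Seeded synthetic origins with planted BUS modules and known ground truth.

The generator emulates DoriC-style origin sequences: a random background of
controlled length and GC content carrying exactly one planted BUS module
(box, optional second box, spacer, trio run) with controlled mismatch
counts, spacer length, trio count and composition, on either strand.  The
background is cleaned by bounded repair-resampling so that outside the
planted locus there is no DnaA-box hit within the first-located mismatch
cap (either strand), no box hit within the secondary cap in the module's
secondary-search windows, and no N-A-N run long enough to qualify (either
strand).  Each generated origin is verified by running the scanner itself:
generation fails loudly rather than emit a fixture whose ground truth the
search could legitimately contradict.

Two conventions keep the planted truth unambiguous: tandem plants use
strictly ordered conservation (the anchoring box has strictly fewer
mismatches), and module edge bases (the two bases before the trio run, the
first base of trio 1, the third base of the last trio, and the two bases
after the run) are kept away from A so no phase-shifted trio run can tie
the planted run's length and score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import (
    CONSENSUS_TRIO,
    DEFAULT_BOX_MOTIF,
    OriginRecord,
    SearchParams,
    revcomp,
    validate_motif,
)
from .scan import TrioArray, find_box_hits, find_trio_arrays, score_trios
from .search import search_origin

logger = logging.getLogger("busscan")

__all__ = [
    "PlantSpec",
    "PlantTruth",
    "generate_origin",
    "generate_negative",
    "sample_spec",
    "inert_background",
    "mutated_box",
]

_MAX_ATTEMPTS = 40
_MAX_REPAIR_ITERS = 120

#: GC-only unit used for fully deterministic constructions: contains no A or
#: T, hence no N-A-N trio on either strand, and cannot approach an AT-rich
#: box motif within the search caps.
_INERT_UNIT = "CGGCCGCGGC"


def inert_background(n: int, phase: int = 0) -> str:
    """Deterministic GC-only filler of length ``n`` (no trios, no AT content)."""
    reps = (n + phase) // len(_INERT_UNIT) + 2
    return (_INERT_UNIT * reps)[phase : phase + n]


def _adjacent_gap_allowed(motif: str, arrangement: str, gap: int) -> bool:
    """Whether a trio-adjacent gap length is geometrically well posed.

    With a gap under 2 bp the two bases preceding the trio run fall inside
    the adjacent box.  If the box contributes an adenine in the run's own
    phase the maximal run absorbs it and the planted spacer/trio count no
    longer describe what a scanner must report (e.g. a 9-bp box ending in
    A with a 1-bp gap); in tandem arrangements an adenine one base before
    the run likewise seeds a phase-shifted run that an upstream box could
    pair with.  Such layouts are rejected rather than planted.
    """
    mlen = len(motif)
    rel2 = mlen + gap - 2  # lands two bases before the run
    if gap < 2 and 0 <= rel2 < mlen and motif[rel2] == "A":
        return False
    if arrangement != "sole":
        rel1 = mlen + gap - 1
        if gap < 2 and 0 <= rel1 < mlen and motif[rel1] == "A":
            return False
    return True


def mutated_box(
    motif: str, n_mismatches: int, rng: np.random.Generator | None = None
) -> str:
    """A copy of ``motif`` carrying exactly ``n_mismatches`` substitutions.

    Substituted bases are drawn from {C,G} (minus the original base), which
    never introduces an adenine and keeps the mutant from drifting toward
    AT-rich motifs.  With no ``rng`` the substituted positions are the first
    ``n_mismatches`` positions, deterministically.
    """
    motif = validate_motif(motif)
    if n_mismatches > len(motif):
        raise ValueError("more mismatches than motif positions")
    if rng is None:
        positions = list(range(n_mismatches))
    else:
        positions = sorted(rng.choice(len(motif), size=n_mismatches, replace=False).tolist())
    out = list(motif)
    for p in positions:
        choices = [b for b in "CG" if b != out[p]] or ["G"]
        out[p] = choices[0] if rng is None else str(rng.choice(choices))
    return "".join(out)


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic origin with a planted BUS module.

    ``arrangement`` is one of ``"sole"`` (one box), ``"tandem_down"``
    (second box downstream of the anchor, inside the spacer) or
    ``"tandem_up"`` (second, more conserved box immediately upstream; the
    takeover case).  For ``tandem_down`` the effective spacer is
    ``box2_gap + len(motif) + trio_gap`` and the anchor must be strictly
    more conserved (``box1_mm < box2_mm``); for ``tandem_up`` the upstream
    box must be strictly more conserved (``box2_mm < box1_mm``) and the
    effective spacer is ``box2_gap + len(motif) + spacer``.
    """

    seed: int
    background_length: int = 300
    gc: float = 0.5
    strand: str = "+"
    offset: int | None = None
    box_motif: str = DEFAULT_BOX_MOTIF
    arrangement: str = "sole"
    box1_mm: int = 0
    box2_mm: int = 0
    box2_gap: int = 2
    trio_gap: int = 4
    spacer: int = 13
    trio_count: int = 5
    trios: tuple[str, ...] | None = None
    expect: str = "auto"  # auto | found | absent | any

    def __post_init__(self) -> None:
        object.__setattr__(self, "box_motif", validate_motif(self.box_motif))
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.arrangement not in ("sole", "tandem_down", "tandem_up"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.trios is not None:
            if len(self.trios) != self.trio_count:
                raise ValueError("trios length must equal trio_count")
            for t in self.trios:
                if len(t) != 3 or t[1] != "A" or "N" in t:
                    raise ValueError(f"planted trio {t!r} is not N-A-N")
        if self.arrangement == "tandem_down" and self.box1_mm >= self.box2_mm:
            raise ValueError("tandem_down requires box1_mm < box2_mm (anchor more conserved)")
        if self.arrangement == "tandem_up" and self.box2_mm >= self.box1_mm:
            raise ValueError("tandem_up requires box2_mm < box1_mm (upstream box takes over)")
        gap = self.trio_gap if self.arrangement == "tandem_down" else self.spacer
        if not _adjacent_gap_allowed(self.box_motif, self.arrangement, gap):
            raise ValueError(
                f"trio-adjacent gap of {gap} bp places a motif adenine in the "
                "trio run's extension frame; choose a different gap length"
            )

    @property
    def tandem(self) -> bool:
        return self.arrangement != "sole"

    def effective_spacer(self) -> int:
        """Spacer from the anchoring (reference) box to the first trio."""
        mlen = len(self.box_motif)
        if self.arrangement == "sole":
            return self.spacer
        if self.arrangement == "tandem_down":
            return self.box2_gap + mlen + self.trio_gap
        return self.box2_gap + mlen + self.spacer


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth recorded at plant time (scanned-strand coordinates)."""

    origin_id: str
    strand: str
    ref_start: int
    ref_mm: int
    tandem: bool
    secondary_start: int | None
    secondary_mm: int | None
    spacer: int
    trio_start: int
    trio_count: int
    trio_score: float
    trios: tuple[str, ...]
    sequence_length: int
    detectable: bool


def _module_trios(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, ...]:
    if spec.trios is not None:
        return spec.trios
    return tuple(CONSENSUS_TRIO for _ in range(spec.trio_count))


def _random_trios(count: int, rng: np.random.Generator, p_consensus: float = 0.5) -> tuple[str, ...]:
    """Random N-A-N trios; edge bases constrained away from A (see module docstring)."""
    trios = []
    for i in range(count):
        if rng.random() < p_consensus:
            trios.append(CONSENSUS_TRIO)
            continue
        first = str(rng.choice(list("CGT" if i == 0 else "ACGT")))
        third = str(rng.choice(list("CGT" if i == count - 1 else "ACGT")))
        trios.append(first + "A" + third)
    # enforce edge constraints even when consensus draw did not apply
    if trios[0][0] == "A":
        trios[0] = str(rng.choice(list("CGT"))) + trios[0][1:]
    if trios[-1][2] == "A":
        trios[-1] = trios[-1][:2] + str(rng.choice(list("CGT")))
    return tuple(trios)


def _mutate_box(motif: str, m: int, rng: np.random.Generator, forbid_a: set[int]) -> str:
    """Plant ``m`` substitutions; positions in ``forbid_a`` never become A."""
    out = list(motif)
    positions = rng.choice(len(motif), size=m, replace=False)
    for p in sorted(int(x) for x in positions):
        choices = [b for b in "ACGT" if b != out[p]]
        if p in forbid_a and "A" in choices:
            choices.remove("A")
        out[p] = str(rng.choice(choices))
    return "".join(out)


def _build_module(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, dict]:
    """Assemble the module string (module strand, 5'->3') and its layout map."""
    motif = spec.box_motif
    mlen = len(motif)
    trios = _module_trios(spec, rng)
    trio_str = "".join(trios)

    def gap_str(n: int, forbid_a_last2: bool = False) -> str:
        # spacer/gap filler; bases drawn uniformly, optionally forcing the
        # last two bases (adjacent to the trio run) away from A
        bases = [str(rng.choice(list("ACGT"))) for _ in range(n)]
        if forbid_a_last2:
            for k in (n - 1, n - 2):
                if k >= 0 and bases[k] == "A":
                    bases[k] = str(rng.choice(list("CGT")))
        return "".join(bases)

    if spec.arrangement == "sole":
        # positions t0-1, t0-2 relative to trio start must avoid A; when the
        # spacer is shorter than 2 those positions fall inside the box
        forbid = set()
        for d in (1, 2):
            rel = mlen + spec.spacer - d
            if 0 <= rel < mlen:
                forbid.add(rel)
        box1 = _mutate_box(motif, spec.box1_mm, rng, forbid)
        module = box1 + gap_str(spec.spacer, forbid_a_last2=True) + trio_str
        layout = {"box1": 0, "box2": None, "ref": 0, "trio": mlen + spec.spacer}
    elif spec.arrangement == "tandem_down":
        # [box1 (anchor)] [box2_gap] [box2] [trio_gap] [trios]
        forbid2 = set()
        for d in (1, 2):
            rel = mlen + spec.trio_gap - d
            if 0 <= rel < mlen:
                forbid2.add(rel)
        box1 = _mutate_box(motif, spec.box1_mm, rng, set())
        box2 = _mutate_box(motif, spec.box2_mm, rng, forbid2)
        module = (
            box1
            + gap_str(spec.box2_gap)
            + box2
            + gap_str(spec.trio_gap, forbid_a_last2=True)
            + trio_str
        )
        b2 = mlen + spec.box2_gap
        layout = {"box1": 0, "box2": b2, "ref": 0, "trio": b2 + mlen + spec.trio_gap}
    else:  # tandem_up: [box2 (anchor)] [box2_gap] [box1] [spacer] [trios]
        forbid1 = set()
        for d in (1, 2):
            rel = mlen + spec.spacer - d
            if 0 <= rel < mlen:
                forbid1.add(rel)
        box2 = _mutate_box(motif, spec.box2_mm, rng, set())
        box1 = _mutate_box(motif, spec.box1_mm, rng, forbid1)
        module = (
            box2
            + gap_str(spec.box2_gap)
            + box1
            + gap_str(spec.spacer, forbid_a_last2=True)
            + trio_str
        )
        b1 = mlen + spec.box2_gap
        layout = {"box1": b1, "box2": 0, "ref": 0, "trio": b1 + mlen + spec.spacer}
    layout["trios"] = trios
    layout["module_len"] = len(module)
    return module, layout


def _random_background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    return rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=[p_at, p_gc, p_gc, p_at]
    )


def _detectable(spec: PlantSpec, params: SearchParams) -> bool:
    """Whether the planted module satisfies every search threshold."""
    motif = spec.box_motif
    cap_sole = params.cap_sole(motif)
    cap_primary = params.cap_primary_tandem(motif)
    cap_first = params.cap_first_located(motif)
    if spec.trio_count < params.min_trios:
        return False
    if spec.arrangement == "sole":
        return spec.box1_mm <= cap_sole and spec.spacer <= params.max_spacer
    if spec.arrangement == "tandem_down":
        if min(spec.box1_mm, spec.box2_mm) > cap_primary:
            return False
        if spec.box2_mm > params.max_mm_secondary:
            return False
        # route 1: the anchor itself is first-located within the spacer cap,
        # the second box sits inside the spacer interval
        if spec.box1_mm <= cap_first and spec.effective_spacer() <= params.max_spacer:
            return True
        # route 2: the downstream box is first-located and the more conserved
        # upstream box takes over (spacer may then exceed the cap)
        return (
            spec.box2_mm <= cap_first
            and spec.trio_gap <= params.max_spacer
            and spec.box2_gap <= params.max_interbox_gap
        )
    # tandem_up: [box2][gap][box1][spacer][trios], box2 strictly more conserved
    if spec.box2_mm > cap_primary or spec.box1_mm > params.max_mm_secondary:
        return False
    # route 1: box1 first-located, upstream box2 found in the gap window, takeover
    if (
        spec.box1_mm <= cap_first
        and spec.spacer <= params.max_spacer
        and spec.box2_gap <= params.max_interbox_gap
    ):
        return True
    # route 2: box2 itself first-located (its whole spacer within the cap),
    # box1 found downstream inside the spacer interval
    return spec.box2_mm <= cap_first and spec.effective_spacer() <= params.max_spacer


def _scan_violations(
    seq: str,
    locked: np.ndarray,
    planted_boxes: list[tuple[int, int]],
    planted_run: tuple[int, int] | None,
    planted_module: tuple[int, int] | None,
    zone: tuple[int, int] | None,
    motif: str,
    params: SearchParams,
) -> list[tuple[str, list[int]]]:
    """Spurious features to repair: each as (kind, candidate positions to mutate).

    Positions are forward-strand, unlocked only.  An empty position list
    marks an unfixable violation (fully locked), which aborts the attempt.
    """
    n = len(seq)
    mlen = len(motif)
    cap_first = params.cap_first_located(motif)
    planted = set(planted_boxes)
    violations: list[tuple[str, list[int]]] = []

    for strand in ("+", "-"):
        for hit in find_box_hits(seq, motif, params.max_mm_secondary, strand):
            if strand == "+":
                fs, fe = hit.start, hit.end
            else:
                fs, fe = n - hit.end, n - hit.start
            is_planted = strand == "+" and (fs, fe) in planted
            if is_planted:
                continue
            in_zone = zone is not None and strand == "+" and fs >= zone[0] and fe <= zone[1]
            if hit.mismatches <= cap_first or in_zone:
                if planted_run is not None:
                    # a box-like window confined to the planted trio block
                    # (trio compositions can spell a near-reverse-complement
                    # of the motif) is left alone: it is unrepairable without
                    # touching planted bases, and any candidate it seeds
                    # scores strictly below the planted run — generation-time
                    # verification has the final word
                    if fs >= planted_run[0] - 2 and fe <= planted_run[1] + 2:
                        continue
                free = [p for p in range(fs, fe) if not locked[p]]
                violations.append(("box", free))

    for strand in ("+", "-"):
        for run in find_trio_arrays(seq, strand):
            if run.count < params.min_trios:
                continue
            if strand == "+":
                fs, fe = run.start, run.end
                middles = [run.start + 3 * k + 1 for k in range(run.count)]
            else:
                fs, fe = n - run.end, n - run.start
                middles = [n - 1 - (run.start + 3 * k + 1) for k in range(run.count)]
            if planted_run is not None:
                if strand == "+" and (fs, fe) == planted_run:
                    continue  # the planted run itself
                # Runs confined to the planted locus are harmless and often
                # unrepairable (their bases are locked).  Plus strand: runs
                # inside the padded trio block are phase-shifted, strictly
                # shorter and lower scoring than the plant.  Minus strand:
                # runs anywhere inside the padded module (box terminal T's
                # can seed them) have no minus-strand box within cap to pair
                # with; generation-time verification has the final word.
                if strand == "+":
                    if fs >= planted_run[0] - 2 and fe <= planted_run[1] + 2:
                        continue
                elif planted_module is not None:
                    if fs >= planted_module[0] - 2 and fe <= planted_module[1] + 2:
                        continue
            free = [p for p in middles if not locked[p]]
            violations.append(("trio_run", free))

    # planted-run edge bases must stay non-A so the run cannot extend; a
    # locked adenine two bases before the run would extend it in-phase and
    # cannot be repaired (the PlantSpec validator rules this out up front),
    # while a locked adenine one base before it is harmless in sole plants
    if planted_run is not None:
        t0, tend = planted_run
        for p in (t0 - 2, t0 - 1, tend, tend + 1):
            if 0 <= p < n and seq[p] == "A":
                if not locked[p]:
                    violations.append(("edge", [p]))
                elif p == t0 - 2:
                    violations.append(("edge", []))
    return violations


def _assemble_and_repair(
    spec: PlantSpec, params: SearchParams, rng: np.random.Generator
) -> tuple[str, dict] | None:
    """One generation attempt: assemble, then repair the background; None on stall."""
    module, layout = _build_module(spec, rng)
    mlen = len(spec.box_motif)
    mod_len = layout["module_len"]
    margin = 4
    if spec.background_length < mod_len + 2 * margin + 2:
        raise ValueError("background_length too short for the planted module")
    if spec.offset is not None:
        off = spec.offset
        if off < 0 or off + mod_len > spec.background_length:
            raise ValueError("offset does not fit in background")
    else:
        off = int(rng.integers(margin, spec.background_length - mod_len - margin + 1))

    arr = _random_background(spec.background_length, spec.gc, rng)
    arr[off : off + mod_len] = np.frombuffer(module.encode("ascii"), dtype=np.uint8)

    locked = np.zeros(spec.background_length, dtype=bool)
    planted_boxes = [(off + layout["box1"], off + layout["box1"] + mlen)]
    if layout["box2"] is not None:
        planted_boxes.append((off + layout["box2"], off + layout["box2"] + mlen))
    for fs, fe in planted_boxes:
        locked[fs:fe] = True
    t0 = off + layout["trio"]
    tend = t0 + 3 * spec.trio_count
    locked[t0:tend] = True
    planted_run = (t0, tend)
    upstream_edge = min(fs for fs, _ in planted_boxes)
    zone = (max(0, upstream_edge - mlen - params.max_interbox_gap), t0)

    gc_codes = np.frombuffer(b"CG", dtype=np.uint8)
    for _ in range(_MAX_REPAIR_ITERS):
        seq = arr.tobytes().decode("ascii")
        violations = _scan_violations(
            seq,
            locked,
            planted_boxes,
            planted_run,
            (off, off + mod_len),
            zone,
            spec.box_motif,
            params,
        )
        if not violations:
            return seq, {**layout, "offset": off}
        for kind, free in violations:
            if not free:
                return None  # fully locked violation: retry with a fresh draw
            pos = int(rng.choice(free))
            current = arr[pos]
            choices = gc_codes[gc_codes != current]
            arr[pos] = choices[0] if len(choices) == 1 else rng.choice(choices)
    return None


def generate_origin(
    spec: PlantSpec,
    params: SearchParams | None = None,
    origin_id: str = "synthetic",
    organism: str = "synthetic construct",
    lineage: tuple[str, ...] = (),
) -> tuple[OriginRecord, PlantTruth]:
    """Generate one synthetic origin and its ground truth.

    Deterministic for a fixed spec (byte-identical sequences across runs).
    The result is verified by running ``search_origin``: a detectable plant
    must be recovered exactly (strand, reference start, spacer, trio count),
    an undetectable one must yield no call.  Raises ``RuntimeError`` with
    the seed after a bounded number of failed attempts.
    """
    params = params or SearchParams()
    mlen = len(spec.box_motif)
    detectable = _detectable(spec, params)
    if spec.expect == "found" and not detectable:
        raise ValueError("spec.expect='found' but parameters are outside the search rules")

    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng([spec.seed % (2**31), attempt])
        built = _assemble_and_repair(spec, params, rng)
        if built is None:
            continue
        seq, layout = built
        off = layout["offset"]
        ref_scan = off + layout["ref"]
        trio_scan = off + layout["trio"]
        trios = layout["trios"]
        score = score_trios(TrioArray(trio_scan, "+", trios), params.trio_scoring)
        sec_start = None
        sec_mm = None
        if spec.arrangement == "tandem_down":
            sec_start, sec_mm = off + layout["box2"], spec.box2_mm
            ref_mm = spec.box1_mm
        elif spec.arrangement == "tandem_up":
            sec_start, sec_mm = off + layout["box1"], spec.box1_mm
            ref_mm = spec.box2_mm
        else:
            ref_mm = spec.box1_mm

        final_seq = seq if spec.strand == "+" else revcomp(seq)
        record = OriginRecord(
            id=origin_id,
            sequence=final_seq,
            organism=organism,
            lineage=lineage,
            box_motif=spec.box_motif,
        )
        truth = PlantTruth(
            origin_id=origin_id,
            strand=spec.strand,
            ref_start=ref_scan,
            ref_mm=ref_mm,
            tandem=spec.tandem,
            secondary_start=sec_start,
            secondary_mm=sec_mm,
            spacer=spec.effective_spacer(),
            trio_start=trio_scan,
            trio_count=spec.trio_count,
            trio_score=score,
            trios=trios,
            sequence_length=len(final_seq),
            detectable=detectable,
        )
        if _verify(record, truth, spec, params):
            return record, truth
    raise RuntimeError(
        f"could not generate a verified origin for seed {spec.seed} "
        f"after {_MAX_ATTEMPTS} attempts"
    )


def _verify(record: OriginRecord, truth: PlantTruth, spec: PlantSpec, params: SearchParams) -> bool:
    expect = spec.expect
    if expect == "any":
        return True
    if expect == "auto":
        expect = "found" if truth.detectable else "absent"
    result = search_origin(record, params)
    if expect == "absent":
        return not result.found
    if not result.found:
        return False
    cand = result.retained
    return (
        cand.strand == truth.strand
        and cand.reference.start == truth.ref_start
        and cand.spacer == truth.spacer
        and cand.trios.count == truth.trio_count
        and cand.trios.start == truth.trio_start
        and cand.tandem == truth.tandem
    )


def generate_negative(
    length: int = 300,
    gc: float = 0.5,
    seed: int = 0,
    params: SearchParams | None = None,
    origin_id: str = "negative",
) -> OriginRecord:
    """A background-only origin: no box hit within cap, no qualifying trio run.

    Scanning it must yield ``found=False``; generation verifies this.
    """
    params = params or SearchParams()
    motif = DEFAULT_BOX_MOTIF
    locked = np.zeros(length, dtype=bool)
    gc_codes = np.frombuffer(b"CG", dtype=np.uint8)
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng([seed % (2**31), 7919, attempt])
        arr = _random_background(length, gc, rng)
        for _ in range(_MAX_REPAIR_ITERS):
            seq = arr.tobytes().decode("ascii")
            violations = _scan_violations(seq, locked, [], None, None, None, motif, params)
            # without a plant, only first-cap boxes and qualifying runs matter
            if not violations:
                record = OriginRecord(id=origin_id, sequence=seq, box_motif=motif)
                if not search_origin(record, params).found:
                    return record
                break
            for _, free in violations:
                pos = int(rng.choice(free))
                current = arr[pos]
                choices = gc_codes[gc_codes != current]
                arr[pos] = choices[0] if len(choices) == 1 else rng.choice(choices)
        else:
            continue
    raise RuntimeError(f"could not generate a negative control for seed {seed}")


def sample_spec(rng: np.random.Generator, motif: str = DEFAULT_BOX_MOTIF) -> PlantSpec:
    """Draw one random plant spec spanning the legal parameter box.

    Arrangements are mixed (sole, tandem with the second box downstream or
    upstream); mismatch counts, gaps, spacer lengths, trio counts and trio
    composition cover the full ranges admitted by the default rules, under
    the generator's strict-conservation convention for tandem pairs.
    """
    params = SearchParams()
    mlen = len(validate_motif(motif))
    cap = params.cap_sole(motif)
    arrangement = str(rng.choice(["sole", "tandem_down", "tandem_up"], p=[0.5, 0.3, 0.2]))
    strand = str(rng.choice(["+", "-"]))
    trio_count = int(rng.integers(3, 9))
    trios = _random_trios(trio_count, rng)
    kwargs = dict(
        seed=int(rng.integers(0, 2**31)),
        gc=float(rng.uniform(0.35, 0.65)),
        strand=strand,
        box_motif=motif,
        arrangement=arrangement,
        trio_count=trio_count,
        trios=trios,
    )
    def draw_gap(high: int) -> int:
        while True:
            g = int(rng.integers(0, high + 1))
            if _adjacent_gap_allowed(motif, arrangement, g):
                return g

    if arrangement == "sole":
        kwargs.update(box1_mm=int(rng.integers(0, cap + 1)), spacer=draw_gap(params.max_spacer))
        mod_len = mlen + kwargs["spacer"] + 3 * trio_count
    elif arrangement == "tandem_down":
        box1_mm = int(rng.integers(0, cap + 1))
        box2_mm = int(rng.integers(box1_mm + 1, params.max_mm_secondary + 1))
        box2_gap = int(rng.integers(0, params.max_interbox_gap + 1))
        trio_gap = draw_gap(params.max_spacer - mlen - box2_gap)
        kwargs.update(box1_mm=box1_mm, box2_mm=box2_mm, box2_gap=box2_gap, trio_gap=trio_gap)
        mod_len = 2 * mlen + box2_gap + trio_gap + 3 * trio_count
    else:
        box1_mm = int(rng.integers(1, cap + 1))
        box2_mm = int(rng.integers(0, box1_mm))
        box2_gap = int(rng.integers(0, params.max_interbox_gap + 1))
        spacer = draw_gap(params.max_spacer)
        kwargs.update(box1_mm=box1_mm, box2_mm=box2_mm, box2_gap=box2_gap, spacer=spacer)
        mod_len = 2 * mlen + box2_gap + spacer + 3 * trio_count
    kwargs["background_length"] = mod_len + int(rng.integers(40, 121))
    return PlantSpec(**kwargs)
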