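"""Core records: origin sequences and search parameters.

An origin record is one predicted *oriC* sequence (e.g. a DoriC entry)
together with the standard DnaA-box motif used to scan it.  The default
standard motif is the *E. coli* highest-affinity DnaA-box 5'-TTATCCACA-3';
species with a divergent box carry their species-specific motif instead,
which may use IUPAC ambiguity codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "DEFAULT_BOX_MOTIF",
    "CONSENSUS_TRIO",
    "revcomp",
    "OriginRecord",
    "TrioScoring",
    "SearchParams",
]

#: E. coli highest-affinity DnaA-box, 5'->3'.
DEFAULT_BOX_MOTIF = "TTATCCACA"

#: DnaA-trio consensus written 5'->3' on the scanned strand.  The field
#: convention writes the trio consensus 3'-GAT-5'; read in the 5'->3'
#: direction this is TAG.
CONSENSUS_TRIO = "TAG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes expanded to the concrete bases they stand for.
#: Used for motif positions only: an ambiguity code in a *motif* is a
#: wildcard over its expansion, while an N in a *sequence* never matches.
IUPAC_DNA = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SEQUENCE_ALPHABET = frozenset("ACGTN")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str) -> str:
    """Uppercase ``raw`` and check it is DNA over {A,C,G,T,N}.

    Raises
    ------
    ValueError
        If any character outside the alphabet remains after uppercasing.
    """
    seq = raw.strip().upper()
    bad = set(seq) - _SEQUENCE_ALPHABET
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)!r}")
    return seq


def validate_motif(motif: str) -> str:
    """Uppercase a box motif and check it only uses IUPAC codes."""
    m = motif.strip().upper()
    if not m:
        raise ValueError("empty box motif")
    bad = set(m) - set(IUPAC_DNA)
    if bad:
        raise ValueError(f"illegal motif characters: {sorted(bad)!r}")
    return m


@dataclass(frozen=True)
class OriginRecord:
    """One predicted replication-origin sequence with its scan motif.

    Parameters
    ----------
    id : str
        Accession or other unique identifier.
    sequence : str
        Origin DNA, uppercased, over {A,C,G,T,N}.
    organism : str
        Free-text organism name.
    lineage : tuple of str
        Ordered taxonomic ranks, highest first; may be empty.
    box_motif : str
        Standard DnaA-box motif (>= 9 bp); IUPAC ambiguity codes allowed.
    """

    id: str
    sequence: str
    organism: str = ""
    lineage: tuple[str, ...] = ()
    box_motif: str = DEFAULT_BOX_MOTIF

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        object.__setattr__(self, "box_motif", validate_motif(self.box_motif))
        object.__setattr__(self, "lineage", tuple(self.lineage))

    @property
    def phylum(self) -> str:
        """First lineage rank, or ``"unclassified"`` when absent."""
        return self.lineage[0] if self.lineage else "unclassified"

    def searchable(self, min_trios: int = 3) -> bool:
        """Whether the sequence can hold a box, a zero spacer and ``min_trios`` trios."""
        return len(self.sequence) >= len(self.box_motif) + 3 * min_trios


_SCHEMES = ("consensus_weighted", "count", "matrix")


@dataclass(frozen=True)
class TrioScoring:
    """DnaA-trio run scoring scheme.

    ``consensus_weighted`` (default): each trio contributes ``w_full`` when it
    equals the consensus TAG (3'-GAT-5'), else ``w_partial``.  ``count``: the
    score is the number of trios.  ``matrix``: each trio contributes the sum of
    per-position weights from ``matrix`` (keys are bases, one mapping per trio
    position).
    """

    scheme: str = "consensus_weighted"
    w_full: float = 3.0
    w_partial: float = 1.0
    matrix: tuple[dict[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(
                f"unknown trio scoring scheme {self.scheme!r}; expected one of {_SCHEMES}"
            )
        if self.scheme == "matrix":
            if self.matrix is None or len(self.matrix) != 3:
                raise ValueError("matrix scheme requires three per-position weight maps")
            object.__setattr__(self, "matrix", tuple(dict(m) for m in self.matrix))


@dataclass(frozen=True)
class SearchParams:
    """Thresholds of the BUS search rule set.

    All mismatch counts are Hamming distances (no indels).  Defaults encode
    the trained rule set: a sole 9-bp box tolerates 2 mismatches, the more
    conserved box of a tandem pair 2, the less conserved 4; motifs longer
    than 9 bp raise the sole/primary cap to 3; the spacer between the
    reference box and the first trio is capped at 16 bp (3 bp inter-box gap
    + 9 bp secondary box + 4 bp second gap); at least 3 N-A-N trios are
    required; screening prefers spacers closest to 13 bp.
    """

    max_mm_sole_9: int = 2
    max_mm_primary_tandem_9: int = 2
    max_mm_secondary: int = 4
    max_mm_long_motif: int = 3
    max_spacer: int = 16
    min_trios: int = 3
    preferred_spacer: int = 13
    max_interbox_gap: int = 3
    trio_scoring: TrioScoring = field(default_factory=TrioScoring)
    both_strands: bool = True

    def __post_init__(self) -> None:
        for name in (
            "max_mm_sole_9",
            "max_mm_primary_tandem_9",
            "max_mm_secondary",
            "max_mm_long_motif",
            "max_spacer",
            "min_trios",
            "preferred_spacer",
            "max_interbox_gap",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        if self.min_trios < 1:
            raise ValueError("min_trios must be >= 1")
        if self.preferred_spacer > self.max_spacer:
            raise ValueError("preferred_spacer must not exceed max_spacer")

    def cap_first_located(self, motif: str) -> int:
        """Mismatch cap for the first-located box (also the sole/primary cap base)."""
        if len(motif) > 9:
            return self.max_mm_long_motif
        return max(self.max_mm_sole_9, self.max_mm_primary_tandem_9)

    def cap_sole(self, motif: str) -> int:
        return self.max_mm_long_motif if len(motif) > 9 else self.max_mm_sole_9

    def cap_primary_tandem(self, motif: str) -> int:
        return self.max_mm_long_motif if len(motif) > 9 else self.max_mm_primary_tandem_9

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SearchParams":
        """Build parameters from a plain mapping (e.g. a YAML config)."""
        data = dict(mapping)
        scoring = data.pop("trio_scoring", None)
        if scoring is not None and not isinstance(scoring, TrioScoring):
            scoring = TrioScoring(**scoring)
        kwargs = {k: v for k, v in data.items()}
        if scoring is not None:
            kwargs["trio_scoring"] = scoring
        return cls(**kwargs)

    def with_(self, **kwargs) -> "SearchParams":
        return replace(self, **kwargs)
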