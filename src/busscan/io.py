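"""Reading origin sequences and writing/reading result tables.

Inputs are FASTA (one record per predicted origin) or a DoriC-style
tab-separated table with a header row; outputs are a TSV (or JSON) result
table with one row per origin.  Reported coordinates are 1-based inclusive
on the forward strand of the input sequence; the strand column records the
orientation of the retained module.  Sequence columns hold forward-strand
slices, so slicing the input with the reported coordinates reproduces them
exactly; the ``trios`` column additionally carries the motif-strand 3-mers
(box-proximal first) used by the cohort statistics.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .records import DEFAULT_BOX_MOTIF, OriginRecord, revcomp
from .search import BusResult

logger = logging.getLogger("busscan")

__all__ = ["read_origins", "results_to_table", "write_results", "read_results", "RESULT_COLUMNS"]

# Accepted column aliases for the DoriC-style table dialect.
_ID_COLS = ("id", "accession", "refseq")
_SEQ_COLS = ("sequence", "oric_sequence", "seq")
_ORG_COLS = ("organism",)
_LINEAGE_COLS = ("lineage",)
_MOTIF_COLS = ("box_motif", "dnaa_box", "motif")

RESULT_COLUMNS = [
    "id",
    "organism",
    "lineage",
    "found",
    "strand",
    "candidates_considered",
    "tie_count",
    "box1_start",
    "box1_end",
    "box1_seq",
    "box1_mm",
    "box2_start",
    "box2_end",
    "box2_seq",
    "box2_mm",
    "reference_box",
    "spacer",
    "trio_start",
    "trio_end",
    "trio_seq",
    "trio_count",
    "trio_score",
    "trios",
]


def _pick(columns: Iterable[str], aliases: tuple[str, ...]) -> str | None:
    lowered = {c.lower(): c for c in columns}
    for a in aliases:
        if a in lowered:
            return lowered[a]
    return None


def read_origins(
    path: str | Path, format: str = "fasta", default_motif: str = DEFAULT_BOX_MOTIF
) -> list[OriginRecord]:
    """Read origin records from FASTA or a DoriC-style table.

    Records whose sequence contains characters outside {A,C,G,T,N} after
    uppercasing are rejected with a logged reason; the run continues.  An
    empty input yields an empty list with a warning.

    Parameters
    ----------
    path : path
        Input file.
    format : {"fasta", "doric_table"}
        ``doric_table`` is tab-separated with a header row naming at least an
        id and a sequence column; ``organism``, ``lineage`` (semicolon-
        separated ranks) and ``box_motif`` columns are optional.
    default_motif : str
        Standard DnaA-box used when a record carries no species-specific one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[OriginRecord] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            desc = rec.description
            organism = desc[len(rec.id) :].strip() if desc.startswith(rec.id) else desc
            try:
                records.append(
                    OriginRecord(
                        id=rec.id,
                        sequence=str(rec.seq),
                        organism=organism,
                        box_motif=default_motif,
                    )
                )
            except ValueError as exc:
                logger.warning("rejecting record %s: %s", rec.id, exc)
    elif format == "doric_table":
        table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        id_col = _pick(table.columns, _ID_COLS)
        seq_col = _pick(table.columns, _SEQ_COLS)
        if id_col is None or seq_col is None:
            raise ValueError(
                f"doric_table must name an id column {_ID_COLS} and a sequence column {_SEQ_COLS}"
            )
        org_col = _pick(table.columns, _ORG_COLS)
        lin_col = _pick(table.columns, _LINEAGE_COLS)
        motif_col = _pick(table.columns, _MOTIF_COLS)
        for _, row in table.iterrows():
            lineage = ()
            if lin_col and row[lin_col]:
                lineage = tuple(p.strip() for p in row[lin_col].split(";") if p.strip())
            motif = row[motif_col].strip() if motif_col and row[motif_col].strip() else default_motif
            try:
                records.append(
                    OriginRecord(
                        id=str(row[id_col]),
                        sequence=row[seq_col],
                        organism=row[org_col] if org_col else "",
                        lineage=lineage,
                        box_motif=motif,
                    )
                )
            except ValueError as exc:
                logger.warning("rejecting record %s: %s", row[id_col], exc)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        logger.warning("no origin records read from %s", path)
    return records


def _fwd_interval(start: int, length: int, strand: str, seq_len: int) -> tuple[int, int]:
    """Scanned-strand offset -> 1-based inclusive forward-strand interval."""
    if strand == "+":
        s0 = start
    else:
        s0 = seq_len - (start + length)
    return s0 + 1, s0 + length


def _fwd_seq(observed: str, strand: str) -> str:
    return observed if strand == "+" else revcomp(observed)


def results_to_table(results: list[BusResult]) -> pd.DataFrame:
    """Canonical one-row-per-origin result table (see module docstring)."""
    rows = []
    for res in results:
        row: dict = {c: "" for c in RESULT_COLUMNS}
        row.update(
            id=res.origin_id,
            organism=res.organism,
            lineage=";".join(res.lineage),
            found=res.found,
            candidates_considered=res.candidates_considered,
            tie_count=res.tie_count,
        )
        cand = res.retained
        if cand is not None:
            L = res.sequence_length
            b1s, b1e = _fwd_interval(cand.box1.start, len(cand.box1.motif), cand.strand, L)
            row.update(
                strand=cand.strand,
                box1_start=b1s,
                box1_end=b1e,
                box1_seq=_fwd_seq(cand.box1.observed, cand.strand),
                box1_mm=cand.box1.mismatches,
                reference_box=cand.reference_box,
                spacer=cand.spacer,
                trio_count=cand.trios.count,
                trio_score=cand.trio_score,
                trios=",".join(cand.trios.trios),
            )
            ts, te = _fwd_interval(cand.trios.start, 3 * cand.trios.count, cand.strand, L)
            row.update(
                trio_start=ts,
                trio_end=te,
                trio_seq=_fwd_seq("".join(cand.trios.trios), cand.strand),
            )
            if cand.box2 is not None:
                b2s, b2e = _fwd_interval(cand.box2.start, len(cand.box2.motif), cand.strand, L)
                row.update(
                    box2_start=b2s,
                    box2_end=b2e,
                    box2_seq=_fwd_seq(cand.box2.observed, cand.strand),
                    box2_mm=cand.box2.mismatches,
                )
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: list[BusResult], path: str | Path, format: str = "tsv") -> None:
    """Write the result table as TSV or JSON (one object per row)."""
    table = results_to_table(results)
    path = Path(path)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = table.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a result table back (e.g. for cohort summarisation)."""
    path = Path(path)
    if format == "tsv":
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    elif format == "json":
        table = pd.DataFrame(json.loads(path.read_text()))
        if table.empty:
            table = pd.DataFrame(columns=RESULT_COLUMNS)
        table = table.astype(str)
    else:
        raise ValueError(f"unknown format {format!r}")
    missing = set(RESULT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"result table missing columns: {sorted(missing)}")
    return table
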