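"""Cohort-level aggregation of BUS search results.

Aggregates per-origin calls into the survey statistics of interest for a
comparative scan across many origins: prevalence of the module, the fraction
of found modules carrying a tandem box pair, the spacer-length histogram,
and per-trio-position base frequencies (trio 1 is the box-proximal trio).
The same statistics are also computed per phylum (first lineage rank) for
phyla with enough sampled genomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import RESULT_COLUMNS, results_to_table
from .search import BusResult

__all__ = ["GroupStats", "CohortSummary", "summarize", "export_tracks"]

_BASES = "ACGT"


@dataclass(frozen=True)
class GroupStats:
    """Aggregate statistics for one group of origins (whole cohort or one phylum)."""

    n_origins: int
    n_found: int
    prevalence: float
    prevalence_defined: bool
    tandem_fraction: float
    spacer_histogram: dict[int, int]
    trio_position_freqs: dict[int, list[dict[str, float]]]

    def to_dict(self) -> dict:
        return {
            "n_origins": self.n_origins,
            "n_found": self.n_found,
            "prevalence": self.prevalence,
            "prevalence_defined": self.prevalence_defined,
            "tandem_fraction": self.tandem_fraction,
            "spacer_histogram": {str(k): v for k, v in sorted(self.spacer_histogram.items())},
            "trio_position_freqs": {
                str(idx): positions for idx, positions in sorted(self.trio_position_freqs.items())
            },
        }


@dataclass(frozen=True)
class CohortSummary:
    """Whole-cohort statistics plus a per-phylum breakdown."""

    overall: GroupStats
    per_phylum: dict[str, GroupStats] = field(default_factory=dict)
    min_genomes: int = 15

    def to_dict(self) -> dict:
        return {
            "overall": self.overall.to_dict(),
            "min_genomes": self.min_genomes,
            "per_phylum": {k: v.to_dict() for k, v in sorted(self.per_phylum.items())},
        }


def _as_table(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    return results_to_table(list(results))


def _truthy(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"true", "1", "yes"}


def _group_stats(table: pd.DataFrame) -> GroupStats:
    n = len(table)
    found_mask = table["found"].map(_truthy).astype(bool)
    found = table[found_mask]
    n_found = len(found)
    prevalence = (n_found / n) if n else 0.0
    tandem = sum(1 for v in found["box2_start"] if str(v).strip() != "") if n_found else 0
    spacer_hist = Counter(int(v) for v in found["spacer"]) if n_found else Counter()
    # Base frequencies per trio index (1 = box-proximal) and per position 1..3
    counts: dict[int, list[Counter]] = {}
    for trios_field in found["trios"]:
        trios = [t for t in str(trios_field).split(",") if t]
        for idx, trio in enumerate(trios, start=1):
            per_pos = counts.setdefault(idx, [Counter(), Counter(), Counter()])
            for pos, base in enumerate(trio):
                if base in _BASES:
                    per_pos[pos][base] += 1
    freqs: dict[int, list[dict[str, float]]] = {}
    for idx, per_pos in counts.items():
        freqs[idx] = []
        for counter in per_pos:
            total = sum(counter.values())
            freqs[idx].append(
                {b: counter[b] / total for b in _BASES if counter[b]} if total else {}
            )
    return GroupStats(
        n_origins=n,
        n_found=n_found,
        prevalence=prevalence,
        prevalence_defined=n > 0,
        tandem_fraction=(tandem / n_found) if n_found else 0.0,
        spacer_histogram=dict(spacer_hist),
        trio_position_freqs=freqs,
    )


def summarize(results, min_genomes: int = 15) -> CohortSummary:
    """Aggregate results (BusResult list or result table) into a CohortSummary.

    Per-phylum groups are reported for phyla with at least one found origin
    and at least ``min_genomes`` sampled origins.  The tandem fraction is
    computed over all found origins of the group.  Deterministic and
    invariant under permutation of the input.
    """
    table = _as_table(results)
    if table.empty:
        table = pd.DataFrame(columns=RESULT_COLUMNS)
    overall = _group_stats(table)
    per_phylum: dict[str, GroupStats] = {}
    if len(table):
        phyla = table["lineage"].map(
            lambda s: str(s).split(";")[0].strip() if str(s).strip() else "unclassified"
        )
        for phylum in sorted(phyla.unique()):
            sub = table[phyla == phylum]
            stats = _group_stats(sub)
            if stats.n_found >= 1 and stats.n_origins >= min_genomes:
                per_phylum[phylum] = stats
    return CohortSummary(overall=overall, per_phylum=per_phylum, min_genomes=min_genomes)


def export_tracks(results, path: str | Path) -> None:
    """Per-origin annotation-track table (TSV).

    One row per origin with the three data tracks of a circular-tree
    annotation: trio score (dot size), spacer length (bar length) and box
    conservation class (mismatch count of the more conserved box), plus a
    tandem flag.  Not-found origins keep empty track fields.
    """
    table = _as_table(results)
    rows = []
    for _, row in table.iterrows():
        found = _truthy(row["found"])
        mm = ""
        if found:
            mms = [int(row["box1_mm"])]
            if str(row["box2_mm"]).strip() != "":
                mms.append(int(row["box2_mm"]))
            mm = min(mms)
        rows.append(
            {
                "id": row["id"],
                "organism": row["organism"],
                "phylum": str(row["lineage"]).split(";")[0].strip()
                if str(row["lineage"]).strip()
                else "unclassified",
                "found": found,
                "trio_score": row["trio_score"] if found else "",
                "spacer": row["spacer"] if found else "",
                "box_conservation": mm,
                "tandem": (str(row["box2_start"]).strip() != "") if found else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "id",
            "organism",
            "phylum",
            "found",
            "trio_score",
            "spacer",
            "box_conservation",
            "tandem",
        ],
    ).to_csv(Path(path), sep="\t", index=False)
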