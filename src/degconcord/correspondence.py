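"""Ortholog matching, correspondence scoring, and the 2x2 table.

A divergence-called animal DEG is matched to the human knowledge base by
symbol (normalization plus explicit synonyms).  For each matched DEG and
each lineage, the lineage's divergence direction selects the codirected
human annotation slot (UP -> overexpression effect, DOWN ->
underexpression effect); when that slot carries a known effect, one
correspondence record is emitted.  A matched DEG therefore contributes
0, 1, or 2 records.  Records are tallied into a 2x2 contingency table,
lineage (domestic/wild) x effect on reproductive potential
(decrease/increase).

The counting unit is the correspondence record, not the distinct gene: a
gene observed in two species or tissues contributes each time.  No
multiple-testing correction is applied across genes; significance is
assessed only on the final table.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .annotation import AnnotationKB, HumanGeneAnnotation
from .enums import Direction, Effect, Lineage
from .ingest import DEGRecord, DivergenceCall

CORRESPONDENCE_COLUMNS = (
    "record_id",
    "animal_symbol",
    "human_symbol",
    "lineage",
    "direction",
    "rp_effect",
    "evidence",
)

CallPair = tuple[DEGRecord, DivergenceCall]
MatchedTriple = tuple[DEGRecord, DivergenceCall, HumanGeneAnnotation]


@dataclass(frozen=True)
class CorrespondenceRecord:
    """One (lineage, effect) tally unit: an animal lineage's divergence
    direction paired with the codirected human expression change and its
    annotated effect on reproductive potential (never UNKNOWN)."""

    record_id: str
    lineage: Lineage
    direction: Direction
    human_symbol: str
    rp_effect: Effect
    animal_symbol: str = ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.rp_effect is Effect.UNKNOWN:
            raise ValueError(
                f"record {self.record_id!r}: correspondence records must "
                f"carry a known effect"
            )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of correspondence records, lineage x effect."""

    n_dom_decrease: int
    n_dom_increase: int
    n_wild_decrease: int
    n_wild_increase: int

    def __post_init__(self) -> None:
        for cell in self.cells:
            if cell < 0:
                raise ValueError(f"negative cell count in {self.cells}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.n_dom_decrease,
            self.n_dom_increase,
            self.n_wild_decrease,
            self.n_wild_increase,
        )

    @property
    def total(self) -> int:
        return sum(self.cells)

    @property
    def row_margins(self) -> tuple[int, int]:
        """(domestic, wild) row totals."""
        return (
            self.n_dom_decrease + self.n_dom_increase,
            self.n_wild_decrease + self.n_wild_increase,
        )

    @property
    def col_margins(self) -> tuple[int, int]:
        """(decrease, increase) column totals."""
        return (
            self.n_dom_decrease + self.n_wild_decrease,
            self.n_dom_increase + self.n_wild_increase,
        )

    def to_dict(self) -> dict:
        return {
            "domestic": {
                "decrease": self.n_dom_decrease,
                "increase": self.n_dom_increase,
            },
            "wild": {
                "decrease": self.n_wild_decrease,
                "increase": self.n_wild_increase,
            },
            "total": self.total,
        }


def match_orthologs(
    pairs: Sequence[CallPair], kb: AnnotationKB
) -> tuple[list[MatchedTriple], list[CallPair]]:
    """Partition divergence-called DEGs by whether their symbol resolves
    in the knowledge base.  Input order is preserved in both outputs;
    a DEG with no orthologous human gene is excluded, not an error.
    """
    matched: list[MatchedTriple] = []
    excluded: list[CallPair] = []
    for rec, call in pairs:
        ann = kb.lookup(rec.symbol)
        if ann is None:
            excluded.append((rec, call))
        else:
            matched.append((rec, call, ann))
    return matched, excluded


def score_correspondences(
    matched: Iterable[MatchedTriple],
) -> list[CorrespondenceRecord]:
    """Emit correspondence records for every matched DEG.

    For each lineage, the lineage's direction selects the codirected
    annotation slot; a record is emitted iff that effect is known.
    """
    out: list[CorrespondenceRecord] = []
    for rec, call, ann in matched:
        for lineage, direction in (
            (Lineage.DOMESTIC, call.domestic_direction),
            (Lineage.WILD, call.wild_direction),
        ):
            effect = ann.effect_for(direction)
            if effect is Effect.UNKNOWN:
                continue
            out.append(
                CorrespondenceRecord(
                    record_id=rec.record_id,
                    lineage=lineage,
                    direction=direction,
                    human_symbol=ann.symbol,
                    rp_effect=effect,
                    animal_symbol=rec.symbol,
                    evidence=ann.evidence,
                )
            )
    return out


def build_contingency(records: Iterable[CorrespondenceRecord]) -> ContingencyTable:
    """Tally correspondence records into the 2x2 lineage x effect table."""
    counts = {
        (Lineage.DOMESTIC, Effect.DECREASE): 0,
        (Lineage.DOMESTIC, Effect.INCREASE): 0,
        (Lineage.WILD, Effect.DECREASE): 0,
        (Lineage.WILD, Effect.INCREASE): 0,
    }
    for r in records:
        counts[(r.lineage, r.rp_effect)] += 1
    return ContingencyTable(
        n_dom_decrease=counts[(Lineage.DOMESTIC, Effect.DECREASE)],
        n_dom_increase=counts[(Lineage.DOMESTIC, Effect.INCREASE)],
        n_wild_decrease=counts[(Lineage.WILD, Effect.DECREASE)],
        n_wild_increase=counts[(Lineage.WILD, Effect.INCREASE)],
    )


def write_correspondence_tsv(
    records: Sequence[CorrespondenceRecord], path: str | Path
) -> None:
    """Flat-file export of correspondence records (Excel-compatible TSV)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CORRESPONDENCE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.animal_symbol,
                    r.human_symbol,
                    r.lineage.value,
                    r.direction.value,
                    r.rp_effect.value,
                    r.evidence,
                ]
            )


def write_contingency_json(
    table: ContingencyTable,
    path: str | Path,
    report: Optional[dict] = None,
    status: str = "ok",
) -> None:
    """JSON export of the table, optionally with attached test results."""
    payload = {"contingency": table.to_dict(), "status": status}
    if report is not None:
        payload["tests"] = report
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
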