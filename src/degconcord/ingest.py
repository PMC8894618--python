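"""Animal DEG tables and ancestral-polarity inference.

A DEG record summarizes one published differential-expression observation
between a domesticated animal and its wild congener by the sign of its
log2 fold change (domestic relative to wild).  Under the most-recent-
common-ancestor convention, that single signed difference is read as two
oppositely directed, equivalent changes in the two lineages since they
diverged from their unobserved common ancestor: the domestic lineage
takes the sign of the log2FC and the wild lineage the opposite sign.
Only the sign is used downstream; magnitudes and source p-values are
carried for provenance.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .annotation import _header_index, _pad_row, _read_tsv_rows
from .enums import Direction, ZeroPolicy
from .errors import DEGTableError, ZeroLogFoldChangeError

DEG_COLUMNS = (
    "symbol",
    "domestic_taxon",
    "wild_taxon",
    "tissue",
    "log2fc",
    "pvalue",
    "source",
)


@dataclass(frozen=True)
class DEGRecord:
    """One animal differential-expression observation.

    ``log2fc`` is the log2 ratio of expression in the domestic animal
    relative to the wild congener, as reported by the source study; the
    significance call is inherited from that study and never re-derived.
    The unit of analysis is the record, i.e. gene x species pair x tissue
    x source: the same gene may legitimately appear in several records.
    """

    record_id: str
    symbol: str
    domestic_taxon: str
    wild_taxon: str
    tissue: str
    log2fc: float
    pvalue: Optional[float] = None
    source: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise DEGTableError(
                f"record {self.record_id!r}: log2fc must be finite, "
                f"got {self.log2fc!r}"
            )

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        """Identity of the observation; duplicates are rejected on read."""
        return (
            self.symbol,
            self.domestic_taxon,
            self.wild_taxon,
            self.tissue,
            self.source,
        )


@dataclass(frozen=True)
class DivergenceCall:
    """Per-lineage expression-change direction relative to the most
    recent common ancestor.  The two directions are opposite by
    construction and the invariant is enforced."""

    record_id: str
    domestic_direction: Direction
    wild_direction: Direction

    def __post_init__(self) -> None:
        if self.domestic_direction is self.wild_direction:
            raise ValueError(
                f"record {self.record_id!r}: lineage directions must be "
                f"opposite, both are {self.domestic_direction.value}"
            )


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    """Read a DEG TSV (columns: symbol, domestic_taxon, wild_taxon,
    tissue, log2fc, pvalue, source; optional record_id and note).

    ``#`` comments and blank lines are skipped.  Unparsable log2fc or
    pvalue fields and duplicate observations are rejected with the
    offending line number.  A header-only file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise DEGTableError(f"DEG table not found: {path}")

    rows = _read_tsv_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise DEGTableError(f"{path}: empty file (no header row)") from None
    try:
        index = _header_index(header, DEG_COLUMNS, path, header_lineno)
    except Exception as exc:
        raise DEGTableError(str(exc)) from None

    records: list[DEGRecord] = []
    seen: dict[tuple, int] = {}
    n = 0
    for lineno, row in rows:
        if len(row) < len(DEG_COLUMNS):
            raise DEGTableError(
                f"{path}:{lineno}: expected at least {len(DEG_COLUMNS)} fields, "
                f"got {len(row)}"
            )
        row = _pad_row(row, len(header))
        n += 1
        raw_lfc = row[index["log2fc"]].strip()
        try:
            log2fc = float(raw_lfc)
        except ValueError:
            raise DEGTableError(
                f"{path}:{lineno}: non-numeric log2fc {raw_lfc!r}"
            ) from None
        if not math.isfinite(log2fc):
            raise DEGTableError(f"{path}:{lineno}: non-finite log2fc {raw_lfc!r}")

        raw_p = row[index["pvalue"]].strip()
        pvalue: Optional[float] = None
        if raw_p not in ("", "NA", "na", "nan", "."):
            try:
                pvalue = float(raw_p)
            except ValueError:
                raise DEGTableError(
                    f"{path}:{lineno}: non-numeric pvalue {raw_p!r}"
                ) from None
            if not (0.0 < pvalue <= 1.0):
                raise DEGTableError(
                    f"{path}:{lineno}: pvalue {pvalue} outside (0, 1]"
                )

        record_id = (
            row[index["record_id"]].strip()
            if "record_id" in index
            else f"deg{n:04d}"
        )
        note = row[index["note"]].strip() if "note" in index else ""
        rec = DEGRecord(
            record_id=record_id,
            symbol=row[index["symbol"]].strip(),
            domestic_taxon=row[index["domestic_taxon"]].strip(),
            wild_taxon=row[index["wild_taxon"]].strip(),
            tissue=row[index["tissue"]].strip(),
            log2fc=log2fc,
            pvalue=pvalue,
            source=row[index["source"]].strip(),
            note=note,
        )
        if rec.key in seen:
            raise DEGTableError(
                f"{path}:{lineno}: duplicate observation {rec.key} "
                f"(first seen at line {seen[rec.key]})"
            )
        seen[rec.key] = lineno
        records.append(rec)
    return records


def write_deg_table(records: list[DEGRecord], path: str | Path) -> None:
    """Serialize records to the TSV dialect accepted by
    :func:`read_deg_table` (with an explicit record_id column)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("record_id",) + DEG_COLUMNS + ("note",))
        for rec in records:
            writer.writerow(
                [
                    rec.record_id,
                    rec.symbol,
                    rec.domestic_taxon,
                    rec.wild_taxon,
                    rec.tissue,
                    repr(rec.log2fc),
                    "" if rec.pvalue is None else repr(rec.pvalue),
                    rec.source,
                    rec.note,
                ]
            )


def infer_divergence(
    rec: DEGRecord, zero_policy: ZeroPolicy = ZeroPolicy.EXCLUDE
) -> Optional[DivergenceCall]:
    """Convert a signed log2FC into the two lineages' divergence
    directions from the most recent common ancestor.

    log2fc > 0 -> domestic UP / wild DOWN; log2fc < 0 -> the reverse.
    A zero log2fc carries no polarity: ``None`` under EXCLUDE, an error
    naming the record under ERROR.
    """
    if rec.log2fc > 0:
        return DivergenceCall(rec.record_id, Direction.UP, Direction.DOWN)
    if rec.log2fc < 0:
        return DivergenceCall(rec.record_id, Direction.DOWN, Direction.UP)
    if zero_policy is ZeroPolicy.ERROR:
        raise ZeroLogFoldChangeError(
            f"record {rec.record_id!r} ({rec.symbol}) has log2fc == 0; "
            f"no divergence direction is inferable"
        )
    return None
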