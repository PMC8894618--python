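"""End-to-end orchestration: ingest -> polarity -> matching -> scoring ->
contingency -> tests, with flat-file exports and an exclusion log.

The funnel is deliberately auditable: every input DEG record ends up
either in a correspondence record or in the exclusion log with a reason
(zero log2 fold change, or no orthologous human gene in the knowledge
base), and the excluded count plus the matched count always equals the
input row count.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .annotation import AnnotationKB, load_annotation_kb
from .correspondence import (
    CallPair,
    ContingencyTable,
    CorrespondenceRecord,
    MatchedTriple,
    build_contingency,
    match_orthologs,
    score_correspondences,
    write_contingency_json,
    write_correspondence_tsv,
)
from .enums import ZeroPolicy
from .errors import StageError, UndefinedMarginError
from .ingest import DEGRecord, infer_divergence, read_deg_table
from .stats import StatReport, run_all_tests

logger = logging.getLogger("degconcord")

STATUS_OK = "ok"
STATUS_UNDEFINED = "undefined margins"


class RunConfig(BaseModel):
    """Configuration of one pipeline run (mirrors the YAML config file)."""

    deg_path: Path
    annotation_path: Path
    synonym_path: Optional[Path] = None
    output_dir: Optional[Path] = None
    zero_policy: ZeroPolicy = ZeroPolicy.EXCLUDE
    yates: bool = False
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)


@dataclass
class ExcludedRecord:
    """One input DEG record dropped from the analysis, and why."""

    record: DEGRecord
    reason: str


@dataclass
class AnalysisResult:
    """In-memory result of the analysis stages (no file I/O)."""

    records: list[DEGRecord]
    matched: list[MatchedTriple]
    excluded: list[ExcludedRecord]
    correspondences: list[CorrespondenceRecord]
    table: ContingencyTable
    report: Optional[StatReport]
    status: str

    @property
    def n_matched(self) -> int:
        return len(self.matched)


@dataclass
class PipelineResult(AnalysisResult):
    """Analysis result plus the paths of any exports written."""

    exports: dict[str, Path] = field(default_factory=dict)


def analyze_records(
    records: Sequence[DEGRecord],
    kb: AnnotationKB,
    zero_policy: ZeroPolicy = ZeroPolicy.EXCLUDE,
) -> AnalysisResult:
    """Run polarity inference, ortholog matching, correspondence scoring,
    the contingency tally and the statistical tests on in-memory records.

    Tests are skipped (``report=None``, status "undefined margins") when
    the table has an empty row or column.
    """
    pairs: list[CallPair] = []
    excluded: list[ExcludedRecord] = []
    for rec in records:
        call = infer_divergence(rec, zero_policy)
        if call is None:
            excluded.append(ExcludedRecord(rec, "zero log2fc: no polarity"))
            logger.info("polarity: excluded %s (%s): zero log2fc", rec.record_id, rec.symbol)
        else:
            pairs.append((rec, call))

    matched, unmatched = match_orthologs(pairs, kb)
    for rec, _call in unmatched:
        excluded.append(ExcludedRecord(rec, "no orthologous human gene in KB"))
        logger.info("matching: excluded %s (%s): no ortholog", rec.record_id, rec.symbol)

    correspondences = score_correspondences(matched)
    table = build_contingency(correspondences)

    report: Optional[StatReport] = None
    status = STATUS_OK
    try:
        report = run_all_tests(table)
    except UndefinedMarginError:
        status = STATUS_UNDEFINED
        logger.info("stats: skipped on table %s: empty margin", table.cells)

    return AnalysisResult(
        records=list(records),
        matched=matched,
        excluded=excluded,
        correspondences=correspondences,
        table=table,
        report=report,
        status=status,
    )


def _write_excluded_tsv(excluded: Sequence[ExcludedRecord], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "symbol", "domestic_taxon", "wild_taxon", "reason"])
        for ex in excluded:
            writer.writerow(
                [
                    ex.record.record_id,
                    ex.record.symbol,
                    ex.record.domestic_taxon,
                    ex.record.wild_taxon,
                    ex.reason,
                ]
            )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full pipeline from files, per :class:`RunConfig`.

    Writes, when ``output_dir`` is set: ``correspondences.tsv`` (flat-file
    export), ``contingency.json`` (table + tests + status), and
    ``excluded.tsv`` (per-record exclusion reasons).  Exports contain no
    timestamps, so reruns on identical inputs are byte-identical.  Any
    stage failure aborts with the stage name and cause.
    """
    try:
        kb = load_annotation_kb(cfg.annotation_path, cfg.synonym_path)
    except Exception as exc:
        raise StageError("load-annotations", exc) from exc

    try:
        records = read_deg_table(cfg.deg_path)
    except Exception as exc:
        raise StageError("ingest", exc) from exc

    try:
        analysis = analyze_records(records, kb, cfg.zero_policy)
    except Exception as exc:
        raise StageError("analysis", exc) from exc

    exports: dict[str, Path] = {}
    if cfg.output_dir is not None:
        try:
            out = Path(cfg.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            corr_path = out / "correspondences.tsv"
            write_correspondence_tsv(analysis.correspondences, corr_path)
            exports["correspondences"] = corr_path

            cont_path = out / "contingency.json"
            write_contingency_json(
                analysis.table,
                cont_path,
                report=None if analysis.report is None else analysis.report.to_dict(),
                status=analysis.status,
            )
            exports["contingency"] = cont_path

            excl_path = out / "excluded.tsv"
            _write_excluded_tsv(analysis.excluded, excl_path)
            exports["excluded"] = excl_path
        except Exception as exc:
            raise StageError("export", exc) from exc

    return PipelineResult(
        records=analysis.records,
        matched=analysis.matched,
        excluded=analysis.excluded,
        correspondences=analysis.correspondences,
        table=analysis.table,
        report=analysis.report,
        status=analysis.status,
        exports=exports,
    )


def fixture_worked_example() -> tuple[Path, Path, Path]:
    """Paths of the packaged worked-example fixtures: the DEG table, the
    human annotation table, and the hemoglobin synonym table.

    The DEG table transcribes the published worked example: 14 records
    whose symbols have no ortholog among the annotated human genes, plus
    20 records that match and reproduce the printed 2x2 marginals
    (domestic 16 decrease / 4 increase; wild 9 decrease / 11 increase).
    Rows whose sign or magnitude is not stated verbatim in the source
    narrative carry a ``note`` explaining what was reconstructed.
    """
    base = resources.files("degconcord").joinpath("fixtures")
    return (
        Path(str(base.joinpath("worked_example_degs.tsv"))),
        Path(str(base.joinpath("worked_example_annotations.tsv"))),
        Path(str(base.joinpath("worked_example_synonyms.tsv"))),
    )
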