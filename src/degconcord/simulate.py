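"""Synthetic DEG tables and annotation knowledge bases with known truth.

The generator emulates the statistical structure the concordance
analysis assumes, so the whole pipeline can be exercised and calibrated
without any external download:

* each synthetic DEG has a human ortholog in the generated knowledge
  base with probability ``match_rate`` (unmatched DEGs get symbols
  absent from the KB);
* for a matched DEG, the effect of the codirected human expression
  change is DECREASE with probability ``theta_dom`` on the domestic
  lineage and ``theta_wild`` on the wild lineage, sampled independently;
* each lineage's annotation slot is blanked to UNKNOWN with probability
  ``annot_missing``;
* the signed log2 fold change realizes the sampled domestic direction,
  with an exponentially distributed magnitude (scale ``lfc_scale``) —
  only the sign matters downstream, the magnitude is cosmetic.

The generator records the ground-truth (lineage, effect) assignments
and their 2x2 tally; running the real pipeline on the generated inputs
must reproduce that tally exactly, for every seed.  All sampling comes
from one ``numpy`` generator seeded with ``seed``; replicate seeds in
:func:`calibrate_type1` are derived by fixed unit increments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .annotation import AnnotationKB, HumanGeneAnnotation, write_annotation_kb
from .correspondence import ContingencyTable, build_contingency
from .enums import Direction, Effect, Lineage, ZeroPolicy
from .ingest import DEGRecord, write_deg_table
from .pipeline import AnalysisResult, analyze_records
from .stats import fisher_exact_two_sided

#: Every ALIAS_EVERY-th matched gene is emitted under an alias symbol
#: that only resolves through the synonym table, so the synonym path is
#: exercised by construction.
ALIAS_EVERY = 5


class SimulationConfig(BaseModel):
    """Knobs of the synthetic corpus.

    Defaults mirror the structure of the published worked example: a
    fully matched 20-record corpus with a domestic-lineage
    decrease probability of 0.8 (16/20) and a wild-lineage one of 0.45
    (9/20), no missing annotation directions, and log2FC magnitudes on
    the order of the published examples (scale 1.5).
    """

    n_degs: int = Field(default=20, ge=1)
    match_rate: float = Field(default=1.0, ge=0.0, le=1.0)
    theta_dom: float = Field(default=0.8, ge=0.0, le=1.0)
    theta_wild: float = Field(default=0.45, ge=0.0, le=1.0)
    annot_missing: float = Field(default=0.0, ge=0.0, le=1.0)
    lfc_scale: float = Field(default=1.5, gt=0.0)
    seed: int = 0


@dataclass(frozen=True)
class TruthAssignment:
    """Ground truth for one synthetic DEG record."""

    record_id: str
    matched: bool
    dom_effect: Optional[Effect] = None  # None <-> no domestic record emitted
    wild_effect: Optional[Effect] = None

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "matched": self.matched,
            "dom_effect": None if self.dom_effect is None else self.dom_effect.value,
            "wild_effect": None if self.wild_effect is None else self.wild_effect.value,
        }


@dataclass
class SyntheticTruth:
    """Per-record assignments and their expected 2x2 tally."""

    expected_table: ContingencyTable
    assignments: list[TruthAssignment]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "expected_table": self.expected_table.to_dict(),
            "assignments": [a.to_dict() for a in self.assignments],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class SyntheticBundle:
    """One generated corpus: records, knowledge base, ground truth, and
    (when written) the file paths of the TSV/JSON exports."""

    config: SimulationConfig
    records: list[DEGRecord]
    kb: AnnotationKB
    truth: SyntheticTruth
    paths: dict[str, Path] = field(default_factory=dict)


Assignment = tuple[Effect, Effect]


def _sample_effect(rng: np.random.Generator, theta: float) -> Effect:
    return Effect.DECREASE if rng.random() < theta else Effect.INCREASE


def generate(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    assignments: Optional[Sequence[Optional[Assignment]]] = None,
) -> SyntheticBundle:
    """Generate one synthetic corpus; deterministic given ``config.seed``.

    ``assignments`` optionally forces the per-record outcomes instead of
    sampling them: one entry per DEG, either ``None`` (record gets a
    non-matching symbol) or a ``(dom_effect, wild_effect)`` pair of
    known effects.  Match and effect sampling are then bypassed;
    direction, magnitude and missingness sampling still apply.

    When ``out_dir`` is given, writes ``degs.tsv``, ``annotations.tsv``,
    ``synonyms.tsv`` and ``truth.json`` there (byte-identical across
    runs with the same config and seed).
    """
    if assignments is not None and len(assignments) != config.n_degs:
        raise ValueError(
            f"assignments must have one entry per DEG "
            f"({config.n_degs}), got {len(assignments)}"
        )
    rng = np.random.default_rng(config.seed)

    records: list[DEGRecord] = []
    entries: dict[str, HumanGeneAnnotation] = {}
    synonym_map: dict[str, str] = {}
    truth_assignments: list[TruthAssignment] = []
    emitted: list = []  # correspondence records for the expected table
    n_matched = 0

    for i in range(config.n_degs):
        record_id = f"sim{i:05d}"
        # Draw order is fixed: match, domestic direction, magnitude, then
        # (for matched records) effects and missingness.
        is_matched = rng.random() < config.match_rate
        dom_dir = Direction.UP if rng.random() < 0.5 else Direction.DOWN
        magnitude = max(float(rng.exponential(config.lfc_scale)), 1e-9)
        log2fc = magnitude if dom_dir is Direction.UP else -magnitude

        forced: Optional[Assignment] = None
        if assignments is not None:
            forced = assignments[i]
            is_matched = forced is not None

        if not is_matched:
            records.append(
                DEGRecord(
                    record_id=record_id,
                    symbol=f"Nomatch{i:05d}",
                    domestic_taxon="Simulus domesticus",
                    wild_taxon="Simulus ferus",
                    tissue="simulated tissue",
                    log2fc=log2fc,
                    pvalue=0.01,
                    source="synthetic",
                )
            )
            truth_assignments.append(TruthAssignment(record_id, matched=False))
            continue

        if forced is not None:
            dom_effect, wild_effect = forced
            miss_dom = miss_wild = False
        else:
            dom_effect = _sample_effect(rng, config.theta_dom)
            wild_effect = _sample_effect(rng, config.theta_wild)
            miss_dom = rng.random() < config.annot_missing
            miss_wild = rng.random() < config.annot_missing

        canonical = f"SIMG{i:05d}"
        n_matched += 1
        if n_matched % ALIAS_EVERY == 0:
            animal_symbol = f"Syng{i:05d}"
            synonym_map[animal_symbol.upper()] = canonical
        else:
            animal_symbol = f"Simg{i:05d}"

        # The annotation is constructed so the pipeline's direction ->
        # slot lookup lands on the sampled effect: the domestic lineage's
        # direction selects one slot, the (opposite) wild direction the
        # other.
        dom_slot = dom_effect if not miss_dom else Effect.UNKNOWN
        wild_slot = wild_effect if not miss_wild else Effect.UNKNOWN
        if dom_dir is Direction.UP:
            effect_over, effect_under = dom_slot, wild_slot
        else:
            effect_under, effect_over = dom_slot, wild_slot
        entries[canonical] = HumanGeneAnnotation(
            symbol=canonical,
            effect_under=effect_under,
            effect_over=effect_over,
            evidence="synthetic",
        )

        records.append(
            DEGRecord(
                record_id=record_id,
                symbol=animal_symbol,
                domestic_taxon="Simulus domesticus",
                wild_taxon="Simulus ferus",
                tissue="simulated tissue",
                log2fc=log2fc,
                pvalue=0.01,
                source="synthetic",
            )
        )
        truth_assignments.append(
            TruthAssignment(
                record_id,
                matched=True,
                dom_effect=None if miss_dom else dom_effect,
                wild_effect=None if miss_wild else wild_effect,
            )
        )
        if not miss_dom:
            emitted.append((Lineage.DOMESTIC, dom_effect))
        if not miss_wild:
            emitted.append((Lineage.WILD, wild_effect))

    expected = _tally(emitted)
    truth = SyntheticTruth(expected_table=expected, assignments=truth_assignments)
    kb = AnnotationKB(entries=entries, synonym_map=synonym_map)
    bundle = SyntheticBundle(config=config, records=records, kb=kb, truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        deg_path = out / "degs.tsv"
        ann_path = out / "annotations.tsv"
        syn_path = out / "synonyms.tsv"
        truth_path = out / "truth.json"
        write_deg_table(records, deg_path)
        write_annotation_kb(kb, ann_path, syn_path)
        truth.to_json(truth_path)
        bundle.paths = {
            "degs": deg_path,
            "annotations": ann_path,
            "synonyms": syn_path,
            "truth": truth_path,
        }
    return bundle


def _tally(emitted: list) -> ContingencyTable:
    counts = {
        (Lineage.DOMESTIC, Effect.DECREASE): 0,
        (Lineage.DOMESTIC, Effect.INCREASE): 0,
        (Lineage.WILD, Effect.DECREASE): 0,
        (Lineage.WILD, Effect.INCREASE): 0,
    }
    for key in emitted:
        counts[key] += 1
    return ContingencyTable(
        n_dom_decrease=counts[(Lineage.DOMESTIC, Effect.DECREASE)],
        n_dom_increase=counts[(Lineage.DOMESTIC, Effect.INCREASE)],
        n_wild_decrease=counts[(Lineage.WILD, Effect.DECREASE)],
        n_wild_increase=counts[(Lineage.WILD, Effect.INCREASE)],
    )


def run_bundle(bundle: SyntheticBundle) -> AnalysisResult:
    """Run the real analysis pipeline on an in-memory bundle."""
    return analyze_records(bundle.records, bundle.kb, ZeroPolicy.EXCLUDE)


def calibrate_type1(
    config: SimulationConfig, n_reps: int, alpha: float
) -> float:
    """Monte-Carlo type-I error rate of the Fisher test under the null.

    Requires ``theta_dom == theta_wild`` (the null of no lineage/effect
    association).  Each replicate derives its seed from the master seed
    by a unit increment, generates a corpus, runs the real pipeline, and
    applies the two-sided Fisher test; replicates whose table has an
    empty margin (possible at small sizes) cannot reject.  Returns the
    fraction of replicates with p <= alpha.
    """
    if config.theta_dom != config.theta_wild:
        raise ValueError(
            "type-I calibration requires theta_dom == theta_wild "
            f"(got {config.theta_dom} vs {config.theta_wild})"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")

    rejections = 0
    for rep in range(n_reps):
        cfg = config.model_copy(update={"seed": config.seed + rep})
        result = run_bundle(generate(cfg))
        table = result.table
        if min(table.row_margins) == 0 or min(table.col_margins) == 0:
            continue
        if fisher_exact_two_sided(table) <= alpha:
            rejections += 1
    return rejections / n_reps
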