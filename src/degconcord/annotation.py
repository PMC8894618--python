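"""Curated knowledge base of human genes annotated for the effect of an
expression change on reproductive potential.

Each entry records, for one human gene, the annotated consequence of
underexpression and of overexpression on human reproductive potential
(the capacity for population growth in the absence of limiting factors).
Entries are keyed by normalized symbol; an explicit, user-supplied
synonym table maps animal-style aliases (e.g. the hemoglobin subunit
``Hbbl``) onto canonical human symbols (e.g. ``HBB``) where case-folding
alone cannot.  No fuzzy matching is ever attempted: a symbol either
normalizes onto an entry, resolves through the synonym table, or does
not match.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .enums import Direction, Effect
from .errors import AnnotationError

ANNOTATION_COLUMNS = ("symbol", "effect_under", "effect_over", "evidence")
SYNONYM_COLUMNS = ("alias", "canonical")

_SPECIES_SUFFIX = re.compile(r"_[A-Za-z0-9]+$")


def normalize_symbol(token: str) -> str:
    """Normalize a raw gene-symbol token for matching.

    Strips surrounding whitespace, keeps only the first whitespace-separated
    token, uppercases, and drops a trailing underscore-joined species
    decoration (``Apoa1_CAVPO`` -> ``APOA1``).  Animal symbols such as
    ``Apoa1`` thereby match the human ``APOA1`` directly; anything beyond
    case and decoration differences must go through the synonym table.
    """
    tok = token.strip()
    if not tok:
        return ""
    tok = tok.split()[0].upper()
    return _SPECIES_SUFFIX.sub("", tok)


def _parse_effect(token: str, lineno: int, path: Path) -> Effect:
    try:
        return Effect[token.strip().upper()]
    except KeyError:
        raise AnnotationError(
            f"{path}:{lineno}: unknown effect token {token!r} "
            f"(expected one of decrease/increase/unknown)"
        ) from None


@dataclass(frozen=True)
class HumanGeneAnnotation:
    """Per-direction effect of a human gene's expression change on
    reproductive potential, with its literature evidence."""

    symbol: str
    effect_under: Effect
    effect_over: Effect
    evidence: str = ""

    @property
    def usable(self) -> bool:
        """True when at least one direction carries a known effect."""
        return (
            self.effect_under is not Effect.UNKNOWN
            or self.effect_over is not Effect.UNKNOWN
        )

    def effect_for(self, direction: Direction) -> Effect:
        """Effect of the human expression change codirected with
        ``direction`` (UP -> overexpression, DOWN -> underexpression)."""
        return self.effect_over if direction is Direction.UP else self.effect_under


@dataclass
class AnnotationKB:
    """In-memory knowledge base: normalized symbol -> annotation, plus an
    alias -> canonical synonym map."""

    entries: dict[str, HumanGeneAnnotation] = field(default_factory=dict)
    synonym_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for alias, canonical in self.synonym_map.items():
            if canonical not in self.entries:
                raise AnnotationError(
                    f"synonym target {canonical!r} (alias {alias!r}) "
                    f"has no knowledge-base entry"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return self.lookup(token) is not None

    def lookup(self, token: str) -> Optional[HumanGeneAnnotation]:
        """Resolve a raw symbol: normalize, apply synonyms, query entries.

        Returns ``None`` when the symbol is not in the knowledge base;
        absence is a valid outcome, not an error.
        """
        key = normalize_symbol(token)
        key = self.synonym_map.get(key, key)
        return self.entries.get(key)

    @property
    def flagged_symbols(self) -> list[str]:
        """Symbols whose both directions are UNKNOWN: loadable, but they
        can never contribute a correspondence record."""
        return [s for s, a in self.entries.items() if not a.usable]


def lookup(kb: AnnotationKB, token: str) -> Optional[HumanGeneAnnotation]:
    """Module-level alias of :meth:`AnnotationKB.lookup`."""
    return kb.lookup(token)


def _read_tsv_rows(path: Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for data lines of a TSV file,
    skipping blank lines and ``#``-prefixed comments."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if all(not cell.strip() for cell in row):
                continue
            yield lineno, row


def _pad_row(row: list[str], width: int) -> list[str]:
    """Pad a short row with empty fields up to the header width: trailing
    optional columns (e.g. ``note``) may legitimately be absent."""
    return row + [""] * (width - len(row)) if len(row) < width else row


def _header_index(
    header: Sequence[str], required: Sequence[str], path: Path, lineno: int
) -> dict[str, int]:
    index = {name.strip(): i for i, name in enumerate(header)}
    missing = [c for c in required if c not in index]
    if missing:
        raise AnnotationError(
            f"{path}:{lineno}: missing required column(s) {', '.join(missing)}"
        )
    return index


def load_annotation_kb(
    path: str | Path, synonyms_path: str | Path | None = None
) -> AnnotationKB:
    """Load the annotation knowledge base from TSV.

    The annotation file carries columns ``symbol``, ``effect_under``,
    ``effect_over``, ``evidence`` (extra columns are ignored); effect
    tokens are parsed case-insensitively.  Duplicate symbols (after
    normalization) are rejected.  The optional synonym file carries
    columns ``alias``, ``canonical``; every canonical target must exist
    and no alias may map to two different canonical symbols.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")

    rows = _read_tsv_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise AnnotationError(f"{path}: empty file (no header row)") from None
    index = _header_index(header, ANNOTATION_COLUMNS, path, header_lineno)

    entries: dict[str, HumanGeneAnnotation] = {}
    for lineno, row in rows:
        if len(row) < len(ANNOTATION_COLUMNS):
            raise AnnotationError(
                f"{path}:{lineno}: expected at least {len(ANNOTATION_COLUMNS)} "
                f"fields, got {len(row)}"
            )
        row = _pad_row(row, len(header))
        raw_symbol = row[index["symbol"]]
        symbol = normalize_symbol(raw_symbol)
        if not symbol:
            raise AnnotationError(f"{path}:{lineno}: empty gene symbol")
        if symbol in entries:
            raise AnnotationError(f"{path}:{lineno}: duplicate symbol {symbol!r}")
        entries[symbol] = HumanGeneAnnotation(
            symbol=symbol,
            effect_under=_parse_effect(row[index["effect_under"]], lineno, path),
            effect_over=_parse_effect(row[index["effect_over"]], lineno, path),
            evidence=row[index["evidence"]].strip(),
        )

    synonym_map: dict[str, str] = {}
    if synonyms_path is not None:
        synonyms_path = Path(synonyms_path)
        if not synonyms_path.exists():
            raise AnnotationError(f"synonym file not found: {synonyms_path}")
        srows = _read_tsv_rows(synonyms_path)
        try:
            s_lineno, s_header = next(srows)
        except StopIteration:
            raise AnnotationError(
                f"{synonyms_path}: empty file (no header row)"
            ) from None
        sindex = _header_index(s_header, SYNONYM_COLUMNS, synonyms_path, s_lineno)
        for lineno, row in srows:
            if len(row) < len(s_header):
                raise AnnotationError(
                    f"{synonyms_path}:{lineno}: expected {len(s_header)} fields, "
                    f"got {len(row)}"
                )
            alias = normalize_symbol(row[sindex["alias"]])
            canonical = normalize_symbol(row[sindex["canonical"]])
            if not alias or not canonical:
                raise AnnotationError(f"{synonyms_path}:{lineno}: empty alias/canonical")
            if alias in synonym_map and synonym_map[alias] != canonical:
                raise AnnotationError(
                    f"{synonyms_path}:{lineno}: alias {alias!r} maps to both "
                    f"{synonym_map[alias]!r} and {canonical!r}"
                )
            synonym_map[alias] = canonical

    return AnnotationKB(entries=entries, synonym_map=synonym_map)


def write_annotation_kb(
    kb: AnnotationKB,
    path: str | Path,
    synonyms_path: str | Path | None = None,
) -> None:
    """Serialize a knowledge base back to the TSV dialect accepted by
    :func:`load_annotation_kb` (lossless round trip, field for field)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for symbol in sorted(kb.entries):
            ann = kb.entries[symbol]
            writer.writerow(
                [ann.symbol, ann.effect_under.value, ann.effect_over.value, ann.evidence]
            )
    if synonyms_path is not None:
        with open(synonyms_path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(SYNONYM_COLUMNS)
            for alias in sorted(kb.synonym_map):
                writer.writerow([alias, kb.synonym_map[alias]])
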