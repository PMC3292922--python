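"""Study catalog and per-study hit-list ingestion.

The catalog is a TSV transcription of the published screen inventory: one row
per study with its organism, disease-model codes, screen type and reported
modifier counts. Hit lists are per-study TSVs of raw identifiers exactly as
curated; deduplication happens later, in integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

ORGANISMS = ("worm", "yeast", "fly")

#: Closed disease-model vocabulary: P = polyQ/Htt/SCA, S = alpha-synuclein,
#: T = tau, SOD = mutant SOD1, Abeta = amyloid-beta 1-42.
DISEASE_MODELS = ("P", "S", "T", "SOD", "Abeta")

_MODEL_SYNONYMS = {
    "p": "P",
    "s": "S",
    "t": "T",
    "sod": "SOD",
    "abeta": "Abeta",
    "ab": "Abeta",
    "aβ": "Abeta",
}

_STUDY_COLUMNS = (
    "study_id",
    "organism",
    "disease_models",
    "construct",
    "screen_type",
    "n_reported",
    "n_orthologues_expected",
    "reference",
)

EFFECTS = ("suppressor", "enhancer", "modifier", "unknown")


@dataclass(frozen=True)
class Study:
    """One published screen."""

    study_id: str
    organism: str
    disease_models: frozenset[str]
    construct: str = ""
    screen_type: str = ""
    n_reported: int = 0
    n_orthologues_expected: int | None = None
    reference: str = ""

    def __post_init__(self) -> None:
        if self.organism not in ORGANISMS:
            raise ValidationError(f"study {self.study_id}: unknown organism {self.organism!r}")
        if not self.disease_models:
            raise ValidationError(f"study {self.study_id}: disease_models must be non-empty")
        unknown = set(self.disease_models) - set(DISEASE_MODELS)
        if unknown:
            raise ValidationError(
                f"study {self.study_id}: unknown disease model code(s) {sorted(unknown)}"
            )
        if self.n_reported < 0:
            raise ValidationError(f"study {self.study_id}: n_reported must be >= 0")


@dataclass(frozen=True)
class RawGeneCall:
    """A single curated hit exactly as reported by its study."""

    study_id: str
    raw_id: str
    species: str
    effect: str = "unknown"
    note: str = ""

    def __post_init__(self) -> None:
        if not self.raw_id.strip():
            raise ValidationError("raw_id must be non-empty")
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")


@dataclass
class CatalogSummary:
    """Exact integer accounting over a study catalog."""

    n_studies: int
    total_reported: int
    total_orthologues_expected: int
    per_organism: dict[str, dict[str, int]] = field(default_factory=dict)


def parse_disease_models(cell: str) -> frozenset[str]:
    """Split a disease-model cell on 'and'/comma separators into codes."""
    tokens = [t for part in cell.replace(" and ", ",").split(",") if (t := part.strip())]
    codes = set()
    for token in tokens:
        code = _MODEL_SYNONYMS.get(token.casefold())
        if code is None:
            raise ValidationError(f"unknown disease model token {token!r}")
        codes.add(code)
    return frozenset(codes)


def read_study_table(path) -> list[Study]:
    """Load a studies TSV into validated :class:`Study` records, in file order."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"study table not found: {path}")
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = set(_STUDY_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"study table missing column(s): {', '.join(sorted(missing))}")

    studies: list[Study] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        sid = row.study_id.strip()
        if sid in seen:
            raise ValidationError(f"duplicate study_id {sid!r}")
        seen.add(sid)
        try:
            n_reported = int(row.n_reported)
        except ValueError:
            raise FormatError(
                f"row {i}: unparseable n_reported {row.n_reported!r}"
            ) from None
        ortho_cell = row.n_orthologues_expected.strip()
        if ortho_cell == "":
            n_ortho: int | None = None
        else:
            try:
                n_ortho = int(ortho_cell)
            except ValueError:
                raise FormatError(
                    f"row {i}: unparseable n_orthologues_expected {ortho_cell!r}"
                ) from None
        studies.append(
            Study(
                study_id=sid,
                organism=row.organism.strip(),
                disease_models=parse_disease_models(row.disease_models),
                construct=row.construct,
                screen_type=row.screen_type,
                n_reported=n_reported,
                n_orthologues_expected=n_ortho,
                reference=row.reference,
            )
        )
    return studies


def write_study_table(studies: list[Study], path) -> None:
    """Serialize a catalog back to its TSV layout (round-trips with the reader)."""
    rows = []
    for s in studies:
        rows.append(
            {
                "study_id": s.study_id,
                "organism": s.organism,
                "disease_models": ", ".join(sorted(s.disease_models)),
                "construct": s.construct,
                "screen_type": s.screen_type,
                "n_reported": s.n_reported,
                "n_orthologues_expected": ""
                if s.n_orthologues_expected is None
                else s.n_orthologues_expected,
                "reference": s.reference,
            }
        )
    pd.DataFrame(rows, columns=list(_STUDY_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_gene_list(path, study: Study) -> tuple[list[RawGeneCall], int]:
    """Load one study's hit list; returns (calls, n_skipped_blank).

    Rows are preserved in order and duplicates retained. A species column, when
    present, must agree with the study organism. A count mismatch against the
    study's declared n_reported logs a warning, not an error: published counts
    and supplementary lists are known to disagree.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"gene list not found: {path}")
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=False,  # blank rows must surface as skip-counted warnings
    )
    frame = frame.fillna("")
    if "raw_id" not in frame.columns:
        raise FormatError(f"gene list {path} missing required column raw_id")

    calls: list[RawGeneCall] = []
    skipped = 0
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw = row.raw_id.strip()
        if not raw:
            skipped += 1
            logger.warning("%s row %d: blank raw_id skipped", path.name, i)
            continue
        species = getattr(row, "species", "").strip()
        if species and species != study.organism:
            raise ValidationError(
                f"{path.name} row {i}: species {species!r} conflicts with "
                f"study organism {study.organism!r}"
            )
        effect = getattr(row, "effect", "").strip() or "unknown"
        calls.append(
            RawGeneCall(
                study_id=study.study_id,
                raw_id=raw,
                species=study.organism,
                effect=effect,
                note=getattr(row, "note", ""),
            )
        )
    if calls and len(calls) != study.n_reported:
        logger.warning(
            "study %s: %d hit rows but n_reported=%d",
            study.study_id,
            len(calls),
            study.n_reported,
        )
    return calls, skipped


def summarize_catalog(studies: list[Study]) -> CatalogSummary:
    """Exact totals of reported modifiers and expected orthologues, overall and per organism."""
    per: dict[str, dict[str, int]] = {
        org: {"n_studies": 0, "n_reported": 0, "n_orthologues_expected": 0}
        for org in ORGANISMS
    }
    for s in studies:
        bucket = per[s.organism]
        bucket["n_studies"] += 1
        bucket["n_reported"] += s.n_reported
        bucket["n_orthologues_expected"] += s.n_orthologues_expected or 0
    return CatalogSummary(
        n_studies=len(studies),
        total_reported=sum(b["n_reported"] for b in per.values()),
        total_orthologues_expected=sum(b["n_orthologues_expected"] for b in per.values()),
        per_organism=per,
    )
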