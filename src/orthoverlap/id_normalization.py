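"""Canonicalization of heterogeneous gene identifiers within species namespaces.

Curated hit lists mix gene symbols, sequence names and isoform-level names with
inconsistent casing. This module makes identifier equality well-defined so the
downstream set algebra (union, overlap) operates on genes, not on spellings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Recognised species namespaces.
SPECIES = frozenset({"worm", "yeast", "fly", "human"})

#: Worm sequence-name shape with a single trailing lowercase isoform letter,
#: e.g. "ZK256.1a" -> stem "ZK256.1". The stem never re-matches, so stripping
#: is idempotent by construction.
_ISOFORM_RE = re.compile(r"^([A-Za-z]+\d+[A-Za-z0-9]*\.\d+)([a-z])$")


@dataclass(frozen=True)
class GeneId:
    """A namespaced gene identifier; equality is on (species, value) only."""

    species: str
    value: str
    display_name: str | None = field(default=None, compare=False)
    note: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if not self.value or self.value != self.value.strip() or " " in self.value:
            raise ValidationError(f"invalid gene identifier {self.value!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.species}:{self.value}"


@dataclass(frozen=True)
class NormalizationOptions:
    """Switches controlling :func:`normalize_gene_id`.

    strip_isoform removes a trailing single lowercase letter from worm
    sequence names (gene-level identity is the analysis unit); strip_trailing_comma
    tolerates truncated curation artifacts like ``"W08D2.5,"``.
    """

    strip_isoform: bool = True
    strip_trailing_comma: bool = True


DEFAULT_OPTIONS = NormalizationOptions()


class AliasTable:
    """Case-insensitive alias -> canonical lookup for one or more species.

    No alias may resolve to two different canonical values within a species;
    the constraint is enforced at construction.
    """

    def __init__(self) -> None:
        self._map: dict[tuple[str, str], tuple[str, str]] = {}
        self.provenance: dict[tuple[str, str], str] = {}

    def add(self, species: str, alias: str, canonical: str, provenance: str = "") -> None:
        if species not in SPECIES:
            raise ValidationError(f"unknown species {species!r} in alias table")
        alias = alias.strip()
        canonical = canonical.strip()
        if not alias or not canonical:
            raise FormatError("alias and canonical must be non-empty")
        key = (species, alias.casefold())
        existing = self._map.get(key)
        if existing is not None and existing[0] != canonical:
            raise ValidationError(
                f"alias {alias!r} ({species}) maps to both {existing[0]!r} and {canonical!r}"
            )
        self._map[key] = (canonical, alias)
        self.provenance[key] = provenance

    def lookup(self, species: str, alias: str) -> str | None:
        """Return the canonical value for *alias*, or None on a miss."""
        hit = self._map.get((species, alias.strip().casefold()))
        return hit[0] if hit else None

    def display_name(self, species: str, alias: str) -> str | None:
        """Original (canonical-case) spelling of a registered alias."""
        hit = self._map.get((species, alias.strip().casefold()))
        return hit[1] if hit else None

    def __len__(self) -> int:
        return len(self._map)


def load_alias_table(path) -> AliasTable:
    """Read an aliases TSV (species, alias, canonical[, provenance])."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"species", "alias", "canonical"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"alias table {path} missing column(s): {', '.join(sorted(missing))}")
    table = AliasTable()
    for row in frame.itertuples(index=False):
        table.add(
            row.species,
            row.alias,
            row.canonical,
            getattr(row, "provenance", ""),
        )
    return table


def strip_isoform_suffix(value: str) -> str:
    """Drop a single trailing lowercase isoform letter from a worm sequence name."""
    match = _ISOFORM_RE.match(value)
    return match.group(1) if match else value


def normalize_gene_id(
    raw: str,
    species: str,
    aliases: AliasTable | None = None,
    options: NormalizationOptions = DEFAULT_OPTIONS,
) -> GeneId:
    """Canonicalize *raw* within the *species* namespace.

    Trims whitespace, optionally strips worm isoform suffixes, then resolves
    through the alias table (case-insensitively). The result is a fixed point:
    normalizing a normalized identifier is the identity. Unresolved identifiers
    pass through as canonical-by-identity, flagged via ``note``.
    """
    if species not in SPECIES:
        raise ValidationError(f"unknown species {species!r}")
    value = raw.strip()
    if not value:
        raise ValidationError("empty gene identifier")

    display: str | None = None
    resolved = False
    # iterate to a fixed point so alias chains and post-alias isoform suffixes
    # cannot break idempotence; curated tables converge in one or two steps
    for _ in range(8):
        start = value
        if options.strip_trailing_comma:
            value = value.rstrip(",").strip()
        if options.strip_isoform and species == "worm":
            value = strip_isoform_suffix(value)
        if aliases is not None:
            canonical = aliases.lookup(species, value)
            if canonical is not None:
                resolved = True
                if canonical != value:
                    display = aliases.display_name(species, value)
                    value = canonical
        if value == start:
            break
    else:  # pragma: no cover - defensive
        raise ValidationError(f"alias resolution did not converge for {raw!r}")
    if not value:
        raise ValidationError(f"identifier {raw!r} normalizes to an empty string")

    note = None if resolved or aliases is None else "unmapped-alias"
    if note is not None:
        logger.debug("identifier %r (%s) kept as-is: no alias entry", raw, species)
    return GeneId(species=species, value=value, display_name=display, note=note)
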