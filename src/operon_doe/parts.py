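"""Part-library ingestion, strength ranking and DoE-table export.

A *part library* is the bridge between characterised biological parts
(promoters, ribosome binding sites, coding sequences, terminators, assembly
linkers and the vector backbone) and the factor table consumed by
design-of-experiments software.  Each part carries a relative strength —
for constitutive promoters this is typically an RPU value measured against
a reference promoter such as J23101 — and, once ranked, an integer rank
with ``1`` denoting the weakest part of its class.  Ranks are what the
design stage uses as discrete-numeric factor levels.

The on-disk format is a plain CSV with the columns::

    part_id,name,part_class,native_host,sequence,strength_value,
    strength_units,reference_standard[,rank]

``rank`` is optional on input and is written by :func:`export_doe_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import (
    EmptyLibraryError,
    PartValidationError,
    SchemaError,
    UnrankedPartError,
)

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes (DNA); sequences are case-folded to upper.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Columns required in a part-library CSV, in canonical order.
REQUIRED_COLUMNS = (
    "part_id",
    "name",
    "part_class",
    "native_host",
    "sequence",
    "strength_value",
    "strength_units",
    "reference_standard",
)

#: Part classes that must carry a non-empty DNA sequence.
SEQUENCE_REQUIRED = frozenset({"promoter", "rbs", "cds", "terminator"})


class PartClass(str, Enum):
    PROMOTER = "promoter"
    RBS = "rbs"
    CDS = "cds"
    TERMINATOR = "terminator"
    LINKER = "linker"
    BACKBONE = "backbone"


@dataclass
class Part:
    """A characterised biological part.

    ``strength_value`` is a relative, non-negative quantity (e.g. RPU for a
    promoter measured against ``reference_standard``); ``rank`` is assigned
    by :func:`rank_parts` and is 1 for the weakest part of its class.
    """

    part_id: str
    name: str
    part_class: PartClass
    native_host: str = ""
    sequence: str = ""
    strength_value: Optional[float] = None
    strength_units: str = ""
    reference_standard: str = ""
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.part_id:
            raise PartValidationError("part_id must be non-empty")
        self.part_class = PartClass(self.part_class)
        self.sequence = (self.sequence or "").upper()
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise PartValidationError(
                f"part {self.part_id!r}: non-IUPAC characters in sequence: {sorted(bad)}"
            )
        if self.part_class.value in SEQUENCE_REQUIRED and not self.sequence:
            raise PartValidationError(
                f"part {self.part_id!r} ({self.part_class.value}) requires a sequence"
            )
        if self.strength_value is not None:
            self.strength_value = float(self.strength_value)
            if self.strength_value < 0:
                raise PartValidationError(
                    f"part {self.part_id!r}: strength_value must be >= 0"
                )
        if self.rank is not None:
            self.rank = int(self.rank)
            if self.rank < 1:
                raise PartValidationError(f"part {self.part_id!r}: rank must be >= 1")


@dataclass
class PartLibrary:
    """An ordered collection of :class:`Part`, unique by ``part_id``."""

    parts: dict[str, Part] = field(default_factory=dict)
    source: Optional[str] = None
    loaded_at: Optional[str] = None

    def __post_init__(self) -> None:
        # dict construction already deduplicates; callers use add() / from_parts()
        # which check for collisions explicitly.
        pass

    @classmethod
    def from_parts(cls, parts: Iterable[Part], source: Optional[str] = None) -> "PartLibrary":
        lib = cls(source=source, loaded_at=datetime.now(timezone.utc).isoformat())
        for p in parts:
            lib.add(p)
        return lib

    def add(self, part: Part) -> None:
        if part.part_id in self.parts:
            raise PartValidationError(f"duplicate part_id: {part.part_id!r}")
        self.parts[part.part_id] = part

    def __len__(self) -> int:
        return len(self.parts)

    def __contains__(self, part_id: str) -> bool:
        return part_id in self.parts

    def get(self, part_id: str) -> Part:
        try:
            return self.parts[part_id]
        except KeyError:
            raise KeyError(f"no part with id {part_id!r}") from None

    def of_class(self, part_class: PartClass | str) -> list[Part]:
        pc = PartClass(part_class)
        return [p for p in self.parts.values() if p.part_class is pc]

    def copy(self) -> "PartLibrary":
        new = PartLibrary(source=self.source, loaded_at=self.loaded_at)
        new.parts = {pid: replace(p) for pid, p in self.parts.items()}
        return new


def load_parts(source: str | Path) -> PartLibrary:
    """Load and validate a part-library CSV.

    Row order is preserved.  Raises :class:`SchemaError` when a required
    column is missing, :class:`PartValidationError` for duplicate ids or
    unknown part classes, and :class:`EmptyLibraryError` for a file with no
    data rows.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyLibraryError(f"{source} contains no part rows")

    dupes = df["part_id"][df["part_id"].duplicated()].unique().tolist()
    if dupes:
        raise PartValidationError(f"duplicate part_id(s): {dupes}")

    valid_classes = {pc.value for pc in PartClass}
    unknown = sorted(set(df["part_class"]) - valid_classes)
    if unknown:
        raise PartValidationError(f"unknown part_class value(s): {unknown}")

    parts = []
    for row in df.itertuples(index=False):
        strength = row.strength_value if row.strength_value != "" else None
        rank = None
        if "rank" in df.columns:
            raw = getattr(row, "rank")
            rank = int(float(raw)) if raw not in ("", None) else None
        parts.append(
            Part(
                part_id=row.part_id,
                name=row.name,
                part_class=PartClass(row.part_class),
                native_host=row.native_host,
                sequence=row.sequence,
                strength_value=strength,
                strength_units=row.strength_units,
                reference_standard=row.reference_standard,
                rank=rank,
            )
        )
    return PartLibrary.from_parts(parts, source=str(source))


def rank_parts(library: PartLibrary, part_class: PartClass | str) -> PartLibrary:
    """Assign strength ranks ``1..k`` to all parts of one class.

    Rank 1 is the weakest part.  Ties in strength are broken
    lexicographically by ``part_id`` into distinct consecutive ranks (the
    design stage needs distinct numeric levels) and a warning is logged.
    Returns a new library; the input is unmodified.
    """
    pc = PartClass(part_class)
    out = library.copy()
    members = out.of_class(pc)
    unranked = [p.part_id for p in members if p.strength_value is None]
    if unranked:
        raise UnrankedPartError(
            f"cannot rank {pc.value}: no strength_value for {unranked}"
        )
    strengths = [p.strength_value for p in members]
    if len(set(strengths)) < len(strengths):
        logger.warning(
            "tied strength values among %s parts; breaking ties by part_id", pc.value
        )
    for i, part in enumerate(
        sorted(members, key=lambda p: (p.strength_value, p.part_id)), start=1
    ):
        out.parts[part.part_id].rank = i
    return out


def export_doe_table(library: PartLibrary, destination: str | Path) -> Path:
    """Write the ranked library as a DoE-ready CSV.

    Refuses to export while any promoter or RBS part is unranked, since the
    downstream design stage treats those classes as discrete-numeric
    factors keyed on rank.  The written file round-trips through
    :func:`load_parts` without loss.
    """
    unranked = [
        p.part_id
        for pc in (PartClass.PROMOTER, PartClass.RBS)
        for p in library.of_class(pc)
        if p.rank is None
    ]
    if unranked:
        raise UnrankedPartError(f"unranked promoter/rbs part(s): {unranked}")
    destination = Path(destination)
    rows = [
        {
            "part_id": p.part_id,
            "name": p.name,
            "part_class": p.part_class.value,
            "native_host": p.native_host,
            "sequence": p.sequence,
            "strength_value": "" if p.strength_value is None else repr(p.strength_value),
            "strength_units": p.strength_units,
            "reference_standard": p.reference_standard,
            "rank": "" if p.rank is None else p.rank,
        }
        for p in library.parts.values()
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["rank"]).to_csv(
        destination, index=False
    )
    return destination
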