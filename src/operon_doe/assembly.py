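"""Liquid-handler build planning for selected constructs.

Turns the selected operon variants into an acoustic-dispenser picklist:
each construct receives a stitch ID, a destination well (row-major fill),
one transfer per DNA element (promoter, RBS-linkers, CDSs, terminator,
backbone) and one per shared reagent (by default a single master mix).
Volumes are quantised *up* to the instrument droplet size (2.5 nL for
Echo-class dispensers) so molar targets are met or exceeded.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .design_types import Construct
from .errors import CapacityError, LayoutError, StitchCollisionError

logger = logging.getLogger(__name__)

PICKLIST_HEADER = (
    "Source Plate Name",
    "Source Well",
    "Destination Plate Name",
    "Destination Well",
    "Transfer Volume",
)

_FORMATS = {96: (8, 12), 384: (16, 24)}

#: Default reagent id for the pooled enzyme/buffer master mix.
MASTER_MIX = "master_mix"


def well_labels(format: int) -> list[str]:
    """Row-major well labels for a plate format (A1..H12 or A1..P24)."""
    rows, cols = _FORMATS[format]
    return [f"{chr(ord('A') + r)}{c + 1}" for r in range(rows) for c in range(cols)]


@dataclass
class PlateLayout:
    """Source-plate map: content id (part/linker/reagent) -> well."""

    plate_name: str
    format: int = 96
    wells: dict[str, str] = field(default_factory=dict)       # content_id -> well
    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.format not in _FORMATS:
            raise LayoutError(f"unsupported plate format: {self.format}")
        valid = set(well_labels(self.format))
        seen: dict[str, str] = {}
        for content, well in self.wells.items():
            if well not in valid:
                raise LayoutError(
                    f"well {well!r} invalid for a {self.format}-well plate"
                )
            if well in seen:
                raise LayoutError(
                    f"well {well} holds both {seen[well]!r} and {content!r}"
                )
            seen[well] = content

    @classmethod
    def auto(cls, content_ids: Sequence[str], plate_name: str = "source_1",
             format: int = 96) -> "PlateLayout":
        """Lay contents row-major onto one plate."""
        labels = well_labels(format)
        if len(content_ids) > len(labels):
            raise CapacityError(
                f"{len(content_ids)} contents exceed a {format}-well plate"
            )
        return cls(plate_name=plate_name, format=format,
                   wells=dict(zip(content_ids, labels)))


def load_layout(path: str | Path) -> list[PlateLayout]:
    """Read source layouts from a CSV (plate_name,well,content_id,concentration,units)."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"plate_name", "well", "content_id"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"layout file missing column(s): {sorted(missing)}")
    plates = []
    for plate_name, group in df.groupby("plate_name", sort=False):
        wells = dict(zip(group["content_id"], group["well"]))
        conc = {
            c: float(v)
            for c, v in zip(group["content_id"], group.get("concentration", ""))
            if v not in ("", None)
        }
        fmt = 384 if any(w[0] > "H" or int(w[1:]) > 12 for w in wells.values()) else 96
        plates.append(PlateLayout(plate_name=str(plate_name), format=fmt,
                                  wells=wells, concentrations=conc))
    return plates


@dataclass(frozen=True)
class Transfer:
    source_plate: str
    source_well: str
    destination_plate: str
    destination_well: str
    volume_nl: float


@dataclass
class Picklist:
    transfers: list[Transfer] = field(default_factory=list)

    def destination_totals(self) -> dict[tuple[str, str], float]:
        totals: dict[tuple[str, str], float] = {}
        for t in self.transfers:
            key = (t.destination_plate, t.destination_well)
            totals[key] = totals.get(key, 0.0) + t.volume_nl
        return totals


@dataclass(frozen=True)
class AssemblyConfig:
    """Volumes and concentrations of one assembly reaction.

    Part plasmids are stocked at 76 nM and RBS-linkers at 1 uM; transfer
    volumes are instrument defaults, configurable per run.
    """

    droplet_nl: float = 2.5
    part_volume_nl: float = 25.0
    linker_volume_nl: float = 25.0
    mix_volume_nl: float = 500.0
    max_well_volume_nl: float = 10_000.0
    part_conc_nM: float = 76.0
    linker_conc_uM: float = 1.0
    destination_plate: str = "assembly_1"
    destination_format: int = 96
    reagents: tuple[str, ...] = (MASTER_MIX,)

    def __post_init__(self) -> None:
        for name in ("droplet_nl", "part_volume_nl", "linker_volume_nl",
                     "mix_volume_nl", "max_well_volume_nl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def quantise_volume(volume_nl: float, droplet_nl: float) -> float:
    """Round a volume up to the next droplet multiple."""
    droplets = math.ceil(round(volume_nl / droplet_nl, 9))
    return droplets * droplet_nl


def assign_stitch_ids(constructs: Sequence[Construct], prefix: str = "S"
                      ) -> list[Construct]:
    """Assign unique zero-padded stitch IDs in list order (idempotent).

    88 constructs with prefix ``"S"`` become S001..S088.  Re-running on
    already-labelled constructs reproduces the same IDs; any pre-existing
    ID that disagrees raises :class:`StitchCollisionError`.
    """
    if not constructs:
        raise ValueError("no constructs to label")
    width = max(3, len(str(len(constructs))))
    out = []
    for i, c in enumerate(constructs, start=1):
        expected = f"{prefix}{i:0{width}d}"
        if c.stitch_id is not None and c.stitch_id != expected:
            raise StitchCollisionError(
                f"construct {i} already carries id {c.stitch_id!r} "
                f"(expected {expected!r})"
            )
        out.append(replace(c, stitch_id=expected))
    return out


def plan_assembly(constructs: Sequence[Construct],
                  layout: PlateLayout | Sequence[PlateLayout],
                  config: AssemblyConfig = AssemblyConfig()) -> Picklist:
    """Plan all transfers for one assembly plate.

    One destination well per construct, filled row-major; per construct one
    transfer per DNA element plus one per shared reagent.  The plan is a
    pure function of its inputs — repeated calls are identical.
    """
    plates = [layout] if isinstance(layout, PlateLayout) else list(layout)
    source: dict[str, tuple[str, str]] = {}
    for plate in plates:
        for content, well in plate.wells.items():
            source.setdefault(content, (plate.plate_name, well))

    dest_wells = well_labels(config.destination_format)
    if len(constructs) > len(dest_wells):
        raise CapacityError(
            f"{len(constructs)} constructs exceed the "
            f"{config.destination_format}-well destination plate"
        )

    picklist = Picklist()
    for construct, dest in zip(constructs, dest_wells):
        label = construct.stitch_id or f"construct#{construct.configuration.config_index}"
        total = 0.0
        element_volumes = []
        # RBS-linkers sit at the even positions 1,3,5 of the 8-element template
        for pos, element in enumerate(construct.all_elements):
            is_linker = pos in (1, 3, 5) and element != construct.backbone_id
            vol = config.linker_volume_nl if is_linker else config.part_volume_nl
            element_volumes.append((element, vol))
        for reagent in config.reagents:
            element_volumes.append((reagent, config.mix_volume_nl))
        for content, vol in element_volumes:
            if content not in source:
                raise LayoutError(
                    f"{content!r} (needed by {label}) is on no source plate"
                )
            q = quantise_volume(vol, config.droplet_nl)
            total += q
            plate_name, well = source[content]
            picklist.transfers.append(
                Transfer(plate_name, well, config.destination_plate, dest, q)
            )
        if total > config.max_well_volume_nl:
            raise CapacityError(
                f"destination {dest} for {label} would hold {total} nL "
                f"(max {config.max_well_volume_nl} nL)"
            )
    return picklist


def write_picklist(picklist: Picklist, destination: str | Path) -> Path:
    """Write the picklist CSV (Echo-importable dialect, volumes in nL)."""
    destination = Path(destination)
    if not picklist.transfers:
        logger.warning("writing an empty picklist (header only): %s", destination)
    with destination.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PICKLIST_HEADER)
        for t in picklist.transfers:
            vol = int(t.volume_nl) if float(t.volume_nl).is_integer() else t.volume_nl
            writer.writerow([t.source_plate, t.source_well,
                             t.destination_plate, t.destination_well, vol])
    return destination


def read_picklist(path: str | Path) -> Picklist:
    """Inverse of :func:`write_picklist` (used for round-trip checks)."""
    picklist = Picklist()
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = tuple(next(reader))
        if header != PICKLIST_HEADER:
            raise LayoutError(f"unexpected picklist header: {header}")
        for row in reader:
            picklist.transfers.append(
                Transfer(row[0], row[1], row[2], row[3], float(row[4]))
            )
    return picklist
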