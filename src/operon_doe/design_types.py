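"""Dataclasses describing factors, configurations and constructs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

from .errors import DesignSpaceError


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor.

    Discrete-numeric factors carry strictly increasing ``numeric_values``
    (part-strength ranks) aligned with ``levels``; categorical factors
    (gene order) carry labels only.  ``part_map`` translates a level label
    to the concrete part realising it (for RBS factors, the assembly linker
    that embeds the RBS).
    """

    name: str
    kind: Literal["discrete_numeric", "categorical"]
    levels: tuple[str, ...]
    numeric_values: Optional[tuple[int, ...]] = None
    part_map: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise DesignSpaceError(f"factor {self.name!r} has no levels")
        if len(set(self.levels)) != len(self.levels):
            raise DesignSpaceError(f"factor {self.name!r} has duplicate levels")
        if self.kind == "discrete_numeric":
            if self.numeric_values is None or len(self.numeric_values) != len(self.levels):
                raise DesignSpaceError(
                    f"factor {self.name!r}: numeric_values must align with levels"
                )
            if any(b <= a for a, b in zip(self.numeric_values, self.numeric_values[1:])):
                raise DesignSpaceError(
                    f"factor {self.name!r}: numeric_values must be strictly increasing"
                )
        elif self.kind != "categorical":
            raise DesignSpaceError(f"factor {self.name!r}: unknown kind {self.kind!r}")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def value_of(self, level: str) -> int:
        """Numeric value (rank) of a level of a discrete-numeric factor."""
        if self.numeric_values is None:
            raise DesignSpaceError(f"factor {self.name!r} is not numeric")
        return self.numeric_values[self.levels.index(level)]

    def level_for_value(self, value: int) -> str:
        if self.numeric_values is None:
            raise DesignSpaceError(f"factor {self.name!r} is not numeric")
        try:
            return self.levels[self.numeric_values.index(int(value))]
        except ValueError:
            raise DesignSpaceError(
                f"factor {self.name!r} has no level with value {value!r}"
            ) from None


@dataclass(frozen=True)
class DesignSpace:
    """An ordered set of factors plus the operon wiring needed for builds.

    ``genes``/``gene_codes``/``terminator_id``/``backbone_id`` are only
    required when configurations are realised as constructs; purely
    statistical uses (enumeration, design selection) need just ``factors``.
    """

    factors: tuple[FactorSpec, ...]
    genes: tuple[str, ...] = ()
    gene_codes: Mapping[str, str] = field(default_factory=dict)  # code -> gene part_id
    terminator_id: Optional[str] = None
    backbone_id: Optional[str] = None

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise DesignSpaceError("duplicate factor names")

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"no factor named {name!r}")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def n_configurations(self) -> int:
        n = 1
        for f in self.factors:
            n *= f.n_levels
        return n


@dataclass(frozen=True)
class Configuration:
    """One point of the design space: a level assignment per factor."""

    assignment: Mapping[str, str]
    config_index: int


@dataclass(frozen=True)
class Construct:
    """A configuration realised as an ordered DNA part list.

    ``ordered_elements`` is the promoter, alternating RBS-linkers and CDSs,
    and the terminator; the vector backbone is carried separately.
    """

    configuration: Configuration
    ordered_elements: tuple[str, ...]
    backbone_id: Optional[str] = None
    stitch_id: Optional[str] = None

    @property
    def all_elements(self) -> tuple[str, ...]:
        if self.backbone_id is None:
            return self.ordered_elements
        return self.ordered_elements + (self.backbone_id,)
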