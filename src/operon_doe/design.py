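"""Factor structure and full-factorial enumeration of an operon library.

A three-gene synthetic operon is varied along five factors: the promoter,
the RBS at each of the three gene positions (discrete-numeric factors whose
levels are part-strength ranks, 1 = weakest) and the gene order (a
categorical factor with ``g!`` levels for ``g`` genes).  For the canonical
5-promoter / 3-RBS / 3-gene library this gives 5 x 3 x 3 x 3 x 6 = 810
configurations.  Each configuration maps to one concrete construct:

    promoter, linker(rbs1), cds_s(1), linker(rbs2), cds_s(2),
    linker(rbs3), cds_s(3), terminator      (+ the vector backbone)

where the RBS parts ride inside the assembly linkers (linker-based modular
cloning) and ``s`` is the gene-order permutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .design_types import Configuration, Construct, DesignSpace, FactorSpec
from .errors import DesignSpaceError, UnrankedPartError
from .parts import PartClass, PartLibrary

__all__ = [
    "FactorSpec",
    "DesignSpace",
    "Configuration",
    "Construct",
    "build_design_space",
    "enumerate_configurations",
    "configuration_to_construct",
]

PROMOTER = "promoter"
RBS_POSITIONS = ("rbs_pos1", "rbs_pos2", "rbs_pos3")
GENE_ORDER = "gene_order"


def _gene_codes(genes: Sequence[str], library: PartLibrary,
                codes: Optional[Mapping[str, str]]) -> dict[str, str]:
    """One single-letter code per gene, used to label gene-order levels."""
    if codes:
        out = {g: codes[g] for g in genes}
    else:
        # default: last character of the part name, upper-cased (crtE -> E)
        out = {g: library.get(g).name[-1].upper() for g in genes}
    if len(set(out.values())) != len(genes):
        raise DesignSpaceError(f"gene codes not unique: {out}")
    return out


def _ranked_levels(parts) -> tuple[list[str], list[int]]:
    if any(p.rank is None for p in parts):
        missing = [p.part_id for p in parts if p.rank is None]
        raise UnrankedPartError(f"unranked part(s): {missing}")
    ordered = sorted(parts, key=lambda p: p.rank)
    return [p.part_id for p in ordered], [p.rank for p in ordered]


def build_design_space(library: PartLibrary, config: Mapping) -> DesignSpace:
    """Construct the operon design space from a ranked library.

    ``config`` keys:

    ``genes``
        ordered list of CDS part_ids (the pathway enzymes).
    ``gene_codes``
        optional mapping part_id -> single-letter code for order labels.
    ``rbs_linkers``
        optional mapping rbs part_id -> linker part_id carrying that RBS;
        defaults to the RBS part itself when no linkers are present.
    ``terminator``, ``backbone``
        optional explicit part_ids; default to the unique part of that class.
    """
    def _single(part_class: PartClass, key: str) -> str:
        if config.get(key):
            pid = config[key]
            if pid not in library:
                raise DesignSpaceError(f"{key} part {pid!r} not in library")
            return pid
        members = library.of_class(part_class)
        if len(members) != 1:
            raise DesignSpaceError(
                f"library must contain exactly one {part_class.value} "
                f"(found {len(members)}) unless {key!r} is set in the config"
            )
        return members[0].part_id

    promoters = library.of_class(PartClass.PROMOTER)
    rbss = library.of_class(PartClass.RBS)
    genes = list(config.get("genes", ()))
    if not genes:
        genes = [p.part_id for p in library.of_class(PartClass.CDS)]
    for cls_name, members in (("promoter", promoters), ("rbs", rbss), ("cds", genes)):
        if not members:
            raise DesignSpaceError(f"library provides no {cls_name} parts")
    for g in genes:
        if g not in library:
            raise DesignSpaceError(f"gene part {g!r} not in library")

    terminator_id = _single(PartClass.TERMINATOR, "terminator")
    backbone_id = _single(PartClass.BACKBONE, "backbone")

    rbs_linkers = dict(config.get("rbs_linkers") or {})
    for r in rbss:
        rbs_linkers.setdefault(r.part_id, r.part_id)
        if rbs_linkers[r.part_id] not in library:
            raise DesignSpaceError(
                f"linker {rbs_linkers[r.part_id]!r} for RBS {r.part_id!r} not in library"
            )

    prom_levels, prom_ranks = _ranked_levels(promoters)
    rbs_levels, rbs_ranks = _ranked_levels(rbss)

    codes = _gene_codes(genes, library, config.get("gene_codes"))
    order_levels = [
        "-".join(perm)
        for perm in itertools.permutations(sorted(codes.values()))
    ]
    code_to_gene = {c: g for g, c in codes.items()}

    factors = [
        FactorSpec(
            name=PROMOTER,
            kind="discrete_numeric",
            levels=tuple(prom_levels),
            numeric_values=tuple(prom_ranks),
            part_map={lev: lev for lev in prom_levels},
        )
    ]
    for pos in RBS_POSITIONS:
        factors.append(
            FactorSpec(
                name=pos,
                kind="discrete_numeric",
                levels=tuple(rbs_levels),
                numeric_values=tuple(rbs_ranks),
                part_map={lev: rbs_linkers[lev] for lev in rbs_levels},
            )
        )
    factors.append(
        FactorSpec(name=GENE_ORDER, kind="categorical", levels=tuple(order_levels))
    )
    return DesignSpace(
        factors=tuple(factors),
        genes=tuple(genes),
        gene_codes=code_to_gene,
        terminator_id=terminator_id,
        backbone_id=backbone_id,
    )


def enumerate_configurations(space: DesignSpace) -> list[Configuration]:
    """All configurations in lexicographic factor-definition order.

    The last factor varies fastest; ``config_index`` is dense ``0..N-1``.
    Two calls yield identical orderings.
    """
    names = [f.name for f in space.factors]
    out = []
    for i, combo in enumerate(
        itertools.product(*(f.levels for f in space.factors))
    ):
        out.append(Configuration(assignment=dict(zip(names, combo)), config_index=i))
    return out


def configuration_to_construct(space: DesignSpace, config: Configuration) -> Construct:
    """Realise one configuration as an ordered part list.

    Template: promoter, then (RBS-linker_i, gene at position i) for each
    position, then terminator; the backbone is carried separately.
    """
    if set(config.assignment) != {f.name for f in space.factors}:
        raise DesignSpaceError(
            f"configuration does not cover the factors of this space: "
            f"{sorted(config.assignment)}"
        )
    if not space.genes:
        raise DesignSpaceError("space carries no gene list; cannot build constructs")

    def mapped(factor_name: str) -> str:
        factor = space.factor(factor_name)
        level = config.assignment[factor_name]
        if factor.part_map is None or level not in factor.part_map:
            raise DesignSpaceError(
                f"level {level!r} of factor {factor_name!r} has no part mapping"
            )
        return factor.part_map[level]

    order_label = config.assignment[GENE_ORDER]
    try:
        ordered_genes = [space.gene_codes[c] for c in order_label.split("-")]
    except KeyError as exc:
        raise DesignSpaceError(f"unknown gene code in order level {order_label!r}") from exc

    elements: list[str] = [mapped(PROMOTER)]
    rbs_positions = RBS_POSITIONS[: len(ordered_genes)]
    for pos, gene in zip(rbs_positions, ordered_genes):
        elements.append(mapped(pos))
        elements.append(gene)
    elements.append(space.terminator_id)
    return Construct(
        configuration=config,
        ordered_elements=tuple(elements),
        backbone_id=space.backbone_id,
    )
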