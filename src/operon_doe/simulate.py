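"""Seeded simulator of combinatorial-library screening outcomes.

Stands in for the wet lab so the whole design/analyse loop is testable.
Each selected construct either fails outright — with probability
``logit^-1(alpha0 + alpha1 * x_prom)``, rising with the coded promoter
strength ``x_prom`` to mimic the metabolic burden of strong expression —
or yields replicate titres from a linear factor-effect model,

    titre = beta0 + beta_prom*x_prom + sum_i beta_rbs_i*x_rbs_i
            + gamma[order] + Normal(0, sigma),

truncated at zero, with titres below the detection floor flagged
undetected.  Failed constructs are emitted as rows with an empty titre:
most show no growth at all, a small fraction grow without product.  All
randomness flows through one seeded generator, so a seed fixes the output
table bitwise.

The default ground truth is a calibration, not an estimate: effects are
chosen so gene order dominates, promoter strength is a clear negative
effect, position-3 RBS a weaker one, roughly half of builds fail, and
detected titres span about 0.05-4.6 mg/g DCW.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .design import GENE_ORDER, PROMOTER, RBS_POSITIONS, enumerate_configurations
from .design_types import Configuration, DesignSpace
from .doe import ModelSpec, ReducedDesign, encode_model_matrix
from .quantify import StandardCurve, od_to_dcw

__all__ = [
    "GroundTruth",
    "default_truth",
    "calibrate_failure_intercept",
    "calibrated_truth",
    "simulate_titres",
    "raw_measurements_from_sim",
]


@dataclass(frozen=True)
class GroundTruth:
    """True effect structure driving the simulator (coded units, mg/g DCW)."""

    beta0: float = 1.7
    beta_prom: float = -0.8
    beta_rbs: tuple[float, float, float] = (0.0, 0.0, -0.45)
    #: per gene-order level, sum-to-zero, aligned with the space's level order
    gamma_order: tuple[float, ...] = (-0.6, 1.2, -0.9, 1.2, -0.3, -0.6)
    sigma: float = 0.25
    alpha0: float = 0.12
    alpha1: float = 1.0          # failure-logit slope on coded promoter, >= 0
    lod: float = 0.05            # detection floor, mg/g DCW
    p_no_growth: float = 45 / 47  # no-growth share among failures

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.alpha1 < 0:
            raise ValueError("alpha1 must be >= 0")
        if self.lod < 0:
            raise ValueError("lod must be >= 0")
        if abs(sum(self.gamma_order)) > 1e-9:
            raise ValueError("gamma_order must sum to zero")
        if not 0.0 <= self.p_no_growth <= 1.0:
            raise ValueError("p_no_growth must be a probability")

    def coefficient_vector(self, space: DesignSpace, model: ModelSpec) -> np.ndarray:
        """Truth expressed on the coded main-effects columns of ``model``."""
        order_k = space.factor(GENE_ORDER).n_levels
        if order_k != len(self.gamma_order):
            raise ValueError(
                f"gamma_order has {len(self.gamma_order)} entries for "
                f"{order_k} gene-order levels"
            )
        coef: list[float] = []
        for term in model.terms:
            if term == ("intercept",):
                coef.append(self.beta0)
            elif term == ("main", PROMOTER):
                coef.append(self.beta_prom)
            elif term[0] == "main" and term[1] in RBS_POSITIONS:
                coef.append(self.beta_rbs[RBS_POSITIONS.index(term[1])])
            elif term == ("main", GENE_ORDER):
                # effects coding: coefficient for level i (< k-1) is gamma_i
                coef.extend(self.gamma_order[:-1])
            else:
                raise ValueError(f"truth has no coefficients for term {term!r}")
        return np.asarray(coef)


def calibrate_failure_intercept(x_prom: Sequence[float], target: float = 0.53,
                                alpha1: float = 1.0) -> float:
    """Solve alpha0 so the mean failure probability over a design hits ``target``."""
    x = np.asarray(x_prom, dtype=float)

    def gap(a0: float) -> float:
        return float(np.mean(expit(a0 + alpha1 * x))) - target

    return float(brentq(gap, -30.0, 30.0))


def default_truth(x_prom: Optional[Sequence[float]] = None,
                  failure_rate: float = 0.53, **overrides) -> GroundTruth:
    """The calibrated default truth.

    When the design's coded promoter column ``x_prom`` is given, the
    failure intercept is solved so the design-average failure probability
    equals ``failure_rate``.
    """
    truth = GroundTruth(**overrides)
    if x_prom is not None:
        a0 = calibrate_failure_intercept(x_prom, failure_rate, truth.alpha1)
        truth = replace(truth, alpha0=a0)
    return truth


def calibrated_truth(space: DesignSpace,
                     design: "ReducedDesign | Sequence[Configuration] | None",
                     target: float = 0.53, replicates: int = 3,
                     **overrides) -> GroundTruth:
    """Default truth with the failure intercept solved against a design.

    A construct "fails to produce" either by the outright failure draw or
    by growing with every replicate below the detection floor; the
    intercept is solved so the design-average probability of either
    outcome equals ``target``.
    """
    truth = GroundTruth(**overrides)
    configs = _design_configs(space, design)
    model = ModelSpec.main_effects(space)
    mm = encode_model_matrix(space, configs, model)
    pred = mm.matrix @ truth.coefficient_vector(space, model)
    x = mm.matrix[:, list(mm.term_columns[("main", PROMOTER)])].ravel()
    if truth.sigma > 0:
        sub_lod = stats.norm.cdf((truth.lod - pred) / truth.sigma) ** replicates
    else:
        sub_lod = (pred < truth.lod).astype(float)

    def gap(a0: float) -> float:
        pi = expit(a0 + truth.alpha1 * x)
        return float(np.mean(pi + (1.0 - pi) * sub_lod)) - target

    return replace(truth, alpha0=float(brentq(gap, -30.0, 30.0)))


def _design_configs(space: DesignSpace,
                    design: ReducedDesign | Sequence[Configuration] | None
                    ) -> list[Configuration]:
    if design is None:
        return enumerate_configurations(space)
    if isinstance(design, ReducedDesign):
        all_configs = enumerate_configurations(space)
        return [all_configs[i] for i in design.run_indices]
    return list(design)


def simulate_titres(space: DesignSpace,
                    design: ReducedDesign | Sequence[Configuration] | None,
                    truth: GroundTruth, replicates: int = 3, *,
                    seed: int = 0, stitch_prefix: str = "S") -> pd.DataFrame:
    """Simulate one screen of the selected (or full) design.

    Returns one row per construct x replicate with the factor columns
    (numeric factors as rank values, gene order as its label) plus
    ``stitch_id, replicate, grew, titre, detected``.  Failed constructs
    carry NaN titres.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    configs = _design_configs(space, design)
    model = ModelSpec.main_effects(space)
    mm = encode_model_matrix(space, configs, model)
    predictor = mm.matrix @ truth.coefficient_vector(space, model)
    x_prom = mm.matrix[:, list(mm.term_columns[("main", PROMOTER)])].ravel()

    rng = np.random.default_rng(seed)
    n = len(configs)
    fail = rng.random(n) < expit(truth.alpha0 + truth.alpha1 * x_prom)
    no_growth = rng.random(n) < truth.p_no_growth
    noise = rng.normal(0.0, truth.sigma, size=(n, replicates)) if truth.sigma > 0 \
        else np.zeros((n, replicates))

    width = max(3, len(str(n)))
    rows = []
    for i, config in enumerate(configs):
        stitch = f"{stitch_prefix}{i + 1:0{width}d}"
        base = {"stitch_id": stitch, "config_index": config.config_index}
        for f in space.factors:
            lev = config.assignment[f.name]
            base[f.name] = f.value_of(lev) if f.kind == "discrete_numeric" else lev
        for rep in range(1, replicates + 1):
            if fail[i]:
                rows.append({**base, "replicate": rep,
                             "grew": not no_growth[i],
                             "titre": np.nan, "detected": False})
            else:
                titre = max(0.0, float(predictor[i] + noise[i, rep - 1]))
                rows.append({**base, "replicate": rep, "grew": True,
                             "titre": titre,
                             "detected": titre >= truth.lod})
    return pd.DataFrame(rows)


def raw_measurements_from_sim(sim: pd.DataFrame, curve: StandardCurve,
                              od600: float = 2.0, *,
                              culture_volume_ml: float = 1.0,
                              extract_volume_ml: float = 1.0) -> pd.DataFrame:
    """Invert the quantification formulas to emit pseudo raw measurements.

    Grown constructs get the stated OD600 and the LC peak area that would
    reproduce the simulated titre through the standard curve; no-growth
    rows get OD 0 and zero area.  Exercises the quantification module on
    synthetic data.
    """
    rows = []
    for row in sim.itertuples(index=False):
        grew = bool(row.grew)
        od = od600 if grew else 0.0
        titre = float(row.titre) if np.isfinite(row.titre) else 0.0
        dcw = od_to_dcw(od, culture_volume_ml)
        conc = titre * dcw / extract_volume_ml       # mg/mL in the extract
        area = curve.slope * conc + curve.intercept if grew else 0.0
        rows.append(
            {
                "stitch_id": row.stitch_id,
                "replicate": int(row.replicate),
                "od600": od,
                "peak_area_450": area * 0.8,  # 450 nm channel runs lower
                "peak_area_471": area,
                "culture_volume_mL": culture_volume_ml,
                "extract_volume_mL": extract_volume_ml,
            }
        )
    return pd.DataFrame(rows)
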