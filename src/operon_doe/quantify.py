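"""Titre quantification: OD600 and LC-DAD peak areas to mg product per g DCW.

Units contract (fixed throughout the package): standard and sample
concentrations in mg/mL, volumes in mL, dry cell weight (DCW) in g, titres
in mg per g DCW.  Biomass is converted from optical density with the fixed
ratio DCW/OD600 = 0.36 g/L, scaled to the culture volume.  Carotenoid
abundance is read off a linear standard curve fitted to external-standard
injections; the default detection channel is 471 nm (the lycopene
absorbance maximum of the two recorded wavelengths), with 450 nm
selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnderdeterminedError, UndefinedTitreError

logger = logging.getLogger(__name__)

#: Grams of dry cell weight per litre of culture per OD600 unit.
DCW_PER_OD_G_PER_L = 0.36


@dataclass(frozen=True)
class StandardCurve:
    """Linear external-standard calibration: area = slope*conc + intercept."""

    slope: float                      # peak-area units per (mg/mL)
    intercept: float
    r_squared: float
    n_points: int
    min_nonzero_conc: Optional[float] = None  # default detection floor, mg/mL

    def concentration(self, area: float) -> float:
        return (area - self.intercept) / self.slope


@dataclass(frozen=True)
class SampleMeasurement:
    stitch_id: str
    replicate: int
    od600: float
    peak_area_450: float = 0.0
    peak_area_471: float = 0.0
    culture_volume_ml: float = 1.0
    extract_volume_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.od600 < 0:
            raise ValueError(f"{self.stitch_id}: od600 must be >= 0")
        if self.culture_volume_ml <= 0 or self.extract_volume_ml <= 0:
            raise ValueError(f"{self.stitch_id}: volumes must be > 0")


@dataclass(frozen=True)
class TitreRecord:
    stitch_id: str
    replicate: int
    dcw_g: float
    titre_mg_per_gdcw: float
    detected: bool


def od_to_dcw(od600: float, culture_volume_ml: float = 1.0) -> float:
    """Dry cell weight in grams from OD600 and culture volume.

    ``0.36 * OD600`` g per litre, scaled by the culture volume; linear and
    homogeneous in OD.
    """
    if od600 < 0:
        raise ValueError("od600 must be >= 0")
    if culture_volume_ml <= 0:
        raise ValueError("culture_volume_ml must be > 0")
    return DCW_PER_OD_G_PER_L * od600 * (culture_volume_ml / 1000.0)


def fit_standard_curve(concentrations_mg_per_ml: Sequence[float],
                       areas: Sequence[float], *,
                       through_origin: bool = False) -> StandardCurve:
    """Ordinary least-squares line through the standards.

    Needs at least two points at two distinct concentrations.  The
    smallest nonzero standard is recorded as the default detection floor.
    ``through_origin`` forces a zero intercept.
    """
    conc = np.asarray(concentrations_mg_per_ml, dtype=float)
    area = np.asarray(areas, dtype=float)
    if conc.shape != area.shape:
        raise ValueError("concentrations and areas differ in length")
    if conc.size < 2 or np.unique(conc).size < 2:
        raise UnderdeterminedError(
            "need >= 2 standards at >= 2 distinct concentrations"
        )
    if through_origin:
        slope = float(conc @ area / (conc @ conc))
        intercept = 0.0
        fitted = slope * conc
        ss_res = float(np.sum((area - fitted) ** 2))
        ss_tot = float(np.sum((area - area.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    else:
        fit = stats.linregress(conc, area)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    nz = conc[conc > 0]
    return StandardCurve(
        slope=slope, intercept=intercept, r_squared=r2, n_points=int(conc.size),
        min_nonzero_conc=float(nz.min()) if nz.size else None,
    )


def peak_area_to_titre(m: SampleMeasurement, curve: StandardCurve,
                       channel: int = 471, *,
                       detection_floor: Optional[float] = None) -> TitreRecord:
    """One measurement to a titre record.

    conc = (area - intercept)/slope [mg/mL]; extracted mass = conc *
    extract volume [mg]; titre = mass / DCW [mg/g].  A concentration below
    the detection floor (default: the smallest nonzero standard) is flagged
    undetected; a negative concentration is clamped to zero with a warning.
    """
    if curve.slope <= 0:
        raise ValueError("standard curve slope must be > 0")
    if channel not in (450, 471):
        raise ValueError("channel must be 450 or 471")
    area = m.peak_area_471 if channel == 471 else m.peak_area_450
    floor = detection_floor if detection_floor is not None else (
        curve.min_nonzero_conc or 0.0
    )
    conc = curve.concentration(area)
    if conc < 0:
        if area > 0:  # an empty injection (area 0) is silently zero signal
            logger.warning(
                "%s rep %d: area %.3g below curve intercept; clamping to zero",
                m.stitch_id, m.replicate, area,
            )
        conc = 0.0
    dcw = od_to_dcw(m.od600, m.culture_volume_ml)
    if dcw == 0.0:
        if conc > 0:
            raise UndefinedTitreError(
                f"{m.stitch_id} rep {m.replicate}: nonzero signal with zero DCW"
            )
        return TitreRecord(m.stitch_id, m.replicate, 0.0, 0.0, False)
    mass_mg = conc * m.extract_volume_ml
    titre = mass_mg / dcw
    return TitreRecord(m.stitch_id, m.replicate, dcw, titre, bool(conc > floor))


def quantify_table(measurements: pd.DataFrame, curve: StandardCurve,
                   channel: int = 471, *,
                   detection_floor: Optional[float] = None) -> pd.DataFrame:
    """Vector version over a measurements table.

    Expects columns ``stitch_id, replicate, od600, peak_area_450,
    peak_area_471`` and optional volume columns; returns the titres table
    (``stitch_id, replicate, dcw_g, titre_mg_per_gdcw, detected``).
    """
    records = []
    for row in measurements.itertuples(index=False):
        m = SampleMeasurement(
            stitch_id=str(row.stitch_id),
            replicate=int(row.replicate),
            od600=float(row.od600),
            peak_area_450=float(getattr(row, "peak_area_450", 0.0)),
            peak_area_471=float(getattr(row, "peak_area_471", 0.0)),
            culture_volume_ml=float(getattr(row, "culture_volume_mL", 1.0)),
            extract_volume_ml=float(getattr(row, "extract_volume_mL", 1.0)),
        )
        records.append(peak_area_to_titre(m, curve, channel,
                                          detection_floor=detection_floor))
    return pd.DataFrame(
        {
            "stitch_id": [r.stitch_id for r in records],
            "replicate": [r.replicate for r in records],
            "dcw_g": [r.dcw_g for r in records],
            "titre_mg_per_gdcw": [r.titre_mg_per_gdcw for r in records],
            "detected": [r.detected for r in records],
        }
    )


@dataclass(frozen=True)
class ScreenSummary:
    """Outcome counts of one library screen."""

    n_constructs: int
    producers: int
    no_growth: int
    no_product: int

    @property
    def failures(self) -> int:
        return self.no_growth + self.no_product

    @property
    def failure_rate_pct(self) -> int:
        """Failed fraction, rounded to the nearest percent."""
        return round(100.0 * self.failures / self.n_constructs)


def screen_summary(titres: pd.DataFrame) -> ScreenSummary:
    """Per-construct screening outcome from a titres table.

    A construct is a *producer* when any replicate is detected; *no
    growth* when every replicate has zero DCW (or a false ``grew`` flag);
    otherwise it grew without detectable product.
    """
    required = {"stitch_id", "detected"}
    missing = required - set(titres.columns)
    if missing:
        raise ValueError(f"titres table missing column(s): {sorted(missing)}")
    producers = no_growth = no_product = 0
    for _, group in titres.groupby("stitch_id", sort=False):
        if bool(group["detected"].any()):
            producers += 1
        else:
            if "grew" in group.columns:
                grew = bool(group["grew"].any())
            elif "dcw_g" in group.columns:
                grew = bool((group["dcw_g"] > 0).any())
            else:
                grew = False
            if grew:
                no_product += 1
            else:
                no_growth += 1
    n = titres["stitch_id"].nunique()
    return ScreenSummary(n_constructs=n, producers=producers,
                         no_growth=no_growth, no_product=no_product)
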