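"""Least-squares effect screening and optimum prediction.

Observed titres from the screened library are modelled with ordinary least
squares on the coded model matrix (numeric factors rescaled to [-1, 1],
categorical factors effects-coded).  Each factor is judged by a partial
F test — the full fit against the fit with that factor's columns removed —
and summarised as a LogWorth, ``-log10(p)``; a LogWorth above 2 (p < 0.01)
is treated as significant.  Constructs that failed to grow or produced no
detectable product are excluded, and replicates of a construct are averaged
by default.  The fitted model is then evaluated over every configuration of
the design space to rank candidate designs by predicted titre.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import enumerate_configurations
from .design_types import Configuration, DesignSpace
from .doe import ModelMatrix, ModelSpec, encode_model_matrix
from .errors import AliasingError, InfeasibleFitError

logger = logging.getLogger(__name__)

#: LogWorth values are capped here to guard against p-value underflow.
LOGWORTH_CAP = 320.0

#: LogWorth significance threshold (p < 0.01).
SIGNIFICANCE_THRESHOLD = 2.0


def logworth(p_value: float) -> float:
    """``-log10(p)``, capped at :data:`LOGWORTH_CAP`."""
    if p_value <= 0.0:
        return LOGWORTH_CAP
    return float(min(-np.log10(p_value), LOGWORTH_CAP))


@dataclass(frozen=True)
class FittedModel:
    """An OLS fit of titre on the coded screening model."""

    coefficients: np.ndarray
    columns: tuple[str, ...]
    model: ModelSpec
    n_obs: int
    residual_df: int
    rss: float
    sigma2: float
    X: np.ndarray
    y: np.ndarray

    def predict(self, mm: ModelMatrix) -> np.ndarray:
        return mm.matrix @ self.coefficients


@dataclass(frozen=True)
class EffectSummary:
    """Per-factor F tests sorted by LogWorth, descending."""

    table: pd.DataFrame  # factor, df, F, p_value, log_worth, significant

    def __getitem__(self, factor: str) -> pd.Series:
        rows = self.table[self.table["factor"] == factor]
        if rows.empty:
            raise KeyError(factor)
        return rows.iloc[0]


@dataclass(frozen=True)
class Prediction:
    configuration: Configuration
    predicted_titre: float
    rank: int


def configurations_from_table(space: DesignSpace, table: pd.DataFrame
                              ) -> list[Configuration]:
    """Rebuild configurations from a flat factor table.

    Numeric factor columns may hold rank values or level labels;
    categorical columns hold labels.  ``config_index`` is taken from the
    table when present, else -1.
    """
    missing = [f.name for f in space.factors if f.name not in table.columns]
    if missing:
        raise ValueError(f"table missing factor column(s): {missing}")
    configs = []
    for _, row in table.iterrows():
        assignment = {}
        for f in space.factors:
            val = row[f.name]
            if f.kind == "discrete_numeric" and str(val) not in f.levels:
                assignment[f.name] = f.level_for_value(int(float(val)))
            else:
                assignment[f.name] = str(val)
        idx = int(row["config_index"]) if "config_index" in table.columns else -1
        configs.append(Configuration(assignment=assignment, config_index=idx))
    return configs


def _observed_table(table: pd.DataFrame, space: DesignSpace,
                    per_replicate: bool, response: str) -> pd.DataFrame:
    """Exclude failed constructs and (by default) average replicates."""
    df = table.copy()
    if "detected" in df.columns:
        key = "stitch_id" if "stitch_id" in df.columns else "config_index"
        produced = df.groupby(key)["detected"].transform("any")
        df = df[produced]
    df = df[np.isfinite(df[response].astype(float))]
    if df.empty:
        raise InfeasibleFitError("no usable observations after exclusions")
    if per_replicate:
        return df
    key = "stitch_id" if "stitch_id" in df.columns else "config_index"
    factor_cols = [f.name for f in space.factors]
    keep = [c for c in ["config_index"] if c in df.columns and c != key]
    agg = {response: "mean", **{c: "first" for c in factor_cols + keep}}
    return df.groupby(key, sort=False, as_index=False).agg(agg)


def fit_effects(table: pd.DataFrame, space: DesignSpace, model: ModelSpec, *,
                per_replicate: bool = False, response: str = "titre"
                ) -> FittedModel:
    """OLS fit of the screening model on observed titres.

    ``table`` joins the design's factor columns with the measured response
    (plus optional ``detected``/``stitch_id``/``replicate`` columns).
    Undetected constructs are excluded; replicates are averaged per
    construct unless ``per_replicate``.  Raises :class:`AliasingError` if
    the observed model matrix is rank deficient and
    :class:`InfeasibleFitError` when fewer observations than parameters
    remain.
    """
    obs = _observed_table(table, space, per_replicate, response)
    configs = configurations_from_table(space, obs)
    mm = encode_model_matrix(space, configs, model)
    X = mm.matrix
    y = obs[response].to_numpy(dtype=float)
    n, p = X.shape
    if n < p:
        raise InfeasibleFitError(f"{n} observations for {p} model columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        thin = [f.name for f in space.factors if obs[f.name].nunique() < 2]
        detail = (
            ", ".join(thin) if thin
            else "confounding involves level combinations"
        )
        raise AliasingError(
            f"model matrix rank {rank} < p={p}; "
            f"factor(s) with a single observed level: {detail}"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    residual_df = n - p
    sigma2 = rss / residual_df if residual_df > 0 else 0.0
    return FittedModel(
        coefficients=coef, columns=mm.columns, model=model, n_obs=n,
        residual_df=residual_df, rss=rss, sigma2=sigma2, X=X, y=y,
    )


def effect_summary(fit: FittedModel, space: DesignSpace) -> EffectSummary:
    """Partial (type-III-style) F test per model factor.

    Each factor's F compares the full fit against the fit without that
    factor's coded columns; under effects coding this matches the effect
    summary of standard DoE software.  When the residual variance is zero
    the p-value is reported at the cap with a warning.
    """
    if fit.residual_df < 1:
        raise InfeasibleFitError("no residual degrees of freedom for F tests")
    mm_terms = fit.model._column_names(space)
    col_index = {name: i for i, name in enumerate(fit.columns)}
    rows = []
    for term in fit.model.terms:
        if term[0] == "intercept":
            continue
        label = term[1] if term[0] == "main" else "*".join(term[1:])
        idx = [col_index[c] for c in mm_terms[term]]
        keep = [i for i in range(len(fit.columns)) if i not in idx]
        Xr = fit.X[:, keep]
        coef_r, _, _, _ = np.linalg.lstsq(Xr, fit.y, rcond=None)
        rss_r = float(np.sum((fit.y - Xr @ coef_r) ** 2))
        df_num = len(idx)
        # an interpolating fit leaves only rounding noise in the residuals
        rss_floor = 1e-12 * max(float(fit.y @ fit.y), 1.0)
        if fit.rss <= rss_floor:
            warnings.warn(
                f"zero residual variance; p for {label!r} reported at the cap",
                stacklevel=2,
            )
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ((rss_r - fit.rss) / df_num) / (fit.rss / fit.residual_df)
            f_stat = max(float(f_stat), 0.0)
            p = float(stats.f.sf(f_stat, df_num, fit.residual_df))
            p = min(max(p, 0.0), 1.0)
        lw = logworth(p)
        rows.append(
            {
                "factor": label,
                "df": df_num,
                "F": f_stat,
                "p_value": p,
                "log_worth": lw,
                "significant": lw > SIGNIFICANCE_THRESHOLD,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("log_worth", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return EffectSummary(table=table)


def predict_optimum(fit: FittedModel, space: DesignSpace, top_k: int = 5
                    ) -> list[Prediction]:
    """Rank every configuration of the space by predicted titre.

    Ranks are dense (1 = best); configurations whose predictions tie (to
    1e-9 relative) share a rank and are all reported.  Returns every
    prediction with rank <= ``top_k``.
    """
    configs = enumerate_configurations(space)
    mm = encode_model_matrix(space, configs, fit.model)
    preds = fit.predict(mm)
    # group ties: quantise to a tolerance scaled by the prediction spread
    scale = max(np.ptp(preds), 1.0)
    keys = np.round(preds / (1e-9 * scale)).astype(np.int64)
    order = np.argsort(-preds, kind="mergesort")
    rank_of_key: dict[int, int] = {}
    for i in order:
        rank_of_key.setdefault(int(keys[i]), len(rank_of_key) + 1)
    out = [
        Prediction(configs[i], float(preds[i]), rank_of_key[int(keys[i])])
        for i in order
        if rank_of_key[int(keys[i])] <= top_k
    ]
    return out


def prediction_table(predictions: Sequence[Prediction], space: DesignSpace
                     ) -> pd.DataFrame:
    rows = []
    for p in predictions:
        row = {"rank": p.rank, "predicted_titre": p.predicted_titre,
               "config_index": p.configuration.config_index}
        for f in space.factors:
            lev = p.configuration.assignment[f.name]
            row[f.name] = f.value_of(lev) if f.kind == "discrete_numeric" else lev
        rows.append(row)
    return pd.DataFrame(rows)


def fit_failure_trend(promoter_rank: Sequence[float], failed: Sequence[bool]
                      ) -> tuple[float, float, float]:
    """Logistic fit of assembly/expression failure on promoter rank.

    Returns (intercept, slope, slope p-value).  Quantifies the observation
    that failures become more frequent as promoter strength rises.
    """
    import statsmodels.api as sm

    x = sm.add_constant(np.asarray(promoter_rank, dtype=float))
    yv = np.asarray(failed, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(yv, x).fit(disp=False)
    return float(res.params[0]), float(res.params[1]), float(res.pvalues[1])
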