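"""D-optimal run reduction over a full-factorial candidate set.

The screening model is linear in coded units: discrete-numeric factors
(part-strength ranks ``r``) are rescaled to ``x = 2(r - r_min)/(r_max -
r_min) - 1`` so every numeric column lies in ``[-1, +1]``; a categorical
factor with ``k`` levels contributes ``k - 1`` effects-coded (sum-to-zero)
columns, the last level coded as all ``-1``.  A D-optimal ``n``-run design
maximises ``det(X'X)`` of the model matrix ``X`` over ``n``-run subsets of
the candidate set, searched here by coordinate exchange: each design row in
turn is tentatively swapped against every candidate and the best
determinant-increasing swap is accepted, sweeping until a full pass makes
no change; the best of several random starts is returned.

The determinant ratio of a single row swap (remove ``u``, add ``v``) is
evaluated in O(p^2) per candidate via the rank-two update

    det(M - uu' + vv')/det(M) = (1 - u'M^{-1}u)(1 + v'M^{-1}v)
                                + (u'M^{-1}v)^2,

so a full sweep over all candidates is a handful of small matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import enumerate_configurations
from .design_types import Configuration, DesignSpace
from .errors import (
    DegenerateTermError,
    InfeasibleDesignError,
    SingularDesignError,
)

__all__ = [
    "ModelSpec",
    "ModelMatrix",
    "ReducedDesign",
    "encode_model_matrix",
    "select_d_optimal",
    "d_efficiency",
    "design_table",
]


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the linear screening model.

    ``terms`` is an ordered tuple of ``("intercept",)``, ``("main", factor)``
    and ``("interaction", factor_a, factor_b)`` entries.
    """

    terms: tuple[tuple[str, ...], ...]

    @classmethod
    def main_effects(cls, space: DesignSpace) -> "ModelSpec":
        """Intercept plus one main-effect term per factor (the default)."""
        return cls(
            terms=(("intercept",),)
            + tuple(("main", f.name) for f in space.factors)
        )

    def with_interaction(self, a: str, b: str) -> "ModelSpec":
        return ModelSpec(terms=self.terms + (("interaction", a, b),))

    def p(self, space: DesignSpace) -> int:
        """Total model-matrix column count for this space."""
        return sum(len(cols) for cols in self._column_names(space).values())

    def _column_names(self, space: DesignSpace) -> dict[tuple, list[str]]:
        names: dict[tuple, list[str]] = {}
        for term in self.terms:
            if term[0] == "intercept":
                names[term] = ["intercept"]
            elif term[0] == "main":
                f = space.factor(term[1])
                if f.n_levels < 2:
                    raise DegenerateTermError(
                        f"factor {f.name!r} has a single level; cannot enter the model"
                    )
                if f.kind == "discrete_numeric":
                    names[term] = [f.name]
                else:
                    names[term] = [f"{f.name}[{lev}]" for lev in f.levels[:-1]]
            elif term[0] == "interaction":
                na = self._column_names_for_main(space, term[1])
                nb = self._column_names_for_main(space, term[2])
                names[term] = [f"{a}:{b}" for a in na for b in nb]
            else:
                raise ValueError(f"unknown term {term!r}")
        return names

    def _column_names_for_main(self, space: DesignSpace, name: str) -> list[str]:
        sub = ModelSpec(terms=(("main", name),))
        return sub._column_names(space)[("main", name)]


@dataclass(frozen=True)
class ModelMatrix:
    """A coded model matrix with column labels and per-term column slices."""

    matrix: np.ndarray
    columns: tuple[str, ...]
    term_columns: dict[tuple, np.ndarray]  # term -> column indices

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def _coded_factor_column(space: DesignSpace, name: str,
                         configs: Sequence[Configuration]) -> np.ndarray:
    """Coded columns of one factor's main effect, shape (n, width)."""
    f = space.factor(name)
    levels = [c.assignment[name] for c in configs]
    if f.kind == "discrete_numeric":
        vals = np.asarray([f.value_of(lev) for lev in levels], dtype=float)
        lo, hi = min(f.numeric_values), max(f.numeric_values)
        if hi == lo:
            raise DegenerateTermError(f"factor {name!r} has a single numeric level")
        return (2.0 * (vals - lo) / (hi - lo) - 1.0)[:, None]
    # effects (sum-to-zero) coding: level i < k-1 -> e_i, last level -> -1s
    k = f.n_levels
    idx = np.asarray([f.levels.index(lev) for lev in levels])
    block = np.zeros((len(levels), k - 1))
    in_body = idx < k - 1
    block[np.arange(len(levels))[in_body], idx[in_body]] = 1.0
    block[~in_body, :] = -1.0
    return block


def encode_model_matrix(space: DesignSpace, configs: Sequence[Configuration],
                        model: ModelSpec) -> ModelMatrix:
    """Encode configurations into the coded model matrix for ``model``."""
    blocks: list[np.ndarray] = []
    columns: list[str] = []
    term_columns: dict[tuple, np.ndarray] = {}
    names = model._column_names(space)
    start = 0
    for term in model.terms:
        if term[0] == "intercept":
            block = np.ones((len(configs), 1))
        elif term[0] == "main":
            block = _coded_factor_column(space, term[1], configs)
        else:  # interaction: all pairwise column products
            a = _coded_factor_column(space, term[1], configs)
            b = _coded_factor_column(space, term[2], configs)
            block = (a[:, :, None] * b[:, None, :]).reshape(len(configs), -1)
        blocks.append(block)
        width = block.shape[1]
        term_columns[term] = np.arange(start, start + width)
        columns.extend(names[term])
        start += width
    matrix = np.hstack(blocks) if blocks else np.empty((len(configs), 0))
    return ModelMatrix(matrix=matrix, columns=tuple(columns),
                       term_columns=term_columns)


@dataclass(frozen=True)
class ReducedDesign:
    """An ``n``-run subset of the candidate set with its D diagnostics."""

    run_indices: tuple[int, ...]
    n_runs: int
    candidate_count: int
    log_det: float
    d_efficiency: float
    seed: int
    n_starts: int
    allow_replicates: bool = False

    @property
    def compression_ratio(self) -> float:
        return self.candidate_count / self.n_runs


def d_efficiency(log_det: float, n: int, p: int) -> float:
    """``100 * det(X'X)^(1/p) / n`` — 100 for an orthogonal +/-1 design."""
    if not np.isfinite(log_det):
        raise SingularDesignError("D-efficiency undefined for a singular design")
    return float(100.0 * np.exp(log_det / p) / n)


def _slogdet(M: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(M)
    return val if sign > 0 else -np.inf


def _exchange_once(F: np.ndarray, idx: np.ndarray, allow_replicates: bool,
                   rtol: float, max_passes: int) -> tuple[np.ndarray, float]:
    """Coordinate-exchange sweeps from one starting design. Monotone in det."""
    n = len(idx)
    X = F[idx]
    M = X.T @ X
    logdet = _slogdet(M)
    for _ in range(max_passes):
        improved = False
        for i in range(n):
            try:
                Minv = np.linalg.inv(M)
            except np.linalg.LinAlgError:  # numerically singular: stop here
                return idx, logdet
            u = F[idx[i]]
            A = F @ Minv                       # (N, p)
            d_v = np.einsum("ij,ij->i", A, F)  # v' M^-1 v per candidate
            d_uv = A @ u
            d_u = float(u @ Minv @ u)
            ratio = (1.0 - d_u) * (1.0 + d_v) + d_uv**2
            if not allow_replicates:
                others = np.delete(idx, i)
                ratio[others] = -np.inf
            j = int(np.argmax(ratio))
            if ratio[j] > 1.0 + rtol and j != idx[i]:
                v = F[j]
                M = M - np.outer(u, u) + np.outer(v, v)
                idx[i] = j
                logdet = _slogdet(M)
                improved = True
        if not improved:
            break
    return idx, logdet


def select_d_optimal(space: DesignSpace, model: ModelSpec, n_runs: int,
                     seed: int, n_starts: int = 10, *,
                     allow_replicates: bool = False, rtol: float = 1e-9,
                     max_passes: int = 50) -> ReducedDesign:
    """Search for an ``n_runs`` D-optimal subset of the full factorial.

    Best of ``n_starts`` seeded random starts, each refined by coordinate
    exchange; the accepted-swap sequence never decreases the determinant,
    so the returned design is at least as good as every intermediate one.
    Identical ``(seed, n_starts)`` give identical ``run_indices``.
    """
    configs = enumerate_configurations(space)
    mm = encode_model_matrix(space, configs, model)
    F = np.ascontiguousarray(mm.matrix)
    N, p = F.shape
    if n_runs < p:
        raise InfeasibleDesignError(
            f"n_runs={n_runs} is below the model column count p={p}"
        )
    if not allow_replicates and n_runs > N:
        raise InfeasibleDesignError(
            f"n_runs={n_runs} exceeds the {N} distinct candidates"
        )
    rng = np.random.default_rng(seed)
    best_idx: Optional[np.ndarray] = None
    best_logdet = -np.inf
    for _ in range(n_starts):
        idx = None
        for _attempt in range(100):
            cand = rng.choice(N, size=n_runs, replace=allow_replicates)
            # rank check rejects numerically singular starts that a raw
            # determinant test would let through
            if np.linalg.matrix_rank(F[cand]) == p:
                idx = cand
                break
        if idx is None:
            raise SingularDesignError(
                "no nonsingular starting design found in 100 draws"
            )
        idx, logdet = _exchange_once(F, idx.copy(), allow_replicates, rtol, max_passes)
        if logdet > best_logdet:
            best_logdet = logdet
            best_idx = np.sort(idx)
    assert best_idx is not None
    return ReducedDesign(
        run_indices=tuple(int(i) for i in best_idx),
        n_runs=n_runs,
        candidate_count=N,
        log_det=float(best_logdet),
        d_efficiency=d_efficiency(best_logdet, n_runs, p),
        seed=seed,
        n_starts=n_starts,
        allow_replicates=allow_replicates,
    )


def design_table(space: DesignSpace, design: ReducedDesign) -> pd.DataFrame:
    """Selected runs as a flat factor table.

    Numeric factors are reported as their rank values, categorical factors
    as level labels — the layout DoE software imports directly.
    """
    configs = enumerate_configurations(space)
    rows = []
    for run_idx in design.run_indices:
        c = configs[run_idx]
        row: dict = {"config_index": c.config_index}
        for f in space.factors:
            lev = c.assignment[f.name]
            row[f.name] = f.value_of(lev) if f.kind == "discrete_numeric" else lev
        rows.append(row)
    return pd.DataFrame(rows)
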