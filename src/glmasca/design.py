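"""Sum-coded factorial design matrices and their orthogonality diagnostics.

The effect decomposition analysed by this package relies on two structural
properties of the experiment: *balance* (equal replication in every
factor-level cell) and *saturation* (one model parameter per cell, i.e. all
main effects and interactions included).  Under sum (deviation) coding the
design matrix then splits into mutually orthogonal column blocks — one per
effect — and the weighted hat matrix collapses to (1/R)-scaled identity
blocks, which is what makes the working-response sum of squares decompose
exactly across effects.  This module builds such designs, reports whether a
given design satisfies the preconditions, and computes the hat matrix so the
block structure can be verified numerically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "build_design",
    "factors_from_metadata",
    "check_balanced_saturated",
    "hat_matrix",
]


@dataclass
class FactorSpec:
    """A categorical design factor: declared levels plus per-sample labels."""

    name: str
    levels: list[str]
    assignment: list[str]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"factor {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"factor {self.name!r} has duplicate levels")
        unknown = set(self.assignment) - set(self.levels)
        if unknown:
            raise ValueError(
                f"factor {self.name!r}: sample(s) assigned undeclared level(s) {sorted(unknown)}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def codes(self) -> np.ndarray:
        """Sum-coded columns (n x (K-1)): level k<K gets +1, last level -1."""
        idx = {lv: i for i, lv in enumerate(self.levels)}
        a = np.array([idx[v] for v in self.assignment])
        K = self.n_levels
        C = np.zeros((len(a), K - 1))
        for k in range(K - 1):
            C[a == k, k] = 1.0
        C[a == K - 1, :] = -1.0
        return C


@dataclass
class DesignMatrix:
    """Full-rank coded design partitioned into effect blocks.

    ``blocks`` maps each effect label (``"(intercept)"``, factor names,
    ``"A:B"`` interactions) to its column indices in ``X``.  ``cells`` holds
    each sample's factor-level combination; ``R`` is the common replicate
    count when the design is balanced, else ``None``.
    """

    X: np.ndarray
    blocks: dict[str, np.ndarray]
    factors: list[FactorSpec]
    cells: list[tuple[str, ...]]
    coding: str = "sum"
    R: int | None = field(default=None)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def effect_labels(self) -> list[str]:
        """Effect labels excluding the intercept block."""
        return [k for k in self.blocks if k != "(intercept)"]

    def block(self, label: str) -> np.ndarray:
        """Columns of ``X`` belonging to one effect."""
        return self.X[:, self.blocks[label]]


def _interaction_label(names: tuple[str, ...]) -> str:
    return ":".join(names)


def build_design(factors, interactions="all") -> DesignMatrix:
    """Build a sum-coded design matrix with intercept, mains and interactions.

    Parameters
    ----------
    factors : list of FactorSpec
        Categorical factors with consistent sample counts.
    interactions : {"all", "none"} or list of tuples of factor names
        ``"all"`` adds every interaction of every order (the saturated
        model); an explicit list adds only the named products.

    Interaction columns are elementwise products of the parent factors'
    sum-coded columns, which keeps distinct effect blocks orthogonal under
    balance.
    """
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names in {names}")
    ns = {len(f.assignment) for f in factors}
    if len(ns) != 1:
        raise ValueError("factors assign different numbers of samples")
    n = ns.pop()

    cols = [np.ones((n, 1))]
    blocks: dict[str, np.ndarray] = {"(intercept)": np.array([0])}
    main_codes = {f.name: f.codes() for f in factors}
    start = 1
    for f in factors:
        C = main_codes[f.name]
        blocks[f.name] = np.arange(start, start + C.shape[1])
        cols.append(C)
        start += C.shape[1]

    if interactions == "all":
        combos = [
            c
            for r in range(2, len(factors) + 1)
            for c in itertools.combinations(names, r)
        ]
    elif interactions in ("none", None):
        combos = []
    else:
        combos = [tuple(c) for c in interactions]
        for c in combos:
            if not set(c) <= set(names):
                raise ValueError(f"interaction {c} references unknown factors")
    for combo in combos:
        parts = [main_codes[nm] for nm in combo]
        C = parts[0]
        for P in parts[1:]:
            # all pairwise column products of the parent blocks
            C = (C[:, :, None] * P[:, None, :]).reshape(n, -1)
        label = _interaction_label(combo)
        blocks[label] = np.arange(start, start + C.shape[1])
        cols.append(C)
        start += C.shape[1]

    X = np.hstack(cols)
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(
            f"design matrix is numerically singular (condition number {cond:.2e}); "
            "check for aliased or empty factor-level combinations"
        )
    cells = list(zip(*[f.assignment for f in factors]))
    counts = pd.Series(cells).value_counts()
    R = int(counts.iloc[0]) if counts.nunique() == 1 else None
    return DesignMatrix(X=X, blocks=blocks, factors=list(factors), cells=cells, R=R)


def factors_from_metadata(metadata: pd.DataFrame, factor_cols, level_orders=None):
    """Turn metadata columns into :class:`FactorSpec` objects.

    Levels are ordered lexicographically unless ``level_orders`` supplies an
    explicit order per factor (this affects only which level is coded -1,
    hence coefficient signs, never the effect matrices).
    """
    level_orders = level_orders or {}
    specs = []
    for col in factor_cols:
        if col not in metadata.columns:
            raise KeyError(f"metadata has no column {col!r}")
        values = metadata[col].astype(str).tolist()
        levels = level_orders.get(col) or sorted(set(values))
        specs.append(FactorSpec(name=col, levels=list(map(str, levels)), assignment=values))
    return specs


def check_balanced_saturated(design: DesignMatrix, tol: float = 1e-10) -> dict:
    """Report whether a design meets the orthogonal-decomposition conditions.

    balanced: every possible factor-level combination occurs with the same
    replicate count; saturated: the model has exactly one parameter per cell
    (all interactions present); block_orthogonal: numerically verified
    ``max |Xf' Xg| < tol`` over distinct blocks.
    """
    all_cells = list(
        itertools.product(*[f.levels for f in design.factors])
    )
    counts = pd.Series(design.cells).value_counts()
    observed = {tuple(c) for c in counts.index}
    balanced = observed == set(all_cells) and counts.nunique() == 1
    R = int(counts.iloc[0]) if balanced else None
    saturated = design.m == len(all_cells)
    labels = list(design.blocks)
    max_cross = 0.0
    for a, b in itertools.combinations(labels, 2):
        cross = design.block(a).T @ design.block(b)
        max_cross = max(max_cross, float(np.max(np.abs(cross))))
    return {
        "balanced": bool(balanced),
        "saturated": bool(saturated),
        "block_orthogonal": max_cross < tol,
        "max_block_cross_product": max_cross,
        "R": R,
        "n_cells": len(all_cells),
    }


def hat_matrix(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Weighted hat matrix ``W^(1/2) X (X' W X)^(-1) X' W^(1/2)``.

    For a balanced saturated design with cell-constant weights this is the
    block matrix of ``(1/R) I`` tiles, the structure underpinning the exact
    effect decomposition.  The result is checked to be symmetric and
    idempotent with trace equal to the column count.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float).ravel()
    if np.any(W <= 0):
        raise ValueError("weights must be strictly positive")
    sw = np.sqrt(W)
    Q = X * sw[:, None]
    XtWX = Q.T @ Q
    if np.linalg.cond(XtWX) > 1e12:
        raise np.linalg.LinAlgError("X'WX is singular or near-singular")
    H = Q @ np.linalg.solve(XtWX, Q.T)
    m = X.shape[1]
    assert np.allclose(H, H.T, atol=1e-8), "hat matrix must be symmetric"
    assert np.allclose(H @ H, H, atol=1e-8), "hat matrix must be idempotent"
    assert abs(np.trace(H) - m) < 1e-6, "hat matrix trace must equal rank"
    return H
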