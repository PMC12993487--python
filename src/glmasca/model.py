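"""GLM-ASCA: multivariate effect decomposition of per-feature GLM fits.

The model fits one GLM per feature (column) of a normalized sample-by-feature
table against a shared sum-coded factorial design, then decomposes the matrix
of IRLS *working responses* ``Z = X B + R_w`` into per-effect matrices
``M_f = X_f B_f``.  For balanced, saturated designs the squared Frobenius
norms decompose exactly,

    ||Z||^2 = sum_f ||M_f||^2 + ||R_w||^2,

so each experimental effect owns a well-defined share of the working-response
variance.  Each effect matrix is then analysed by an uncentered PCA (the
intercept matrix plays the role of the grand mean), yielding scores per
sample, loadings per feature, and replicate-level "augmented" scores obtained
by projecting ``M_f + R_w`` onto the effect's loadings.

The public surface follows the statsmodels convention: :class:`GLMASCA` is
the model object, ``fit()`` returns a :class:`GLMASCAResults` carrying the
estimates and diagnostics, and permutation inference hangs off the results
object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, build_design, check_balanced_saturated, factors_from_metadata
from .normalization import filter_features, normalize
from .tweedie import (
    estimate_power_dispersion_multi,
    get_link,
    irls_fit_multi,
)

__all__ = [
    "GLMASCA",
    "GLMASCAResults",
    "EffectMatrix",
    "EffectPCA",
    "fit_multiresponse",
    "effect_matrices",
    "verify_orthogonality",
    "percent_variation",
    "effect_pca",
    "augmented_scores",
    "combine_effects",
]

_FAMILY_RHO = {"gaussian": 0.0, "poisson": 1.0, "gamma": 2.0}


@dataclass
class EffectMatrix:
    """One design effect's share of the working-response matrix."""

    label: str
    M: np.ndarray


@dataclass
class EffectPCA:
    """Uncentered PCA of an effect matrix.

    ``component_variance`` holds each component's share of ``||M||^2``;
    ``augmented_scores`` are the projections of ``M + R_w`` onto the
    loadings, carrying replicate scatter for error bars.
    """

    effect: str
    scores: np.ndarray
    loadings: np.ndarray
    component_variance: np.ndarray
    q: int
    rank: int
    total_ss: float
    augmented_scores: np.ndarray | None = field(default=None)


def effect_pca(M: EffectMatrix | np.ndarray, q="var80", residuals=None) -> EffectPCA:
    """PCA of an effect matrix by SVD without re-centering.

    The intercept effect already removes the grand mean, so no further
    centering is applied.  ``q`` may be an integer, ``"full"`` (the rank) or
    ``"var80"`` (smallest q with cumulative explained variance >= 80%).
    Loadings follow a deterministic sign convention (the largest-magnitude
    loading of each component is positive).
    """
    label = M.label if isinstance(M, EffectMatrix) else "effect"
    A = M.M if isinstance(M, EffectMatrix) else np.asarray(M, dtype=float)
    total = float(np.sum(A**2))
    if total == 0:
        raise ValueError(f"effect matrix {label!r} is identically zero")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(A.shape) * np.finfo(float).eps))
    shares = s**2 / np.sum(s**2)
    q = _resolve_q(q, shares, rank, label)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U[:, :q] * s[:q]
    loadings = Vt[:q].T
    aug = None
    if residuals is not None:
        aug = (A + residuals) @ loadings
    return EffectPCA(
        effect=label,
        scores=scores,
        loadings=loadings,
        component_variance=shares[:q],
        q=q,
        rank=rank,
        total_ss=total,
        augmented_scores=aug,
    )


def _resolve_q(q, shares, rank, label):
    if q == "full":
        return rank
    if isinstance(q, str):
        if not q.startswith("var"):
            raise ValueError(f"unknown q rule {q!r}")
        frac = float(q[3:]) / 100.0
        cum = np.cumsum(shares)
        return int(np.searchsorted(cum, frac - 1e-12) + 1)
    q = int(q)
    if q < 1:
        raise ValueError("q must be >= 1")
    if q > rank:
        warnings.warn(
            f"requested q={q} exceeds rank {rank} of effect {label!r}; clipping",
            RuntimeWarning,
        )
        q = rank
    return q


def augmented_scores(M: EffectMatrix | np.ndarray, residuals, loadings):
    """Project the residual-augmented effect matrix onto effect loadings."""
    A = M.M if isinstance(M, EffectMatrix) else np.asarray(M, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if A.shape != residuals.shape:
        raise ValueError("effect matrix and residuals must share a shape")
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape[0] != A.shape[1]:
        raise ValueError("loadings rows must match the number of features")
    return (A + residuals) @ loadings


def combine_effects(matrices) -> EffectMatrix:
    """Elementwise sum of effect matrices (e.g. a main plus its interaction)."""
    mats = list(matrices)
    shape = mats[0].M.shape
    if any(m.M.shape != shape for m in mats):
        raise ValueError("effect matrices must share a shape to be combined")
    return EffectMatrix(label="+".join(m.label for m in mats), M=sum(m.M for m in mats))


class GLMASCA:
    """Multivariate GLM-ASCA model for a normalized count table.

    Parameters
    ----------
    endog : ndarray or DataFrame, n samples x p features
        Nonnegative (normalized) responses.
    design : DesignMatrix
        Sum-coded factorial design; should be balanced and saturated for the
        exact decomposition (a diagnostic warning is issued otherwise).
    family : {"tweedie", "poisson", "gamma", "gaussian"}
        Shorthand for the Tweedie power parameter: "tweedie" estimates a
        per-feature power on ``rho_grid``; the others fix rho at 1, 2 or 0.
    rho : float, array or None
        Explicit power parameter(s), overriding ``family``.
    link : {"log", "identity"} or link object
    rho_grid : array, optional
        Grid inside (1, 2) for profile-likelihood power estimation.
    drop_nonconverged : bool
        Drop features whose IRLS fit did not converge before decomposition.
    """

    def __init__(
        self,
        endog,
        design: DesignMatrix,
        family: str = "tweedie",
        rho=None,
        link="log",
        rho_grid=None,
        tol: float = 1e-8,
        max_iter: int = 100,
        drop_nonconverged: bool = False,
        offset=None,
    ):
        if offset is not None:
            raise ValueError(
                "offset terms are not supported: an offset breaks the "
                "orthogonal effect decomposition; normalize the counts instead"
            )
        if isinstance(endog, pd.DataFrame):
            self.feature_names = np.asarray(endog.columns.astype(str))
            self.sample_ids = np.asarray(endog.index.astype(str))
            Y = endog.to_numpy(dtype=float)
        else:
            Y = np.asarray(endog, dtype=float)
            self.feature_names = np.array([f"feature_{j}" for j in range(Y.shape[1])])
            self.sample_ids = np.array([f"sample_{i}" for i in range(Y.shape[0])])
        if Y.ndim != 2:
            raise ValueError("endog must be 2-d (samples x features)")
        if np.any(Y < 0) or np.any(~np.isfinite(Y)):
            raise ValueError("endog must be finite and nonnegative")
        if Y.shape[0] != design.n:
            raise ValueError(
                f"endog has {Y.shape[0]} samples but the design describes {design.n}"
            )
        self.endog = Y
        self.design = design
        self.family = family
        if rho is None and family != "tweedie":
            try:
                rho = _FAMILY_RHO[family]
            except KeyError:
                raise ValueError(f"unknown family {family!r}")
        self.rho = rho
        self.link = get_link(link)
        self.rho_grid = rho_grid
        self.tol = tol
        self.max_iter = max_iter
        self.drop_nonconverged = drop_nonconverged
        self.diagnostics = check_balanced_saturated(design)
        if not (self.diagnostics["balanced"] and self.diagnostics["saturated"]):
            warnings.warn(
                "design is not balanced and saturated; the effect decomposition "
                f"is only approximate (diagnostics: {self.diagnostics})",
                UserWarning,
            )

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        factors,
        interactions="all",
        normalization: str = "poscounts",
        level_orders=None,
        filter_kwargs: dict | None = None,
        **kwargs,
    ) -> "GLMASCA":
        """Build a model from raw counts plus sample metadata.

        ``counts`` is samples x features with sample IDs in the index
        matching ``metadata``.  Filtering (optional) and normalization are
        applied here so the model always sees the table it will decompose.
        """
        metadata = metadata.loc[counts.index]
        specs = factors_from_metadata(metadata, factors, level_orders=level_orders)
        design = build_design(specs, interactions=interactions)
        values = counts.to_numpy(dtype=float)
        cols = counts.columns
        if filter_kwargs:
            values, kept = filter_features(values, **filter_kwargs)
            cols = cols[kept]
        norm = normalize(values, method=normalization)
        table = pd.DataFrame(norm.values, index=counts.index, columns=cols)
        model = cls(table, design, **kwargs)
        model.normalization = norm
        return model

    # -- estimation -----------------------------------------------------------

    def _default_mu_floor(self, Y):
        """Detection-limit floor for fitted means: min positive value / R.

        For a balanced design the smallest data-supported cell mean is one
        detection at the feature's minimum positive value averaged over R
        replicates, so flooring there never clips an interior estimate while
        keeping all-zero (boundary) cells on the data's own scale.
        """
        R = self.diagnostics.get("R") or self.design.R
        denom = float(R) if R else 2.0 * Y.shape[0]
        pos_min = np.where(
            np.any(Y > 0, axis=0), np.min(np.where(Y > 0, Y, np.inf), axis=0), 1.0
        )
        return pos_min / denom

    def fit(self) -> "GLMASCAResults":
        """Estimate per-feature GLMs and assemble the working decomposition."""
        Y = self.endog
        all_zero = ~np.any(Y > 0, axis=0)
        if np.any(all_zero):
            warnings.warn(
                f"excluding {int(all_zero.sum())} all-zero feature(s): "
                f"{self.feature_names[all_zero].tolist()[:10]}",
                UserWarning,
            )
            Y = Y[:, ~all_zero]
        feature_names = self.feature_names[~all_zero]
        X = self.design.X

        self.mu_floor = self._default_mu_floor(Y)
        if self.rho is None:  # family == "tweedie": estimate per feature
            rho, phi = estimate_power_dispersion_multi(
                Y, X, rho_grid=self.rho_grid, link=self.link,
                tol=self.tol, max_iter=self.max_iter,
            )
        else:
            rho = np.broadcast_to(np.asarray(self.rho, dtype=float), (Y.shape[1],)).copy()
            phi = None
        fit = irls_fit_multi(
            Y, X, rho, link=self.link, tol=self.tol, max_iter=self.max_iter,
            mu_floor=self.mu_floor,
        )
        if phi is None:
            # Pearson-type moment estimate at the fitted means
            dof = max(Y.shape[0] - X.shape[1], 1)
            phi = np.sum((Y - fit["mu"]) ** 2 / fit["mu"] ** rho, axis=0) / dof
        frac_bad = np.mean(~fit["converged"])
        if frac_bad > 0.2:
            warnings.warn(
                f"{frac_bad:.0%} of feature fits failed to converge; "
                "results may be unreliable",
                UserWarning,
            )
        keep = np.ones(Y.shape[1], dtype=bool)
        if self.drop_nonconverged:
            keep = fit["converged"]
        return GLMASCAResults(
            model=self,
            endog=Y[:, keep],
            feature_names=feature_names[keep],
            B=fit["beta"][:, keep],
            Z=fit["working_response"][:, keep],
            R_w=fit["working_residuals"][:, keep],
            eta=fit["eta"][:, keep],
            mu=fit["mu"][:, keep],
            weights=fit["weights"][:, keep],
            rho=rho[keep],
            phi=phi[keep],
            converged=fit["converged"][keep],
            n_iter=fit["n_iter"][keep],
            deviance=fit["deviance"][keep],
        )


@dataclass
class GLMASCAResults:
    """Fitted GLM-ASCA decomposition.

    Carries the coefficient matrix ``B`` (design columns x features), the
    working responses ``Z``, working residuals ``R_w`` and per-feature
    Tweedie parameters, and exposes the decomposition, explained-variance
    accounting, per-effect PCA and permutation tests.
    """

    model: GLMASCA
    endog: np.ndarray
    feature_names: np.ndarray
    B: np.ndarray
    Z: np.ndarray
    R_w: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    weights: np.ndarray
    rho: np.ndarray
    phi: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray
    deviance: np.ndarray

    # -- decomposition --------------------------------------------------------

    @property
    def design(self) -> DesignMatrix:
        return self.model.design

    def effect_matrix(self, effect) -> EffectMatrix:
        """Effect matrix ``M_f = X_f B_f``; pass a list to combine effects."""
        if isinstance(effect, (list, tuple)):
            return combine_effects([self.effect_matrix(e) for e in effect])
        idx = self.design.blocks[effect]
        return EffectMatrix(label=effect, M=self.design.X[:, idx] @ self.B[idx])

    def effect_matrices(self) -> list[EffectMatrix]:
        """All effect matrices, intercept first."""
        return [self.effect_matrix(lbl) for lbl in self.design.blocks]

    def verify_orthogonality(self, tol: float = 1e-8) -> dict:
        """Numerically check the sum-of-squares decomposition.

        Returns the relative gap
        ``| ||Z||^2 - sum_f ||M_f||^2 - ||R_w||^2 | / ||Z||^2`` plus the raw
        cross inner products between effect matrices and with the residuals.
        A warning is raised when the gap exceeds ``tol`` (expected for
        unbalanced or unsaturated designs).
        """
        mats = self.effect_matrices()
        ss_z = float(np.sum(self.Z**2))
        ss_effects = sum(float(np.sum(m.M**2)) for m in mats)
        ss_resid = float(np.sum(self.R_w**2))
        gap = abs(ss_z - ss_effects - ss_resid) / ss_z
        cross = {}
        for i, a in enumerate(mats):
            for b in mats[i + 1:]:
                cross[(a.label, b.label)] = float(np.sum(a.M * b.M))
            cross[(a.label, "residuals")] = float(np.sum(a.M * self.R_w))
        if gap > tol:
            warnings.warn(
                f"orthogonal decomposition violated: relative gap {gap:.3e} > {tol:g}",
                UserWarning,
            )
        return {"relative_gap": gap, "cross_terms": cross, "tol": tol, "ok": gap <= tol}

    def percent_variation(self) -> pd.DataFrame:
        """Percent of centred working-response variance per effect.

        ``%Var_f = 100 * ||M_f||^2 / (||Z||^2 - ||M_0||^2)``; the residual row
        uses ``||R_w||^2`` with the same denominator, so under exact
        orthogonality the column sums to 100.
        """
        mats = {m.label: m for m in self.effect_matrices()}
        ss_z = float(np.sum(self.Z**2))
        ss_m0 = float(np.sum(mats["(intercept)"].M ** 2))
        denom = ss_z - ss_m0
        if denom <= 0:
            raise ValueError("no variation beyond the intercept effect")
        rows = []
        for lbl in self.design.effect_labels:
            ss = float(np.sum(mats[lbl].M ** 2))
            rows.append({"effect": lbl, "SS": ss, "percent_variation": 100.0 * ss / denom})
        ss_r = float(np.sum(self.R_w**2))
        rows.append(
            {"effect": "residuals", "SS": ss_r, "percent_variation": 100.0 * ss_r / denom}
        )
        return pd.DataFrame(rows).set_index("effect")

    # -- per-effect PCA -------------------------------------------------------

    def pca(self, effect, q="var80") -> EffectPCA:
        """Uncentered PCA of one (or a combined) effect matrix.

        Augmented scores (projections of ``M_f + R_w``) are attached for
        replicate-level visualization.
        """
        M = self.effect_matrix(effect)
        return effect_pca(M, q=q, residuals=self.R_w)

    # -- inference ------------------------------------------------------------

    def permutation_test(
        self,
        effects=None,
        n_permutations: int = 999,
        seed: int = 0,
        q="var80",
        alpha: float = 0.05,
        feature_tests: bool = True,
        reestimate_power: bool = False,
    ):
        """Global and per-feature permutation tests; see
        :func:`glmasca.inference.permutation_tests`."""
        from .inference import permutation_tests

        return permutation_tests(
            self,
            effects=effects,
            n_permutations=n_permutations,
            seed=seed,
            q_rule=q,
            alpha=alpha,
            feature_tests=feature_tests,
            reestimate_power=reestimate_power,
        )

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        """Plain-text overview in the spirit of statsmodels results."""
        diag = self.model.diagnostics
        orth = self.verify_orthogonality()
        pv = self.percent_variation()
        lines = [
            "GLM-ASCA decomposition",
            "=" * 60,
            f"samples: {self.Z.shape[0]}    features: {self.Z.shape[1]}"
            f"    design columns: {self.B.shape[0]}",
            f"family: {self.model.family} (link: {self.model.link.name})",
            f"balanced: {diag['balanced']}  saturated: {diag['saturated']}"
            f"  replicates/cell: {diag['R']}",
            f"converged fits: {int(self.converged.sum())}/{len(self.converged)}",
            f"orthogonality gap (relative): {orth['relative_gap']:.3e}",
            "",
            "Explained variation (% of centred working-response SS)",
            "-" * 60,
        ]
        for lbl, row in pv.iterrows():
            lines.append(f"{lbl:<30s} {row['percent_variation']:10.2f}")
        lines.append("-" * 60)
        lines.append(f"{'total':<30s} {pv['percent_variation'].sum():10.2f}")
        return "\n".join(lines)


# -- functional aliases mirroring the operation-level API ----------------------


def fit_multiresponse(Y, design, **kwargs) -> GLMASCAResults:
    """Fit per-feature GLMs and return the assembled decomposition."""
    return GLMASCA(Y, design, **kwargs).fit()


def effect_matrices(fit: GLMASCAResults):
    return fit.effect_matrices()


def verify_orthogonality(fit: GLMASCAResults, tol: float = 1e-8):
    return fit.verify_orthogonality(tol=tol)


def percent_variation(fit: GLMASCAResults):
    return fit.percent_variation()
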