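"""Permutation inference for GLM-ASCA effects and features.

Two tests share one permutation engine.  The *global* test asks whether a
design effect influences the feature table at all: its statistic is the
squared Frobenius norm of the first-q principal-component scores of the
effect matrix, compared against refits on row-permuted response tables.  The
*feature* test asks which features carry a significant effect: its statistic
is the scaled leverage — the feature's squared loadings on the first q
components weighted by the variances those components explain — with the
same permutation scheme and Benjamini-Hochberg correction across features.
By default the weights are the absolute component variances (so the feature
statistics sum to the global statistic and respond to effect scale);
``leverage_scale="share"`` switches to variance shares, a scale-free variant.

Permuting the rows of the response table while keeping the design fixed
breaks every association between samples and design cells, so both
statistics are recomputed per permutation from a full refit (IRLS per
feature, effect matrices, PCA).  Per-feature Tweedie powers are held at
their observed-data estimates during refits (they are nuisance parameters;
re-estimation per permutation is available but costly).  P-values use the
add-one convention, so the smallest attainable p is exactly
``1/(n_permutations + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .model import GLMASCAResults, _resolve_q
from .tweedie import estimate_power_dispersion_multi, irls_fit_multi

__all__ = [
    "GlobalTestResult",
    "FeatureTestResult",
    "scaled_leverages",
    "bh_adjust",
    "permutation_tests",
    "global_permutation_test",
    "feature_permutation_test",
]


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def scaled_leverages(loadings, component_variance, q=None):
    """Variance-weighted feature leverages on a PCA subspace.

    With ``C = P[:, :q] * sqrt(v_k)`` (loadings scaled by the square roots of
    the components' explained-variance shares), the leverage of feature j is
    ``h_j = sum_k v_k * P_jk^2`` — the diagonal of ``C C'``.  Leverages over
    all features sum to the cumulative variance share of the q components.
    """
    P = np.asarray(loadings, dtype=float)
    v = np.asarray(component_variance, dtype=float)
    if q is None:
        q = P.shape[1]
    if q > P.shape[1]:
        raise ValueError(f"q={q} exceeds the {P.shape[1]} available components")
    return (P[:, :q] ** 2) @ v[:q]


@dataclass
class GlobalTestResult:
    """Global permutation test of one design effect."""

    effect: str
    q: int
    SS_obs: float
    SS_perm: np.ndarray
    p_value: float
    N_p: int
    seed: int

    def __repr__(self) -> str:
        return (
            f"GlobalTestResult(effect={self.effect!r}, q={self.q}, "
            f"SS_obs={self.SS_obs:.4g}, p_value={self.p_value:.4g}, N_p={self.N_p})"
        )


@dataclass
class FeatureTestResult:
    """Scaled-leverage permutation test of every feature for one effect."""

    effect: str
    q: int
    leverage: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    alpha: float
    N_p: int
    seed: int
    feature_names: np.ndarray | None = field(default=None)

    def to_frame(self):
        import pandas as pd

        idx = (
            self.feature_names
            if self.feature_names is not None
            else np.arange(len(self.leverage))
        )
        return pd.DataFrame(
            {
                "leverage": self.leverage,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "significant": self.significant,
            },
            index=idx,
        )


def _effect_columns(design, effect):
    """Column indices for an effect label or a combination of labels."""
    if isinstance(effect, (list, tuple)):
        return np.concatenate([design.blocks[e] for e in effect])
    return design.blocks[effect]


def _effect_label(effect):
    return "+".join(effect) if isinstance(effect, (list, tuple)) else effect


def _svd_stats(M, q, leverage_scale="absolute"):
    """(top-q score SS, scaled leverages) of one effect matrix."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s2 = s**2
    qq = min(q, len(s))
    ss = float(s2[:qq].sum())
    if leverage_scale == "absolute":
        w = s2[:qq]
    else:  # "share"
        total = s2.sum()
        w = s2[:qq] / total if total > 0 else s2[:qq]
    h = (Vt[:qq] ** 2 * w[:, None]).sum(axis=0)
    return ss, h


def permutation_tests(
    results: GLMASCAResults,
    effects=None,
    n_permutations: int = 999,
    seed: int = 0,
    q_rule="var80",
    alpha: float = 0.05,
    feature_tests: bool = True,
    reestimate_power: bool = False,
    leverage_scale: str = "absolute",
):
    """Joint global and feature permutation tests for several effects.

    One shared set of row permutations of the (normalized) response table
    drives every requested effect, so a single refit per permutation serves
    all tests.  ``effects`` may contain effect labels and/or tuples of labels
    (tested as the summed, combined effect matrix).  Per-permutation RNG
    streams are spawned from the master seed, so results do not depend on
    execution order.

    Returns ``(global_results, feature_results)`` dicts keyed by effect
    label; ``feature_results`` is empty when ``feature_tests=False``.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations for meaningful p-values")
    design = results.design
    if effects is None:
        effects = list(design.effect_labels)
    for eff in effects:
        for lbl in eff if isinstance(eff, (list, tuple)) else [eff]:
            if lbl not in design.blocks:
                raise KeyError(f"unknown effect label {lbl!r}")

    X = design.X
    Y = results.endog
    n, p = Y.shape
    rho = results.rho

    # observed statistics, with q fixed by the observed-data PCA
    obs = {}
    for eff in effects:
        label = _effect_label(eff)
        cols = _effect_columns(design, eff)
        M = X[:, cols] @ results.B[cols]
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        s2 = s**2
        shares = s2 / s2.sum()
        rank = int(np.sum(s > s[0] * max(M.shape) * np.finfo(float).eps))
        q = _resolve_q(q_rule, shares, rank, label)
        ss_obs, h_obs = _svd_stats(M, q, leverage_scale)
        obs[label] = {
            "cols": cols,
            "q": q,
            "ss": ss_obs,
            "h": h_obs,
            "ge_ss": 0,
            "ge_h": np.zeros(p, dtype=int),
        }

    children = np.random.SeedSequence(seed).spawn(n_permutations)
    ss_perm = {lbl: np.empty(n_permutations) for lbl in obs}
    for k, child in enumerate(children):
        perm = np.random.default_rng(child).permutation(n)
        Yk = Y[perm]
        if reestimate_power:
            rho_k, _ = estimate_power_dispersion_multi(Yk, X, link=results.model.link)
        else:
            rho_k = rho
        fit = irls_fit_multi(
            Yk, X, rho_k, link=results.model.link,
            tol=results.model.tol, max_iter=results.model.max_iter,
            mu_floor=getattr(results.model, "mu_floor", None),
        )
        B = fit["beta"]
        for label, st in obs.items():
            M = X[:, st["cols"]] @ B[st["cols"]]
            ss_k, h_k = _svd_stats(M, st["q"], leverage_scale)
            ss_perm[label][k] = ss_k
            st["ge_ss"] += ss_k >= st["ss"]
            if feature_tests:
                st["ge_h"] += h_k >= st["h"]

    global_results = {}
    feature_results = {}
    for label, st in obs.items():
        pval = (st["ge_ss"] + 1) / (n_permutations + 1)
        global_results[label] = GlobalTestResult(
            effect=label,
            q=st["q"],
            SS_obs=st["ss"],
            SS_perm=ss_perm[label],
            p_value=pval,
            N_p=n_permutations,
            seed=seed,
        )
        if feature_tests:
            p_raw = (st["ge_h"] + 1) / (n_permutations + 1)
            p_adj = bh_adjust(p_raw)
            feature_results[label] = FeatureTestResult(
                effect=label,
                q=st["q"],
                leverage=st["h"],
                p_raw=p_raw,
                p_adj=p_adj,
                significant=p_adj < alpha,
                alpha=alpha,
                N_p=n_permutations,
                seed=seed,
                feature_names=results.feature_names,
            )
    return global_results, feature_results


def global_permutation_test(
    results: GLMASCAResults, effect, n_permutations=999, seed=0, q_rule="var80"
) -> GlobalTestResult:
    """Convenience wrapper: global test of a single effect."""
    g, _ = permutation_tests(
        results,
        effects=[effect],
        n_permutations=n_permutations,
        seed=seed,
        q_rule=q_rule,
        feature_tests=False,
    )
    return g[_effect_label(effect)]


def feature_permutation_test(
    results: GLMASCAResults,
    effect,
    n_permutations=999,
    seed=0,
    q_rule="var80",
    alpha=0.05,
) -> FeatureTestResult:
    """Convenience wrapper: scaled-leverage feature test of a single effect."""
    _, f = permutation_tests(
        results,
        effects=[effect],
        n_permutations=n_permutations,
        seed=seed,
        q_rule=q_rule,
        alpha=alpha,
    )
    return f[_effect_label(effect)]
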