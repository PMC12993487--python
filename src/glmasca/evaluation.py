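"""Performance metrics and the replicated simulation-study driver.

The study driver generates spike-in datasets, runs the full analysis
pipeline (filter, normalize, per-feature Tweedie fits, effect decomposition,
scaled-leverage permutation feature tests with BH correction) and scores the
calls against the generator's ground truth per effect: false discovery rate,
sensitivity, specificity, F1, Matthews correlation and a rank-based AUC
(using one minus the raw permutation p-value as the ranking score).
Features removed by abundance filtering are counted as non-calls, so a
spiked taxon lost to filtering shows up as a false negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import GLMASCA
from .normalization import filter_features, normalize
from .simulate import EFFECT_CLASSES, generate_dataset

__all__ = [
    "confusion_metrics",
    "auc_score",
    "StudyConfig",
    "analyze_dataset",
    "run_simulation_study",
]


def confusion_metrics(calls, truth) -> dict:
    """Confusion-matrix metrics for boolean calls against boolean truth.

    The FDR of an empty call set is 0 by convention; F1 and MCC fall back to
    0 when undefined.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fn = int(np.sum(~calls & truth))
    tn = int(np.sum(~calls & ~truth))
    fdr = fp / max(tp + fp, 1)
    sens = tp / (tp + fn) if tp + fn > 0 else np.nan
    spec = tn / (tn + fp) if tn + fp > 0 else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "FDR": fdr, "sensitivity": sens, "specificity": spec,
        "F1": f1, "MCC": mcc,
    }


def auc_score(scores, truth) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUC needs both classes present in the truth labels")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


@dataclass
class StudyConfig:
    """Configuration of a replicated spike-in evaluation study."""

    n_list: tuple = (40,)
    n_datasets: int = 20
    n_permutations: int = 999
    seed: int = 1
    normalization: str = "poscounts"
    alpha: float = 0.05
    min_count: int = 10
    min_samples: int = 5
    q_rule: str | int = "var80"
    rho_grid: np.ndarray | None = field(default=None)
    p: int = 206

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "n_list" in d:
            d["n_list"] = tuple(d["n_list"])
        return cls(**d)


def analyze_dataset(
    dataset,
    n_permutations: int = 999,
    perm_seed: int = 0,
    normalization: str = "poscounts",
    alpha: float = 0.05,
    min_count: int = 10,
    min_samples: int = 5,
    q_rule="var80",
    rho_grid=None,
):
    """Run the full pipeline on one simulated dataset and score it.

    Returns ``(rows, detail)`` where ``rows`` is a list of per-effect metric
    dicts and ``detail`` holds the fitted results and test objects.
    """
    counts = dataset.counts.to_numpy()
    p_total = counts.shape[1]
    filtered, kept = filter_features(
        counts, min_count=min_count, min_samples=min_samples, mode="global"
    )
    norm = normalize(filtered, method=normalization)
    model = GLMASCA(norm.values, dataset.design, family="tweedie", rho_grid=rho_grid)
    res = model.fit()
    effects = {
        "condition": "condition",
        "time": "time",
        "interaction": "condition:time",
    }
    gtests, ftests = res.permutation_test(
        effects=list(effects.values()),
        n_permutations=n_permutations,
        seed=perm_seed,
        q=q_rule,
        alpha=alpha,
    )
    rows = []
    for cls, label in effects.items():
        ft = ftests[label]
        calls = np.zeros(p_total, dtype=bool)
        calls[kept] = ft.significant
        scores = np.zeros(p_total)
        scores[kept] = 1.0 - ft.p_raw
        truth = dataset.truth[cls].to_numpy()
        row = confusion_metrics(calls, truth)
        row["AUC"] = auc_score(scores, truth)
        row["effect"] = cls
        row["global_p"] = gtests[label].p_value
        row["n_kept"] = len(kept)
        rows.append(row)
    return rows, {"results": res, "global": gtests, "feature": ftests, "kept": kept}


def run_simulation_study(config: StudyConfig | dict | None = None, **overrides):
    """Replicated spike-in study; returns (per-dataset table, summary table).

    For every sample size in ``config.n_list`` (replicates = n/8 in the
    2 x 4 factorial), ``n_datasets`` datasets are generated, analysed and
    scored per effect.  Dataset and permutation seeds are derived
    deterministically from the master seed, so the output is reproducible.
    Per-dataset failures are logged and skipped rather than aborting the
    study.
    """
    if config is None:
        config = StudyConfig()
    elif isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    if overrides:
        config = StudyConfig(**{**config.__dict__, **overrides})
    master = np.random.default_rng(config.seed)
    rows = []
    for n in config.n_list:
        if n % 8 != 0:
            raise ValueError(f"sample size {n} is not a multiple of the 8 design cells")
        for rep in range(config.n_datasets):
            data_seed = int(master.integers(2**31))
            perm_seed = int(master.integers(2**31))
            try:
                ds = generate_dataset(
                    seed=data_seed, replicates=n // 8, p=config.p
                )
                metric_rows, _ = analyze_dataset(
                    ds,
                    n_permutations=config.n_permutations,
                    perm_seed=perm_seed,
                    normalization=config.normalization,
                    alpha=config.alpha,
                    min_count=config.min_count,
                    min_samples=config.min_samples,
                    q_rule=config.q_rule,
                    rho_grid=config.rho_grid,
                )
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(
                    f"dataset n={n} replicate={rep} failed and was skipped: {exc}",
                    RuntimeWarning,
                )
                continue
            for row in metric_rows:
                row.update({"n": n, "replicate": rep, "seed": data_seed})
                rows.append(row)
    results = pd.DataFrame(rows)
    metrics = ["FDR", "sensitivity", "specificity", "F1", "MCC", "AUC"]
    per_effect = results.groupby(["n", "effect"])[metrics].agg(["mean", "sem"])
    pooled = results.groupby("n")[metrics].agg(["mean", "sem"])
    pooled.index = pd.MultiIndex.from_product([pooled.index, ["pooled"]], names=["n", "effect"])
    summary = pd.concat([per_effect, pooled]).sort_index()
    return results, summary
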