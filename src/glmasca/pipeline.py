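"""End-to-end analysis pipeline: from count/metadata files to result tables.

``run_pipeline`` wires the full workflow together: abundance filtering,
normalization, per-feature Tweedie GLM fits, effect decomposition with an
orthogonality check, explained-variance accounting, per-effect PCA (with
optional combined effects such as a main effect plus its interaction) and
permutation tests, writing every result as TSV plus a YAML run log carrying
the seed and configuration for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_count_table, read_metadata, write_table
from .model import GLMASCA

__all__ = ["RunConfig", "run_pipeline", "parse_effect"]


@dataclass
class RunConfig:
    """Settings of one pipeline run (file paths, model, test parameters)."""

    counts: str
    metadata: str
    factors: list
    interactions: str = "all"
    level_orders: dict | None = field(default=None)
    orientation: str = "samples_rows"
    family: str = "tweedie"
    link: str = "log"
    normalization: str = "poscounts"
    filter_min_count: int | None = field(default=None)
    filter_min_samples: int | None = field(default=None)
    filter_mode: str = "global"
    q_rule: str = "var80"
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    effects: list | None = field(default=None)
    out_dir: str = "glmasca_results"
    force: bool = False

    def __post_init__(self):
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def parse_effect(spec: str):
    """Parse an effect spec: ``"condition"`` or ``"condition+condition:time"``."""
    parts = [s.strip() for s in spec.split("+")]
    return parts[0] if len(parts) == 1 else tuple(parts)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all outputs under ``out_dir``."""
    counts = read_count_table(config.counts, orientation=config.orientation)
    metadata = read_metadata(config.metadata)
    missing = counts.index.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")

    filter_kwargs = None
    if config.filter_min_count is not None:
        filter_kwargs = {
            "min_count": config.filter_min_count,
            "min_samples": config.filter_min_samples,
            "mode": config.filter_mode,
        }
        if config.filter_mode == "per_group_all":
            cells = metadata.loc[counts.index, config.factors].astype(str).agg("|".join, axis=1)
            filter_kwargs["groups"] = cells.to_numpy()

    model = GLMASCA.from_dataframes(
        counts,
        metadata,
        config.factors,
        interactions=config.interactions,
        normalization=config.normalization,
        level_orders=config.level_orders,
        filter_kwargs=filter_kwargs,
        family=config.family,
        link=config.link,
    )
    diag = model.diagnostics
    if not (diag["balanced"] and diag["saturated"]) and not config.force:
        raise ValueError(
            "the design is not balanced and saturated, so the effect "
            f"decomposition would not be exact (diagnostics: {diag}); "
            "rerun with force=True to proceed anyway"
        )
    results = model.fit()
    orth = results.verify_orthogonality()
    pvar = results.percent_variation()

    effects = config.effects or list(model.design.effect_labels)
    effects = [parse_effect(e) if isinstance(e, str) else tuple(e) for e in effects]
    gtests, ftests = results.permutation_test(
        effects=effects,
        n_permutations=config.n_permutations,
        seed=config.seed,
        q=config.q_rule,
        alpha=config.alpha,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(pvar, out / "percent_variation.tsv", index_label="effect")
    gdf = pd.DataFrame(
        [
            {"effect": g.effect, "q": g.q, "SS_obs": g.SS_obs, "p_value": g.p_value,
             "n_permutations": g.N_p}
            for g in gtests.values()
        ]
    ).set_index("effect")
    write_table(gdf, out / "global_tests.tsv", index_label="effect")
    pcas = {}
    for eff in effects:
        label = "+".join(eff) if isinstance(eff, tuple) else eff
        safe = label.replace(":", "x").replace("+", "_plus_")
        write_table(
            ftests[label].to_frame(), out / f"feature_tests_{safe}.tsv",
            index_label="feature",
        )
        pca = results.pca(list(eff) if isinstance(eff, tuple) else eff, q=config.q_rule)
        pcas[label] = pca
        comp = [f"PC{k + 1}" for k in range(pca.q)]
        write_table(
            pd.DataFrame(pca.scores, index=results.model.sample_ids, columns=comp),
            out / f"scores_{safe}.tsv", index_label="sample",
        )
        write_table(
            pd.DataFrame(pca.augmented_scores, index=results.model.sample_ids, columns=comp),
            out / f"augmented_scores_{safe}.tsv", index_label="sample",
        )
        write_table(
            pd.DataFrame(pca.loadings, index=results.feature_names, columns=comp),
            out / f"loadings_{safe}.tsv", index_label="feature",
        )

    cfg = asdict(config)
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    log = {
        "glmasca_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": cfg_hash,
        "n_samples": int(results.Z.shape[0]),
        "n_features": int(results.Z.shape[1]),
        "balanced": diag["balanced"],
        "saturated": diag["saturated"],
        "orthogonality_relative_gap": float(orth["relative_gap"]),
        "n_converged": int(results.converged.sum()),
        "n_nonconverged": int((~results.converged).sum()),
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return {
        "results": results,
        "percent_variation": pvar,
        "global_tests": gtests,
        "feature_tests": ftests,
        "pca": pcas,
        "orthogonality": orth,
        "log": log,
        "out_dir": out,
    }
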