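"""Zero-inflated spike-in simulator for factorial microbiome experiments.

Each taxon j is described by three null parameters: the probability of a
structural zero ``pi_j``, and the mean ``mu_log_j`` and variance
``sigma2_log_j`` of its log abundance when present.  Counts are drawn from a
zero-inflated truncated log-normal: with probability ``pi_j`` the entry is
zero, otherwise ``round(exp(Normal(mu_ij, sigma2_j)))`` truncated below at 1
(so every realized nonzero value looks like a detected count).

Differential taxa ("spikes") shift the per-sample mean log abundance
additively through the sum-coded design covariates::

    mu_ij = mu_log_j + b1*x1_i           (condition)
                     + b2*x2_i + b3*x3_i + b4*x4_i   (time)
                     + b5*x5_i + b6*x6_i + b7*x7_i   (condition x time)

The default configuration emulates a two-condition x four-timepoint
factorial with 5 replicates per cell (n = 40): 206 taxa of which 45 are
spiked — 20 on the condition effect, 15 on time, 10 on the interaction —
with effect sizes (2, 3, 1.5, 1.5, 2.8, 2.4, 1.4), positive for half of the
spiked taxa in each class and negated for the other half.  Spiked taxa are
drawn from taxa with prevalence of at least 20%.  Null parameters default to
values typical of filtered 16S surveys; they can instead be estimated from a
template table by method of moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorSpec, build_design

__all__ = [
    "TaxonParams",
    "SpikeConfig",
    "SimulatedDataset",
    "default_design",
    "default_taxon_params",
    "estimate_null_params",
    "default_spike_config",
    "spike_in_means",
    "generate_dataset",
    "DEFAULT_EFFECT_SIZES",
]

#: (b1; b2, b3, b4; b5, b6, b7) for condition, time and interaction spikes
DEFAULT_EFFECT_SIZES = np.array([2.0, 3.0, 1.5, 1.5, 2.8, 2.4, 1.4])

EFFECT_CLASSES = ("condition", "time", "interaction")


@dataclass
class TaxonParams:
    """Per-taxon null parameters of the zero-inflated log-normal."""

    mu_log: np.ndarray
    sigma2_log: np.ndarray
    pi_zero: np.ndarray

    def __post_init__(self):
        self.mu_log = np.asarray(self.mu_log, dtype=float)
        self.sigma2_log = np.asarray(self.sigma2_log, dtype=float)
        self.pi_zero = np.asarray(self.pi_zero, dtype=float)
        if np.any((self.pi_zero < 0) | (self.pi_zero > 1)):
            raise ValueError("pi_zero must lie in [0, 1]")
        usable = self.pi_zero < 1
        if np.any(self.sigma2_log[usable & np.isfinite(self.sigma2_log)] <= 0):
            raise ValueError("sigma2_log must be positive for taxa with pi_zero < 1")

    @property
    def p(self) -> int:
        return len(self.mu_log)


@dataclass
class SpikeConfig:
    """Assignment of taxa to effect classes plus their signed effect sizes.

    ``assignment[j]`` is one of "null", "condition", "time", "interaction";
    ``betas`` is a p x 7 matrix of signed effect sizes (rows of zeros for
    null taxa); ``covariates`` the n x 7 sum-coded design columns
    (condition, 3 x time, 3 x interaction).
    """

    assignment: np.ndarray
    betas: np.ndarray
    covariates: np.ndarray

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=object)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(self.assignment), 7):
            raise ValueError("betas must be p x 7")
        if self.covariates.shape[1] != 7:
            raise ValueError("covariates must be n x 7")
        spiked = self.assignment != "null"
        if np.any(np.all(self.betas[spiked] == 0, axis=1)):
            raise ValueError("spiked taxa must carry nonzero effect sizes")

    def truth_frame(self) -> pd.DataFrame:
        """Boolean truth labels per effect class plus the class name."""
        df = pd.DataFrame({"class": self.assignment})
        for cls in EFFECT_CLASSES:
            df[cls] = self.assignment == cls
        return df


@dataclass
class SimulatedDataset:
    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    design: DesignMatrix
    params: TaxonParams
    spike: SpikeConfig
    seed: int


def default_design(replicates: int = 5) -> DesignMatrix:
    """Two conditions x four timepoints, fully crossed with ``replicates``."""
    conds, times = ["control", "starved"], ["d04", "d08", "d12", "d16"]
    cond_assign, time_assign = [], []
    for c in conds:
        for t in times:
            cond_assign += [c] * replicates
            time_assign += [t] * replicates
    factors = [
        FactorSpec("condition", conds, cond_assign),
        FactorSpec("time", times, time_assign),
    ]
    return build_design(factors, interactions="all")


def default_taxon_params(p: int = 206, rng=None) -> TaxonParams:
    """Null parameters typical of a filtered 16S count table.

    Mean log abundances around ``exp(3.5) ~ 33`` counts with a spread of one
    log unit, per-taxon log standard deviations between 0.5 and 1.5, and
    zero fractions between 5% and 60%.
    """
    rng = np.random.default_rng(rng)
    return TaxonParams(
        mu_log=rng.normal(3.5, 1.0, size=p),
        sigma2_log=rng.uniform(0.5, 1.5, size=p) ** 2,
        pi_zero=rng.uniform(0.05, 0.60, size=p),
    )


def estimate_null_params(template) -> TaxonParams:
    """Method-of-moments null parameters from a template count table.

    ``pi_j`` is the zero fraction; ``mu_log_j`` and ``sigma2_log_j`` the mean
    and variance of the log of the positive entries.  Taxa with fewer than
    two positive entries get NaN log-moments (flagged unusable).
    """
    Y = np.asarray(template, dtype=float)
    if Y.size == 0:
        raise ValueError("template table is empty")
    if np.any(Y < 0):
        raise ValueError("template counts must be nonnegative")
    n = Y.shape[0]
    npos = (Y > 0).sum(axis=0)
    pi = 1.0 - npos / n
    logs = np.where(Y > 0, np.log(np.where(Y > 0, Y, 1.0)), np.nan)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(logs, axis=0)
        s2 = np.nanvar(logs, axis=0, ddof=1)
    mu[npos < 2] = np.nan
    s2[npos < 2] = np.nan
    return TaxonParams(mu_log=mu, sigma2_log=s2, pi_zero=pi)


def _spike_covariates(design: DesignMatrix) -> np.ndarray:
    cols = np.concatenate(
        [design.blocks["condition"], design.blocks["time"], design.blocks["condition:time"]]
    )
    return design.X[:, cols]


def default_spike_config(
    params: TaxonParams,
    design: DesignMatrix,
    rng=None,
    n_condition: int = 20,
    n_time: int = 15,
    n_interaction: int = 10,
    effect_sizes=DEFAULT_EFFECT_SIZES,
    min_prevalence: float = 0.20,
) -> SpikeConfig:
    """Assign spiked taxa and signed effect sizes for the default design.

    Eligible taxa have prevalence (nonzero fraction) of at least
    ``min_prevalence``; spiked taxa are drawn among them without
    replacement.  Within each effect class, half of the taxa take the
    positive effect sizes and half the negated ones (the extra taxon of an
    odd class is positive).
    """
    rng = np.random.default_rng(rng)
    effect_sizes = np.asarray(effect_sizes, dtype=float)
    if effect_sizes.shape != (7,):
        raise ValueError("effect_sizes must have length 7")
    p = params.p
    n_spiked = n_condition + n_time + n_interaction
    eligible = np.where(1.0 - params.pi_zero >= min_prevalence)[0]
    if len(eligible) < n_spiked:
        raise ValueError(
            f"only {len(eligible)} taxa reach prevalence {min_prevalence:.0%}; "
            f"{n_spiked} spikes requested"
        )
    chosen = rng.choice(eligible, size=n_spiked, replace=False)
    assignment = np.array(["null"] * p, dtype=object)
    betas = np.zeros((p, 7))
    slices = {
        "condition": (chosen[:n_condition], [0]),
        "time": (chosen[n_condition:n_condition + n_time], [1, 2, 3]),
        "interaction": (chosen[n_condition + n_time:], [4, 5, 6]),
    }
    for cls, (idx, cols) in slices.items():
        assignment[idx] = cls
        half = (len(idx) + 1) // 2
        for rank, j in enumerate(idx):
            sign = 1.0 if rank < half else -1.0
            betas[j, cols] = sign * effect_sizes[cols]
    return SpikeConfig(
        assignment=assignment, betas=betas, covariates=_spike_covariates(design)
    )


def spike_in_means(params: TaxonParams, spike: SpikeConfig, design: DesignMatrix):
    """Per-sample mean log abundances ``mu_ij`` (n x p)."""
    cov = spike.covariates
    if cov.shape[0] != design.n:
        raise ValueError("spike covariates do not match the design's sample count")
    return params.mu_log[None, :] + cov @ spike.betas.T


def generate_dataset(
    params: TaxonParams | None = None,
    spike: SpikeConfig | None = None,
    design: DesignMatrix | None = None,
    seed: int = 0,
    replicates: int = 5,
    p: int = 206,
) -> SimulatedDataset:
    """Draw one zero-inflated spike-in dataset with ground-truth labels.

    With all of ``params``/``spike``/``design`` omitted this reproduces the
    default study configuration (n = 8 * replicates samples, 206 taxa, 45
    spiked as 20/15/10).  The same seed yields a bit-identical dataset.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = default_design(replicates=replicates)
    if params is None:
        params = default_taxon_params(p=p, rng=rng)
    if spike is None:
        spike = default_spike_config(params, design, rng=rng)
    n = design.n
    mu = spike_in_means(params, spike, design)
    nonzero = rng.random((n, params.p)) >= params.pi_zero[None, :]
    draws = rng.normal(mu, np.sqrt(params.sigma2_log)[None, :])
    counts = np.where(nonzero, np.maximum(np.rint(np.exp(draws)), 1.0), 0.0)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    feat_ids = [f"taxon_{j + 1:04d}" for j in range(params.p)]
    meta = pd.DataFrame(
        {f.name: f.assignment for f in design.factors}, index=sample_ids
    )
    truth = spike.truth_frame()
    truth.index = pd.Index(feat_ids)
    return SimulatedDataset(
        counts=pd.DataFrame(counts, index=sample_ids, columns=feat_ids),
        metadata=meta,
        truth=truth,
        design=design,
        params=params,
        spike=spike,
        seed=seed,
    )
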