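"""Library-size normalization and abundance filtering for count tables.

Two normalizations tolerant of zero inflation are provided:

* **poscounts** — median-of-ratios size factors where each feature's
  reference is the geometric mean of its *positive* counts (zeros excluded
  from the log sum but the sample count kept in the denominator).  Division
  by the size factor leaves zeros at zero and removes sequencing-depth
  differences.
* **mCLR** — a modified centered log-ratio transform: each sample's nonzero
  entries are log-transformed and centred by the mean log of that sample's
  nonzero entries; zeros are left untouched, and one global positive shift
  makes all transformed nonzero values strictly positive so a Tweedie model
  (support on {0} and the positive reals) still applies.

Neither output is rounded: the compound Poisson-gamma family supports
continuous positive data with exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormalizedTable",
    "poscounts_size_factors",
    "mclr_transform",
    "filter_features",
    "normalize",
]


@dataclass
class NormalizedTable:
    values: np.ndarray
    method: str
    size_factors: np.ndarray | None = field(default=None)
    shift: float | None = field(default=None)


def poscounts_size_factors(counts):
    """Size factors from geometric means over positive counts.

    Per feature j the reference is ``g_j = exp(sum_{i: y_ij>0} log y_ij / n)``;
    a sample's size factor is the median of ``y_ij / g_j`` over the features
    where both the count and the reference are positive, rescaled so the size
    factors have geometric mean 1.  Returns ``(size_factors, normalized)``.
    """
    Y = np.asarray(counts, dtype=float)
    if np.any(Y < 0):
        raise ValueError("counts must be nonnegative")
    n, p = Y.shape
    if np.any(~np.any(Y > 0, axis=1)):
        bad = np.where(~np.any(Y > 0, axis=1))[0].tolist()
        raise ValueError(f"sample(s) {bad} contain only zeros")
    with np.errstate(divide="ignore"):
        logY = np.where(Y > 0, np.log(np.where(Y > 0, Y, 1.0)), 0.0)
    log_g = logY.sum(axis=0) / n  # zeros contribute 0 to the sum
    has_pos = np.any(Y > 0, axis=0)
    if not np.any(has_pos):
        raise ValueError("no feature has a positive geometric mean")
    s = np.empty(n)
    for i in range(n):
        use = has_pos & (Y[i] > 0)
        if not np.any(use):
            raise ValueError(f"sample {i} shares no positive feature with the reference")
        s[i] = np.exp(np.median(logY[i, use] - log_g[use]))
    s /= np.exp(np.mean(np.log(s)))  # geometric mean 1 for identifiability
    return s, Y / s[:, None]


def mclr_transform(counts, eps: float = 1.0) -> NormalizedTable:
    """Modified centered log-ratio transform preserving zeros.

    Nonzero entries become ``log(y) - mean(log of the sample's nonzero
    entries)``; zeros stay exactly zero; a single global shift of
    ``|min transformed nonzero| + eps`` is then added to all nonzero entries
    so every transformed nonzero value is strictly positive.
    """
    Y = np.asarray(counts, dtype=float)
    if np.any(Y < 0):
        raise ValueError("counts must be nonnegative")
    npos = (Y > 0).sum(axis=1)
    if np.any(npos < 2):
        bad = np.where(npos < 2)[0].tolist()
        raise ValueError(f"sample(s) {bad} have fewer than 2 positive counts")
    out = np.zeros_like(Y)
    pos = Y > 0
    logY = np.where(pos, np.log(np.where(pos, Y, 1.0)), 0.0)
    center = logY.sum(axis=1) / npos
    out[pos] = (logY - center[:, None])[pos]
    shift = float(np.abs(out[pos].min()) + eps)
    out[pos] += shift
    return NormalizedTable(values=out, method="mclr", shift=shift)


def normalize(counts, method: str = "poscounts", eps: float = 1.0) -> NormalizedTable:
    """Dispatch on the normalization method ("poscounts", "mclr", "none")."""
    if method == "poscounts":
        s, vals = poscounts_size_factors(counts)
        return NormalizedTable(values=vals, method="poscounts", size_factors=s)
    if method == "mclr":
        return mclr_transform(counts, eps=eps)
    if method in ("none", None):
        return NormalizedTable(values=np.asarray(counts, dtype=float), method="none")
    raise ValueError(f"unknown normalization method {method!r}")


def filter_features(counts, min_count: int, min_samples: int, groups=None, mode: str = "global"):
    """Keep features with enough well-supported samples.

    global mode keeps feature j when at least ``min_samples`` samples have
    ``y_ij >= min_count``; per_group_all requires that criterion inside every
    group (e.g. every factor-level cell).  Returns ``(filtered, kept_idx)``.
    """
    Y = np.asarray(counts, dtype=float)
    if min_count < 1 or min_samples < 1:
        raise ValueError("thresholds must be >= 1")
    hits = Y >= min_count
    if mode == "global":
        keep = hits.sum(axis=0) >= min_samples
    elif mode == "per_group_all":
        if groups is None:
            raise ValueError("per_group_all filtering needs group labels")
        groups = np.asarray(groups)
        keep = np.ones(Y.shape[1], dtype=bool)
        for g in np.unique(groups):
            keep &= hits[groups == g].sum(axis=0) >= min_samples
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    kept_idx = np.where(keep)[0]
    return Y[:, keep], kept_idx
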