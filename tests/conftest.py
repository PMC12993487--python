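import numpy as np
import pytest

from glmasca.design import FactorSpec, build_design
from glmasca.tweedie import tweedie_rvs


def random_balanced_design(rng, max_factors=2, max_levels=3, max_reps=3):
    """A random fully-crossed sum-coded design with all interactions."""
    n_factors = rng.integers(1, max_factors + 1)
    specs = []
    for f in range(n_factors):
        K = int(rng.integers(2, max_levels + 1))
        specs.append((f"F{f}", [f"l{k}" for k in range(K)]))
    R = int(rng.integers(1, max_reps + 1))
    cells = [[]]
    for _, levels in specs:
        cells = [c + [lv] for c in cells for lv in levels]
    factors = []
    for i, (name, levels) in enumerate(specs):
        assign = [c[i] for c in cells for _ in range(R)]
        factors.append(FactorSpec(name, levels, assign))
    return build_design(factors, interactions="all")


def positive_tweedie_table(design, rng, p=6, rho=1.5, phi=0.3, base=20.0):
    """Response table with interior MLEs: every cell keeps positive data.

    Cell means are drawn well away from zero and entries resampled until
    each feature has a positive value in every design cell, so saturated
    log-link fits stay off the boundary.
    """
    n = design.n
    cells = np.array([hash(c) for c in design.cells])
    _, cell_idx = np.unique(cells, return_inverse=True)
    n_cells = cell_idx.max() + 1
    Y = np.empty((n, p))
    for j in range(p):
        mu_cells = base * np.exp(rng.normal(0, 0.5, size=n_cells))
        mu = mu_cells[cell_idx]
        y = tweedie_rvs(mu, phi, rho, size=(n,), rng=rng)
        for _ in range(100):
            ok = np.ones(n, dtype=bool)
            for c in range(n_cells):
                if not np.any(y[cell_idx == c] > 0):
                    ok[cell_idx == c] = False
            if ok.all():
                break
            y[~ok] = tweedie_rvs(mu[~ok], phi, rho, size=(int((~ok).sum()),), rng=rng)
        Y[:, j] = y
    return Y


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def design_2x2():
    f1 = FactorSpec("A", ["a1", "a2"], ["a1"] * 6 + ["a2"] * 6)
    f2 = FactorSpec("B", ["b1", "b2"], (["b1"] * 3 + ["b2"] * 3) * 2)
    return build_design([f1, f2], interactions="all")
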