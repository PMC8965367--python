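"""Statistical power to detect a true RRS under incomplete offspring sampling.

Each replicate draws per-parent reproductive success from negative
binomials — natural-origin mean m, hatchery-origin mean m * rrs_true,
common dispersion (size) k — thins each offspring independently with the
sampling proportion, and applies the two-sided permutation test of mean
RS. Power is the fraction of replicates with p <= alpha.

Replicates use per-replicate seed substreams with inverse-CDF negative-
binomial draws and per-offspring uniform thinning, so two cells simulated
with the same seed share random numbers: power comparisons along the
mean, sampling-proportion and parent-number axes are properly paired
(common random numbers).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rrs import permutation_test_rs

__all__ = ["PowerCell", "PowerGrid", "simulate_power_cell", "power_grid",
           "interpolate_power"]

_THIN_CAP = 512  # max brood size enumerated for per-offspring thinning


@dataclass
class PowerCell:
    """One point of the power surface."""

    n_h: int = 437
    n_n: int = 214
    m: float = 2.0
    k: float = 1.0
    p_sample: float = 1.0
    rrs_true: float = 0.5
    alpha: float = 0.05
    n_reps: int = 2000
    n_perm: int = 1000
    power: Optional[float] = None
    mc_se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100")
        if not 0.0 < self.p_sample <= 1.0:
            raise ValueError("p_sample must lie in (0, 1]")
        if self.m <= 0 or self.k <= 0 or self.rrs_true < 0:
            raise ValueError("m, k must be positive and rrs_true nonnegative")


@dataclass
class PowerGrid:
    cells: pd.DataFrame
    axes: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _nb_ppf(u: np.ndarray, mean: float, k: float) -> np.ndarray:
    """Inverse-CDF negative binomial draw (monotone in the mean)."""
    return stats.nbinom.ppf(u, k, k / (k + mean)).astype(np.int64)


def _thin(counts: np.ndarray, p: float, u: np.ndarray) -> np.ndarray:
    """Per-offspring binomial thinning from shared uniforms.

    ``u`` has shape (n_parents, cap); offspring j of a parent is retained
    iff u[i, j] < p, which couples thinning across p and across counts.
    """
    if p >= 1.0:
        return counts
    c = np.minimum(counts, u.shape[1])
    mask = u < p
    idx = np.arange(u.shape[1])[None, :] < c[:, None]
    return (mask & idx).sum(axis=1)


def simulate_power_cell(cell: PowerCell, seed: int = 0) -> PowerCell:
    """Fill in the rejection rate for one (n_H, n_N, m, k, p_sample,
    rrs_true) combination."""
    hits = 0
    need_thin = cell.p_sample < 1.0
    for rep in range(cell.n_reps):
        ss = np.random.SeedSequence([int(seed), rep])
        kids = ss.spawn(3)
        rng_nb = np.random.default_rng(kids[0])
        u = rng_nb.random(cell.n_n + cell.n_h)
        x_n = _nb_ppf(u[: cell.n_n], cell.m, cell.k)
        x_h = _nb_ppf(u[cell.n_n:], cell.m * cell.rrs_true, cell.k)
        if need_thin:
            rng_thin = np.random.default_rng(kids[1])
            u_thin = rng_thin.random((cell.n_n + cell.n_h, _THIN_CAP))
            x_n = _thin(x_n, cell.p_sample, u_thin[: cell.n_n])
            x_h = _thin(x_h, cell.p_sample, u_thin[cell.n_n:])
        rng_perm = np.random.default_rng(kids[2])
        p = permutation_test_rs(x_h, x_n, n_perm=cell.n_perm, rng=rng_perm)
        hits += p <= cell.alpha
    power = hits / cell.n_reps
    return replace(cell, power=power,
                   mc_se=float(np.sqrt(power * (1 - power) / cell.n_reps)))


def power_grid(
    m_values: Sequence[float],
    k_values: Sequence[float],
    p_values: Sequence[float],
    n_h: int = 437,
    n_n: int = 214,
    rrs_true: float = 0.5,
    alpha: float = 0.05,
    n_reps: int = 2000,
    n_perm: int = 1000,
    seed: int = 0,
    share_seed: bool = True,
) -> PowerGrid:
    """Power over a (m, k, p_sample) grid.

    With ``share_seed`` (default) every cell reuses the same replicate
    seed substreams, giving paired comparisons between cells; otherwise
    each cell gets its own derived seed.
    """
    for name, ax in (("m_values", m_values), ("k_values", k_values),
                     ("p_values", p_values)):
        ax = list(ax)
        if len(ax) == 0:
            raise ValueError(f"{name} is empty")
        if any(b <= a for a, b in zip(ax, ax[1:])):
            raise ValueError(f"{name} must be strictly increasing")
    rows = []
    for i, (m, k, p) in enumerate(itertools.product(m_values, k_values, p_values)):
        cell_seed = seed if share_seed else int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        )
        cell = simulate_power_cell(
            PowerCell(n_h=n_h, n_n=n_n, m=m, k=k, p_sample=p,
                      rrs_true=rrs_true, alpha=alpha, n_reps=n_reps,
                      n_perm=n_perm),
            seed=cell_seed,
        )
        rows.append({
            "m": m, "k": k, "p_sample": p, "n_h": n_h, "n_n": n_n,
            "rrs_true": rrs_true, "alpha": alpha, "n_reps": n_reps,
            "power": cell.power, "mc_se": cell.mc_se,
        })
    return PowerGrid(
        pd.DataFrame(rows),
        axes={"m": list(m_values), "k": list(k_values), "p_sample": list(p_values)},
    )


def interpolate_power(grid: PowerGrid, queries: pd.DataFrame) -> np.ndarray:
    """Bilinear interpolation of power on the (m, p_sample) plane for each
    k level; queries must fall inside the grid hull and on a grid k."""
    from scipy.interpolate import RegularGridInterpolator

    m_ax = np.asarray(grid.axes["m"], float)
    p_ax = np.asarray(grid.axes["p_sample"], float)
    k_ax = list(grid.axes["k"])
    interp = {}
    for k in k_ax:
        sub = grid.cells[grid.cells["k"] == k]
        z = (
            sub.pivot(index="m", columns="p_sample", values="power")
            .reindex(index=m_ax, columns=p_ax)
            .to_numpy()
        )
        interp[k] = RegularGridInterpolator(
            (m_ax, p_ax), z, method="linear", bounds_error=True
        )
    out = np.empty(len(queries))
    for i, row in enumerate(queries.itertuples(index=False)):
        if row.k not in interp:
            raise ValueError(f"k={row.k} is not a grid level")
        try:
            out[i] = interp[row.k]([[row.m, row.p_sample]])[0]
        except ValueError as e:
            raise ValueError(
                f"query (m={row.m}, p_sample={row.p_sample}) outside grid hull"
            ) from e
    return np.clip(out, 0.0, 1.0)
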