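"""Quantitative null models for weighted bipartite matrices.

Null matrices preserve the observed row totals, column totals and number of
filled cells (connectance), so a metric's deviation from the ensemble —
z = (obs - exp) / sd.exp — isolates structure beyond what the marginals
impose.  The generator follows the swap-web recipe: draw a table with the
observed marginals uniformly (Patefield's algorithm), then shift weight
around 2x2 submatrices (which leaves marginals untouched) until the number
of filled cells matches the observed network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .network import InteractionMatrix

__all__ = [
    "NullEnsemble",
    "patefield_sample",
    "swap_web_null",
    "standardize",
    "standardize_many",
]


@dataclass
class NullEnsemble:
    """Observed metric value against a null-model ensemble."""

    metric_name: str
    obs: float
    null_values: np.ndarray
    exp: float
    sd_exp: float
    z: float | None
    p_two_sided: float
    n_null: int
    seed: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "obs": self.obs,
            "exp": self.exp,
            "sd_exp": self.sd_exp,
            "z": self.z,
            "p_two_sided": self.p_two_sided,
            "n_null": self.n_null,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def patefield_sample(
    row_sums: np.ndarray, col_sums: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniform draw from integer tables with the given marginals.

    Sequential conditional construction: each row is a multivariate
    hypergeometric draw of its total from the remaining column capacities,
    which yields the uniform distribution over all tables (Patefield's
    r2dtable algorithm).
    """
    row_sums = np.asarray(row_sums, dtype=np.int64)
    col_sums = np.asarray(col_sums, dtype=np.int64)
    if np.any(row_sums < 0) or np.any(col_sums < 0):
        raise ValueError("marginal totals must be nonnegative")
    if row_sums.sum() != col_sums.sum() or row_sums.sum() == 0:
        raise ValueError(
            f"marginal totals disagree: rows sum to {row_sums.sum()}, "
            f"columns to {col_sums.sum()} (both must be equal and positive)"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    remaining = col_sums.copy()
    out = np.empty((len(row_sums), len(col_sums)), dtype=np.int64)
    for i, rs in enumerate(row_sums):
        draw = rng.multivariate_hypergeometric(remaining, int(rs))
        out[i] = draw
        remaining -= draw
    return out


def _shift(w: np.ndarray, i1, i2, j1, j2, amount) -> None:
    """Move ``amount`` across the diagonal of a 2x2 submatrix (marginal-safe)."""
    w[i1, j1] -= amount
    w[i2, j2] -= amount
    w[i1, j2] += amount
    w[i2, j1] += amount


def _decrease_fill(w: np.ndarray, rng: np.random.Generator) -> bool:
    """One swap lowering the nonzero count by 1 or 2; True on success."""
    n = w.shape[0]
    for _ in range(200):
        i1, i2 = rng.choice(n, size=2, replace=False)
        common = np.flatnonzero((w[i1] > 0) & (w[i2] > 0))
        if len(common) < 2:
            continue
        j1, j2 = rng.choice(common, size=2, replace=False)
        # move the full min across; at least one source cell reaches zero
        # while both destination cells stay positive
        _shift(w, i1, i2, j1, j2, min(w[i1, j1], w[i2, j2]))
        return True
    return False


def _increase_fill(w: np.ndarray, rng: np.random.Generator, need: int) -> bool:
    """One swap raising the nonzero count by 1 or 2; True on success."""
    n = w.shape[0]
    for _ in range(200):
        i1, i2 = rng.choice(n, size=2, replace=False)
        j1_opts = np.flatnonzero((w[i1] > 0) & (w[i2] == 0))
        j2_opts = np.flatnonzero((w[i2] > 0) & (w[i1] == 0))
        if len(j1_opts) == 0 or len(j2_opts) == 0:
            continue
        j1 = rng.choice(j1_opts)
        j2 = rng.choice(j2_opts)
        a, b = w[i1, j1], w[i2, j2]
        if a != b:
            # full-min move empties exactly one source: net +1
            _shift(w, i1, i2, j1, j2, min(a, b))
        elif a > 1 and need >= 2:
            # partial move keeps both sources: net +2
            _shift(w, i1, i2, j1, j2, int(rng.integers(1, a)))
        elif a > 1:
            _shift(w, i1, i2, j1, j2, int(rng.integers(1, a)))
        else:
            # a == b == 1: full move is fill-neutral; look elsewhere
            continue
        return True
    return False


def swap_web_null(
    m: InteractionMatrix, seed: int | np.random.Generator, max_iter: int = 10**6
) -> InteractionMatrix:
    """Null matrix with the observed marginals and fill (swap-web).

    Starts from a Patefield draw of the observed row/column totals and applies
    marginal-preserving 2x2 weight shifts until the number of nonzero cells
    equals the observed fill.  Requires integer weights (read counts).
    """
    if not np.allclose(m.w, np.round(m.w)):
        raise ValueError(
            "swap-web nulls require integer weights (read counts); "
            "got non-integer entries"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    target = m.fill
    r = np.round(m.row_totals).astype(np.int64)
    c = np.round(m.col_totals).astype(np.int64)
    w = patefield_sample(r, c, rng)
    for _ in range(max_iter):
        fill = int(np.count_nonzero(w))
        if fill == target:
            break
        ok = (
            _decrease_fill(w, rng)
            if fill > target
            else _increase_fill(w, rng, target - fill)
        )
        if not ok:
            # local dead end: restart from a fresh Patefield draw
            w = patefield_sample(r, c, rng)
    else:
        raise RuntimeError(
            f"could not reach observed fill {target} within {max_iter} swaps "
            f"(achieved {int(np.count_nonzero(w))})"
        )
    return InteractionMatrix(list(m.plant_ids), list(m.fungus_ids), w.astype(float))


def standardize_many(
    metric_fns: dict[str, Callable[[InteractionMatrix], float]],
    m: InteractionMatrix,
    n_null: int = 1000,
    seed: int = 0,
) -> dict[str, NullEnsemble]:
    """Standardize several metrics against one shared null ensemble.

    Generating each swap-web null once and evaluating every metric on it
    keeps the ensembles consistent across metrics and avoids regenerating
    expensive null matrices per metric.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    rng = np.random.default_rng(seed)
    obs = {name: float(fn(m)) for name, fn in metric_fns.items()}
    null_values: dict[str, list[float]] = {name: [] for name in metric_fns}
    for _ in range(n_null):
        null = swap_web_null(m, rng)
        for name, fn in metric_fns.items():
            null_values[name].append(float(fn(null)))
    out: dict[str, NullEnsemble] = {}
    for name in metric_fns:
        nv = np.asarray(null_values[name])
        exp = float(nv.mean())
        sd = float(nv.std(ddof=1))
        degenerate = sd == 0
        p = (1 + int(np.sum(np.abs(nv - exp) >= abs(obs[name] - exp)))) / (n_null + 1)
        out[name] = NullEnsemble(
            metric_name=name,
            obs=obs[name],
            null_values=nv,
            exp=exp,
            sd_exp=sd,
            z=None if degenerate else (obs[name] - exp) / sd,
            p_two_sided=float(p),
            n_null=n_null,
            seed=seed,
            degenerate=degenerate,
        )
    return out


def standardize(
    metric_fn: Callable[[InteractionMatrix], float],
    m: InteractionMatrix,
    n_null: int = 1000,
    seed: int = 0,
    metric_name: str | None = None,
) -> NullEnsemble:
    """Standardize a network metric against swap-web nulls.

    z = (obs - exp) / sd.exp where exp and sd.exp are the mean and standard
    deviation of the metric over ``n_null`` randomized matrices; the
    two-sided empirical p-value counts nulls at least as far from the null
    mean as the observation, with add-one correction.  A zero-variance
    ensemble is flagged degenerate (z is None) rather than reported as an
    infinite z.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    rng = np.random.default_rng(seed)
    obs = float(metric_fn(m))
    null_values = np.array(
        [float(metric_fn(swap_web_null(m, rng))) for _ in range(n_null)]
    )
    exp = float(null_values.mean())
    sd = float(null_values.std(ddof=1))
    degenerate = sd == 0
    z = None if degenerate else (obs - exp) / sd
    p = (1 + int(np.sum(np.abs(null_values - exp) >= abs(obs - exp)))) / (n_null + 1)
    return NullEnsemble(
        metric_name=metric_name or getattr(metric_fn, "__name__", "metric"),
        obs=obs,
        null_values=null_values,
        exp=exp,
        sd_exp=sd,
        z=z,
        p_two_sided=float(p),
        n_null=n_null,
        seed=seed,
        degenerate=degenerate,
    )
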