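"""Community-composition statistics.

Hellinger transformation, Bray-Curtis dissimilarity, nonmetric
multidimensional scaling (NMDS), ANOSIM, the Mantel test, and a paired t-test
on log-transformed richness.  The permutation tests follow the classical
formulations: ANOSIM contrasts mean ranks of between- vs within-group
dissimilarities, the Mantel statistic is the Pearson correlation of the
lower-triangle vectors of two distance matrices, and both report
add-one-corrected empirical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, t as t_dist

from .otu_io import OtuTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermutationTestResult",
    "hellinger",
    "bray_curtis",
    "nmds",
    "anosim",
    "mantel",
    "paired_t_log",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities keyed by entity identifiers."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        self.d = (self.d + self.d.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Lower/upper-triangle vector in scipy condensed order."""
        return squareform(self.d, checks=False)

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        """Return the matrix restricted/permuted to ``ids``."""
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float))


@dataclass
class OrdinationResult:
    """NMDS configuration with Kruskal stress-1."""

    ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_starts_used: int
    converged: bool


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    tail: str
    seed: int | None = None
    statistic_name: str = ""
    extra: dict | None = None


def hellinger(table: OtuTable) -> np.ndarray:
    """Hellinger transformation: sqrt of relative abundance per sample.

    Rows of the result have unit sum of squares, which downweights dominant
    taxa before distance computation.
    """
    counts = np.asarray(table.counts, dtype=float)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total reads"
        )
    return np.sqrt(counts / totals[:, None])


def bray_curtis(matrix: np.ndarray, ids: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows: sum|x-y| / sum(x+y)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if np.any(matrix < 0):
        raise ValueError("Bray-Curtis requires nonnegative entries")
    row_sums = matrix.sum(axis=1)
    if np.count_nonzero(row_sums == 0) >= 2:
        raise ValueError("two all-zero rows: Bray-Curtis undefined for that pair")
    if ids is None:
        ids = [f"s{i}" for i in range(matrix.shape[0])]
    d = squareform(pdist(matrix, metric="braycurtis"))
    return DistanceMatrix(list(ids), d)


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling used as a deterministic NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    comp = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    return comp


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling minimizing Kruskal stress-1.

    Runs SMACOF with isotonic (pool-adjacent-violators) regression of the
    configuration distances on the dissimilarity ranks, from ``n_starts``
    random configurations plus one metric (Torgerson) scaling start, and
    returns the lowest-stress solution with column-centered coordinates.
    """
    from sklearn.manifold import MDS

    n = dist.n
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n - 1:
        # n points always embed exactly in n-1 dimensions
        raise ValueError(f"k={k} must be <= n-1={n - 1}")

    import inspect
    import warnings

    # the MDS keyword naming is in transition across sklearn releases
    params = inspect.signature(MDS.__init__).parameters
    if "metric_mds" in params:
        mode_kw = {"metric_mds": False, "metric": "precomputed"}
    else:
        mode_kw = {"metric": False, "dissimilarity": "precomputed"}
    common = dict(
        n_components=k,
        max_iter=max_iter,
        eps=tol,
        normalized_stress=True,
        n_jobs=None,
        **mode_kw,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(n_init=n_starts, random_state=seed, **common)
        coords = mds.fit_transform(dist.d)
        best_coords, best_stress, best_iter = coords, mds.stress_, mds.n_iter_
        # one additional deterministic start from metric scaling
        init = _classical_scaling(dist.d, k)
        mds2 = MDS(n_init=1, random_state=seed, **common)
        coords2 = mds2.fit_transform(dist.d, init=init)
    if mds2.stress_ < best_stress:
        best_coords, best_stress, best_iter = coords2, mds2.stress_, mds2.n_iter_
    best_coords = best_coords - best_coords.mean(axis=0)
    return OrdinationResult(
        ids=list(dist.ids),
        coordinates=best_coords,
        stress=float(best_stress),
        n_starts_used=n_starts + 1,
        converged=bool(best_iter < max_iter),
    )


def anosim(
    dist: DistanceMatrix,
    groups: dict[str, str],
    n_perm: int = 9999,
    seed: int = 0,
) -> PermutationTestResult:
    """Analysis of similarities (ANOSIM).

    R = (mean rank of between-group dissimilarities - mean rank of
    within-group) / (M/2) with M = n(n-1)/2 pairwise dissimilarities ranked by
    mid-ranks.  The one-tailed p-value counts label permutations with
    R_perm >= R_obs, with add-one correction.
    """
    labels = np.asarray([groups[i] for i in dist.ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if counts.min() < 2:
        raise ValueError("every group must have at least two members")
    n = dist.n
    ranks = rankdata(dist.condensed())  # mid-ranks
    iu = np.triu_indices(n, k=1)
    denom = (n * (n - 1) / 2) / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if r_stat(labels[perm]) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return PermutationTestResult(
        statistic=float(r_obs),
        p_value=float(p),
        n_permutations=n_perm,
        tail="greater",
        seed=seed,
        statistic_name="ANOSIM R",
    )


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    tail: str = "greater",
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """One-tailed Mantel test between two distance matrices.

    The statistic is the Pearson correlation of the lower-triangle vectors;
    significance is assessed by simultaneously permuting rows and columns of
    the second matrix.  ``tail='greater'`` tests for positive association,
    ``'less'`` for negative.
    """
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share the same id set")
    d2 = d2.reorder(d1.ids)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1 = d1.d[iu]
    if v1.std() == 0 or d2.d[iu].std() == 0:
        raise ValueError("zero variance in a distance matrix triangle")
    v1c = (v1 - v1.mean()) / (v1.std() * np.sqrt(v1.size))

    def corr(mat: np.ndarray) -> float:
        v2 = mat[iu]
        v2c = (v2 - v2.mean()) / (v2.std() * np.sqrt(v2.size))
        return float(v1c @ v2c)

    r_obs = corr(d2.d)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_p = corr(d2.d[np.ix_(p, p)])
        if (tail == "greater" and r_p >= r_obs) or (tail == "less" and r_p <= r_obs):
            exceed += 1
    p_val = (1 + exceed) / (n_perm + 1)
    return PermutationTestResult(
        statistic=r_obs,
        p_value=float(p_val),
        n_permutations=n_perm,
        tail=tail,
        seed=seed,
        statistic_name="Mantel r",
    )


def paired_t_log(
    a: dict[str, float],
    b: dict[str, float],
    tail: str = "greater",
) -> PermutationTestResult:
    """Paired t-test on log-transformed positive values.

    t = mean(log a - log b) / (sd / sqrt(n)) with df = n - 1; the p-value is
    taken from the t distribution per ``tail``.
    """
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    if set(a) != set(b):
        raise ValueError("paired test requires identical id sets")
    ids = sorted(a)
    x = np.array([a[i] for i in ids], dtype=float)
    y = np.array([b[i] for i in ids], dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log transform requires strictly positive values")
    diff = np.log(x) - np.log(y)
    n = diff.size
    if n < 2:
        raise ValueError("need at least two pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return PermutationTestResult(0.0, 1.0, 0, tail, statistic_name="paired t")
        raise ValueError("zero variance in paired differences")
    t_stat = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    if tail == "greater":
        p = t_dist.sf(t_stat, df)
    else:
        p = 2 * t_dist.sf(abs(t_stat), df)
    return PermutationTestResult(
        statistic=float(t_stat),
        p_value=float(p),
        n_permutations=0,
        tail=tail,
        statistic_name="paired t",
        extra={"df": df},
    )
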