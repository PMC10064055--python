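"""Weighted bipartite network metrics.

Plant-fungus interaction matrices carry read counts as interaction weights.
Four network-level indices are provided:

* ``specialization_h2`` — H2', the network-level specialization of Bluthgen's
  two-dimensional Shannon entropy, rescaled between the marginal-constrained
  entropy extremes (0 = perfectly generalized, 1 = perfectly specialized).
* ``weighted_connectance`` — Bersier-style linkage density (mean effective
  number of partners, weighted by interaction totals) divided by species
  number; at most 0.5.
* ``wnodf`` — weighted Nestedness based on Overlap and Decreasing Fill, on a
  0-100 scale, with ties in marginal totals contributing zero (strict
  decreasing fill).
* ``modularity`` — Barber's weighted bipartite modularity Q maximized by
  label propagation with agglomerative refinement (LPAwb+-style), best of
  several restarts.

All four are invariant to simultaneous row/column permutation and to positive
rescaling of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .otu_io import OtuTable

__all__ = [
    "InteractionMatrix",
    "ModularityResult",
    "specialization_h2",
    "weighted_connectance",
    "wnodf",
    "modularity",
]


@dataclass
class InteractionMatrix:
    """Plants x fungi nonnegative weight matrix with identifiers."""

    plant_ids: list[str]
    fungus_ids: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.plant_ids), len(self.fungus_ids)):
            raise ValueError("weight matrix shape does not match id lists")
        if np.any(self.w < 0):
            raise ValueError("interaction weights must be nonnegative")
        if self.w.sum() <= 0:
            raise ValueError("interaction matrix must have positive total weight")
        if np.any(self.w.sum(axis=1) == 0):
            raise ValueError("all-zero plant row in interaction matrix")
        if np.any(self.w.sum(axis=0) == 0):
            raise ValueError("all-zero fungus column in interaction matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.w.shape

    @property
    def row_totals(self) -> np.ndarray:
        return self.w.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.w.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.w.sum())

    @property
    def fill(self) -> int:
        """Number of nonzero cells (realized links)."""
        return int(np.count_nonzero(self.w))

    @classmethod
    def from_otu_table(cls, table: OtuTable) -> "InteractionMatrix":
        """Treat samples as plants and OTUs as fungi; drop empty rows/columns."""
        w = np.asarray(table.counts, dtype=float)
        keep_r = w.sum(axis=1) > 0
        keep_c = w.sum(axis=0) > 0
        return cls(
            [s for s, k in zip(table.sample_ids, keep_r) if k],
            [o for o, k in zip(table.otu_ids, keep_c) if k],
            w[np.ix_(keep_r, keep_c)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=self.plant_ids, columns=self.fungus_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )


@dataclass
class ModularityResult:
    Q: float
    module_of: dict[str, int]
    n_modules: int
    restarts_used: int
    seed: int


def _entropy_nats(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _h2_min_exact(r: np.ndarray, c: np.ndarray, total: float) -> float:
    """Exact minimum entropy over tables with the given integer marginals.

    Entropy is concave, so its minimum over the transportation polytope is
    attained at a vertex; every vertex arises from a sequence of allocations
    each saturating a row or a column.  The recursion enumerates those
    sequences over the multisets of remaining marginal totals (row/column
    identity is irrelevant to entropy), which keeps the memoized state space
    tiny for small matrices.
    """
    from functools import lru_cache

    r0 = tuple(sorted(int(round(x)) for x in r if x > 0))
    c0 = tuple(sorted(int(round(x)) for x in c if x > 0))

    @lru_cache(maxsize=None)
    def rec(rt: tuple, ct: tuple) -> float:
        if not rt:
            return 0.0
        best = np.inf
        for rv in set(rt):
            for cv in set(ct):
                a = min(rv, cv)
                p = a / total
                h = -p * np.log(p)
                nrt = list(rt)
                nrt.remove(rv)
                nct = list(ct)
                nct.remove(cv)
                if rv > a:
                    nrt.append(rv - a)
                if cv > a:
                    nct.append(cv - a)
                cand = h + rec(tuple(sorted(nrt)), tuple(sorted(nct)))
                if cand < best:
                    best = cand
        return best

    return rec(r0, c0)


def _h2_min_greedy(r: np.ndarray, c: np.ndarray, total: float) -> float:
    """Minimum-entropy allocation by greedy packing.

    Repeatedly places the largest possible weight min(r_i, c_j) into the cell
    formed by the currently largest remaining row and column totals,
    concentrating each row's weight into the fewest admissible cells.
    """
    r = r.astype(float).copy()
    c = c.astype(float).copy()
    h = 0.0
    while True:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        a = min(r[i], c[j])
        if a <= 0:
            break
        p = a / total
        h -= p * np.log(p)
        r[i] -= a
        c[j] -= a
    return h


def specialization_h2(m: InteractionMatrix) -> float:
    """Network-level specialization H2' in [0, 1].

    H2 is the Shannon entropy (nats) of the interaction weight distribution;
    it is rescaled between H2max (entropy of the independence table
    r_i c_j / W, i.e. the sum of marginal entropies) and H2min (greedy
    marginal-constrained packing), so the index is scale-free and comparable
    across networks: H2' = (H2max - H2) / (H2max - H2min).
    """
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("H2' needs at least a 2x2 matrix")
    total = m.total
    p = m.w / total
    h2 = _entropy_nats(p.ravel())
    h2max = _entropy_nats(m.row_totals / total) + _entropy_nats(m.col_totals / total)
    r, c = m.row_totals, m.col_totals
    integral = np.allclose(r, np.round(r)) and np.allclose(c, np.round(c))
    if integral and total <= 200 and n * k <= 100:
        h2min = _h2_min_exact(r, c, total)
    else:
        h2min = _h2_min_greedy(r, c, total)
    if h2max - h2min < 1e-12:
        return 0.0
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


def weighted_connectance(m: InteractionMatrix) -> float:
    """Weighted connectance: linkage density over total species number.

    Linkage density LD = (1/(2W)) [sum_j c_j 2^(H_j) + sum_i r_i 2^(H_i)]
    where H_i is the base-2 Shannon entropy of row i's weight distribution
    (2^H is the effective number of partners) and similarly for columns.
    """
    w, total = m.w, m.total
    r, c = m.row_totals, m.col_totals

    def eff_partners(vecs: np.ndarray, totals: np.ndarray) -> np.ndarray:
        p = vecs / totals[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=1)
        return 2.0**h

    ld = (r @ eff_partners(w, r) + c @ eff_partners(w.T, c)) / (2.0 * total)
    return float(ld / (m.shape[0] + m.shape[1]))


def _nodf_pair_terms(w: np.ndarray) -> float:
    """Sum of WNODF paired terms over ordered row pairs of ``w``.

    After sorting rows by decreasing totals, the pair (upper u, lower l)
    contributes 100 * #{j : 0 < w_lj < w_uj} / fill(row l), or 0 when the
    marginal totals are tied (strict decreasing fill).
    """
    totals = w.sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    w = w[order]
    totals = totals[order]
    fills = np.count_nonzero(w, axis=1).astype(float)
    # overlap[u, l] = #{j : 0 < w_lj < w_uj}
    lower = w[None, :, :]
    overlap = ((lower > 0) & (lower < w[:, None, :])).sum(axis=2)
    valid = np.triu(totals[:, None] > totals[None, :], k=1) & (fills[None, :] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(valid, 100.0 * overlap / fills[None, :], 0.0)
    return float(terms.sum())


def wnodf(m: InteractionMatrix) -> float:
    """Weighted nestedness (WNODF) on a 0-100 scale.

    Rows and columns are sorted by decreasing marginal totals; each ordered
    pair contributes the percentage of the lower member's nonzero cells that
    are strictly smaller than the upper member's in the same position, or zero
    when marginal totals are tied.
    """
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("WNODF needs at least a 2x2 matrix")
    pairs = n * (n - 1) / 2 + k * (k - 1) / 2
    return float((_nodf_pair_terms(m.w) + _nodf_pair_terms(m.w.T)) / pairs)


def modularity_q(
    m: InteractionMatrix, row_labels: np.ndarray, col_labels: np.ndarray
) -> float:
    """Barber bipartite modularity of a given module assignment."""
    w, total = m.w, m.total
    r, c = m.row_totals, m.col_totals
    q = 0.0
    for lab in np.unique(np.concatenate([row_labels, col_labels])):
        ri = row_labels == lab
        cj = col_labels == lab
        if ri.any() and cj.any():
            q += w[np.ix_(ri, cj)].sum() - r[ri].sum() * c[cj].sum() / total
    return float(q / total)


def _best_labels(
    w_to_side: np.ndarray, own_totals: np.ndarray, other_totals: np.ndarray,
    other_labels: np.ndarray, total: float, free_label: int
) -> np.ndarray:
    """Assign each node the label maximizing its modularity contribution.

    ``w_to_side`` is (n_nodes, n_other); a node joining module L contributes
    sum(w to L-members) - own_total * (L-members' totals) / W.  A fresh label
    (contribution 0) is used when every existing label has negative gain.
    Ties break toward the lowest label index.
    """
    labs = np.unique(other_labels)
    mask = other_labels[None, :] == labs[:, None]  # (n_labs, n_other)
    wsum = w_to_side @ mask.T  # (n_nodes, n_labs)
    tsum = mask @ other_totals  # (n_labs,)
    gain = wsum - np.outer(own_totals, tsum) / total
    best = np.argmax(gain, axis=1)
    best_gain = gain[np.arange(len(best)), best]
    out = labs[best]
    out[best_gain < 0] = free_label
    return out


def modularity(
    m: InteractionMatrix, n_restarts: int = 20, seed: int = 0
) -> ModularityResult:
    """Maximize Barber bipartite modularity by label propagation.

    Alternates best-label updates between the two guilds until stable, then
    greedily merges module pairs while any merge increases Q, repeating both
    phases until no improvement.  The best assignment over ``n_restarts``
    random initializations (the first is the identity partition) is returned.
    """
    w, total = m.w, m.total
    r, c = m.row_totals, m.col_totals
    n, k = m.shape
    rng = np.random.default_rng(seed)
    free = n + k  # label id guaranteed unused by initial assignments

    def refine(row_lab: np.ndarray, col_lab: np.ndarray):
        q_prev = -np.inf
        while True:
            # label propagation to a local optimum
            for _ in range(200):
                col_new = _best_labels(w.T, c, r, row_lab, total, free)
                row_new = _best_labels(w, r, c, col_new, total, free + 1)
                if np.array_equal(col_new, col_lab) and np.array_equal(
                    row_new, row_lab
                ):
                    break
                row_lab, col_lab = row_new, col_new
            # agglomerative phase: merge module pairs with positive Q gain
            while True:
                labs = np.unique(np.concatenate([row_lab, col_lab]))
                if len(labs) < 2:
                    break
                rw = np.stack([w[row_lab == L].sum(axis=0) for L in labs])
                rs = np.array([r[row_lab == L].sum() for L in labs])
                cm = np.stack([rw[:, col_lab == L].sum(axis=1) for L in labs]).T
                cs = np.array([c[col_lab == L].sum() for L in labs])
                # gain of merging A and B: cross-guild terms between them
                gain = (
                    cm + cm.T - (np.outer(rs, cs) + np.outer(cs, rs)) / total
                )
                np.fill_diagonal(gain, -np.inf)
                a, b = np.unravel_index(np.argmax(gain), gain.shape)
                if gain[a, b] <= 1e-12:
                    break
                row_lab[row_lab == labs[b]] = labs[a]
                col_lab[col_lab == labs[b]] = labs[a]
            q = modularity_q(m, row_lab, col_lab)
            if q <= q_prev + 1e-12:
                return q, row_lab, col_lab
            q_prev = q

    best = (-np.inf, None, None)
    for start in range(max(1, n_restarts)):
        if start == 0:
            row_lab = np.arange(n)
            col_lab = _best_labels(w.T, c, r, row_lab, total, free)
        else:
            n_groups = int(rng.integers(1, n + 1))
            row_lab = rng.integers(0, n_groups, size=n)
            col_lab = _best_labels(w.T, c, r, row_lab, total, free)
        q, rl, cl = refine(row_lab.copy(), col_lab.copy())
        if q > best[0]:
            best = (q, rl, cl)

    q, rl, cl = best
    # relabel modules 0..K-1 in order of first appearance
    relabel: dict[int, int] = {}
    module_of: dict[str, int] = {}
    for name, lab in zip(
        list(m.plant_ids) + list(m.fungus_ids), list(rl) + list(cl)
    ):
        module_of[name] = relabel.setdefault(int(lab), len(relabel))
    return ModularityResult(
        Q=float(q),
        module_of=module_of,
        n_modules=len(relabel),
        restarts_used=max(1, n_restarts),
        seed=seed,
    )
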