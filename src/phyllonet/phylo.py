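"""Host-tree handling and phylogenetic-signal statistics.

Trees are read from newick (dendropy does the parsing); from them we derive
patristic (cophenetic) distances for Mantel tests and the Brownian-motion
covariance kernel shared by the two signal statistics:

* Blomberg's K — a variance ratio contrasting the observed trait variance
  with the variance expected under Brownian motion on the tree; K ~ 1 under
  Brownian evolution, K << 1 for traits with no phylogenetic structure.
  Significance by permuting trait values across tips.
* Pagel's lambda — a multiplier on off-diagonal phylogenetic covariances
  estimated by maximum likelihood on [0, 1]; significance by likelihood-ratio
  test against lambda = 0 (chi-square, 1 df).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .community import DistanceMatrix

__all__ = [
    "Phylogeny",
    "SignalResult",
    "read_newick",
    "cophenetic_distances",
    "bm_covariance",
    "blomberg_k",
    "pagel_lambda",
]


@dataclass
class SignalResult:
    statistic_name: str
    estimate: float
    p_value: float
    n_permutations: int = 0
    log_likelihoods: tuple[float, float] | None = None


class Phylogeny:
    """Rooted tree with branch lengths and uniquely labeled tips.

    Thin wrapper over a :class:`dendropy.Tree` exposing the pieces the signal
    statistics need: tip labels in stable order, tip depths, and patristic
    distances.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = [leaf for leaf in tree.leaf_node_iter()]
        labels = [t.taxon.label if t.taxon else None for t in tips]
        if any(lab is None for lab in labels):
            raise ValueError("all tips must be labeled")
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        if len(labels) < 2:
            raise ValueError("a phylogeny needs at least two tips")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("every edge must carry a branch length")
            if edge.length < 0:
                raise ValueError("branch lengths must be nonnegative")
        self.tip_labels: list[str] = sorted(labels)
        self._shared_paths: np.ndarray | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def shared_path_matrix(self) -> np.ndarray:
        """Root-to-MRCA shared path lengths V_ij, aligned to ``tip_labels``.

        Computed once by a post-order traversal (pairs of tips in different
        child subtrees share the ancestor node's depth) and cached.
        """
        if self._shared_paths is not None:
            return self._shared_paths
        idx = {lab: i for i, lab in enumerate(self.tip_labels)}
        n = self.n_tips
        v = np.zeros((n, n))
        depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
        tipsets: dict[int, np.ndarray] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                depth[id(node)] = depth[id(node.parent_node)] + (
                    node.edge.length or 0.0
                )
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                v[i, i] = depth[id(node)]
                tipsets[id(node)] = np.array([i])
                continue
            children = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    v[np.ix_(children[a], children[b])] = d
                    v[np.ix_(children[b], children[a])] = d
            tipsets[id(node)] = np.concatenate(children)
        self._shared_paths = v
        return v

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        depths = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.tip_depths().values())
        return max(depths) - min(depths) <= tol


def read_newick(path) -> Phylogeny:
    """Parse a newick file (or string buffer) into a :class:`Phylogeny`."""
    if hasattr(path, "read"):
        data = path.read()
    else:
        with open(path) as fh:
            data = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"newick parse error: {exc}") from exc
    return Phylogeny(tree)


def parse_newick(newick: str) -> Phylogeny:
    return read_newick(io.StringIO(newick))


def cophenetic_distances(tree: Phylogeny) -> DistanceMatrix:
    """Patristic distances (sums of branch lengths) between all tip pairs.

    d_ij = depth_i + depth_j - 2 V_ij where V is the shared-path matrix.
    """
    v = tree.shared_path_matrix()
    dvec = np.diag(v)
    d = dvec[:, None] + dvec[None, :] - 2.0 * v
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return DistanceMatrix(list(tree.tip_labels), (d + d.T) / 2.0)


def bm_covariance(tree: Phylogeny, lambda_scale: float = 1.0) -> np.ndarray:
    """Brownian-motion covariance: V_ij = shared root-to-MRCA path length.

    Off-diagonal entries are multiplied by ``lambda_scale`` (Pagel's lambda
    transformation); the diagonal (tip depths) is untouched.  Rows/columns
    follow ``tree.tip_labels`` order.
    """
    v = tree.shared_path_matrix().copy()
    off = ~np.eye(v.shape[0], dtype=bool)
    v[off] *= lambda_scale
    return v


def _phylo_mean_and_quadratics(x: np.ndarray, vinv: np.ndarray):
    ones = np.ones(len(x))
    w = vinv @ ones
    s = ones @ w
    a_hat = (w @ x) / s
    resid = x - a_hat
    return resid, float(resid @ resid), float(resid @ vinv @ resid), s


def blomberg_k(
    tree: Phylogeny,
    trait: dict[str, float],
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Blomberg's K with permutation p-value.

    K is the ratio of observed to Brownian-expected (MSE0/MSE); the p-value is
    the add-one-corrected fraction of tip-label permutations with
    K_perm >= K_obs.
    """
    labels = tree.tip_labels
    missing = [t for t in labels if t not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    x = np.array([trait[t] for t in labels], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; K undefined")
    v = bm_covariance(tree)
    try:
        vinv = np.linalg.inv(v)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc
    n = len(x)

    def k_of(xv: np.ndarray) -> float:
        resid, mse0_num, mse_num, s = _phylo_mean_and_quadratics(xv, vinv)
        expected = (np.trace(v) - n / s) / (n - 1)
        return (mse0_num / mse_num) / expected

    k_obs = k_of(x)
    rng = np.random.default_rng(seed)
    exceed = sum(k_of(x[rng.permutation(n)]) >= k_obs for _ in range(n_perm))
    p = (1 + exceed) / (n_perm + 1)
    return SignalResult("K", float(k_obs), float(p), n_permutations=n_perm)


def _lambda_loglik(lam: float, x: np.ndarray, tree: Phylogeny) -> float:
    """Profile log-likelihood of lambda (mean and rate profiled out)."""
    v = bm_covariance(tree, lambda_scale=lam)
    n = len(x)
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0:
        return -np.inf
    vinv = np.linalg.inv(v)
    resid, _, mse_num, _ = _phylo_mean_and_quadratics(x, vinv)
    sigma2 = mse_num / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda(tree: Phylogeny, trait: dict[str, float]) -> SignalResult:
    """Pagel's lambda by bounded maximum likelihood on [0, 1].

    The likelihood-ratio test against lambda = 0 (no phylogenetic covariance)
    uses a chi-square with one degree of freedom; when the MLE sits at the
    lambda = 0 boundary the LR statistic is 0 and p = 1.
    """
    labels = tree.tip_labels
    missing = [t for t in labels if t not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    x = np.array([trait[t] for t in labels], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; lambda undefined")

    neg = lambda lam: -_lambda_loglik(lam, x, tree)
    res = minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded")
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # guard against the optimizer missing a boundary optimum
    for cand in (0.0, 1.0):
        ll_c = _lambda_loglik(cand, x, tree)
        if ll_c > ll_hat:
            lam_hat, ll_hat = cand, ll_c
    ll0 = _lambda_loglik(0.0, x, tree)
    lr = max(0.0, 2 * (ll_hat - ll0))
    p = float(chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return SignalResult(
        "lambda", lam_hat, p, log_likelihoods=(ll_hat, ll0)
    )


def read_trait_tsv(path) -> dict[str, float]:
    """Two-column TSV (tip_id, value) -> trait map."""
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return {str(k): float(v) for k, v in df.iloc[:, 0].items()}
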