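"""Synthetic data generators emulating a paired phyllosphere-fungus survey.

Everything downstream — preprocessing, community tests, phylogenetic signal,
network metrics, robustness — can be exercised without external sequence
data.  Three generators are provided:

* ``simulate_tree`` — pure-birth (Yule) ultrametric host phylogenies scaled
  to unit height, so the lambda signal dial is directly interpretable.
* ``simulate_trait_bm`` — Brownian-motion tip traits under a Pagel-lambda
  covariance transformation (off-diagonal phylogenetic covariances scaled by
  ``lambda_sim``; 0 = i.i.d. tips, 1 = full Brownian structure).
* ``simulate_paired_communities`` — paired epiphyte/endophyte OTU tables over
  the same hosts.  Per-OTU host affinities evolve on the tree (epiphytes with
  ``signal_lambda``, endophytes with an independent dial, 0 by default,
  mirroring the contrast where host phylogeny constrains surface but not
  interior communities); affinities map through a softmax to per-host
  composition and reads are drawn multinomially at fixed depth.
* ``simulate_network`` — plant x fungus weight matrices with tunable
  structure (random / modular / nested / specialized) and an off-structure
  noise dial.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .network import InteractionMatrix
from .otu_io import OtuTable
from .phylo import Phylogeny, bm_covariance

__all__ = [
    "CommunitySimParams",
    "NetworkSimParams",
    "simulate_tree",
    "simulate_trait_bm",
    "simulate_paired_communities",
    "simulate_network",
]


@dataclass
class CommunitySimParams:
    """Study-design parameters for paired-community simulation.

    Defaults emulate the mangrove survey layout: 11 host species sampled in
    two leaf compartments, ~800 OTUs per compartment with a quarter shared,
    samples rarefiable to 78,264 reads, strongly host-specialized OTUs
    (``concentration`` = 3), full Brownian host structuring of the epiphyte
    pool and none for the endophyte pool.
    """

    n_hosts: int = 11
    n_otus: int = 800
    shared_fraction: float = 0.25
    signal_lambda: float = 1.0
    endo_signal_lambda: float = 0.0
    depth: int = 78264
    concentration: float = 3.0
    sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shared_fraction", "signal_lambda", "endo_signal_lambda"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.concentration <= 0 or self.sigma2 <= 0:
            raise ValueError("concentration and sigma2 must be positive")
        if self.n_hosts < 2 or self.n_otus < 1:
            raise ValueError("need at least 2 hosts and 1 OTU")


@dataclass
class NetworkSimParams:
    """Structure dial for synthetic plant x fungus interaction matrices."""

    n_plants: int = 11
    n_fungi: int = 40
    structure: str = "modular"
    n_modules: int = 2
    noise: float = 0.0
    total_weight: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in ("random", "modular", "nested", "specialized"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")
        if not 1 <= self.n_modules <= min(self.n_plants, self.n_fungi):
            raise ValueError("n_modules must be in [1, min(n_plants, n_fungi)]")
        if self.total_weight < 1:
            raise ValueError("total_weight must be >= 1")


def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with unit height.

    Forward simulation: lineages split at exponential waiting times (rate
    proportional to the number of live lineages) until ``n_tips`` are extant,
    then all pending branches are extended to the present and the tree is
    rescaled to height 1.  Tips are labeled ``t01``, ``t02``, ...
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # each active entry: (node, birth_time)
    root = tree.seed_node
    active = [(root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    t_end = t + rng.exponential(1.0 / len(active))
    width = max(n_tips, 2)
    for i, (node, birth) in enumerate(active):
        node.edge.length = t_end - birth
        node.taxon = taxa.new_taxon(label=f"t{i + 1:0{len(str(width))}d}")
    root.edge.length = 0.0
    # rescale to unit height (the pre-split stem carries no depth)
    height = max(Phylogeny(tree).tip_depths().values())
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length = edge.length / height
    return Phylogeny(tree)


def _bm_cholesky(tree: Phylogeny, lambda_sim: float, sigma2: float) -> np.ndarray:
    v = sigma2 * bm_covariance(tree, lambda_scale=lambda_sim)
    # tiny jitter keeps the Cholesky factorization stable for lambda near 1
    return np.linalg.cholesky(v + 1e-12 * np.eye(v.shape[0]))


def simulate_trait_bm(
    tree: Phylogeny, lambda_sim: float, sigma2: float, seed: int
) -> dict[str, float]:
    """One multivariate-normal trait draw under lambda-scaled BM covariance."""
    if not 0.0 <= lambda_sim <= 1.0:
        raise ValueError("lambda_sim must lie in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    chol = _bm_cholesky(tree, lambda_sim, sigma2)
    x = chol @ rng.standard_normal(tree.n_tips)
    return dict(zip(tree.tip_labels, x))


def _community_table(
    tree: Phylogeny,
    otu_ids: list[str],
    lambda_sim: float,
    params: CommunitySimParams,
    rng: np.random.Generator,
) -> OtuTable:
    n_otus = len(otu_ids)
    chol = _bm_cholesky(tree, lambda_sim, params.sigma2)
    # host-affinity traits, one BM realization per OTU
    traits = rng.standard_normal((n_otus, tree.n_tips)) @ chol.T
    # skewed baseline abundances, as in real amplicon communities
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_otus)
    weights = base[:, None] * np.exp(params.concentration * traits)
    probs = weights / weights.sum(axis=0, keepdims=True)
    counts = np.stack(
        [rng.multinomial(params.depth, probs[:, h]) for h in range(tree.n_tips)]
    )
    return OtuTable(list(tree.tip_labels), list(otu_ids), counts)


def simulate_paired_communities(
    tree: Phylogeny, params: CommunitySimParams
) -> tuple[OtuTable, OtuTable]:
    """Paired epiphyte/endophyte OTU tables over the hosts of ``tree``.

    Both tables have ``params.n_otus`` OTU columns; a ``shared_fraction`` of
    the ids is common to both compartments.  Epiphyte host affinities carry
    phylogenetic signal ``signal_lambda``; endophyte affinities use
    ``endo_signal_lambda`` (default 0).  Every sample sums to ``depth``.
    """
    if tree.n_tips != params.n_hosts:
        raise ValueError(
            f"tree has {tree.n_tips} tips but params expect {params.n_hosts} hosts"
        )
    rng = np.random.default_rng(params.seed)
    n_shared = int(round(params.shared_fraction * params.n_otus))
    n_specific = params.n_otus - n_shared
    shared_ids = [f"OTU_S{i:05d}" for i in range(n_shared)]
    epi_ids = shared_ids + [f"OTU_E{i:05d}" for i in range(n_specific)]
    endo_ids = shared_ids + [f"OTU_N{i:05d}" for i in range(n_specific)]
    epi = _community_table(tree, epi_ids, params.signal_lambda, params, rng)
    endo = _community_table(tree, endo_ids, params.endo_signal_lambda, params, rng)
    return epi, endo


def _nested_pattern(n: int, m: int) -> np.ndarray:
    """Strictly nested staircase: fills and weights strictly decrease."""
    w = np.zeros((n, m))
    for i in range(n):
        k = m - i  # row i keeps the first m - i columns
        if k < 1:
            k = 1
        w[i, :k] = (n - i) * (m - np.arange(k))
    return w


def simulate_network(params: NetworkSimParams) -> InteractionMatrix:
    """Plant x fungus weight matrix with a chosen structural archetype.

    ``modular``: weight split equally across ``n_modules`` diagonal blocks
    (noise-free block totals are exactly equal); ``nested``: a strictly
    decreasing staircase pattern; ``specialized``: each fungus attached to a
    single plant; ``random``: a Patefield draw from near-uniform marginals.
    A ``noise`` fraction of the total weight is scattered uniformly over all
    cells.
    """
    n, m = params.n_plants, params.n_fungi
    rng = np.random.default_rng(params.seed)
    plant_ids = [f"P{i + 1:02d}" for i in range(n)]
    fungus_ids = [f"F{j + 1:03d}" for j in range(m)]
    total = params.total_weight

    if params.structure == "random":
        rs = np.full(n, total // n)
        rs[: total % n] += 1
        cs = np.full(m, total // m)
        cs[: total % m] += 1
        from .nulls import patefield_sample

        w = patefield_sample(rs, cs, rng).astype(float)
        return InteractionMatrix(plant_ids, fungus_ids, w)

    noise_w = int(round(params.noise * total))
    struct_w = total - noise_w

    if params.structure == "modular":
        row_mod = np.arange(n) % params.n_modules
        col_mod = np.arange(m) % params.n_modules
        w = np.zeros((n, m))
        block_tot = np.full(params.n_modules, struct_w // params.n_modules)
        block_tot[: struct_w % params.n_modules] += 1
        for b in range(params.n_modules):
            cells = np.ix_(row_mod == b, col_mod == b)
            shape = w[cells].shape
            alloc = rng.multinomial(block_tot[b], np.full(shape, 1.0).ravel() / (shape[0] * shape[1]))
            w[cells] = w[cells] + alloc.reshape(shape)
    elif params.structure == "nested":
        pattern = _nested_pattern(n, m)
        if noise_w == 0:
            # keep the exact strictly-nested integer pattern (scaled)
            w = pattern * max(1, round(struct_w / pattern.sum()))
        else:
            w = rng.multinomial(struct_w, (pattern / pattern.sum()).ravel()).reshape(
                n, m
            ).astype(float)
    else:  # specialized
        host_of = np.arange(m) % n
        w = np.zeros((n, m))
        if noise_w == 0:
            per = struct_w // m
            w[host_of, np.arange(m)] = max(1, per)
        else:
            probs = np.zeros((n, m))
            probs[host_of, np.arange(m)] = 1.0 / m
            w = rng.multinomial(struct_w, probs.ravel()).reshape(n, m).astype(float)

    if noise_w:
        w = w + rng.multinomial(noise_w, np.full(n * m, 1.0 / (n * m))).reshape(n, m)
    # guard the no-empty-row/column invariant under sparse noise draws
    for i in np.flatnonzero(w.sum(axis=1) == 0):
        w[i, int(rng.integers(m))] += 1
    for j in np.flatnonzero(w.sum(axis=0) == 0):
        w[int(rng.integers(n)), j] += 1
    return InteractionMatrix(plant_ids, fungus_ids, w)
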