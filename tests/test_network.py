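import itertools
import subprocess

import numpy as np
import pytest

from phyllonet import (
    InteractionMatrix,
    modularity,
    specialization_h2,
    weighted_connectance,
    wnodf,
)
from phyllonet.network import modularity_q


def _im(w):
    w = np.asarray(w, dtype=float)
    n, m = w.shape
    return InteractionMatrix(
        [f"p{i}" for i in range(n)], [f"f{j}" for j in range(m)], w
    )


def brute_force_h2min(r, c, total):
    """Minimum entropy over all integer tables with the given marginals."""

    def tables(rows, cols):
        if len(rows) == 1:
            yield [list(cols)]
            return
        def rowfill(tot, caps):
            if len(caps) == 1:
                if tot <= caps[0]:
                    yield [tot]
                return
            for v in range(min(tot, caps[0]) + 1):
                for rest in rowfill(tot - v, caps[1:]):
                    yield [v] + rest
        for row in rowfill(rows[0], cols):
            rem = [ci - vi for ci, vi in zip(cols, row)]
            for rest in tables(rows[1:], rem):
                yield [row] + rest

    def h2(mat):
        p = np.asarray(mat, float).ravel() / total
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    return min(h2(t) for t in tables(list(r), list(c)))


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


class TestSpecializationH2:
    def test_diagonal_is_perfectly_specialized(self):
        assert specialization_h2(_im(np.eye(4) * 5)) == pytest.approx(1.0)

    def test_outer_product_is_perfectly_generalized(self):
        r = np.array([4.0, 2.0, 2.0])
        c = np.array([3.0, 3.0, 2.0])
        assert specialization_h2(_im(np.outer(r, c) / 8.0)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            specialization_h2(_im([[1.0, 2.0]]))

    def test_matches_brute_force_enumeration(self):
        # random small integer matrices: H2' with exhaustive-search H2min
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 20:
            w = rng.multinomial(int(rng.integers(5, 13)), np.ones(9) / 9).reshape(3, 3)
            if (w.sum(1) == 0).any() or (w.sum(0) == 0).any():
                continue
            m = _im(w)
            total = w.sum()
            p = w.ravel() / total
            p = p[p > 0]
            h2 = float(-(p * np.log(p)).sum())
            pr, pc = w.sum(1) / total, w.sum(0) / total
            h2max = float(-(pr * np.log(pr)).sum() - (pc * np.log(pc)).sum())
            h2min = brute_force_h2min(w.sum(1), w.sum(0), total)
            expected = (
                0.0
                if h2max - h2min < 1e-12
                else np.clip((h2max - h2) / (h2max - h2min), 0, 1)
            )
            assert specialization_h2(m) == pytest.approx(expected, abs=1e-10)
            checked += 1


class TestWeightedConnectance:
    def test_single_cell(self):
        assert weighted_connectance(_im([[7.0]])) == pytest.approx(0.5)

    def test_uniform_complete_matrix(self):
        assert weighted_connectance(_im(np.full((3, 5), 2.0))) == pytest.approx(0.5)

    def test_equal_weight_diagonal(self):
        n = 6
        assert weighted_connectance(_im(np.eye(n) * 3)) == pytest.approx(1 / (2 * n))


class TestWnodf:
    def test_hand_computed_nested(self):
        assert wnodf(_im([[3, 2], [1, 0]])) == pytest.approx(100.0)

    def test_checkerboard_ties_force_zero(self):
        assert wnodf(_im([[1, 0], [0, 1]])) == pytest.approx(0.0)

    def test_permutation_invariance(self, random_interaction):
        rng = np.random.default_rng(0)
        pr, pc = rng.permutation(10), rng.permutation(30)
        permuted = _im(random_interaction.w[np.ix_(pr, pc)])
        assert wnodf(permuted) == pytest.approx(wnodf(random_interaction))

    def test_matches_vegan_on_strictly_ordered_matrix(self):
        # a staircase whose row and column fills and totals are all strictly
        # decreasing: the totals-based and fill-based rules coincide
        w = np.array(
            [[8, 5, 3, 1], [6, 4, 2, 0], [5, 3, 0, 0], [4, 0, 0, 0]],
            dtype=float,
        )
        mine = wnodf(_im(w))
        flat = ",".join(str(int(v)) for v in w.ravel())
        r_code = (
            "suppressMessages(library(vegan));"
            f"m <- matrix(c({flat}), nrow=4, byrow=TRUE);"
            'cat(unname(nestednodf(m, weighted=TRUE)$statistic["NODF"]))'
        )
        proc = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        assert mine == pytest.approx(float(proc.stdout), abs=1e-4)


class TestModularity:
    def test_one_module_partition_scores_zero(self):
        m = _im(np.outer([2.0, 1.0], [1.0, 3.0]))
        q = modularity_q(m, np.zeros(2, dtype=int), np.zeros(2, dtype=int))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_blocks(self):
        w = np.zeros((4, 6))
        w[:2, :3] = 2.0
        w[2:, 3:] = 2.0
        res = modularity(_im(w), n_restarts=5, seed=0)
        assert res.Q == pytest.approx(0.5, abs=1e-12)
        assert res.n_modules == 2
        mods = res.module_of
        assert mods["p0"] == mods["p1"] == mods["f0"]
        assert mods["p2"] == mods["p3"] == mods["f5"]
        assert mods["p0"] != mods["p2"]

    def test_matches_exhaustive_partition_search(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            n, m = rng.integers(2, 4, 2)
            if n + m > 6:
                continue
            w = rng.integers(0, 5, (n, m)).astype(float)
            if (w.sum(1) == 0).any() or (w.sum(0) == 0).any():
                continue
            mat = _im(w)
            best = -np.inf
            for part in set_partitions(list(range(n + m))):
                rl = np.zeros(n, int)
                cl = np.zeros(m, int)
                for g, members in enumerate(part):
                    for x in members:
                        if x < n:
                            rl[x] = g
                        else:
                            cl[x - n] = g
                best = max(best, modularity_q(mat, rl, cl))
            assert modularity(mat, n_restarts=10, seed=1).Q == pytest.approx(
                best, abs=1e-10
            )

    def test_reproducible_under_seed(self, random_interaction):
        a = modularity(random_interaction, n_restarts=5, seed=9)
        b = modularity(random_interaction, n_restarts=5, seed=9)
        assert a.Q == b.Q and a.module_of == b.module_of


class TestMetricInvariances:
    @pytest.mark.parametrize(
        "metric",
        [
            specialization_h2,
            weighted_connectance,
            wnodf,
            lambda m: modularity(m, n_restarts=4, seed=0).Q,
        ],
        ids=["h2", "connectance", "wnodf", "modularity"],
    )
    def test_permutation_and_scale_invariance(self, metric, random_interaction):
        base = metric(random_interaction)
        rng = np.random.default_rng(1)
        pr, pc = rng.permutation(10), rng.permutation(30)
        permuted = _im(random_interaction.w[np.ix_(pr, pc)])
        scaled = _im(random_interaction.w * 4.0)
        assert metric(permuted) == pytest.approx(base, abs=1e-9)
        assert metric(scaled) == pytest.approx(base, abs=1e-9)
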