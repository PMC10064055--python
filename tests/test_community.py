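import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from phyllonet import (
    DistanceMatrix,
    OtuTable,
    anosim,
    bray_curtis,
    hellinger,
    mantel,
    nmds,
    paired_t_log,
)


def _dm(points):
    n = len(points)
    return DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(points)))


class TestHellinger:
    def test_single_taxon_row(self):
        t = OtuTable(["s"], ["a", "b"], np.array([[4, 0]]))
        assert np.allclose(hellinger(t), [[1.0, 0.0]])

    def test_even_row(self):
        t = OtuTable(["s"], ["a", "b"], np.array([[1, 1]]))
        assert np.allclose(hellinger(t), np.sqrt(0.5))

    def test_rows_have_unit_sum_of_squares(self):
        rng = np.random.default_rng(0)
        t = OtuTable(
            [f"s{i}" for i in range(4)],
            [f"o{j}" for j in range(7)],
            rng.integers(1, 50, (4, 7)),
        )
        assert np.allclose((hellinger(t) ** 2).sum(axis=1), 1.0)

    def test_zero_total_sample_named(self):
        t = OtuTable(["good", "empty"], ["a"], np.array([[3], [0]]))
        with pytest.raises(ValueError, match="empty"):
            hellinger(t)


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        d = bray_curtis(np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        assert d.d[0, 1] == 0.0
        assert d.d[0, 2] == 1.0

    def test_hand_value(self):
        d = bray_curtis(np.array([[2.0, 1.0], [1.0, 1.0]]))
        assert d.d[0, 1] == pytest.approx(0.2)

    def test_two_all_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]]))

    def test_bounded_and_permutation_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 9))
        d = bray_curtis(hellinger(OtuTable(
            [f"s{i}" for i in range(6)], [f"o{j}" for j in range(9)],
            rng.integers(1, 100, (6, 9)))))
        assert np.all(d.d >= 0) and np.all(d.d <= 1)
        perm = rng.permutation(6)
        d2 = bray_curtis(x[perm])
        d1 = bray_curtis(x)
        assert np.allclose(d1.d[np.ix_(perm, perm)], d2.d)


class TestNmds:
    def test_recovers_embeddable_configuration(self):
        pts = np.random.default_rng(2).random((10, 2))
        res = nmds(_dm(pts), k=2, n_starts=8, seed=0)
        assert res.stress < 1e-3

    def test_three_points_embed_exactly(self):
        pts = np.random.default_rng(3).random((3, 3))
        res = nmds(_dm(pts), k=2, n_starts=4, seed=0)
        assert res.stress < 1e-6

    def test_deterministic_under_seed(self):
        pts = np.random.default_rng(4).random((8, 4))
        r1 = nmds(_dm(pts), seed=7)
        r2 = nmds(_dm(pts), seed=7)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coordinates, r2.coordinates)

    def test_coordinates_centered(self):
        pts = np.random.default_rng(5).random((9, 4))
        res = nmds(_dm(pts), seed=1)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-12)

    def test_k_too_large_rejected(self):
        # 4 points always embed in 3 dimensions; k=4 is meaningless
        pts = np.random.default_rng(6).random((4, 2))
        with pytest.raises(ValueError):
            nmds(_dm(pts), k=4)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        pts = np.vstack([np.zeros((4, 2)), np.ones((4, 2)) * 10])
        pts += np.random.default_rng(0).random((8, 2)) * 0.01
        d = _dm(pts)
        groups = {f"s{i}": "a" if i < 4 else "b" for i in range(8)}
        res = anosim(d, groups, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_singleton_group_rejected(self):
        pts = np.random.default_rng(1).random((4, 2))
        with pytest.raises(ValueError):
            anosim(_dm(pts), {"s0": "a", "s1": "b", "s2": "b", "s3": "b"})

    def test_p_respects_permutation_floor(self):
        pts = np.random.default_rng(2).random((8, 3))
        groups = {f"s{i}": "a" if i < 4 else "b" for i in range(8)}
        res = anosim(_dm(pts), groups, n_perm=99, seed=3)
        assert res.p_value >= 1 / 100

    def test_statistic_matches_scikit_bio(self):
        import skbio

        rng = np.random.default_rng(7)
        pts = rng.random((9, 4))
        d = _dm(pts)
        groups = {f"s{i}": "a" if i < 4 else "b" for i in range(9)}
        ours = anosim(d, groups, n_perm=49, seed=0).statistic
        sk = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d.d, d.ids),
            [groups[i] for i in d.ids],
            permutations=9,
        )["test statistic"]
        assert ours == pytest.approx(sk, abs=1e-12)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(8)
        rs = []
        for s in range(300):
            pts = rng.random((10, 3))
            groups = {f"s{i}": "a" if i < 5 else "b" for i in range(10)}
            rs.append(anosim(_dm(pts), groups, n_perm=1, seed=s).statistic)
        assert abs(np.mean(rs)) < 0.02


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _dm(np.random.default_rng(0).random((7, 3)))
        res = mantel(d, d, tail="greater", n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_affine_anticorrelation(self):
        d = _dm(np.random.default_rng(1).random((6, 3)))
        flipped = np.where(np.eye(d.n, dtype=bool), 0.0, d.d.max() - d.d)
        res = mantel(d, DistanceMatrix(d.ids, flipped), tail="less", n_perm=99, seed=0)
        assert res.statistic == pytest.approx(-1.0)

    def test_statistic_matches_scikit_bio(self):
        from skbio.stats.distance import mantel as sk_mantel
        import skbio

        rng = np.random.default_rng(2)
        d1, d2 = _dm(rng.random((8, 3))), _dm(rng.random((8, 3)))
        ours = mantel(d1, d2, tail="greater", n_perm=9, seed=0).statistic
        sk_r = sk_mantel(
            skbio.DistanceMatrix(d1.d, d1.ids),
            skbio.DistanceMatrix(d2.d, d2.ids),
            permutations=0,
        )[0]
        assert ours == pytest.approx(sk_r, abs=1e-12)

    def test_zero_variance_rejected(self):
        ids = ["a", "b", "c"]
        const = DistanceMatrix(ids, np.ones((3, 3)) - np.eye(3))
        d = _dm(np.random.default_rng(3).random((3, 2)))
        d = DistanceMatrix(ids, d.d)
        with pytest.raises(ValueError):
            mantel(const, d)


class TestPairedTLog:
    def test_identical_inputs(self):
        a = {"x": 2.0, "y": 3.0, "z": 5.0}
        res = paired_t_log(a, dict(a), tail="two-sided")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_ratio_has_zero_variance(self):
        a = {"x": 2.0, "y": 4.0}
        b = {"x": 1.0, "y": 2.0}
        with pytest.raises(ValueError, match="variance"):
            paired_t_log(a, b)

    def test_one_tailed_p_from_t_distribution(self):
        # construct 11 pairs whose log-differences give exactly t = 1.92
        n, t_target = 11, 1.92
        eps = np.arange(n, dtype=float)
        eps = (eps - eps.mean()) / eps.std(ddof=1)
        diffs = t_target / np.sqrt(n) + eps  # mean/sd(ddof=1)/sqrt(n) = t/n...
        a = {f"h{i}": float(np.exp(d)) for i, d in enumerate(diffs)}
        b = {f"h{i}": 1.0 for i in range(n)}
        res = paired_t_log(a, b, tail="greater")
        assert res.statistic == pytest.approx(1.92, abs=1e-9)
        assert res.p_value == pytest.approx(0.042, abs=0.001)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            paired_t_log({"x": 1.0, "y": 0.0}, {"x": 1.0, "y": 1.0})
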