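import subprocess

import numpy as np
import pytest

from phyllonet import (
    blomberg_k,
    bm_covariance,
    cophenetic_distances,
    pagel_lambda,
    read_newick,
    simulate_trait_bm,
    simulate_tree,
)
from phyllonet.phylo import parse_newick
from phyllonet.simulate import _bm_cholesky


class TestNewickIO:
    def test_cherry(self):
        t = parse_newick("(A:1,B:1):0;")
        assert t.n_tips == 2
        assert t.tip_depths() == {"A": 1.0, "B": 1.0}

    def test_round_trip_preserves_cophenetic(self, tmp_path, tree11):
        path = tmp_path / "t.nwk"
        tree11.write_newick(path)
        back = read_newick(path)
        assert back.tip_labels == tree11.tip_labels
        assert np.allclose(
            cophenetic_distances(back).d, cophenetic_distances(tree11).d
        )

    def test_malformed_string_rejected(self):
        with pytest.raises(ValueError, match="parse"):
            parse_newick("((A:1,B:1:0;")


class TestCopheneticDistances:
    def test_cherry_distance(self):
        assert cophenetic_distances(parse_newick("(A:1,B:1):0;")).d[0, 1] == 2.0

    def test_ultrametric_three_point_condition(self, tree11):
        d = cophenetic_distances(tree11).d
        n = d.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    a, b, c = sorted([d[i, j], d[i, k], d[j, k]])
                    assert b == pytest.approx(c, abs=1e-9)

    def test_matches_dendropy_path_sums(self):
        # independent oracle: dendropy's own patristic distance machinery
        tree = simulate_tree(9, seed=17)
        mine = cophenetic_distances(tree)
        pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
        for i, a in enumerate(mine.ids):
            for j in range(i + 1, len(mine.ids)):
                ref = pdm.patristic_distance(taxa[a], taxa[mine.ids[j]])
                assert mine.d[i, j] == pytest.approx(ref, abs=1e-12)


class TestBmCovariance:
    def test_lambda_zero_is_diagonal_of_depths(self, tree11):
        v = bm_covariance(tree11, lambda_scale=0.0)
        depths = tree11.tip_depths()
        assert np.allclose(v, np.diag([depths[t] for t in tree11.tip_labels]))

    def test_cherry_without_stem_is_identity(self):
        v = bm_covariance(parse_newick("(A:1,B:1):0;"))
        assert np.allclose(v, np.eye(2))

    def test_positive_semidefinite_on_random_trees(self):
        for seed in range(50):
            v = bm_covariance(simulate_tree(10, seed=seed))
            assert np.linalg.eigvalsh(v).min() > -1e-10

    def test_consistent_with_cophenetic(self, tree11):
        v = bm_covariance(tree11)
        d = cophenetic_distances(tree11).d
        depths = np.diag(v)
        assert np.allclose(d, depths[:, None] + depths[None, :] - 2 * v, atol=1e-12)


class TestBlombergK:
    def test_mean_near_one_under_brownian_motion(self):
        ks = []
        rng = np.random.default_rng(0)
        for ti in range(4):
            tree = simulate_tree(64, seed=100 + ti)
            chol = _bm_cholesky(tree, 1.0, 1.0)
            for _ in range(25):
                x = chol @ rng.standard_normal(64)
                trait = dict(zip(tree.tip_labels, x))
                ks.append(blomberg_k(tree, trait, n_perm=0).estimate)
        assert 0.85 < np.mean(ks) < 1.15

    def test_iid_traits_low_k_calibrated_p(self):
        tree = simulate_tree(32, seed=7)
        ks, ps = [], []
        for s in range(120):
            trait = simulate_trait_bm(tree, 0.0, 1.0, seed=s)
            res = blomberg_k(tree, trait, n_perm=99, seed=s)
            ks.append(res.estimate)
            ps.append(res.p_value)
        assert np.mean(ks) < 0.6  # well below the Brownian expectation
        rej = np.mean(np.asarray(ps) <= 0.05)
        assert 0.0 <= rej <= 0.12  # near-nominal type-I error

    def test_constant_trait_rejected(self, tree11):
        with pytest.raises(ValueError):
            blomberg_k(tree11, {t: 1.0 for t in tree11.tip_labels})


class TestPagelLambda:
    def test_loglik_at_mle_beats_endpoints(self, tree11):
        from phyllonet.phylo import _lambda_loglik

        trait = simulate_trait_bm(tree11, 0.7, 1.0, seed=5)
        res = pagel_lambda(tree11, trait)
        x = np.array([trait[t] for t in tree11.tip_labels])
        for lam in (0.0, 1.0):
            assert res.log_likelihoods[0] >= _lambda_loglik(lam, x, tree11) - 1e-9

    def test_lr_statistic_nonnegative_and_boundary_p_one(self):
        tree = simulate_tree(16, seed=3)
        for s in range(10):
            trait = simulate_trait_bm(tree, 0.0, 1.0, seed=s)
            res = pagel_lambda(tree, trait)
            ll_hat, ll0 = res.log_likelihoods
            assert ll_hat >= ll0 - 1e-9
            if res.estimate == 0.0:
                assert res.p_value == 1.0

    def test_recovery_at_both_extremes(self):
        hit1 = hit0 = 0
        for rep in range(40):
            tree = simulate_tree(64, seed=200 + rep % 5)
            hit1 += pagel_lambda(tree, simulate_trait_bm(tree, 1.0, 1.0, seed=rep)).estimate >= 0.8
            hit0 += pagel_lambda(tree, simulate_trait_bm(tree, 0.0, 1.0, seed=rep)).estimate <= 0.2
        assert hit1 >= 36 and hit0 >= 36


class TestAgainstRPhytools:
    def test_k_and_lambda_match_phytools(self):
        tree = simulate_tree(12, seed=3)
        trait = simulate_trait_bm(tree, 1.0, 1.0, seed=4)
        mine_k = blomberg_k(tree, trait, n_perm=0).estimate
        mine_l = pagel_lambda(tree, trait)
        newick = tree.as_newick().replace("'", "")
        vals = ",".join(repr(float(trait[t])) for t in tree.tip_labels)
        names = ",".join(f'"{t}"' for t in tree.tip_labels)
        r_code = (
            "suppressMessages(library(phytools));"
            f'tr <- read.tree(text="{newick}");'
            f"x <- c({vals}); names(x) <- c({names});"
            'k <- phylosig(tr, x, method="K");'
            'l <- phylosig(tr, x, method="lambda");'
            'cat(as.numeric(k), l$lambda, l$logL, sep="\\n")'
        )
        proc = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        r_k, r_lambda, r_logl = map(float, proc.stdout.split())
        assert mine_k == pytest.approx(r_k, rel=1e-5)
        # phytools bounds lambda slightly above 0; compare loosely at the boundary
        assert mine_l.estimate == pytest.approx(r_lambda, abs=1e-3)
        assert mine_l.log_likelihoods[0] == pytest.approx(r_logl, abs=1e-3)
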