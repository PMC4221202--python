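"""Phylogenetic signal, contrasts, and the mass-residual workflow."""

import numpy as np
import pandas as pd
import pytest

from snoutshape.phylo import (
    blomberg_k, contrast_correlation, independent_contrasts, mass_residuals,
    pagel_lambda,
)
from snoutshape.simulate import brownian_traits, simulate_yule
from snoutshape.trees import parse_newick, tree_vcv


def star_tree(n):
    return parse_newick("(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");")


def imbalanced_tree(n):
    """Fully pectinate (caterpillar) tree with unit branches."""
    newick = f"t0:{n - 1}.0"
    for i in range(1, n):
        newick = f"({newick},t{i}:{n - i}.0):1.0"
    return parse_newick(newick[: newick.rfind(":")] + ";")


class TestBlombergK:
    def test_star_tree_k_is_exactly_one(self, rng):
        tree = star_tree(8)
        trait = pd.Series(rng.normal(size=8), index=[f"t{i}" for i in range(8)])
        k, _ = blomberg_k(trait, tree, permutations=49, seed=1)
        assert k == pytest.approx(1.0, abs=1e-12)

    def test_iid_traits_on_imbalanced_tree_show_no_signal(self):
        tree = imbalanced_tree(16)
        ks, ps = [], []
        for seed in range(100):
            rng = np.random.default_rng(5_000 + seed)
            trait = pd.Series(rng.normal(size=16), index=[f"t{i}" for i in range(16)])
            k, p = blomberg_k(trait, tree, permutations=99, seed=rng)
            ks.append(k)
            ps.append(p)
        assert np.mean(ks) < 1.0
        assert np.mean(ps) > 0.2

    def test_affine_invariance(self, rng):
        tree = imbalanced_tree(8)
        trait = pd.Series(rng.normal(size=8), index=[f"t{i}" for i in range(8)])
        k1, _ = blomberg_k(trait, tree, permutations=9, seed=0)
        k2, _ = blomberg_k(3.2 * trait - 7.0, tree, permutations=9, seed=0)
        assert k1 == pytest.approx(k2, abs=1e-8)


class TestPagelLambda:
    def test_loglik_at_one_matches_direct_determinant_oracle(self, rng):
        tree = simulate_yule(10, rng=rng)
        trait = brownian_traits(tree, sigma2=2.0, rng=rng)
        from snoutshape.phylo import _lambda_loglik
        taxa = sorted(trait.index)
        c = tree_vcv(tree, taxa)
        x = trait.reindex(taxa).to_numpy()
        n = len(x)
        # independent direct-determinant evaluation of the BM likelihood
        cinv = np.linalg.inv(c)
        ones = np.ones(n)
        a = (ones @ cinv @ x) / (ones @ cinv @ ones)
        r = x - a
        s2 = r @ cinv @ r / n
        logl = float(
            -0.5 * n * np.log(2 * np.pi * s2)
            - 0.5 * np.log(np.linalg.det(c))
            - 0.5 * (r @ cinv @ r) / s2
        )
        assert _lambda_loglik(1.0, x, c) == pytest.approx(logl, abs=1e-6)

    def test_affine_invariance(self, rng):
        tree = simulate_yule(12, rng=rng)
        trait = brownian_traits(tree, rng=rng)
        lam1, _, _ = pagel_lambda(trait, tree)
        lam2, _, _ = pagel_lambda(-0.5 * trait + 11.0, tree)
        assert lam1 == pytest.approx(lam2, abs=1e-6)


class TestContrasts:
    def test_two_tip_closed_form(self):
        tree = parse_newick("(a:1.0,b:1.0);")
        cs = independent_contrasts(pd.Series({"a": 3.0, "b": 1.0}), tree)
        assert cs.contrasts.shape == (1,)
        assert abs(cs.contrasts[0]) == pytest.approx(2.0 / np.sqrt(2.0), abs=1e-12)

    def test_constant_trait_gives_zero_contrasts(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        cs = independent_contrasts(pd.Series({t: 4.2 for t in "abcd"}), tree)
        np.testing.assert_allclose(cs.contrasts, 0.0, atol=1e-12)

    def test_balanced_four_tip_hand_pruning_table(self):
        # hand-executed pruning on ((a:1,b:1):1,(c:1,d:1):1)
        # node ab: contrast (1-3)/sqrt(2), value 2, branch 1 + 1/2
        # node cd: contrast (6-2)/sqrt(2), value 4, branch 1 + 1/2
        # root:    contrast (2-4)/sqrt(3)
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        trait = pd.Series({"a": 1.0, "b": 3.0, "c": 6.0, "d": 2.0})
        cs = independent_contrasts(trait, tree)
        expected = sorted(
            [2.0 / np.sqrt(2.0), 4.0 / np.sqrt(2.0), 2.0 / np.sqrt(3.0)]
        )
        np.testing.assert_allclose(sorted(np.abs(cs.contrasts)), expected, atol=1e-12)
        cherry_cd = dict(zip(cs.node_ids, np.abs(cs.contrasts)))["c"]
        assert cherry_cd == pytest.approx(4.0 / np.sqrt(2.0), abs=1e-12)

    def test_count_equals_tips_minus_one(self, rng):
        tree = simulate_yule(17, rng=rng)
        trait = brownian_traits(tree, rng=rng)
        cs = independent_contrasts(trait, tree)
        assert cs.contrasts.shape == (16,)

    def test_bm_contrasts_standardised(self):
        # pooled contrasts from BM sims are ~ iid N(0, sigma2)
        pooled = []
        for seed in range(40):
            rng = np.random.default_rng(9_000 + seed)
            tree = simulate_yule(12, rng=rng)
            trait = brownian_traits(tree, sigma2=1.0, rng=rng)
            pooled.extend(independent_contrasts(trait, tree).contrasts)
        pooled = np.asarray(pooled)
        from scipy import stats
        assert stats.shapiro(pooled).pvalue > 0.01
        assert np.var(pooled) == pytest.approx(1.0, rel=0.2)


class TestContrastCorrelation:
    def test_perfect_concordance(self, rng):
        tree = simulate_yule(10, rng=rng)
        trait = brownian_traits(tree, rng=rng)
        cs = independent_contrasts(trait, tree)
        rho, _ = contrast_correlation(cs, cs, "spearman")
        tau, _ = contrast_correlation(cs, cs, "kendall")
        assert rho == pytest.approx(1.0)
        assert tau == pytest.approx(1.0)

    def test_anticoncordance_after_positivisation(self, rng):
        tree = simulate_yule(10, rng=rng)
        trait = brownian_traits(tree, rng=rng)
        cx = independent_contrasts(trait, tree)
        cy = independent_contrasts(-trait, tree)
        rho, _ = contrast_correlation(cx, cy, "spearman")
        assert rho == pytest.approx(-1.0)

    def test_type_one_error_of_independent_traits(self):
        rejections = 0
        trials = 300
        for seed in range(trials):
            rng = np.random.default_rng(70_000 + seed)
            tree = simulate_yule(16, rng=rng)
            cx = independent_contrasts(brownian_traits(tree, rng=rng), tree)
            cy = independent_contrasts(brownian_traits(tree, rng=rng), tree)
            _, p = contrast_correlation(cx, cy, "spearman")
            rejections += p < 0.05
        assert 0.03 <= rejections / trials <= 0.07


class TestMassResiduals:
    def test_exact_linear_relationship_gives_zero_residuals(self):
        mass = pd.Series({f"s{i}": 10.0 ** (3 + i) for i in range(5)})
        score = pd.Series({f"s{i}": 2.0 * (3 + i) - 1.0 for i in range(5)})
        resid = mass_residuals(score, mass)
        np.testing.assert_allclose(resid.to_numpy(), 0.0, atol=1e-10)

    def test_residuals_sum_to_zero(self, rng):
        ids = [f"s{i}" for i in range(10)]
        mass = pd.Series(np.exp(rng.normal(11, 1, 10)), index=ids)
        score = pd.Series(rng.normal(size=10), index=ids)
        assert mass_residuals(score, mass).sum() == pytest.approx(0.0, abs=1e-10)

    def test_slope_matches_normal_equations_oracle(self, rng):
        ids = [f"s{i}" for i in range(5)]
        mass = pd.Series([1e3, 1e4, 2e4, 1e5, 5e5], index=ids)
        score = pd.Series([0.2, -0.1, 0.5, 0.9, 0.3], index=ids)
        x = np.log10(mass.to_numpy())
        y = score.to_numpy()
        slope = (np.sum(x * y) - len(x) * x.mean() * y.mean()) / (
            np.sum(x * x) - len(x) * x.mean() ** 2
        )
        intercept = y.mean() - slope * x.mean()
        resid = mass_residuals(score, mass)
        np.testing.assert_allclose(
            resid.to_numpy(), y - (slope * x + intercept), atol=1e-10
        )

    def test_constant_mass_rejected(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError, match="constant"):
            mass_residuals(
                pd.Series([1.0, 2.0, 3.0], index=ids),
                pd.Series([5.0, 5.0, 5.0], index=ids),
            )
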