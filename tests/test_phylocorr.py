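"""Phylogeny-corrected correlation: reduction to ordinary Pearson, the
independent-contrasts oracle at lambda = 1, lambda recovery, and the
r^2 / adjusted-r^2 / p arithmetic."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from evoscreen import (
    PagelLambdaCorrelation,
    ValidationError,
    correlation_stats,
    fit_lambda_ml,
    phylo_pearson,
    tree_vcv,
)
from evoscreen.datasets import SimulationConfig, simulate_tree_and_traits
from conftest import random_binary_tree, star_tree


def pic_correlation(tree: dendropy.Tree, traits: pd.DataFrame) -> float:
    """Independent oracle: Felsenstein contrasts, correlation through the
    origin, computed by explicit pruning."""
    x = dict(zip(traits["species"], traits["x"].astype(float)))
    y = dict(zip(traits["species"], traits["y"].astype(float)))
    cx, cy = [], []

    def prune(node):
        # returns (x value, y value, extra branch length to add above)
        if node.is_leaf():
            return x[node.taxon.label], y[node.taxon.label], node.edge.length or 0.0
        children = [prune(ch) for ch in node.child_nodes()]
        (xa, ya, va), (xb, yb, vb) = children
        cx.append((xa - xb) / np.sqrt(va + vb))
        cy.append((ya - yb) / np.sqrt(va + vb))
        xanc = (xa / va + xb / vb) / (1 / va + 1 / vb)
        yanc = (ya / va + yb / vb) / (1 / va + 1 / vb)
        extra = va * vb / (va + vb)
        return xanc, yanc, (node.edge.length or 0.0) + extra

    prune(tree.seed_node)
    cx, cy = np.asarray(cx), np.asarray(cy)
    return float(np.sum(cx * cy) / np.sqrt(np.sum(cx**2) * np.sum(cy**2)))


class TestVCV:
    def test_hand_tree(self, small_tree):
        C, labels = tree_vcv(small_tree, tip_order=["A", "B", "C"])
        expected = np.array([[1.5, 0.5, 0.0], [0.5, 2.5, 0.0], [0.0, 0.0, 3.0]])
        assert C == pytest.approx(expected)

    def test_symmetric_psd_on_random_trees(self, rng):
        for _ in range(10):
            tree = random_binary_tree(12, rng)
            C, _ = tree_vcv(tree)
            assert C == pytest.approx(C.T)
            assert np.linalg.eigvalsh(C).min() > -1e-10


class TestPhyloPearson:
    def test_lambda_zero_equals_ordinary_pearson(self):
        cfg = SimulationConfig(seed=4, n_tips=8)
        tree, _ = simulate_tree_and_traits(cfg)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        traits = pd.DataFrame(
            {"species": labels[:4], "x": [1, 2, 3, 4], "y": [1, 3, 2, 4]}
        )
        # restrict to 4 tips: prune the tree to those species
        sub = tree.extract_tree_with_taxa_labels(labels[:4])
        res = phylo_pearson(traits, sub, lam=0.0)
        assert res.r == pytest.approx(0.8, abs=1e-10)

    def test_star_tree_equals_pearson_for_any_lambda(self, rng):
        tree = star_tree(10)
        traits = pd.DataFrame(
            {
                "species": [f"S{i}" for i in range(10)],
                "x": rng.normal(size=10),
                "y": rng.normal(size=10),
            }
        )
        expected = float(np.corrcoef(traits["x"], traits["y"])[0, 1])
        for lam in (0.0, 0.37, 1.0):
            res = phylo_pearson(traits, tree, lam)
            assert res.r == pytest.approx(expected, abs=1e-10)

    def test_perfect_correlation(self):
        tree = star_tree(6)
        traits = pd.DataFrame(
            {
                "species": [f"S{i}" for i in range(6)],
                "x": [1.0, 2, 3, 4, 5, 6],
                "y": [2.0, 4, 6, 8, 10, 12],
            }
        )
        res = phylo_pearson(traits, tree, 0.0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value > 0  # smallest representable, never exactly zero

    def test_lambda_one_matches_contrasts_oracle(self, rng):
        for i in range(100):
            n = int(rng.integers(5, 15))
            tree = random_binary_tree(n, rng)
            labels = [l.taxon.label for l in tree.leaf_node_iter()]
            traits = pd.DataFrame(
                {
                    "species": labels,
                    "x": rng.normal(size=n),
                    "y": rng.normal(size=n),
                }
            )
            gls = phylo_pearson(traits, tree, 1.0).r
            pic = pic_correlation(tree, traits)
            assert gls == pytest.approx(pic, abs=1e-8)

    def test_species_missing_from_tree_rejected(self, small_tree):
        traits = pd.DataFrame(
            {"species": ["A", "B", "Z"], "x": [1.0, 2, 3], "y": [1.0, 2, 3]}
        )
        with pytest.raises(ValidationError, match="Z"):
            phylo_pearson(traits, small_tree, 0.5)


class TestCorrelationStats:
    def test_adjusted_r2_arithmetic(self):
        r2, adj, _ = correlation_stats(np.sqrt(0.9), 13)
        assert r2 == pytest.approx(0.9)
        assert adj == pytest.approx(1 - 0.1 * 12 / 11)

    def test_null_and_perfect_cases(self):
        r2, adj, p = correlation_stats(0.0, 10)
        assert r2 == 0 and adj < 0 and p == pytest.approx(1.0)
        r2, adj, p = correlation_stats(1.0, 10)
        assert r2 == 1 and adj == 1 and 0 < p < 1e-300

    def test_adjusted_below_raw_r2(self, rng):
        for r in rng.uniform(-0.99, 0.99, 20):
            if abs(r) < 1e-6:
                continue
            r2, adj, _ = correlation_stats(float(r), 12)
            assert adj < r2

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            correlation_stats(0.5, 2)


class TestLambdaFit:
    def test_star_tree_flat_likelihood(self, rng):
        tree = star_tree(12)
        traits = pd.DataFrame(
            {
                "species": [f"S{i}" for i in range(12)],
                "x": rng.normal(size=12),
                "y": rng.normal(size=12),
            }
        )
        fit = fit_lambda_ml(traits, tree)
        assert fit.flat_likelihood
        assert fit.lambda_hat == 0.0

    def test_constant_x_rejected(self):
        tree = star_tree(6)
        traits = pd.DataFrame(
            {
                "species": [f"S{i}" for i in range(6)],
                "x": [1.0] * 6,
                "y": [1.0, 2, 3, 4, 5, 6],
            }
        )
        with pytest.raises(ValidationError, match="constant|singular"):
            fit_lambda_ml(traits, tree)

    @pytest.mark.parametrize("lam_true,bound", [(1.0, "lower"), (0.0, "upper")])
    def test_lambda_recovery_small(self, lam_true, bound):
        # reduced-size recovery check; the full-size version runs in the
        # acceptance suite
        ests = []
        for s in range(20):
            cfg = SimulationConfig(
                seed=s, n_tips=60, lambda_true=lam_true, trait_correlation=0.5
            )
            tree, traits = simulate_tree_and_traits(cfg)
            ests.append(fit_lambda_ml(traits, tree).lambda_hat)
        mean = float(np.mean(ests))
        if bound == "lower":
            assert mean >= 0.85
        else:
            assert mean <= 0.15


class TestEstimator:
    def test_headline_method_switches_with_signal(self):
        cfg = SimulationConfig(seed=9, n_tips=60, lambda_true=1.0,
                               trait_correlation=0.7)
        tree, traits = simulate_tree_and_traits(cfg)
        model = PagelLambdaCorrelation().fit(traits, tree)
        assert model.method_ == "lambda_corrected"
        assert model.result_.r == model.corrected_.r
        fixed = PagelLambdaCorrelation(lam=0.0).fit(traits, tree)
        assert fixed.method_ == "ordinary"
        assert fixed.result_.r == pytest.approx(fixed.ordinary_.r, abs=1e-10)
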