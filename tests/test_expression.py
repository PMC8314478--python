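"""Expression screens: BH adjustment vs a brute-force oracle, the NB Wald
test's null behaviour, the three-criterion venom-gland filter with boundary
cases, concentration statistics, and biased-gene classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from evoscreen import (
    ValidationError,
    bh_adjust,
    classify_biased,
    cumulative_concentration,
    identify_vggs,
    nb_de_test,
)
from conftest import expression_matrix_from_arrays


def bh_oracle(p):
    """Literal step-up: q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBHAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_constant(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.5, 0.5, 0.5]) == pytest.approx([0.5] * 3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.2])

    def test_agrees_with_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 51))
            p = rng.uniform(0, 1, n)
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)


class TestNBWaldTest:
    def test_identical_counts_are_null(self, rng):
        vals = rng.integers(1, 500, size=(50, 3))
        both = np.hstack([vals, vals])
        em = expression_matrix_from_arrays(
            both, [f"g{i}" for i in range(50)], ["a", "b"], 3, "counts"
        )
        res = nb_de_test(em, "a", "b")
        assert res["log2_fold_change"].abs().max() == 0.0
        assert (res["p_value"] >= 0.99).all()

    def test_all_zero_genes_excluded_and_reported(self):
        vals = np.array([[0, 0, 0, 0, 0, 0], [5, 6, 7, 8, 9, 10]])
        em = expression_matrix_from_arrays(
            vals, ["gz", "gk"], ["a", "b"], 3, "counts"
        )
        from evoscreen import NegativeBinomialWaldTest

        t = NegativeBinomialWaldTest("a", "b").fit(em)
        assert t.excluded_ == ["gz"]
        assert list(t.results_["gene_id"]) == ["gk"]

    def test_requires_counts_and_replication(self):
        em = expression_matrix_from_arrays(
            np.ones((3, 6)), ["g1", "g2", "g3"], ["a", "b"], 3, "FPKM"
        )
        with pytest.raises(ValidationError, match="counts"):
            nb_de_test(em, "a", "b")
        em2 = expression_matrix_from_arrays(
            np.ones((3, 2)), ["g1", "g2", "g3"], ["a", "b"], 1, "counts"
        )
        with pytest.raises(ValidationError, match="replicates"):
            nb_de_test(em2, "a", "b")

    def test_strong_signal_detected(self, rng):
        base = rng.poisson(200, size=(200, 3)).astype(float)
        up = rng.poisson(1600, size=(20, 3)).astype(float)
        vals = np.vstack(
            [
                np.hstack([np.vstack([up, base[:180]]), base]),
            ]
        )
        ids = [f"g{i}" for i in range(200)]
        em = expression_matrix_from_arrays(vals, ids, ["a", "b"], 3, "counts")
        res = nb_de_test(em, "a", "b").set_index("gene_id")
        planted = res.loc[[f"g{i}" for i in range(20)]]
        assert (planted["q_value"] < 0.05).mean() >= 0.9
        assert planted["log2_fold_change"].median() == pytest.approx(3.0, abs=0.3)


class TestVGGFilter:
    @staticmethod
    def five_gene_fixture():
        # vg medians: g1 1000, g2 600, g3 400, g4 200, g5 100
        vg = np.array(
            [[1000, 1000, 1000], [600, 600, 600], [400, 400, 400],
             [200, 200, 200], [100, 100, 100]],
            dtype=float,
        )
        cc = np.array(
            [[5, 5, 5], [50, 50, 50], [10, 10, 10], [120, 120, 120], [1, 1, 1]],
            dtype=float,
        )
        em = expression_matrix_from_arrays(
            np.hstack([vg, cc]),
            [f"g{i}" for i in range(1, 6)],
            ["venom_gland", "carcass"],
            3,
            "FPKM",
        )
        de = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(1, 6)],
                "log2_fold_change": [7.6, 3.6, 5.3, 0.7, -0.5],
                "q_value": [0.001, 0.02, 0.3, 0.001, 0.001],
            }
        )
        return em, de

    def test_criteria_applied_by_hand(self):
        em, de = self.five_gene_fixture()
        rec = identify_vggs(em, de, n_top=4).set_index("gene_id")
        # g1: all three criteria pass
        assert bool(rec.loc["g1", "is_vgg"])
        # g2: carcass median exactly 50 -> fails strict <
        assert not bool(rec.loc["g2", "passes_c"]) and not bool(rec.loc["g2", "is_vgg"])
        # g3: q = 0.3 fails criterion (b)
        assert not bool(rec.loc["g3", "passes_b"])
        # g4: carcass 120 fails (c)
        assert not bool(rec.loc["g4", "is_vgg"])
        # g5: rank 5 > n_top=4 -> not emitted at all
        assert "g5" not in rec.index
        # flagged genes come first
        assert rec["is_vgg"].to_numpy()[0] and not rec["is_vgg"].to_numpy()[-1]

    def test_rank_boundary_excludes_rank_beyond_n_top(self):
        em, de = self.five_gene_fixture()
        rec = identify_vggs(em, de, n_top=1).set_index("gene_id")
        assert list(rec.index) == ["g1"]

    def test_q_boundary_excluded(self):
        em, de = self.five_gene_fixture()
        de.loc[de["gene_id"] == "g1", "q_value"] = 0.05  # exactly the cutoff
        rec = identify_vggs(em, de, n_top=4).set_index("gene_id")
        assert not bool(rec.loc["g1", "passes_b"])

    def test_output_subset_of_top_n(self):
        em, de = self.five_gene_fixture()
        rec = identify_vggs(em, de, n_top=3)
        assert len(rec) == 3
        assert rec["is_vgg"].sum() <= 3


class TestCumulativeConcentration:
    def test_uniform_closed_form(self):
        assert cumulative_concentration([1.0] * 100, 0.8) == 80

    def test_simple_arithmetic(self):
        assert cumulative_concentration([50, 30, 20], 0.8) == 2

    def test_single_dominant_gene(self):
        v = [1000.0] + [0.0] * 99
        for f in (0.1, 0.5, 1.0):
            assert cumulative_concentration(v, f) == 1

    def test_all_zero_and_bad_fraction_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_concentration([0.0, 0.0], 0.8)
        with pytest.raises(ValidationError):
            cumulative_concentration([1.0], 1.5)

    @settings(deadline=None, max_examples=50)
    @given(
        v=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=200)
        .filter(lambda v: sum(v) > 0)
    )
    def test_monotone_in_fraction(self, v):
        assert cumulative_concentration(v, 0.8) <= cumulative_concentration(v, 0.9)


class TestClassifyBiased:
    DE = pd.DataFrame(
        {
            "gene_id": ["up_small", "up_pass", "boundary", "q_boundary", "down"],
            "log2_fold_change": [1.5, 4.1, 4.0, 5.0, -4.5],
            "q_value": [0.01, 0.01, 0.01, 0.05, 0.001],
        }
    )

    def test_fold_arithmetic_and_boundaries(self):
        res = classify_biased(self.DE, min_fold=16, q_max=0.05, direction="up")
        # 2^4.1 ~ 17.1 > 16 passes; 2^4.0 = 16 exactly fails strict >;
        # q = 0.05 exactly fails strict <
        assert list(res["gene_id"]) == ["up_pass"]
        assert res["fold_change"].iloc[0] == pytest.approx(2**4.1)

    def test_direction_filters_sign(self):
        down = classify_biased(self.DE, min_fold=16, direction="down")
        assert list(down["gene_id"]) == ["down"]
        both = classify_biased(self.DE, min_fold=16, direction="both")
        assert set(both["gene_id"]) == {"up_pass", "down"}

    def test_threshold_monotone(self):
        at4 = set(classify_biased(self.DE, min_fold=4)["gene_id"])
        at16 = set(classify_biased(self.DE, min_fold=16)["gene_id"])
        assert at16 <= at4

    def test_min_fold_must_exceed_one(self):
        with pytest.raises(ValidationError):
            classify_biased(self.DE, min_fold=1.0)
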