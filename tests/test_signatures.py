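"""Count normalization and Welch-t signature construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mrsynergy import (
    ExpressionMatrix,
    compute_signature,
    is_represented,
    median_ratio_normalize,
    signature_de,
)


def _matrix(values, genes, samples, conditions):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), conditions)


class TestMedianRatioNormalize:
    def test_identical_columns_give_unit_factors(self):
        em = _matrix([[3.0, 3.0], [7.0, 7.0]], ["g1", "g2"], ["s1", "s2"], {"s1": "A", "s2": "B"})
        norm, sf = median_ratio_normalize(em)
        assert np.allclose(sf.factors, 1.0)
        assert np.allclose(norm.values, em.values)

    def test_hand_computed_factors(self):
        # geometric means sqrt(8), sqrt(128); ratios give factors 1/sqrt(2), sqrt(2)
        em = _matrix([[2.0, 4.0], [8.0, 16.0]], ["g1", "g2"], ["s1", "s2"], {"s1": "A", "s2": "B"})
        norm, sf = median_ratio_normalize(em)
        assert np.allclose(sf.factors, [2 ** -0.5, 2 ** 0.5], atol=1e-4)
        assert np.allclose(norm.values["s1"], norm.values["s2"])

    @given(c=st.floats(0.1, 10.0))
    def test_scale_equivariance_of_factor_ratios(self, c):
        """Rescaling one column by c multiplies its factor by c *relative to the
        others* and changes the normalized matrix only by one global scalar."""
        rng = np.random.default_rng(5)
        vals = rng.integers(1, 100, size=(20, 4)).astype(float)
        conditions = {f"s{j}": "A" for j in range(4)}
        base = _matrix(vals, [f"g{i}" for i in range(20)], list(conditions), conditions)
        scaled_vals = vals.copy()
        scaled_vals[:, 0] *= c
        scaled = _matrix(scaled_vals, [f"g{i}" for i in range(20)], list(conditions), conditions)
        norm0, sf0 = median_ratio_normalize(base)
        norm1, sf1 = median_ratio_normalize(scaled)
        ratio0 = sf0.factors.iloc[0] / sf0.factors.iloc[1]
        ratio1 = sf1.factors.iloc[0] / sf1.factors.iloc[1]
        assert np.isclose(ratio1, c * ratio0, rtol=1e-9)
        scale = norm1.values.iloc[0, 1] / norm0.values.iloc[0, 1]
        assert np.allclose(norm1.values, norm0.values * scale, rtol=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(11)
        vals = rng.poisson(50, size=(50, 6)).astype(float) + 1
        conditions = {f"s{j}": "A" for j in range(6)}
        em = _matrix(vals, [f"g{i}" for i in range(50)], list(conditions), conditions)
        norm, _ = median_ratio_normalize(em)
        _, sf2 = median_ratio_normalize(norm)
        assert np.allclose(sf2.factors, 1.0, atol=1e-12)

    def test_negative_counts_rejected(self):
        em = _matrix([[1.0, -2.0]], ["g1"], ["s1", "s2"], {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="non-negative"):
            median_ratio_normalize(em)

    def test_no_qualifying_gene_advises_pseudocount(self):
        em = _matrix([[0.0, 5.0], [3.0, 0.0]], ["g1", "g2"], ["s1", "s2"], {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="pseudocount"):
            median_ratio_normalize(em)
        norm, sf = median_ratio_normalize(em, pseudocount=1.0)
        assert (sf.factors > 0).all()


class TestComputeSignature:
    def test_welch_example(self):
        em = _matrix(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            ["g1"],
            [f"s{i}" for i in range(6)],
            {f"s{i}": ("A" if i < 3 else "B") for i in range(6)},
        )
        sig = compute_signature(em, "A", "B")
        # means 2 vs 5, per-group var 1, se = sqrt(1/3 + 1/3)
        assert sig.scores["g1"] == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-3)

    def test_constant_gene_scores_zero(self):
        em = _matrix(
            [[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0]],
            ["flat", "var"],
            ["s1", "s2", "s3", "s4"],
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        sig = compute_signature(em, "A", "B")
        assert sig.scores["flat"] == 0.0

    def test_zero_variance_unequal_means_capped_not_infinite(self):
        em = _matrix(
            [[1.0, 1.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]],
            ["step", "var"],
            ["s1", "s2", "s3", "s4"],
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        sig = compute_signature(em, "A", "B")
        assert np.isfinite(sig.scores["step"])
        assert sig.scores["step"] > sig.scores["var"] > 0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(30, 6))
        samples = [f"s{i}" for i in range(6)]
        conditions = {s: ("A" if i < 3 else "B") for i, s in enumerate(samples)}
        em = _matrix(vals, [f"g{i}" for i in range(30)], samples, conditions)
        shuffled = [samples[i] for i in [2, 0, 1, 5, 3, 4]]
        em2 = ExpressionMatrix(em.values[shuffled], conditions)
        sig1 = compute_signature(em, "A", "B")
        sig2 = compute_signature(em2, "A", "B")
        assert np.allclose(sig1.scores.sort_index(), sig2.scores.sort_index())

    def test_missing_condition_label_rejected(self, tiny_expression):
        with pytest.raises(ValueError, match="absent"):
            compute_signature(tiny_expression, "A", "Z")

    def test_too_few_samples_rejected(self):
        em = _matrix([[1.0, 2.0, 3.0]], ["g1"], ["s1", "s2", "s3"],
                     {"s1": "A", "s2": "B", "s3": "B"})
        with pytest.raises(ValueError, match=">= 2 samples"):
            compute_signature(em, "A", "B")

    def test_null_scores_match_t_reference(self):
        """Under a per-gene Gaussian null the Welch t should reject ~5%."""
        rng = np.random.default_rng(42)
        n_genes, spc = 10_000, 3
        vals = rng.normal(size=(n_genes, 2 * spc))
        samples = [f"s{i}" for i in range(2 * spc)]
        conditions = {s: ("A" if i < spc else "B") for i, s in enumerate(samples)}
        em = _matrix(vals, [f"g{i}" for i in range(n_genes)], samples, conditions)
        sig = compute_signature(em, "A", "B")
        # independent Welch computation: statistic and Welch-Satterthwaite df
        a, b = vals[:, :spc], vals[:, spc:]
        va, vb = a.var(ddof=1, axis=1), b.var(ddof=1, axis=1)
        se2 = va / spc + vb / spc
        t_manual = (b.mean(1) - a.mean(1)) / np.sqrt(se2)
        assert np.allclose(np.sort(t_manual), np.sort(sig.scores.to_numpy()), atol=1e-10)
        # with equal group sizes the Welch statistic coincides with the pooled
        # t, which under this null is exactly t-distributed with 2(n-1) df
        from scipy import stats
        crit = stats.t.ppf(0.975, 2 * (spc - 1))
        frac = np.mean(np.abs(sig.scores.to_numpy()) > crit)
        assert frac == pytest.approx(0.05, abs=0.01)


class TestSignatureDE:
    def test_present_gene_returns_score(self, ladder_signature):
        assert signature_de(ladder_signature, "g03") == 8.0

    def test_absent_gene_is_not_represented_marker(self, ladder_signature):
        assert not is_represented(signature_de(ladder_signature, "missing"))

    def test_top_ranked_gene_has_maximal_score(self, ladder_signature):
        top = ladder_signature.genes[0]
        assert signature_de(ladder_signature, top) == ladder_signature.scores.max()
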