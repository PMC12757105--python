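"""Pool normalization, gene-level CNA calling and VAF allelic states."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apchits.cna import (
    AmpliconCountMatrix,
    gene_cna_call,
    normalize_by_pool,
    vaf_allelic_state,
)
from apchits.variants import VariantCall
from conftest import make_ratio_matrix


def single_pool_matrix(counts_by_sample):
    n = len(next(iter(counts_by_sample.values())))
    amplicons = pd.DataFrame({
        "amplicon_id": [f"a{i}" for i in range(n)],
        "gene": ["APC"] * n,
        "pool_id": ["pool1"] * n,
        "start": np.arange(n), "end": np.arange(n) + 150,
    })
    roles = {s: ("normal_reference" if s.startswith("N") else "tumor")
             for s in counts_by_sample}
    return AmpliconCountMatrix(
        amplicons=amplicons,
        counts=pd.DataFrame(counts_by_sample, index=amplicons["amplicon_id"]),
        sample_roles=roles,
    )


class TestNormalizeByPool:
    def test_hand_example_with_pseudocount(self):
        m = single_pool_matrix({"T1": [10, 30]})
        scaled = normalize_by_pool(m, pseudocount=0.5)
        assert scaled["T1"].to_numpy() == pytest.approx([10.5 / 41, 30.5 / 41])

    def test_three_amplicon_oracle(self):
        # independent arithmetic: (c + 0.5) / sum(c + 0.5)
        counts = [7, 0, 13]
        expected = [(c + 0.5) / (sum(counts) + 1.5) for c in counts]
        m = single_pool_matrix({"T1": counts})
        assert normalize_by_pool(m)["T1"].to_numpy() == pytest.approx(expected)

    def test_fractions_sum_to_one_per_pool_and_sample(self):
        rng = np.random.default_rng(0)
        n = 30
        amplicons = pd.DataFrame({
            "amplicon_id": [f"a{i}" for i in range(n)],
            "gene": ["G"] * n,
            "pool_id": [f"pool{i % 3}" for i in range(n)],
        })
        counts = pd.DataFrame(rng.integers(0, 5000, size=(n, 4)),
                              index=amplicons["amplicon_id"],
                              columns=["N1", "T1", "T2", "T3"])
        m = AmpliconCountMatrix(amplicons=amplicons, counts=counts,
                                sample_roles={"N1": "normal_reference",
                                              "T1": "tumor", "T2": "tumor",
                                              "T3": "tumor"})
        scaled = normalize_by_pool(m)
        pools = amplicons.set_index("amplicon_id")["pool_id"]
        for pool in pools.unique():
            sums = scaled.loc[pools[pools == pool].index].sum(axis=0)
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_scale_invariance_without_pseudocount(self):
        base = {"N1": [100, 220, 80], "T1": [50, 120, 40]}
        m1 = single_pool_matrix(base)
        m2 = single_pool_matrix({"N1": base["N1"], "T1": [10 * c for c in base["T1"]]})
        s1 = normalize_by_pool(m1, pseudocount=0.0)
        s2 = normalize_by_pool(m2, pseudocount=0.0)
        assert np.allclose(s1["T1"], s2["T1"])

    def test_all_zero_pool_warns_and_is_uniform(self):
        m = single_pool_matrix({"T1": [0, 0, 0]})
        with pytest.warns(UserWarning, match="zero total"):
            scaled = normalize_by_pool(m)
        assert np.allclose(scaled["T1"], 1 / 3)


class TestGeneCnaCall:
    def test_textbook_t_oracle(self):
        """t and p match the hand formula t = mean / (sd / sqrt(n)) on <=10 values."""
        log2r = np.array([-0.9, -1.1, -1.05, -0.8, -1.2, -0.95, -1.0])
        matrix, scaled = make_ratio_matrix(log2r)
        call = gene_cna_call(scaled, matrix, "APC", "T1", normal_ids=["N1"])
        t_manual = log2r.mean() / (log2r.std(ddof=1) / np.sqrt(len(log2r)))
        p_manual = 2 * stats.t.sf(abs(t_manual), len(log2r) - 1)
        assert call.t_statistic == pytest.approx(t_manual, abs=1e-10)
        assert call.p_value == pytest.approx(p_manual, abs=1e-12)
        assert call.degrees_of_freedom == len(log2r) - 1
        # cross-check the same numbers against scipy's implementation
        t_sp, p_sp = stats.ttest_1samp(log2r, 0.0)
        assert call.t_statistic == pytest.approx(t_sp)
        assert call.p_value == pytest.approx(p_sp)
        assert call.call == "loss"

    def test_degenerate_variance_is_no_call(self):
        matrix, scaled = make_ratio_matrix(np.zeros(8))
        call = gene_cna_call(scaled, matrix, "APC", "T1", normal_ids=["N1"])
        assert call.call == "no_call"
        assert call.p_value == 1.0
        assert call.t_statistic == 0.0

    def test_too_few_amplicons_is_no_call(self):
        matrix, scaled = make_ratio_matrix([0.0, -1.0, -1.0])
        call = gene_cna_call(scaled, matrix, "APC", "T1", normal_ids=["N1"])
        assert call.call == "no_call"
        assert "fewer than" in call.reason

    def test_simulated_single_copy_loss_detected(self):
        rng = np.random.default_rng(42)
        log2r = np.log2(0.5) + rng.normal(0, 0.1, size=12)
        matrix, scaled = make_ratio_matrix(log2r)
        call = gene_cna_call(scaled, matrix, "APC", "T1", normal_ids=["N1"])
        assert call.call == "loss"
        assert call.p_value < 0.05
        assert call.mean_log2_ratio < -0.32

    def test_significant_but_tiny_shift_stays_neutral(self):
        rng = np.random.default_rng(1)
        log2r = -0.05 + rng.normal(0, 0.01, size=12)
        matrix, scaled = make_ratio_matrix(log2r)
        call = gene_cna_call(scaled, matrix, "APC", "T1", normal_ids=["N1"])
        assert call.p_value < 0.05 and call.call == "neutral"

    def test_gain_called(self):
        rng = np.random.default_rng(2)
        log2r = 0.58 + rng.normal(0, 0.08, size=10)
        matrix, scaled = make_ratio_matrix(log2r)
        call = gene_cna_call(scaled, matrix, "APC", "T1", normal_ids=["N1"])
        assert call.call == "gain"

    def test_sliding_window_localizes_partial_loss(self):
        log2r = np.concatenate([np.zeros(8), np.full(6, -1.0)])
        log2r += np.random.default_rng(3).normal(0, 0.05, size=14)
        matrix, scaled = make_ratio_matrix(log2r)
        whole = gene_cna_call(scaled, matrix, "APC", "T1", normal_ids=["N1"])
        windowed = gene_cna_call(scaled, matrix, "APC", "T1", normal_ids=["N1"],
                                 window=5)
        assert windowed.mean_log2_ratio < whole.mean_log2_ratio
        assert windowed.call == "loss"

    def test_type_one_error_calibrated(self):
        """Neutral simulations reject at ~alpha (Monte-Carlo bound, 400 reps)."""
        rng = np.random.default_rng(7)
        n_rej = 0
        reps = 400
        for _ in range(reps):
            log2r = rng.normal(0, 0.1, size=12)
            matrix, scaled = make_ratio_matrix(log2r)
            call = gene_cna_call(scaled, matrix, "APC", "T1", normal_ids=["N1"])
            n_rej += call.p_value < 0.05
        bound = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(n_rej / reps - 0.05) < bound


class TestVafAllelicState:
    def make(self, vaf, depth, sample="T1"):
        return VariantCall(sample_id=sample, gene="APC", hgvs_c="c.1417C>T",
                           hgvs_p="p.Q473*", vaf=vaf, depth=depth,
                           origin="germline")

    def test_blood_low_vaf_is_postzygotic(self):
        state = vaf_allelic_state(self.make(0.167, 300, "blood"), "blood")
        assert state.state == "postzygotic_mosaic"
        assert state.p_value < 1e-6

    def test_tumor_half_is_balanced(self):
        assert vaf_allelic_state(self.make(0.50, 200), "tumor").state == "balanced"

    def test_tumor_low_vaf_is_decreased(self):
        assert vaf_allelic_state(self.make(0.257, 300), "tumor").state == "decreased"

    def test_tumor_high_vaf_is_increased(self):
        assert vaf_allelic_state(self.make(0.72, 300), "tumor").state == "increased"

    def test_normal_het_noise_not_flagged(self):
        # 0.45 at depth 300 deviates but sits above the mosaic ceiling
        state = vaf_allelic_state(self.make(0.42, 3000, "N1"), "normal")
        assert state.state != "postzygotic_mosaic"

    def test_zero_depth_indeterminate(self):
        assert vaf_allelic_state(self.make(0.3, 0), "tumor").state == "indeterminate"

    def test_binomial_p_matches_scipy(self):
        state = vaf_allelic_state(self.make(0.3, 100), "tumor")
        assert state.p_value == pytest.approx(stats.binomtest(30, 100, 0.5).pvalue)
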