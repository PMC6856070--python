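"""Normalization, dispersion, NB Wald test, BH, fold-change conventions."""

import numpy as np
import pandas as pd
import pytest

from wttsapa import (
    DEParams,
    bh_adjust,
    estimate_dispersion,
    median_of_ratios,
    nb_wald_test,
    run_de,
    signed_fold_change,
)
from wttsapa.differential import _wald_vectorized, mapq_filter
from wttsapa.simulate import simulate_count_matrix


def de_tables(n_sites=200, n_per_group=8, dispersion=0.1, seed=0, **kw):
    counts, treated, lfc = simulate_count_matrix(
        n_sites, n_per_group, dispersion, seed, **kw
    )
    samples = [f"s{i}" for i in range(counts.shape[1])]
    table = pd.DataFrame(counts, columns=samples)
    table.insert(0, "cluster_id", [f"c{i}" for i in range(n_sites)])
    table["mean_mapq"] = 60.0
    design = pd.DataFrame(
        {"sample_id": samples,
         "condition": ["treated" if t else "control" for t in treated]}
    )
    return table, design, treated, lfc


class TestMedianOfRatios:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[10], [50], [200]], (1, 2))
        np.testing.assert_allclose(median_of_ratios(counts), [1.0, 1.0])

    def test_doubled_sample_splits_geometrically(self):
        counts = np.array([[10, 20], [50, 100], [7, 14]])
        np.testing.assert_allclose(
            median_of_ratios(counts), [1 / np.sqrt(2), np.sqrt(2)], atol=1e-9
        )

    def test_global_scaling_leaves_factors_unchanged(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(40, (100, 4)) + 1
        np.testing.assert_allclose(
            median_of_ratios(counts), median_of_ratios(counts * 10), rtol=1e-12
        )

    def test_single_sample_scaling_is_equivariant(self):
        rng = np.random.default_rng(2)
        counts = (rng.poisson(40, (101, 4)) + 1).astype(float)
        scaled = counts.copy()
        scaled[:, 2] *= 3.0
        f0, f1 = median_of_ratios(counts), median_of_ratios(scaled)
        # factor of the scaled sample grows 3x up to the re-normalized reference
        assert f1[2] / f0[2] == pytest.approx(3.0 * (f1[0] / f0[0]), rel=1e-9)

    def test_no_allpositive_site_is_an_error(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            median_of_ratios(counts)

    def test_matches_deseq2_reference_implementation(self):
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(10, 0.1, size=(300, 6))
        _, sf = deseq2_norm(counts.T)
        np.testing.assert_allclose(
            median_of_ratios(counts), np.asarray(sf).ravel(), rtol=1e-10
        )


class TestDispersion:
    def test_poisson_counts_floor_the_median(self):
        counts, treated, _ = simulate_count_matrix(2000, 8, 0.0, 11)
        sf = median_of_ratios(counts)
        disp = estimate_dispersion(counts, sf, treated)
        assert np.median(disp) == pytest.approx(1e-8)

    def test_nb_dispersion_recovered(self):
        counts, treated, _ = simulate_count_matrix(2000, 8, 0.1, 12)
        sf = median_of_ratios(counts)
        disp = estimate_dispersion(counts, sf, treated)
        assert 0.05 <= np.median(disp) <= 0.2

    def test_constant_counts_hit_the_floor(self):
        counts = np.full((50, 16), 40)
        treated = np.arange(16) >= 8
        disp = estimate_dispersion(counts, np.ones(16), treated)
        assert np.all(disp == pytest.approx(1e-8))

    def test_requires_two_samples_per_condition(self):
        counts = np.full((5, 3), 10)
        with pytest.raises(ValueError):
            estimate_dispersion(counts, np.ones(3), np.array([True, False, False]))


class TestWald:
    def test_null_site_large_counts(self):
        counts = np.array([1000.0] * 16)
        treated = np.arange(16) >= 8
        lfc, p = nb_wald_test(counts, np.ones(16), 1e-8, treated)
        assert lfc == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_site_degenerate(self):
        counts = np.zeros(16)
        treated = np.arange(16) >= 8
        assert nb_wald_test(counts, np.ones(16), 0.1, treated) == (0.0, 1.0)

    def test_label_swap_negates_fold_changes_keeps_p(self):
        table, design, treated, _ = de_tables(seed=21)
        res1, _ = run_de(table, design, DEParams(mapq_min=0))
        design2 = design.copy()
        design2["condition"] = design2["condition"].map(
            {"treated": "control", "control": "treated"}
        )
        res2, _ = run_de(table, design2, DEParams(mapq_min=0))
        np.testing.assert_allclose(res2["log2_fc"], -res1["log2_fc"], atol=1e-10)
        np.testing.assert_allclose(res2["p_value"], res1["p_value"], atol=1e-10)
        np.testing.assert_allclose(res2["signed_fc"], -res1["signed_fc"], atol=1e-10)


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_dominates_raw_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "t,c,expected", [(8, 2, 4.0), (2, 8, -4.0), (5, 5, 1.0)]
    )
    def test_convention(self, t, c, expected):
        assert signed_fold_change(t, c, pseudocount=0.0) == pytest.approx(expected)

    def test_zero_means_finite_with_pseudocount(self):
        assert np.isfinite(signed_fold_change(0.0, 10.0, 0.5))


class TestMapqGate:
    def test_boundary_strict_less(self):
        df = pd.DataFrame(
            {"site_id": ["a", "b"], "p_value": [0.001, 0.001],
             "p_adj": [0.01, 0.01], "mean_mapq": [70.0, 69.9]}
        )
        flagged, removed = mapq_filter(df, DEParams())
        assert list(flagged["passed_mapq"]) == [True, False]
        assert list(removed["site_id"]) == ["b"]

    def test_empty_results(self):
        df = pd.DataFrame(columns=["site_id", "p_value", "p_adj", "mean_mapq"])
        flagged, removed = mapq_filter(df, DEParams())
        assert len(flagged) == 0 and len(removed) == 0


class TestRunDe:
    def test_summary_counts_consistent(self):
        table, design, _, lfc = de_tables(
            n_sites=500, seed=31, n_de=50, log2_effect=2.0, mean_range=(100, 300)
        )
        results, summary = run_de(table, design, DEParams(mapq_min=0))
        assert summary["n_tested"] == 500
        sig = results["p_value"] < 0.01
        assert summary["n_sig_raw"] == int(sig.sum())
        assert summary["n_up_raw"] + summary["n_down_raw"] == int(sig.sum())
        # planted up-shifts recovered with the right sign
        up_truth = lfc > 0
        assert (results.loc[up_truth & sig.to_numpy(), "signed_fc"] > 0).all()

    def test_padj_dominates_p(self):
        table, design, _, _ = de_tables(seed=41)
        results, _ = run_de(table, design, DEParams(mapq_min=0))
        assert (results["p_adj"] >= results["p_value"] - 1e-12).all()
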