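"""Enrichment scores, error model, replicate merging, centering, effect classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucleoscan import (
    center_scores,
    classify_effects,
    compute_enrichment,
    fit_error_model,
    merge_replicates,
    score_counts,
)
from nucleoscan.scoring import ErrorModel, poisson_log_moments
from nucleoscan.synthetic_data import simulate_experiment

from conftest import make_count_table


def _toy_table(mini_design, reps=3):
    wt = mini_design.wt_coding_seq
    rows = []
    for seq, base in [(wt, 1000), ("ATGGTTTTTAAA", 100), ("ATGGCCTTTAAA", 200)]:
        counts = {}
        for r in range(1, reps + 1):
            counts[f"input{r}"] = base
            counts[f"output{r}"] = base * 2
        rows.append((seq, counts))
    return make_count_table(mini_design, rows)


class TestEnrichment:
    def test_wild_type_scores_zero_in_every_replicate(self, mini_design):
        ns = compute_enrichment(_toy_table(mini_design))
        wt_row = ns.iloc[0]
        assert np.allclose(wt_row, 0.0)

    def test_two_variant_hand_arithmetic(self, mini_design):
        table = make_count_table(
            mini_design,
            [
                (mini_design.wt_coding_seq, {"input1": 1000, "output1": 2000}),
                ("ATGGTTTTTAAA", {"input1": 100, "output1": 50}),
            ],
        )
        ns = compute_enrichment(table, pseudocount=0)
        # ln[(50/100)/(2000/1000)] = ln 0.25; totals cancel
        assert ns.loc[1, "ns_rep1"] == pytest.approx(np.log(0.25), abs=1e-12)

    def test_depth_invariance_with_zero_pseudocount(self, mini_design):
        table = _toy_table(mini_design)
        scaled = table.copy()
        scaled["output2"] = scaled["output2"] * 10
        a = compute_enrichment(table, pseudocount=0)
        b = compute_enrichment(scaled, pseudocount=0)
        assert np.max(np.abs(a.to_numpy() - b.to_numpy())) < 1e-12

    def test_missing_wildtype_errors(self, mini_design):
        table = make_count_table(
            mini_design, [("ATGGTTTTTAAA", {"input1": 10, "output1": 10})]
        )
        with pytest.raises(ValueError, match="no_wildtype"):
            compute_enrichment(table)

    def test_log_bias_correction_is_exact_for_poisson(self):
        # the debiasing term equals the exact Poisson expectation shortfall
        lam = np.array([0.5, 2.0, 10.0, 40.0])
        bias, var = poisson_log_moments(lam, 0.5)
        for l, b, v in zip(lam, bias, var):
            c = np.arange(0, 400)
            pmf = stats.poisson.pmf(c, l)
            assert b == pytest.approx((pmf * np.log(c + 0.5)).sum() - np.log(l), abs=1e-9)
            ex = (pmf * np.log(c + 0.5)).sum()
            assert v == pytest.approx((pmf * np.log(c + 0.5) ** 2).sum() - ex ** 2, abs=1e-9)


class TestMerge:
    def test_equal_variances_give_plain_mean(self):
        ns = pd.DataFrame({"ns_rep1": [1.0, -2.0], "ns_rep2": [3.0, 0.0]})
        var = pd.DataFrame({"var_rep1": [0.5, 0.5], "var_rep2": [0.5, 0.5]})
        merged = merge_replicates(ns, var)
        assert merged["ns"].tolist() == [2.0, -1.0]

    def test_unit_variances_merge_to_inverse_sqrt_n(self):
        ns = pd.DataFrame({f"ns_rep{r}": [0.0] for r in (1, 2, 3)})
        var = pd.DataFrame({f"var_rep{r}": [1.0] for r in (1, 2, 3)})
        assert merge_replicates(ns, var)["sigma"].iloc[0] == pytest.approx(1 / np.sqrt(3))

    def test_huge_variance_replicates_are_ignored(self):
        ns = pd.DataFrame({"ns_rep1": [1.0], "ns_rep2": [50.0], "ns_rep3": [-50.0]})
        var = pd.DataFrame({"var_rep1": [1.0], "var_rep2": [1e12], "var_rep3": [1e12]})
        assert merge_replicates(ns, var)["ns"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_merged_sigma_non_increasing_in_replicates(self, rng):
        variances = rng.uniform(0.1, 2.0, size=6)
        sigmas = []
        for k in range(1, 7):
            ns = pd.DataFrame({f"ns_rep{r}": [0.0] for r in range(1, k + 1)})
            var = pd.DataFrame(
                {f"var_rep{r}": [variances[r - 1]] for r in range(1, k + 1)}
            )
            sigmas.append(merge_replicates(ns, var)["sigma"].iloc[0])
        assert all(b <= a + 1e-15 for a, b in zip(sigmas, sigmas[1:]))


class TestCentering:
    def _scores(self, ns, sigma, var_class, n_nt):
        return pd.DataFrame(
            {"ns": ns, "sigma": sigma, "var_class": var_class, "n_nt_subs": n_nt}
        )

    def test_weighted_synonymous_mean_is_zero_after_centering(self):
        scores = self._scores(
            [0.5, 0.3, -0.2, 2.0],
            [0.1, 0.4, 0.2, 0.3],
            ["synonymous"] * 3 + ["missense"],
            [1, 1, 1, 2],
        )
        centered, offset = center_scores(scores)
        mask = (centered["var_class"] == "synonymous") & (centered["n_nt_subs"] == 1)
        w = 1 / centered.loc[mask, "sigma"] ** 2
        assert np.average(centered.loc[mask, "ns"], weights=w) == pytest.approx(0, abs=1e-14)

    def test_equal_sigmas_reduce_to_plain_mean(self):
        scores = self._scores([1.0, 2.0, 3.0], [0.5] * 3, ["synonymous"] * 3, [1] * 3)
        centered, offset = center_scores(scores)
        assert offset == pytest.approx(2.0)
        assert centered["ns"].tolist() == [-1.0, 0.0, 1.0]

    def test_centering_is_idempotent(self):
        scores = self._scores([1.0, 2.0, 5.0], [0.5, 0.2, 1.0], ["synonymous"] * 2 + ["missense"], [1, 1, 2])
        once, _ = center_scores(scores)
        twice, second_offset = center_scores(once)
        assert second_offset == pytest.approx(0, abs=1e-14)
        pd.testing.assert_frame_equal(once, twice)

    def test_no_synonymous_errors(self):
        scores = self._scores([1.0], [0.5], ["missense"], [2])
        with pytest.raises(ValueError, match="no_synonymous"):
            center_scores(scores)


def brute_force_bh(pvals):
    """Literal Benjamini-Hochberg step-up: q_i = min over j>=rank(i) of n*p_(j)/j."""
    n = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, n * pvals[idx] / rank)
        q[idx] = running
    return q


class TestClassify:
    def test_bh_q_values_match_literal_step_up(self, rng):
        z = rng.normal(0, 2.5, size=20)
        scores = pd.DataFrame({"ns": z, "sigma": np.ones(20)})
        out = classify_effects(scores, fdr=0.1)
        p = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(out["q"].to_numpy(), brute_force_bh(p), atol=1e-12)

    def test_zero_score_is_always_wt_like(self):
        scores = pd.DataFrame({"ns": [0.0, 5.0], "sigma": [0.5, 0.5]})
        out = classify_effects(scores, fdr=0.5)
        assert out["effect_class"].iloc[0] == "wt_like"

    def test_extreme_z_is_significant(self):
        scores = pd.DataFrame({"ns": [5.0], "sigma": [0.5]})
        assert classify_effects(scores, fdr=0.1)["effect_class"].iloc[0] == "increase"

    def test_signs_map_to_directions(self):
        scores = pd.DataFrame({"ns": [5.0, -5.0, 0.01], "sigma": [0.1, 0.1, 1.0]})
        out = classify_effects(scores, fdr=0.1)
        assert out["effect_class"].tolist() == ["increase", "decrease", "wt_like"]

    def test_stricter_fdr_never_creates_significance(self, rng):
        z = rng.normal(0, 2, size=50)
        scores = pd.DataFrame({"ns": z, "sigma": np.ones(50)})
        loose = classify_effects(scores, fdr=0.1)["effect_class"]
        strict = classify_effects(scores, fdr=0.01)["effect_class"]
        became_significant = (loose == "wt_like") & (strict != "wt_like")
        assert not became_significant.any()


class TestErrorModel:
    def test_pure_poisson_counts_fit_near_unit_modifiers(self):
        counts, _ = simulate_experiment(n_variants=2000, seed=0)
        _, model = score_counts(counts, min_input_reads=10)
        assert np.all(model.m_in < 1.35)
        assert np.all(model.m_out < 1.35)
        assert np.all(model.a < 0.01)

    def test_modifiers_respect_bounds(self):
        counts, _ = simulate_experiment(n_variants=500, seed=1)
        scores, model = score_counts(counts, min_input_reads=10)
        assert np.all(model.m_in >= 1.0) and np.all(model.m_out >= 1.0)
        assert np.all(model.a >= 0.0)
        # no modelled sigma below the pure-Poisson floor
        pure = ErrorModel(m_in=np.ones(3), m_out=np.ones(3), a=np.zeros(3))
        from nucleoscan.scoring import poisson_terms
        from nucleoscan.variant_calling import apply_variant_filters

        tab, _ = apply_variant_filters(counts, min_input_reads=10)
        in_t, out_t = poisson_terms(tab.reset_index(drop=True), 0.5)
        assert np.all(model.variance(in_t, out_t) >= pure.variance(in_t, out_t) - 1e-12)

    def test_single_replicate_errors(self, mini_design):
        table = make_count_table(
            mini_design,
            [
                (mini_design.wt_coding_seq, {"input1": 100, "output1": 100}),
                ("ATGGTTTTTAAA", {"input1": 50, "output1": 50}),
            ],
        )
        ns = compute_enrichment(table)
        with pytest.raises(ValueError, match="two replicates"):
            fit_error_model(table, ns)


class TestCalibration:
    def test_standardized_residuals_have_unit_variance_where_model_is_fit(self):
        """On variants with informative counts (pooled expectation >= 10 in
        every sample) the standardized residuals (ns - true)/sigma have
        variance within [0.85, 1.15]; sigma is conservative elsewhere."""
        from nucleoscan.scoring import _count_arrays, pooled_expected_counts
        from nucleoscan.variant_calling import apply_variant_filters

        counts, truth = simulate_experiment(n_variants=2000, seed=0)
        tab, _ = apply_variant_filters(counts, min_input_reads=10)
        tab = tab.reset_index(drop=True)
        scores, _ = score_counts(counts, min_input_reads=10)
        cin, cout, _ = _count_arrays(tab)
        expected = np.hstack([pooled_expected_counts(cin), pooled_expected_counts(cout)])
        informative = (expected >= 10).all(axis=1)
        merged = scores.assign(informative=informative).merge(
            truth[["nt_seq", "ns_true"]], on="nt_seq"
        )
        resid = (merged["ns"] - merged["ns_true"]) / merged["sigma"]
        assert 0.85 <= resid[merged["informative"]].var() <= 1.15
        covered = np.abs(merged["ns"] - merged["ns_true"]) <= 1.96 * merged["sigma"]
        assert 0.92 <= covered.mean() <= 0.97


class TestPipeline:
    def test_score_table_contract(self):
        counts, _ = simulate_experiment(n_variants=300, seed=4)
        scores, model = score_counts(counts, min_input_reads=10)
        for col in ("ns", "sigma", "z", "q", "effect_class", "ns_rep1", "sigma_rep3"):
            assert col in scores.columns
        assert (scores["sigma"] > 0).all()
        assert scores["q"].between(0, 1).all()
        merged_le_each = (
            scores["sigma"].to_numpy()
            <= scores[["sigma_rep1", "sigma_rep2", "sigma_rep3"]].min(axis=1).to_numpy() + 1e-12
        )
        assert merged_le_each.all()

    def test_depth_scaling_leaves_scores_stable(self):
        counts, _ = simulate_experiment(n_variants=300, seed=4)
        scores, _ = score_counts(counts, min_input_reads=10)
        scaled = counts.copy()
        for c in ("input1", "output1"):
            scaled[c] = scaled[c] * 2
        scores2, _ = score_counts(scaled, min_input_reads=10)
        both = scores.merge(scores2, on="nt_seq", suffixes=("_a", "_b"))
        # pseudocount and refit perturb scores only marginally at 2x depth
        assert np.corrcoef(both["ns_a"], both["ns_b"])[0, 1] > 0.99
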