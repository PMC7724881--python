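import numpy as np
import pandas as pd
import pytest

from litfdr import (
    PanelConfig,
    adjusted_means,
    apply_dataset_filter,
    bootstrap_bands,
    build_model_frame,
    fit_lmm,
    generate_journal_panel,
    percent_excess,
    screen_interactions,
    twofold_jif_effect,
)
from litfdr.journal_model import GLOBAL_TERMS, STRATIFIED_TERMS, FitError


def _panel_frame(cfg=None):
    """Model frame whose response is the generator's true pi0."""
    cfg = cfg or PanelConfig(seed=1)
    meta, truth, coefs = generate_journal_panel(cfg)
    est = truth.rename(columns={"true_pi0": "fdr"})[["journal", "year", "fdr"]]
    return build_model_frame(est, meta), coefs


def _toy_estimates_meta():
    rows_e, rows_m = [], []
    fdr = {"A": 0.2, "B": 0.25, "C": 0.3}
    oa = {"A": [0, 0, 0, 0, 0], "B": [1, 1, 1, 1, 1], "C": [0, 0, 1, 1, 1]}
    for j in "ABC":
        for i, year in enumerate(range(2011, 2016)):
            rows_e.append({"journal": j, "year": year, "fdr": fdr[j]})
            rows_m.append({"journal": j, "year": year, "subject": "oncology",
                           "oncology": 1, "oa": oa[j][i], "jif": 3.0})
    return pd.DataFrame(rows_e), pd.DataFrame(rows_m)


class TestDatasetFilters:
    def test_clean_panel_all_datasets_identical(self):
        est, meta = _toy_estimates_meta()
        est = est[est["journal"] != "C"]
        meta = meta[meta["journal"] != "C"]
        keeps = {
            which: set(apply_dataset_filter(est, meta, which)[0]["journal"])
            for which in ("all", "oa_stable", "nonzero_fdr", "oa_stable_and_nonzero")
        }
        assert all(k == {"A", "B"} for k in keeps.values())

    def test_oa_switcher_excluded_only_by_oa_filters(self):
        est, meta = _toy_estimates_meta()  # C switches to OA in 2013
        for which, expect_c in [("all", True), ("nonzero_fdr", True),
                                ("oa_stable", False), ("oa_stable_and_nonzero", False)]:
            kept, _ = apply_dataset_filter(est, meta, which)
            assert ("C" in set(kept["journal"])) is expect_c

    def test_near_zero_fdr_journal_excluded(self):
        est, meta = _toy_estimates_meta()
        est.loc[(est["journal"] == "A") & (est["year"] == 2013), "fdr"] = 1e-7
        for which, expect_a in [("all", True), ("oa_stable", True),
                                ("nonzero_fdr", False), ("oa_stable_and_nonzero", False)]:
            kept, _ = apply_dataset_filter(est, meta, which, zero_tol=1e-4)
            assert ("A" in set(kept["journal"])) is expect_a

    def test_unknown_id_rejected(self):
        est, meta = _toy_estimates_meta()
        with pytest.raises(ValueError):
            apply_dataset_filter(est, meta, "bogus")

    def test_filters_idempotent(self):
        est, meta = _toy_estimates_meta()
        e1, m1 = apply_dataset_filter(est, meta, "oa_stable_and_nonzero")
        e2, m2 = apply_dataset_filter(e1, m1, "oa_stable_and_nonzero")
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(m1, m2)


class TestFitLmm:
    def test_exact_linear_response_recovered(self):
        # zero-noise frame: fdr depends only on the oncology indicator
        cfg = PanelConfig(n_oncology=3, n_medicine=3, intercept=0.2,
                          beta_year=0, beta_oa=0, beta_logjif=0, beta_oncology=0.07,
                          random_intercept_sd=0, residual_sd=0, seed=4)
        frame, _ = _panel_frame(cfg)
        res = fit_lmm(frame, ["oncology"])
        assert res.table.loc["oncology", "estimate"] == pytest.approx(0.07, abs=1e-6)
        assert res.table.loc["Intercept", "estimate"] == pytest.approx(0.2, abs=1e-6)

    def test_full_terms_fit_reports_variances_and_metadata(self):
        frame, _ = _panel_frame()
        res = fit_lmm(frame, list(GLOBAL_TERMS))
        assert res.re_var >= 0 and res.resid_var > 0
        assert res.n_obs == len(frame)
        assert res.n_groups == frame["journal"].nunique()
        assert "df_method" in res.method
        tab = res.table
        assert ((tab["ci_low"] <= tab["estimate"]) & (tab["estimate"] <= tab["ci_high"])).all()

    def test_too_small_frame_rejected(self):
        frame, _ = _panel_frame()
        with pytest.raises(FitError):
            fit_lmm(frame[frame["journal"] == frame["journal"].iloc[0]], ["year_c"])

    def test_permuted_response_yields_uniform_pvalues(self):
        # slope p-values under a permutation null should be ~U(0,1)
        cfg = PanelConfig(n_oncology=20, n_medicine=20, seed=8)
        frame, _ = _panel_frame(cfg)
        rng = np.random.default_rng(5)
        n_sig, B = 0, 100
        for _ in range(B):
            perm = frame.copy()
            perm["fdr"] = rng.permutation(perm["fdr"].values)
            res = fit_lmm(perm, ["log_jif"])
            n_sig += res.table.loc["log_jif", "pvalue"] < 0.05
        assert n_sig / B < 0.12  # ~0.05 expected; 3 sd of binomial above


class TestScreenInteractions:
    def test_no_interaction_frame_keeps_main_effects_only(self):
        frame, _ = _panel_frame(PanelConfig(seed=12))
        final, log = screen_interactions(frame, list(GLOBAL_TERMS))
        assert final == list(GLOBAL_TERMS)
        # the three-way was assessed before any nested two-way was removed
        first = next(e for e in log if e["step"] == 0)
        assert list(first["testable_pvalues"]) == ["oncology:oa:log_jif"]

    def test_injected_two_way_interaction_retained(self):
        cfg = PanelConfig(n_oncology=30, n_medicine=30, residual_sd=0.02,
                          random_intercept_sd=0.02, seed=13)
        meta, truth, _ = generate_journal_panel(cfg)
        est = truth.rename(columns={"true_pi0": "fdr"})[["journal", "year", "fdr"]]
        frame = build_model_frame(est, meta)
        frame["fdr"] = frame["fdr"] + 0.08 * frame["oa"] * frame["log_jif"]
        final, _ = screen_interactions(frame, list(STRATIFIED_TERMS))
        assert "oa:log_jif" in final

    def test_deterministic_selection(self):
        frame, _ = _panel_frame(PanelConfig(seed=14))
        r1 = screen_interactions(frame, list(GLOBAL_TERMS))
        r2 = screen_interactions(frame, list(GLOBAL_TERMS))
        assert r1[0] == r2[0]

    def test_constant_covariate_pruned(self):
        frame, _ = _panel_frame(PanelConfig(n_oncology=4, n_medicine=4,
                                            oa_prevalence=0.0, seed=15))
        final, log = screen_interactions(frame, list(GLOBAL_TERMS))
        assert "oa" not in final
        assert log[0]["step"] == "prune"


class TestDerivedEffects:
    @pytest.mark.parametrize("beta,expected", [
        (-0.029, 0.020), (-0.041, 0.028), (0.0, 0.0),
    ])
    def test_twofold_jif_effect_values(self, beta, expected):
        assert round(twofold_jif_effect(beta), 3) == expected

    def test_twofold_linear_and_sign_reversing(self):
        rng = np.random.default_rng(0)
        for b in rng.normal(size=5):
            assert twofold_jif_effect(-b) == pytest.approx(-twofold_jif_effect(b))
            assert twofold_jif_effect(2 * b) == pytest.approx(2 * twofold_jif_effect(b))

    def test_adjusted_mean_difference_equals_coefficient(self):
        frame, _ = _panel_frame()
        res = fit_lmm(frame, list(GLOBAL_TERMS))
        means = adjusted_means(res, frame, "oncology")
        assert means[1] - means[0] == pytest.approx(
            res.table.loc["oncology", "estimate"], abs=1e-10)

    def test_adjusted_means_near_generator_truth(self):
        cfg = PanelConfig(seed=16)
        frame, coefs = _panel_frame(cfg)
        res = fit_lmm(frame, list(GLOBAL_TERMS))
        means = adjusted_means(res, frame, "oncology")
        expected_gap = coefs["beta_oncology"]
        assert means[1] - means[0] == pytest.approx(expected_gap, abs=0.03)
        assert 0.05 < means[0] < 0.5 and 0.05 < means[1] < 0.6

    def test_percent_excess_from_published_style_means(self):
        assert round(percent_excess(0.264, 0.194)) == 36

    def test_group_term_missing_rejected(self):
        frame, _ = _panel_frame()
        res = fit_lmm(frame, ["year_c"])
        with pytest.raises(ValueError):
            adjusted_means(res, frame, "oncology")


class TestBootstrapBands:
    def test_zero_noise_bands_collapse(self):
        cfg = PanelConfig(n_oncology=4, n_medicine=4, random_intercept_sd=0,
                          residual_sd=0, beta_oncology=0.0, seed=17)
        frame, _ = _panel_frame(cfg)
        bands = bootstrap_bands(frame, list(STRATIFIED_TERMS),
                                np.linspace(0, 2, 5), B=20, seed=3)
        assert np.allclose(bands["upper"] - bands["lower"], 0, atol=1e-8)

    def test_same_seed_identical(self):
        frame, _ = _panel_frame(PanelConfig(n_oncology=6, n_medicine=6, seed=18))
        b1 = bootstrap_bands(frame, list(STRATIFIED_TERMS), [0.5, 1.0], B=25, seed=9)
        b2 = bootstrap_bands(frame, list(STRATIFIED_TERMS), [0.5, 1.0], B=25, seed=9)
        pd.testing.assert_frame_equal(b1, b2)

    def test_bands_bracket_point_prediction(self):
        frame, _ = _panel_frame(PanelConfig(seed=19))
        bands = bootstrap_bands(frame, list(STRATIFIED_TERMS),
                                np.linspace(0, 2, 7), B=60, seed=10)
        assert (bands["lower"] <= bands["point"] + 1e-6).all()
        assert (bands["point"] <= bands["upper"] + 1e-6).all()

    def test_b_too_small_rejected(self):
        frame, _ = _panel_frame()
        with pytest.raises(ValueError):
            bootstrap_bands(frame, list(STRATIFIED_TERMS), [1.0], B=1, seed=0)
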