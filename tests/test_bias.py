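"""GEE bias models: OLS equivalence, Wald tests, marginal means, deltas,
stratification and the targeted age/atrophy analyses."""
import numpy as np
import pandas as pd
import pytest

from centistress.bias import (ModelSpec, atrophy_target_analysis,
                              factor_age_correlations, fit_gee,
                              marginal_means, pairwise_deltas,
                              standard_pipeline_cl, stratify_amyloid,
                              wald_type3)
from centistress.errors import FitError, StratificationError
from centistress.quantify import STANDARD_PIPELINE
from centistress.tablesim import simulate_long_table

ONE_FACTOR = ModelSpec(between_factors=(), within_factors=("rr",),
                       interactions=())


@pytest.fixture(scope="module")
def balanced_table():
    return simulate_long_table(n_subjects=40,
                               offsets={"rr": {"Pons": -8.0, "CGM": -3.0}},
                               seed=3)


def _mini_table(cl_by_subject):
    """One standard-pipeline harmonized row per subject plus a dummy row."""
    rows = []
    for sid, cl in cl_by_subject.items():
        for pid, harm in ((STANDARD_PIPELINE.pipeline_id, True),
                          ("Pons-GAAIN-GAAIN-MNI", True)):
            rows.append({"subject_id": sid, "pipeline_id": pid,
                         "harmonized": harm, "cl": cl, "rr": pid.split("-")[0],
                         "rr_type": "GAAIN", "t_type": "GAAIN", "space": "MNI",
                         "age": 70.0, "atrophy": 0.9, "tracer": "FMM",
                         "diagnosis": "MCI", "group": "negative",
                         "true_cl": cl, "native_fwhm": 6.0, "suvr": 1.2})
    return pd.DataFrame(rows)


class TestStratification:
    def test_boundary_is_strict(self):
        table = _mini_table({"a": 24.0, "b": 24.01, "c": -3.0})
        negative, positive = stratify_amyloid(table)
        assert set(negative["subject_id"]) == {"a", "c"}
        assert set(positive["subject_id"]) == {"b"}

    def test_partition_of_all_rows(self, balanced_table):
        negative, positive = stratify_amyloid(balanced_table)
        assert len(negative) + len(positive) == len(balanced_table)
        assert not (set(negative["subject_id"])
                    & set(positive["subject_id"]))

    def test_missing_standard_record_raises(self):
        table = _mini_table({"a": 10.0})
        broken = table[table["pipeline_id"] != STANDARD_PIPELINE.pipeline_id]
        with pytest.raises(StratificationError):
            standard_pipeline_cl(broken)


class TestGEE:
    def test_independence_gee_equals_ols(self, balanced_table):
        fit = fit_gee(balanced_table, ModelSpec.main_bias(),
                      cov_struct="independence")
        X = np.asarray(fit.result.model.exog)
        y = np.asarray(fit.result.model.endog)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(fit.params - beta)) < 1e-8

    def test_duplicating_clusters_preserves_estimates(self, balanced_table):
        fit = fit_gee(balanced_table, ONE_FACTOR)
        doubled = pd.concat([
            balanced_table,
            balanced_table.assign(
                subject_id=balanced_table["subject_id"] + "_dup")],
            ignore_index=True)
        fit2 = fit_gee(doubled, ONE_FACTOR)
        assert np.allclose(fit.params, fit2.params, atol=1e-6)

    def test_constant_response_has_zero_effects(self, balanced_table):
        table = balanced_table.assign(cl=5.0)
        with pytest.warns(UserWarning, match="constant response"):
            fit = fit_gee(table, ONE_FACTOR)
        assert np.allclose(fit.params[1:], 0.0, atol=1e-10)
        assert fit.params[0] == pytest.approx(5.0)

    def test_single_row_clusters_fall_back_to_independence(self):
        table = simulate_long_table(n_subjects=30, seed=0)
        singles = table.groupby("subject_id").head(1).copy()
        with pytest.warns(UserWarning, match="independence"):
            fit = fit_gee(singles, ONE_FACTOR)
        assert fit.cov_struct_name == "independence"

    def test_interaction_without_main_effect_rejected(self):
        with pytest.raises(FitError):
            ModelSpec(between_factors=(), within_factors=("rr",),
                      interactions=(("tracer", "rr"),))


class TestWald:
    def test_single_df_term_equals_squared_z(self, balanced_table):
        spec = ModelSpec(between_factors=(), within_factors=("t_type",),
                         interactions=())
        fit = fit_gee(balanced_table, spec)
        wald = wald_type3(fit)
        coef, se = fit.params[1], np.sqrt(fit.robust_cov[1, 1])
        assert wald["chi2"].iloc[0] == pytest.approx((coef / se) ** 2,
                                                     rel=1e-8)
        assert wald["df"].iloc[0] == 1

    def test_invariant_to_level_relabelling(self, balanced_table):
        fit = fit_gee(balanced_table, ONE_FACTOR)
        relabelled = balanced_table.assign(
            rr=balanced_table["rr"].map({"WCB": "zWCB", "CGM": "aCGM",
                                         "Pons": "mPons",
                                         "WCB_BSTM": "bBSTM"}))
        fit2 = fit_gee(relabelled, ONE_FACTOR)
        chi = wald_type3(fit)["chi2"].iloc[0]
        chi2 = wald_type3(fit2)["chi2"].iloc[0]
        assert chi == pytest.approx(chi2, rel=1e-8)


class TestMarginalMeans:
    def test_balanced_one_factor_equals_cell_means(self, balanced_table):
        fit = fit_gee(balanced_table, ONE_FACTOR)
        mm = marginal_means(fit, "rr")
        cells = balanced_table.groupby("rr")["cl"].mean()
        for level, est in zip(mm.levels, mm.estimates):
            assert est == pytest.approx(cells[level], abs=1e-8)

    def test_ci_halfwidth_is_1p96_se(self, balanced_table):
        fit = fit_gee(balanced_table, ONE_FACTOR)
        mm = marginal_means(fit, "rr")
        assert np.allclose(mm.ci_high - mm.estimates, 1.959964 * mm.ses,
                           atol=1e-6)

    def test_absent_factor_rejected(self, balanced_table):
        fit = fit_gee(balanced_table, ONE_FACTOR)
        with pytest.raises(ValueError):
            marginal_means(fit, "space")


@pytest.fixture(scope="module")
def mm(balanced_table):
    fit = fit_gee(balanced_table, ONE_FACTOR)
    return marginal_means(fit, "rr")


class TestDeltas:
    def test_reference_vs_itself_is_zero_and_irrelevant(self, mm):
        deltas = pairwise_deltas(mm, "WCB").set_index("level")
        assert deltas.loc["WCB", "delta"] == 0.0
        assert not deltas.loc["WCB", "relevant"]

    def test_relevance_threshold_at_3cl(self, mm):
        deltas = pairwise_deltas(mm, "WCB").set_index("level")
        # injected offsets: Pons -8 (relevant), CGM -3 (borderline relevant)
        assert deltas.loc["Pons", "relevant"]
        assert abs(deltas.loc["WCB_BSTM", "delta"]) < 3.0
        assert not deltas.loc["WCB_BSTM", "relevant"]

    def test_antisymmetric_under_reference_swap(self, mm):
        ab = pairwise_deltas(mm, "WCB").set_index("level")
        ba = pairwise_deltas(mm, "Pons").set_index("level")
        assert ab.loc["Pons", "delta"] == pytest.approx(
            -ba.loc["WCB", "delta"])


class TestRecovery:
    def test_marginal_means_recover_injected_offsets(self):
        """Additive pipeline-factor offsets injected at the table level are
        recovered by the GEE marginal-mean deltas within 3 SEs."""
        offsets = {"rr": {"Pons": -15.0, "CGM": -5.0, "WCB_BSTM": 1.0},
                   "t_type": {"subject": 3.5}, "space": {"native": -2.0}}
        table = simulate_long_table(n_subjects=300, offsets=offsets, seed=9)
        fit = fit_gee(table, ModelSpec.main_bias())
        for factor, reference in (("rr", "WCB"), ("t_type", "GAAIN"),
                                  ("space", "MNI")):
            deltas = pairwise_deltas(marginal_means(fit, factor),
                                     reference).set_index("level")
            for level, truth in offsets[factor].items():
                row = deltas.loc[level]
                assert abs(row["delta"] - truth) < 3 * row["se"], \
                    f"{factor}/{level}: {row['delta']} vs {truth}"


class TestTargetedAnalyses:
    def test_constant_delta_is_degenerate(self):
        table = simulate_long_table(n_subjects=20, seed=1, noise_sd=0.0)
        out = factor_age_correlations(table).set_index("contrast")
        assert out["degenerate"].all()
        assert (out["rho"] == 0.0).all()

    def test_age_linked_offset_gives_positive_rho(self):
        table = simulate_long_table(n_subjects=60, seed=2, noise_sd=0.5)
        ages = table.groupby("subject_id")["age"].first()
        shift = table["subject_id"].map(2.0 * (ages - ages.mean()))
        table.loc[table["rr"] == "Pons", "cl"] -= \
            shift[table["rr"] == "Pons"]
        out = factor_age_correlations(table).set_index("contrast")
        assert out.loc["dCL(WCB-Pons)", "rho"] > 0.8
        assert out.loc["dCL(WCB-Pons)", "p"] < 0.001

    def test_atrophy_analysis_recovers_linear_trend(self):
        table = simulate_long_table(n_subjects=50, seed=3, noise_sd=0.0)
        atrophy = table.groupby("subject_id")["atrophy"].first()
        shift = table["subject_id"].map(-40.0 * (atrophy - 1.0))
        sel = table["t_type"] == "subject"
        table.loc[sel, "cl"] += shift[sel]
        table["group"] = "positive"
        res = atrophy_target_analysis(table)
        assert res.r == pytest.approx(-1.0, abs=1e-6)
        assert res.dementia_mean is not None and res.dementia_mean > 0

    def test_zero_delta_atrophy_is_degenerate(self):
        table = simulate_long_table(n_subjects=20, seed=4, noise_sd=0.0)
        res = atrophy_target_analysis(table)
        assert res.degenerate and res.r == 0.0
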