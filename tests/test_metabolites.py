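"""Preprocessing, per-metabolite models, BH, ANOVA/Tukey, sub-pathways."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptrmetab.metabolites import (
    MetaboliteTable,
    anova_tukey,
    bh_adjust,
    differential_analysis,
    fit_treatment_model,
    preprocess,
    summarize_by_subpathway,
    treatment_lm,
)
from ptrmetab.synthetic import MetabolomeScenario, simulate_metabolome


def _metadata(n, seed=0):
    rng = np.random.default_rng(seed)
    regions = np.tile(["AC", "TC", "DC"], int(np.ceil(n / 3)))[:n]
    brs = np.tile(["BR1", "BR2", "BR3"], int(np.ceil(n / 3)))[:n]
    rng.shuffle(brs)
    treatment = np.array(["control", "LGG"] * (n // 2 + 1))[:n]
    return pd.DataFrame(
        {
            "region": regions,
            "bioreplicate": brs,
            "treatment": treatment,
            "day": rng.integers(1, 10, n),
        },
        index=[f"s{i:03d}" for i in range(n)],
    )


def _table(intensities, meta=None):
    meta = meta if meta is not None else _metadata(intensities.shape[0])
    return MetaboliteTable(intensities=intensities, metadata=meta)


class TestPreprocess:
    def test_half_minimum_imputation_then_log2(self):
        x = pd.DataFrame({"m1": [4.0, 8.0, np.nan]}, index=[f"s{i:03d}" for i in range(3)])
        out = preprocess(_table(x, _metadata(3)))
        assert np.allclose(sorted(out.intensities["m1"]), [1.0, 2.0, 3.0])
        assert out.log2_transformed

    def test_idempotent_on_rerun(self):
        x = pd.DataFrame(
            {"m1": [4.0, 8.0, 16.0]}, index=[f"s{i:03d}" for i in range(3)]
        )
        once = preprocess(_table(x))
        twice = preprocess(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)

    def test_mostly_missing_metabolite_dropped(self):
        n = 10
        x = pd.DataFrame(
            {
                "bad": [1.0] + [np.nan] * (n - 1),
                "empty": [np.nan] * n,
                "good": np.arange(1.0, n + 1),
            },
            index=[f"s{i:03d}" for i in range(n)],
        )
        with pytest.warns(UserWarning, match="dropping"):
            out = preprocess(_table(x, _metadata(n)))
        assert list(out.intensities.columns) == ["good"]


class TestTreatmentModel:
    def test_matches_statsmodels_ols(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(2)
        meta = _metadata(36)
        y = pd.DataFrame(
            rng.normal(10, 1, size=(36, 5)),
            index=meta.index,
            columns=[f"m{i}" for i in range(5)],
        )
        res = treatment_lm(y, meta)
        for col in y.columns:
            df = meta.assign(y=y[col])
            fit = smf.ols(
                "y ~ C(treatment, Treatment('control')) + C(bioreplicate) + C(region)",
                df,
            ).fit()
            name = "C(treatment, Treatment('control'))[T.LGG]"
            assert res.loc[col, "coefficient"] == pytest.approx(
                fit.params[name], abs=1e-10
            )
            assert res.loc[col, "p_value"] == pytest.approx(
                fit.pvalues[name], abs=1e-10
            )

    def test_constant_metabolite_flagged(self):
        meta = _metadata(12)
        y = pd.Series(np.full(12, 7.0), index=meta.index, name="m")
        coef, p = fit_treatment_model(y, meta)
        assert coef == 0.0 and p == 1.0

    def test_effect_recovery_power(self):
        """Planted +1 log2 treatment effect, noise 0.25, 48 samples: the
        coefficient lands in [0.7, 1.3] with p < 0.01 in >= 95% of 200
        replicates (all replicates fitted in one vectorised call)."""
        meta = _metadata(48, seed=1)
        is_lgg = (meta["treatment"] == "LGG").values.astype(float)
        rng = np.random.default_rng(3)
        n_rep = 200
        Y = pd.DataFrame(
            10.0
            + is_lgg[:, None] * 1.0
            + rng.normal(0, 0.25, size=(48, n_rep)),
            index=meta.index,
            columns=[f"rep{r}" for r in range(n_rep)],
        )
        res = treatment_lm(Y, meta)
        ok = (
            (res["coefficient"] > 0.7)
            & (res["coefficient"] < 1.3)
            & (res["p_value"] < 0.01)
        )
        assert ok.mean() >= 0.95

    def test_null_p_values_uniform(self):
        meta = _metadata(48, seed=4)
        rng = np.random.default_rng(5)
        Y = pd.DataFrame(
            rng.normal(10, 0.5, size=(48, 1000)),
            index=meta.index,
            columns=[f"m{i}" for i in range(1000)],
        )
        res = treatment_lm(Y, meta)
        assert stats.kstest(res["p_value"], "uniform").pvalue > 0.01

    def test_shift_invariance_and_column_order_independence(self):
        meta = _metadata(24, seed=6)
        rng = np.random.default_rng(7)
        Y = pd.DataFrame(
            rng.normal(8, 1, size=(24, 6)),
            index=meta.index,
            columns=[f"m{i}" for i in range(6)],
        )
        base = treatment_lm(Y, meta)
        shifted = treatment_lm(Y + 100.0, meta)
        assert np.allclose(base["p_value"], shifted["p_value"], atol=1e-9)
        perm = treatment_lm(Y[Y.columns[::-1]], meta)
        assert np.allclose(
            base["p_value"].sort_index(), perm["p_value"].sort_index(), atol=1e-12
        )

    def test_single_treatment_level_rejected(self):
        meta = _metadata(12)
        meta["treatment"] = "control"
        y = pd.DataFrame({"m": np.arange(12.0)}, index=meta.index)
        with pytest.raises(ValueError, match="treatment levels"):
            treatment_lm(y, meta)


class TestBHAdjust:
    def test_step_up_examples(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.all(q <= 0.05)  # all four rejected at alpha 0.05
        q2 = bh_adjust([0.001, 0.049, 0.05, 0.9])
        assert q2[0] <= 0.05
        assert np.all(q2[1:] > 0.05)  # the chain above rank 1 is broken
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)
        assert bh_adjust([]).size == 0

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_fdr_control_with_planted_nulls(self):
        """Empirical FDR over replicates stays below alpha + 2 MC SE with
        10% non-null metabolites."""
        meta = _metadata(48, seed=8)
        is_lgg = (meta["treatment"] == "LGG").values.astype(float)
        rng = np.random.default_rng(9)
        n_met, n_rep, alpha = 1000, 50, 0.05
        fdps = []
        for _ in range(n_rep):
            effects = np.zeros(n_met)
            effects[:100] = 1.0
            Y = pd.DataFrame(
                10.0 + np.outer(is_lgg, effects) + rng.normal(0, 0.25, (48, n_met)),
                index=meta.index,
            )
            res = treatment_lm(Y, meta)
            rej = bh_adjust(res["p_value"].values) <= alpha
            fp = rej[100:].sum()
            fdps.append(fp / max(rej.sum(), 1))
        fdr = np.mean(fdps)
        mc_se = np.std(fdps, ddof=1) / np.sqrt(n_rep)
        assert fdr <= alpha + 2 * mc_se


class TestAnovaTukey:
    def test_identical_groups_nothing_significant(self):
        y = np.tile([5.0, 5.0, 5.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        F, p, table = anova_tukey(y, g)
        assert F == 0.0
        assert not table["reject"].any()

    def test_separated_group_detected(self):
        y = np.array([1, 2, 3, 1, 2, 3, 7, 8, 9], dtype=float)
        g = np.repeat(["g1", "g2", "g3"], 3)
        _, _, table = anova_tukey(y, g)
        by_pair = table.set_index(["group_1", "group_2"])["reject"]
        assert by_pair[("g1", "g3")] and by_pair[("g2", "g3")]
        assert not by_pair[("g1", "g2")]

    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        _, _, table = anova_tukey(np.r_[a, b], np.repeat(["a", "b"], 8))
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert table["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_matches_studentized_range_oracle_on_balanced_grid(self):
        """Brute-force oracle: q = |mean_i - mean_j| / sqrt(MSE/n), with p
        from the studentized range distribution, over all balanced designs
        k <= 4, n <= 5."""
        rng = np.random.default_rng(12)
        for k in (2, 3, 4):
            for n in (2, 3, 4, 5):
                y = rng.normal(0, 1, size=k * n) + np.repeat(rng.normal(0, 1, k), n)
                g = np.repeat([f"g{i}" for i in range(k)], n)
                _, _, table = anova_tukey(y, g)
                groups = [y[g == f"g{i}"] for i in range(k)]
                mse = np.mean([np.var(arr, ddof=1) for arr in groups])
                df = k * (n - 1)
                for _, row in table.iterrows():
                    i = int(row["group_1"][1:])
                    j = int(row["group_2"][1:])
                    q = abs(groups[i].mean() - groups[j].mean()) / np.sqrt(mse / n)
                    p_oracle = stats.studentized_range.sf(q, k, df)
                    assert row["p_adj"] == pytest.approx(p_oracle, abs=1e-8)

    def test_singleton_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="solo"):
            anova_tukey(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "solo"]))


class TestSubpathways:
    def test_shifted_subpathway_flagged_null_not(self):
        scenario = MetabolomeScenario(
            n_metabolites=80,
            frac_treatment_affected=0.0,
            frac_region_restricted=0.0,
            noise_sd_log2=0.3,
            seed=21,
        )
        table, _, _ = simulate_metabolome(scenario)
        table = preprocess(table)
        # plant a +1 log2 shift on every member of the first sub-pathway
        first = table.annotations["sub_pathway"].iloc[0]
        members = table.annotations.index[table.annotations["sub_pathway"] == first]
        lgg = table.metadata["treatment"] == "LGG"
        table.intensities.loc[lgg, members] += 1.0
        res = summarize_by_subpathway(table)
        assert res.loc[first, "significant"]
        assert res["significant"].sum() <= 2  # at most stray false flags

    def test_unannotated_metabolites_grouped_not_dropped(self):
        scenario = MetabolomeScenario(n_metabolites=20, seed=22)
        table, _, _ = simulate_metabolome(scenario)
        table.annotations.loc[table.annotations.index[:5], "sub_pathway"] = np.nan
        res = summarize_by_subpathway(table)
        assert "unannotated" in res.index


class TestDifferentialAnalysis:
    def test_recovers_planted_effects(self, default_metabolome):
        _, table, _, truth = default_metabolome
        res = differential_analysis(table)
        sig = set(res.index[res["significant"]])
        recall = len(sig & truth.affected_metabolites) / len(truth.affected_metabolites)
        assert recall >= 0.9
        false_hits = len(sig - truth.affected_metabolites)
        assert false_hits <= 0.1 * max(len(sig), 1) + 2
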