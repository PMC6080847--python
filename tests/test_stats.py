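"""Group statistics: summaries, ANOVA + Tukey HSD, t-tests, stars."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fibralign.stats import (
    anova_tukey,
    assign_stars,
    summarize_groups,
    validate_group_table,
    wounded_vs_unwounded_ttests,
)


def table(groups: dict[str, list[float]], *, condition="unwounded",
          timepoint=None) -> pd.DataFrame:
    rows = []
    for g, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {"image_id": f"{g}_{i}", "group": g,
                 "timepoint": timepoint or g, "condition": condition, "ai": v}
            )
    return pd.DataFrame(rows)


def paired_table(timepoint: str, wounded, unwounded) -> pd.DataFrame:
    frames = [
        table({timepoint: list(wounded)}, condition="wounded"),
        table({timepoint: list(unwounded)}, condition="unwounded"),
    ]
    df = pd.concat(frames, ignore_index=True)
    df["image_id"] = df["image_id"] + "_" + df["condition"]
    return df


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, "ns"), (0.05, "ns"), (0.049, "*"), (0.01, "*"), (0.009, "**"),
         (0.001, "**"), (0.0009, "***"), (0.0001, "***"), (0.00009, "****"),
         (0.0, "****")],
    )
    def test_ladder_thresholds(self, p, expected):
        assert assign_stars(p) == expected

    def test_nan_and_out_of_range(self):
        assert assign_stars(float("nan")) == "na"
        assert assign_stars(1.5) == "na"


class TestSummaries:
    def test_mean_and_sample_sd(self):
        out = summarize_groups(table({"a": [0.1, 0.2, 0.3]}))
        assert out.loc[0, "n"] == 3
        assert out.loc[0, "mean"] == pytest.approx(0.2)
        assert out.loc[0, "sd"] == pytest.approx(0.1)

    def test_known_values(self):
        out = summarize_groups(table({"a": [0.1, 0.2, 0.3], "b": [0.5, 0.5, 0.5]}))
        a = out.set_index("group")
        assert a.loc["a", "mean"] == pytest.approx(0.2)
        assert a.loc["a", "sd"] == pytest.approx(0.1)
        assert a.loc["b", "sd"] == 0.0

    def test_singleton_group_sd_is_nan(self):
        out = summarize_groups(table({"a": [0.5], "b": [0.1, 0.2]}))
        assert np.isnan(out.set_index("group").loc["a", "sd"])

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0.2, 0.8, 12)
        out = summarize_groups(table({"g": list(vals)}))
        assert out.loc[0, "mean"] == pytest.approx(vals.mean(), abs=1e-12)
        assert out.loc[0, "sd"] == pytest.approx(vals.std(ddof=1), abs=1e-12)

    def test_schema_and_range_validation(self):
        df = table({"a": [0.1, 0.2]})
        with pytest.raises(ValueError, match="missing"):
            validate_group_table(df.drop(columns=["condition"]))
        bad = df.copy()
        bad.loc[0, "ai"] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            validate_group_table(bad)


class TestAnovaTukey:
    def test_null_rarely_rejects(self):
        # three groups from one normal: omnibus p > 0.05 in >= 90/100 trials
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            draws = np.clip(rng.normal(0.5, 0.1, (3, 15)), 0, 1)
            reports = anova_tukey(table({g: list(v) for g, v in
                                         zip("abc", draws)}))
            hits += reports[0].p_value > 0.05
        assert hits >= 90

    def test_strong_effect_is_detected(self):
        # group means 0.2 vs 0.6, SD 0.08, n=12: essentially always ****
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            a = np.clip(rng.normal(0.2, 0.08, 12), 0, 1)
            b = np.clip(rng.normal(0.6, 0.08, 12), 0, 1)
            reports = anova_tukey(table({"lo": list(a), "hi": list(b)}))
            hits += reports[0].p_value < 1e-4
        assert hits >= 95

    def test_identical_groups_have_tukey_p_near_one(self):
        vals = [0.2, 0.3, 0.4, 0.5]
        reports = anova_tukey(table({"a": vals, "b": vals, "c": [0.7, 0.8, 0.9, 0.85]}))
        pair = next(r for r in reports if r.comparison == "a vs b")
        assert pair.p_value == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_variance_is_degenerate_not_crash(self):
        reports = anova_tukey(table({"a": [0.5, 0.5], "b": [0.5, 0.5]}))
        assert reports[0].degenerate

    def test_tukey_adjusted_p_not_below_raw_pairwise_p(self):
        # raw reference: two-sided p of the same studentized statistic
        # without the family-wise range correction
        rng = np.random.default_rng(9)
        draws = [np.clip(rng.normal(m, 0.1, 10), 0, 1) for m in (0.4, 0.5, 0.6, 0.45)]
        groups = {g: list(v) for g, v in zip("abcd", draws)}
        reports = anova_tukey(table(groups))
        dof = sum(len(v) - 1 for v in draws)
        mse = sum(np.sum((v - v.mean()) ** 2) for v in draws) / dof
        labels = list(groups)
        for r in reports:
            if r.test != "tukey":
                continue
            i, j = (labels.index(x) for x in r.comparison.split(" vs "))
            se = np.sqrt(mse * (1 / len(draws[i]) + 1 / len(draws[j])))
            t = abs(draws[i].mean() - draws[j].mean()) / se
            raw = 2 * sps.t.sf(t, dof)
            assert r.p_value >= raw - 1e-12

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(10)
        df = table({g: list(np.clip(rng.normal(m, 0.1, 8), 0, 1))
                    for g, m in zip("abc", (0.3, 0.5, 0.6))})
        ours = {r.comparison: r.p_value for r in anova_tukey(df)
                if r.test == "tukey"}
        sm = pairwise_tukeyhsd(df["ai"], df["group"])
        for row in sm.summary().data[1:]:
            key = f"{row[0]} vs {row[1]}"
            assert ours[key] == pytest.approx(float(row[3]), abs=1e-3)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey(table({"a": [0.1, 0.2]}))


class TestTTests:
    def test_identical_samples_give_p_one(self):
        df = paired_table("5dpi", [0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        [report] = wounded_vs_unwounded_ttests(df)
        assert report.statistic == pytest.approx(0.0, abs=1e-12)
        assert report.p_value == pytest.approx(1.0, abs=1e-12)
        assert report.stars == "ns"

    def test_early_repair_effect_is_detected(self):
        # 0.34 +/- 0.15 wounded vs 0.60 +/- 0.11 unwounded, n=10 per arm:
        # detection rates must match the noncentral-t power prediction
        n, m1, s1, m2, s2 = 10, 0.34, 0.15, 0.60, 0.11
        rng = np.random.default_rng(11)
        hits_05, hits_001 = 0, 0
        n_reps = 200
        for _ in range(n_reps):
            w = np.clip(rng.normal(m1, s1, n), 0, 1)
            u = np.clip(rng.normal(m2, s2, n), 0, 1)
            [r] = wounded_vs_unwounded_ttests(paired_table("5dpi", w, u))
            hits_05 += r.p_value < 0.05
            hits_001 += r.p_value < 1e-3
        # analytic oracle: pooled-variance noncentral t
        dof = 2 * n - 2
        ncp = (m2 - m1) / np.sqrt((s1**2 + s2**2) / n)
        for alpha, hits in ((0.05, hits_05), (1e-3, hits_001)):
            t_crit = sps.t.ppf(1 - alpha / 2, dof)
            power = sps.nct.sf(t_crit, dof, ncp) + sps.nct.cdf(-t_crit, dof, ncp)
            assert hits / n_reps == pytest.approx(power, abs=0.10)
        assert hits_05 / n_reps >= 0.9  # the effect is reliably detected

    def test_late_repair_difference_is_usually_ns(self):
        # 0.50 +/- 0.13 vs 0.54 +/- 0.10, n=10: mostly indistinguishable
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(100):
            w = np.clip(rng.normal(0.50, 0.13, 10), 0, 1)
            u = np.clip(rng.normal(0.54, 0.10, 10), 0, 1)
            [r] = wounded_vs_unwounded_ttests(paired_table("16dpi", w, u))
            hits += r.p_value > 0.05
        assert hits >= 80

    def test_missing_condition_skipped_with_warning(self, caplog):
        df = table({"5dpi": [0.3, 0.4]}, condition="wounded")
        with caplog.at_level("WARNING", logger="fibralign.stats"):
            reports = wounded_vs_unwounded_ttests(df)
        assert reports == []
        assert any("skipped" in r.message for r in caplog.records)

    def test_pooled_variant_matches_scipy(self):
        rng = np.random.default_rng(13)
        w = np.clip(rng.normal(0.4, 0.1, 8), 0, 1)
        u = np.clip(rng.normal(0.5, 0.1, 8), 0, 1)
        [r] = wounded_vs_unwounded_ttests(paired_table("x", w, u), welch=False)
        t, p = sps.ttest_ind(w, u, equal_var=True)
        assert r.statistic == pytest.approx(t)
        assert r.p_value == pytest.approx(p)
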