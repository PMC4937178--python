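"""Split-plot ANOVA against independent oracles, Tukey HSD, Pearson correlation."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from cardiofit import ValidationError, mixed_anova, pearson_r, tukey_posthoc
from cardiofit.study_stats import _gg_epsilon, _hf_epsilon


def long_table(wide: dict[str, list[list[float]]], times: list[str]) -> pd.DataFrame:
    """Build a tidy table from {group: [[subject values per time], ...]}."""
    rows = []
    for g, subjects in wide.items():
        for i, vals in enumerate(subjects):
            for t, v in zip(times, vals):
                rows.append((f"{g}{i}", g, t, float(v)))
    return pd.DataFrame(rows, columns=["subject", "group", "time", "value"])


def brute_force_split_plot(table: pd.DataFrame) -> dict[str, float]:
    """Independent sums-of-squares oracle: plain loops over the definitions."""
    wide = table.pivot(index="subject", columns="time", values="value")
    groups = table.groupby("subject")["group"].first().reindex(wide.index)
    Y = wide.to_numpy()
    n, k = Y.shape
    grand = Y.mean()
    ss_group = 0.0
    for g in groups.unique():
        sub = Y[(groups == g).to_numpy()]
        ss_group += len(sub) * k * (sub.mean() - grand) ** 2
    ss_between = sum(k * (Y[i].mean() - grand) ** 2 for i in range(n))
    ss_time = sum(n * (Y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_inter = 0.0
    for g in groups.unique():
        sub = Y[(groups == g).to_numpy()]
        for j in range(k):
            dev = sub[:, j].mean() - sub.mean() - Y[:, j].mean() + grand
            ss_inter += len(sub) * dev**2
    ss_within = sum(
        (Y[i, j] - Y[i].mean()) ** 2 for i in range(n) for j in range(k)
    )
    return {
        "group": ss_group,
        "subjects(group)": ss_between - ss_group,
        "time": ss_time,
        "time:group": ss_inter,
        "error(within)": ss_within - ss_time - ss_inter,
    }


# hand-computable 2 groups x 2 times fixture
FIXTURE_2X2 = long_table(
    {"A": [[10, 12], [11, 15], [9, 11]], "B": [[14, 13], [16, 18], [15, 15]]},
    ["pre", "post"],
)


class TestMixedAnova:
    def test_matches_brute_force_ss_oracle(self):
        result = mixed_anova(FIXTURE_2X2)
        oracle = brute_force_split_plot(FIXTURE_2X2)
        for name, ss in oracle.items():
            assert result.ss_components[name] == pytest.approx(ss, abs=1e-10)
        assert result.ss_total == pytest.approx(sum(oracle.values()), abs=1e-8)

    def test_matches_pingouin_mixed_anova(self):
        rng = np.random.default_rng(17)
        rows = []
        for g, n in (("A", 8), ("B", 10), ("C", 12)):
            for i in range(n):
                base = rng.normal(50, 8)
                for t, off in (("pre", 0.0), ("post", 1.5)):
                    rows.append((f"{g}{i}", g, t, base + off + rng.normal(0, 3)))
        table = pd.DataFrame(rows, columns=["subject", "group", "time", "value"])
        mine = mixed_anova(table)
        theirs = pg.mixed_anova(
            table, dv="value", within="time", between="group", subject="subject"
        ).set_index("Source")
        assert mine.effects["group"].F == pytest.approx(theirs.loc["group", "F"], rel=1e-9)
        assert mine.effects["time"].F == pytest.approx(theirs.loc["time", "F"], rel=1e-9)
        assert mine.effects["time:group"].F == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-9
        )

    def test_two_within_levels_need_no_correction(self):
        result = mixed_anova(FIXTURE_2X2)
        assert result.effects["time"].correction == "none"
        assert result.effects["time"].epsilon is None

    def test_identical_values_are_degenerate_with_zero_f(self):
        table = long_table({"A": [[5, 5], [5, 5]], "B": [[5, 5], [5, 5]]}, ["pre", "post"])
        result = mixed_anova(table)
        assert result.degenerate
        assert all(e.F == 0.0 for e in result.effects.values())

    def test_invariant_to_row_order_and_relabeling(self):
        shuffled = FIXTURE_2X2.sample(frac=1.0, random_state=0)
        a = mixed_anova(FIXTURE_2X2)
        b = mixed_anova(shuffled)
        assert a.effects["time"].F == pytest.approx(b.effects["time"].F, rel=1e-12)
        renamed = FIXTURE_2X2.assign(subject=FIXTURE_2X2["subject"].map(lambda s: "X" + s))
        c = mixed_anova(renamed)
        assert a.ss_components == c.ss_components

    def test_permuting_group_labels_preserves_ss_total(self):
        swapped = FIXTURE_2X2.assign(
            group=FIXTURE_2X2["group"].map({"A": "B", "B": "A"})
        )
        assert mixed_anova(FIXTURE_2X2).ss_total == pytest.approx(
            mixed_anova(swapped).ss_total, abs=1e-10
        )

    def test_unbalanced_table_rejected_listing_subjects(self):
        broken = FIXTURE_2X2[~((FIXTURE_2X2.subject == "A1") & (FIXTURE_2X2.time == "post"))]
        with pytest.raises(ValidationError, match="A1"):
            mixed_anova(broken)


class TestEpsilonCorrections:
    @pytest.fixture
    def three_level_wide(self):
        rng = np.random.default_rng(23)
        cov = np.array([[9.0, 3.0, 1.0], [3.0, 6.0, 2.0], [1.0, 2.0, 12.0]])
        Y = rng.normal(0, 5, size=(15, 1)) + np.array([0.0, 1.0, 2.0]) + (
            rng.multivariate_normal(np.zeros(3), cov, size=15)
        )
        return pd.DataFrame(Y, columns=["w0", "w1", "w2"])

    def test_gg_and_hf_match_pingouin(self, three_level_wide):
        cov = np.cov(three_level_wide.to_numpy().T)
        gg = _gg_epsilon(cov)
        assert gg == pytest.approx(pg.epsilon(three_level_wide, correction="gg"), abs=1e-9)
        hf = _hf_epsilon(gg, n_subjects=15, n_groups=1, k=3)
        assert hf == pytest.approx(
            min(1.0, pg.epsilon(three_level_wide, correction="hf")), abs=1e-9
        )

    def test_correction_rule_selects_gg_below_075(self):
        # severe sphericity violation: one time level far noisier than the rest
        rng = np.random.default_rng(5)
        n = 12
        Y = np.column_stack(
            [rng.normal(0, 1, n), rng.normal(0, 1, n), rng.normal(0, 30, n)]
        )
        table = pd.DataFrame(
            [
                (f"S{i}", "G", f"t{j}", Y[i, j])
                for i in range(n)
                for j in range(3)
            ],
            columns=["subject", "group", "time", "value"],
        )
        result = mixed_anova(table)
        assert result.effects["time"].correction == "GG"
        assert result.effects["time"].epsilon < 0.75
        # corrected p never smaller than the uncorrected one
        assert result.effects["time"].p >= result.effects["time"].p_uncorrected

    def test_correction_rule_selects_hf_otherwise(self):
        rng = np.random.default_rng(6)
        n = 20
        Y = rng.normal(0, 1, size=(n, 3))   # near-spherical
        table = pd.DataFrame(
            [(f"S{i}", "G", f"t{j}", Y[i, j]) for i in range(n) for j in range(3)],
            columns=["subject", "group", "time", "value"],
        )
        result = mixed_anova(table)
        assert result.effects["time"].correction == "HF"
        assert result.effects["time"].epsilon >= 0.75


class TestTukey:
    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 15)
        table = pd.DataFrame(
            [("a%d" % i, "A", "pre", v) for i, v in enumerate(a)]
            + [("b%d" % i, "B", "pre", v) for i, v in enumerate(b)],
            columns=["subject", "group", "time", "value"],
        )
        res = tukey_posthoc(table)
        t_p = stats.ttest_ind(a, b).pvalue
        assert res["p"].iloc[0] == pytest.approx(t_p, rel=1e-6)

    def test_equal_mean_groups_yield_large_p(self):
        rng = np.random.default_rng(9)
        rows = []
        for g in ("A", "B", "C"):
            for i, v in enumerate(rng.normal(10, 1, 400)):
                rows.append((f"{g}{i}", g, "pre", v))
        table = pd.DataFrame(rows, columns=["subject", "group", "time", "value"])
        res = tukey_posthoc(table)
        assert (res["p"] > 0.05).all()

    def test_antisymmetric_differences(self):
        res = tukey_posthoc(FIXTURE_2X2)
        ab = res[(res.group_a == "A") & (res.group_b == "B")].iloc[0]
        ba = res[(res.group_a == "B") & (res.group_b == "A")].iloc[0]
        assert ab["diff"] == -ba["diff"]
        assert ab["p"] == ba["p"]

    def test_single_group_rejected(self):
        table = FIXTURE_2X2[FIXTURE_2X2.group == "A"]
        with pytest.raises(ValidationError):
            tukey_posthoc(table)

    def test_at_time_restricts_to_one_level(self):
        res = tukey_posthoc(FIXTURE_2X2, at_time="pre")
        means = FIXTURE_2X2[FIXTURE_2X2.time == "pre"].groupby("group")["value"].mean()
        ab = res[(res.group_a == "A") & (res.group_b == "B")].iloc[0]
        assert ab["diff"] == pytest.approx(means["A"] - means["B"])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_formula(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert pearson_r(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 2.0], [3.0, 4.0])
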