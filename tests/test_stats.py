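"""Cohort statistics: test gating, BH, meaningful sites, regression, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aluedit.annotations import CohortDesign
from aluedit.stats import (
    bh_adjust,
    compare_multi_groups,
    compare_two_groups,
    correlate,
    covariate_regression,
    interaction_model,
    meaningful_sites,
    roc_auc,
)


def design_for(groups: dict[str, int], **extra) -> CohortDesign:
    rows = []
    for g, n in groups.items():
        for i in range(n):
            row = {"sample": f"{g}{i}", "group": g}
            row.update({k: v for k, v in extra.items()})
            rows.append(row)
    return CohortDesign(pd.DataFrame(rows))


def series_for(design: CohortDesign, values_by_group: dict[str, list]) -> pd.Series:
    data = {}
    for g, vals in values_by_group.items():
        for s, v in zip(design.samples_in(g), vals):
            data[s] = v
    return pd.Series(data)


class TestTwoGroups:
    def test_fully_separated_small_groups_exact_u(self):
        d = design_for({"a": 5, "b": 5})
        v = series_for(d, {"a": [1, 2, 3, 4, 5], "b": [6, 7, 8, 9, 10]})
        res = compare_two_groups(v, d, ("a", "b"))
        assert res.test_used == "mann_whitney"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)  # exact enumeration
        assert res.direction == "up"

    def test_identical_multisets_give_p_one(self):
        d = design_for({"a": 5, "b": 5})
        vals = [1.0, 2.0, 2.0, 3.0, 4.0]
        v = series_for(d, {"a": vals, "b": vals})
        res = compare_two_groups(v, d, ("a", "b"))
        assert res.p_value == pytest.approx(1.0)
        assert res.direction == "none"

    def test_small_n_forces_nonparametric_even_if_normal(self, rng):
        d = design_for({"a": 5, "b": 5})
        v = series_for(d, {"a": list(rng.normal(0, 1, 5)), "b": list(rng.normal(0, 1, 5))})
        assert compare_two_groups(v, d, ("a", "b")).test_used == "mann_whitney"

    def test_large_normal_groups_use_t(self, rng):
        d = design_for({"a": 40, "b": 40})
        v = series_for(d, {"a": list(rng.normal(0, 1, 40)), "b": list(rng.normal(0.5, 1, 40))})
        res = compare_two_groups(v, d, ("a", "b"))
        assert res.test_used == "t"

    def test_large_skewed_groups_fall_back_to_mann_whitney(self, rng):
        d = design_for({"a": 40, "b": 40})
        v = series_for(
            d, {"a": list(rng.lognormal(0, 1.5, 40)), "b": list(rng.lognormal(0, 1.5, 40))}
        )
        assert compare_two_groups(v, d, ("a", "b")).test_used == "mann_whitney"

    def test_sem_and_direction_semantics(self):
        d = design_for({"control": 3, "patient": 3})
        v = series_for(d, {"control": [5.0, 6.0, 7.0], "patient": [1.0, 2.0, 3.0]})
        res = compare_two_groups(v, d, ("control", "patient"))
        assert res.direction == "down"  # patient mean below control mean
        assert res.sems[0] == pytest.approx(np.std([5, 6, 7], ddof=1) / np.sqrt(3))

    def test_too_few_values_rejected(self):
        d = design_for({"a": 2, "b": 5})
        v = series_for(d, {"a": [1, 2], "b": [1, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match=">= 3"):
            compare_two_groups(v, d, ("a", "b"))


class TestMultiGroups:
    def test_two_groups_redirects(self):
        d = design_for({"a": 5, "b": 5})
        v = series_for(d, {"a": [1] * 5, "b": [2] * 5})
        with pytest.raises(ValueError, match="compare_two_groups"):
            compare_multi_groups(v, d)

    def test_shifted_group_detected_and_flagged(self, rng):
        d = design_for({"a": 12, "b": 12, "c": 12})
        v = series_for(
            d,
            {"a": list(rng.normal(0, 1, 12)), "b": list(rng.normal(0, 1, 12)),
             "c": list(rng.normal(10, 1, 12))},
        )
        omnibus, pairwise = compare_multi_groups(v, d)
        assert omnibus.test_used == "kruskal_wallis"
        assert omnibus.p_value < 1e-3
        flagged = {frozenset(c.groups) for c in pairwise if c.adjusted_p < 0.05}
        assert frozenset(("a", "c")) in flagged and frozenset(("b", "c")) in flagged

    def test_null_rarely_flags_pairs(self, rng):
        # identically drawn groups: expect no BH-significant pair in the
        # vast majority of replicates (spec envelope: >= 94% over nulls)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            d = design_for({"a": 10, "b": 10, "c": 10})
            v = series_for(
                d, {g: list(rng.normal(0, 1, 10)) for g in ("a", "b", "c")}
            )
            _, pairwise = compare_multi_groups(v, d)
            if any(c.adjusted_p < 0.05 for c in pairwise):
                hits += 1
        assert hits / n_sim <= 0.06


class TestBH:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_definition(self, pvals):
        adj = bh_adjust(pvals)
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            j = np.arange(rank_pos, m)
            expected[idx] = min(1.0, np.min(m * p[order][j] / (j + 1)))
        np.testing.assert_allclose(adj, expected, atol=1e-12)


class TestMeaningfulSites:
    @staticmethod
    def site_table(rng, n_per_group, shifts: dict[str, float], coverage=50,
                   base=0.16):
        d = design_for({"control": n_per_group, "patient": n_per_group})
        rows = []
        for site, shift in shifts.items():
            for s in d.samples:
                level = base + (shift if s.startswith("patient") else 0.0)
                cov = coverage
                edited = rng.binomial(cov, level)
                rows.append(
                    {"sample": s, "site": site, "gene": site, "coverage": cov,
                     "edited": edited, "level_pct": 100 * edited / cov,
                     "included": cov >= 10}
                )
        return pd.DataFrame(rows), d

    def test_observed_small_diff_never_meaningful_regardless_of_p(self, rng):
        # huge coverage: the difference is measured precisely (~2pp) and the
        # rank test is decisively significant, yet the threshold rule blocks it
        table, d = self.site_table(rng, 15, {"s1": 0.02}, coverage=4000)
        calls, _ = meaningful_sites(table, d, ("control", "patient"))
        (call,) = calls
        assert call.p_value < 0.05
        assert abs(call.mean_diff_pct) < 5
        assert not call.meaningful

    def test_paper_scale_shift_called(self, rng):
        table, d = self.site_table(rng, 15, {"s1": 0.11}, coverage=50)
        calls, _ = meaningful_sites(table, d, ("control", "patient"))
        assert calls[0].meaningful

    def test_sparse_sites_excluded(self, rng):
        table, d = self.site_table(rng, 15, {"s1": 0.0, "s2": 0.0}, coverage=50)
        table.loc[(table["site"] == "s2") & table["sample"].str.startswith("patient"),
                  "included"] = False
        calls, excluded = meaningful_sites(table, d, ("control", "patient"))
        assert excluded == ["s2"]
        assert [c.site for c in calls] == ["s1"]


class TestRegression:
    @staticmethod
    def covariate_design(rng, n=40, effect=0.4, age_effect=0.0):
        rows, resp = [], {}
        for i in range(2 * n):
            g = "case" if i >= n else "control"
            age = float(rng.uniform(40, 80))
            sex = str(rng.choice(["F", "M"]))
            name = f"s{i}"
            rows.append({"sample": name, "group": g, "age": age, "sex": sex})
            resp[name] = (
                effect * (g == "case") + age_effect * age + rng.normal(0, 0.5)
            )
        return CohortDesign(pd.DataFrame(rows)), pd.Series(resp)

    def test_group_effect_recovered_within_two_se(self, rng):
        hits = 0
        for _ in range(40):
            d, y = self.covariate_design(rng, n=40, effect=0.4)
            fit = covariate_regression(y, d, ("control", "case"))
            row = fit[fit["term"] == "group"].iloc[0]
            if abs(row["coef"] - 0.4) <= 2 * row["stderr"]:
                hits += 1
        assert hits >= 34  # ~95% nominal coverage

    def test_null_group_effect_calibrated(self, rng):
        pvals = []
        for _ in range(120):
            d, y = self.covariate_design(rng, n=25, effect=0.0, age_effect=0.02)
            fit = covariate_regression(y, d, ("control", "case"))
            pvals.append(fit[fit["term"] == "group"].iloc[0]["p_value"])
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.005 <= rate <= 0.12

    def test_constant_response_handled(self, rng):
        d, _ = self.covariate_design(rng, n=10)
        y = pd.Series(1.0, index=d.samples)
        fit = covariate_regression(y, d, ("control", "case"))
        assert fit.attrs["r_squared"] == 0.0
        assert fit[fit["term"] == "group"].iloc[0]["coef"] == pytest.approx(0.0, abs=1e-9)

    def test_collinear_design_named(self, rng):
        d, y = self.covariate_design(rng, n=10)
        d.table["age"] = 50.0  # constant age column is collinear with intercept
        with pytest.raises(ValueError, match="age"):
            covariate_regression(y, d, ("control", "case"))

    def test_missing_covariates_beyond_tolerance_rejected(self, rng):
        d, y = self.covariate_design(rng, n=10)
        d.table.loc[:9, "age"] = np.nan  # 50% missing
        with pytest.raises(ValueError, match="age/sex"):
            covariate_regression(y, d, ("control", "case"))


class TestCorrelate:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 1.0),
            ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], 0.8),  # rank-difference formula
        ],
    )
    def test_known_rhos(self, x, y, expected):
        rho, _ = correlate(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = correlate([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2, 3])


class TestInteraction:
    def test_true_interaction_detected_most_runs(self, rng):
        hits = 0
        for _ in range(60):
            z1, z2 = rng.normal(size=100), rng.normal(size=100)
            y = 1 + 0.3 * z1 + 0.3 * z2 + 0.2 * z1 * z2 + rng.normal(0, 0.3, 100)
            fit = interaction_model(y, z1, z2)
            if fit[fit["term"] == "adar1:isg"].iloc[0]["p_value"] < 0.05:
                hits += 1
        assert hits / 60 >= 0.8

    def test_additive_null_calibrated(self, rng):
        pvals = []
        for _ in range(150):
            z1, z2 = rng.normal(size=100), rng.normal(size=100)
            y = 1 + 0.3 * z1 + 0.3 * z2 + rng.normal(0, 0.3, 100)
            fit = interaction_model(y, z1, z2)
            pvals.append(fit[fit["term"] == "adar1:isg"].iloc[0]["p_value"])
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.005 <= rate <= 0.12

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="10"):
            interaction_model([1] * 5, [1] * 5, [1] * 5)


class TestRoc:
    def test_hand_enumerated_pairs(self):
        res = roc_auc([3, 5, 1, 2, 4], ["case", "case", "ctrl", "ctrl", "ctrl"], "case")
        assert res.auc == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        res = roc_auc([10, 11, 1, 2], ["c", "c", "n", "n"], "c")
        assert res.auc == 1.0

    def test_label_permutation_centers_on_half(self, rng):
        aucs = []
        for _ in range(200):
            v = rng.normal(size=30)
            labels = rng.permutation(["case"] * 15 + ["ctrl"] * 15)
            aucs.append(roc_auc(v, labels, "case").auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], ["a", "a", "a"], "a")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equals_exhaustive_pairwise(self, seed):
        r = np.random.default_rng(seed)
        n1, n0 = int(r.integers(2, 26)), int(r.integers(2, 26))
        # coarse grid to force ties
        case = r.integers(0, 10, n1).astype(float)
        ctrl = r.integers(0, 10, n0).astype(float)
        res = roc_auc(
            np.concatenate([case, ctrl]),
            ["case"] * n1 + ["ctrl"] * n0,
            "case",
        )
        wins = sum((c > d) + 0.5 * (c == d) for c in case for d in ctrl)
        assert res.auc == pytest.approx(wins / (n1 * n0), abs=1e-12)
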