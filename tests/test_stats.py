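"""The statistical procedures against from-scratch oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meaningmaps.stats import (
    cook_screened_correlation,
    gg_epsilon,
    mixed_anova_2x2,
    paired_t,
    paired_t_power,
    paired_wilcoxon,
    pages_test,
    power_mde_paired_t,
    rm_anova_2x3_gg,
    welch_t,
)


def _mixed_frame(y, groups):
    """y: (N, 2) within-level values; groups: per-subject between label."""
    rows = []
    for i, (row, g) in enumerate(zip(y, groups)):
        for j, v in enumerate(row):
            rows.append(
                {"subject": f"s{i}", "between": g, "within": f"w{j}", "value": v}
            )
    return pd.DataFrame(rows)


def _mixed_anova_ss_oracle(y, groups):
    """Brute-force sums of squares via explicit cell means."""
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    grand = y.mean()
    ss = {}
    subj_means = y.mean(axis=1)
    g_means = {g: subj_means[groups == g].mean() for g in labels}
    n_per = (groups == labels[0]).sum()
    ss["between"] = 2 * n_per * sum((g_means[g] - grand) ** 2 for g in labels)
    ss["subj"] = 2 * sum(
        (subj_means[i] - g_means[groups[i]]) ** 2 for i in range(len(y))
    )
    w_means = y.mean(axis=0)
    ss["within"] = len(y) * ((w_means - grand) ** 2).sum()
    cell = {
        (g, j): y[groups == g, j].mean() for g in labels for j in range(2)
    }
    ss["inter"] = n_per * sum(
        (cell[(g, j)] - g_means[g] - w_means[j] + grand) ** 2
        for g in labels
        for j in range(2)
    )
    ss["total"] = ((y - grand) ** 2).sum()
    ss["resid"] = ss["total"] - ss["between"] - ss["subj"] - ss["within"] - ss["inter"]
    return ss


class TestMixedAnova:
    def test_all_equal_f_zero(self):
        df = _mixed_frame(np.full((8, 2), 3.0), ["a"] * 4 + ["b"] * 4)
        res = mixed_anova_2x2(df)
        assert all(e.F == 0.0 for e in res.effects)

    def test_pure_between_offset(self, rng):
        base = rng.normal(size=(8, 1)) + np.zeros((8, 2))
        y = base.copy()
        y[4:] += 5.0  # constant offset for group b, both within-levels
        res = mixed_anova_2x2(_mixed_frame(y, ["a"] * 4 + ["b"] * 4))
        assert res["between"].F > 0
        assert res["interaction"].F == pytest.approx(0.0, abs=1e-18)

    def test_ss_matches_bruteforce_oracle(self, rng):
        y = rng.normal(size=(8, 2))
        groups = ["a"] * 4 + ["b"] * 4
        res = mixed_anova_2x2(_mixed_frame(y, groups))
        oracle = _mixed_anova_ss_oracle(y, groups)
        assert res.ss["between"] == pytest.approx(oracle["between"], abs=1e-9)
        assert res.ss["within"] == pytest.approx(oracle["within"], abs=1e-9)
        assert res.ss["interaction"] == pytest.approx(oracle["inter"], abs=1e-9)
        assert res.ss["residual"] == pytest.approx(oracle["resid"], abs=1e-9)

    def test_ss_conservation(self, rng):
        y = rng.normal(size=(12, 2))
        res = mixed_anova_2x2(_mixed_frame(y, ["a"] * 6 + ["b"] * 6))
        parts = (
            res.ss["between"] + res.ss["subjects_within_groups"]
            + res.ss["within"] + res.ss["interaction"] + res.ss["residual"]
        )
        assert parts == pytest.approx(res.ss["total"], rel=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(10, 2))
        df = _mixed_frame(y, ["a"] * 5 + ["b"] * 5)
        res = mixed_anova_2x2(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="within", subject="subject", between="between"
        ).set_index("Source")
        assert res["between"].F == pytest.approx(ref.loc["between", "F"], rel=1e-9)
        assert res["within"].F == pytest.approx(ref.loc["within", "F"], rel=1e-9)
        assert res["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )

    def test_missing_cell_errors(self):
        df = _mixed_frame(np.zeros((4, 2)), ["a", "a", "b", "b"]).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            mixed_anova_2x2(df)


class TestPairedWilcoxon:
    def test_identical_samples_p_one(self):
        r = paired_wilcoxon([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r.p == 1.0

    def test_six_positive_differences_exact(self):
        """All-positive n=6: one-sided exact p = 1/2^6 = 1/64."""
        x = np.arange(1.0, 7.0) + np.linspace(0.5, 1.5, 6)
        y = np.arange(1.0, 7.0)
        r = paired_wilcoxon(x, y, alternative="greater")
        assert r.p == pytest.approx(1 / 64)

    def test_bonferroni_doubles_p(self, rng):
        x = rng.normal(0.5, 1, size=30)
        y = rng.normal(0.0, 1, size=30)
        raw = paired_wilcoxon(x, y, n_comparisons=1)
        corr = paired_wilcoxon(x, y, n_comparisons=2)
        assert corr.p == pytest.approx(min(1.0, 2 * raw.p))
        assert "x2" in corr.correction_applied

    def test_all_zero_differences(self):
        r = paired_wilcoxon([1.0, 2.0], [1.0, 2.0])
        assert r.p == 1.0 and "zero" in r.correction_applied


class TestTTests:
    def test_identical_samples_zero_t_errors(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_shifted_samples_zero_variance_errors(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [2, 3, 4])

    def test_paired_matches_formula(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = paired_t(x, y)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(20))
        assert r.statistic == pytest.approx(t, rel=1e-12)
        assert r.df == 19
        assert r.ci95[0] < d.mean() < r.ci95[1]

    def test_welch_matches_formula(self, rng):
        a, b = rng.normal(size=15), rng.normal(1.0, 2.0, size=25)
        r = welch_t(a, b)
        se = np.sqrt(a.var(ddof=1) / 15 + b.var(ddof=1) / 25)
        assert r.statistic == pytest.approx((a.mean() - b.mean()) / se, rel=1e-12)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-12)


class TestPagesTest:
    def test_perfect_ordering_maximum(self):
        m = np.tile([1.0, 2.0, 3.0], (122, 1))
        r = pages_test(m)
        assert r.L == 1708.0 == 14 * 122
        assert r.p < 1e-10

    def test_all_tied_null_expectation(self):
        r = pages_test(np.ones((9, 3)))
        assert r.L == 12 * 9

    def test_exact_matches_bruteforce_enumeration(self, rng):
        """n=4, k=3: exact p equals enumeration over all 6^4 rank orders."""
        m = rng.normal(size=(4, 3))
        r = pages_test(m)
        assert r.method == "exact"
        perms = list(itertools.permutations([1, 2, 3]))
        j = np.array([1, 2, 3])
        count = total = 0
        for combo in itertools.product(perms, repeat=4):
            L = sum((j * np.array(p)).sum() for p in combo)
            total += 1
            if L >= r.L:
                count += 1
        assert r.p == pytest.approx(count / total, rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        m = rng.normal(size=(10, 4))
        assert pages_test(m).L == pages_test(np.exp(m)).L

    def test_k_too_small_errors(self):
        with pytest.raises(ValueError):
            pages_test(np.zeros((5, 2)))


class TestCookScreen:
    def test_collinear_no_exclusions(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        res = cook_screened_correlation(x, y)
        assert res["screen"].excluded_indices == ()
        assert res["r"] == pytest.approx(1.0, abs=1e-6)

    def test_gross_outlier_excluded(self, rng):
        x = np.linspace(0, 10, 21)
        y = 3 * x + rng.normal(0, 0.3, 21)
        x = np.append(x, 5.0)
        y = np.append(y, 200.0)  # gross outlier
        res = cook_screened_correlation(x, y)
        assert res["screen"].excluded_indices == (21,)
        assert res["r"] > 0.99 > res["r_unscreened"]

    def test_clean_data_screened_equals_unscreened(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = cook_screened_correlation(x, y)
        if not res["screen"].excluded_indices:
            assert res["r"] == pytest.approx(res["r_unscreened"], abs=1e-12)

    def test_cooks_distance_definitional(self, rng):
        """Cook's D from the leave-one-out definition matches statsmodels'."""
        x = rng.normal(size=12)
        y = 1.0 + 2.0 * x + rng.normal(size=12)
        X = np.column_stack([np.ones(12), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        p = 2
        s2 = (resid**2).sum() / (12 - p)
        hat = X @ np.linalg.inv(X.T @ X) @ X.T
        h = np.diag(hat)
        d_oracle = resid**2 / (p * s2) * h / (1 - h) ** 2
        import statsmodels.api as sm

        model = sm.OLS(y, X).fit()
        d_sm = model.get_influence().cooks_distance[0]
        assert np.allclose(d_oracle, d_sm, rtol=1e-9)


class TestPower:
    def test_study_sample_size_effect(self):
        """n=122, alpha=.05 two-tailed, power .95 -> minimal D_z = 0.33."""
        spec = power_mde_paired_t(122, 0.05, 0.95)
        assert round(spec.mde_dz, 2) == 0.33

    def test_monotone_in_n_and_power(self):
        d_small_n = power_mde_paired_t(20, 0.05, 0.9).mde_dz
        d_big_n = power_mde_paired_t(200, 0.05, 0.9).mde_dz
        assert d_big_n < d_small_n
        d_lo = power_mde_paired_t(50, 0.05, 0.8).mde_dz
        d_hi = power_mde_paired_t(50, 0.05, 0.95).mde_dz
        assert d_hi > d_lo

    def test_power_function_bruteforce_grid(self):
        """Root sits where a dense D_z grid first reaches the target power."""
        n, alpha, target = 10, 0.05, 0.9
        spec = power_mde_paired_t(n, alpha, target)
        grid = np.linspace(0.01, 3.0, 3000)
        powers = np.array([paired_t_power(d, n, alpha) for d in grid])
        first = grid[np.argmax(powers >= target)]
        assert spec.mde_dz == pytest.approx(first, abs=1e-3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            power_mde_paired_t(1)
        with pytest.raises(ValueError):
            power_mde_paired_t(10, alpha=1.5)


def _rm_frame(cube):
    rows = []
    n = cube.shape[0]
    for s in range(n):
        for ci, c in enumerate(("con", "incon")):
            for pi, p in enumerate(("L", "M", "H")):
                rows.append(
                    {"subject": s, "condition": c, "ptype": p, "value": cube[s, ci, pi]}
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_all_equal_f_zero(self):
        res = rm_anova_2x3_gg(_rm_frame(np.full((6, 2, 3), 2.0)))
        assert all(e.F == 0.0 for e in res.effects)

    def test_ss_matches_bruteforce(self, rng):
        cube = rng.normal(size=(10, 2, 3))
        res = rm_anova_2x3_gg(_rm_frame(cube))
        grand = cube.mean()
        # oracle: explicit loops over marginal means
        m_a = [cube[:, a, :].mean() for a in range(2)]
        m_b = [cube[:, :, b].mean() for b in range(3)]
        ss_a = 10 * 3 * sum((m - grand) ** 2 for m in m_a)
        ss_b = 10 * 2 * sum((m - grand) ** 2 for m in m_b)
        ss_ab = 10 * sum(
            (cube[:, a, b].mean() - m_a[a] - m_b[b] + grand) ** 2
            for a in range(2)
            for b in range(3)
        )
        assert res.ss["condition"] == pytest.approx(ss_a, abs=1e-9)
        assert res.ss["ptype"] == pytest.approx(ss_b, abs=1e-9)
        assert res.ss["interaction"] == pytest.approx(ss_ab, abs=1e-9)
        total_parts = sum(
            res.ss[k]
            for k in (
                "subject", "condition", "ptype", "interaction",
                "condition_x_subject", "ptype_x_subject", "residual",
            )
        )
        assert total_parts == pytest.approx(res.ss["total"], rel=1e-12)

    def test_gg_epsilon_bounds_and_identity_covariance(self, rng):
        # orthonormal-contrast scores with iid covariance -> epsilon ~ 1
        scores = rng.normal(size=(4000, 2))
        eps = gg_epsilon(scores)
        assert 0.5 <= eps <= 1.0 and eps == pytest.approx(1.0, abs=0.05)
        # epsilon from a maximally non-spherical covariance approaches 1/(k-1)
        base = rng.normal(size=4000)
        degenerate = np.column_stack([base, 1e-6 * rng.normal(size=4000)])
        assert gg_epsilon(degenerate) == pytest.approx(0.5, abs=0.01)

    def test_epsilon_from_constructed_covariance(self):
        """Epsilon formula against eigenvalue closed form for a known S."""
        lam = np.array([3.0, 1.0])
        expect = lam.sum() ** 2 / (2 * (lam**2).sum())
        rng = np.random.default_rng(0)
        z = rng.normal(size=(60000, 2))
        scores = z * np.sqrt(lam)
        assert gg_epsilon(scores) == pytest.approx(expect, abs=0.02)

    def test_strong_ptype_effect_detected(self, rng):
        cube = rng.normal(size=(12, 2, 3)) * 0.3
        cube[:, :, 0] += 1.4
        cube[:, :, 1] += 2.4
        cube[:, :, 2] += 4.7
        res = rm_anova_2x3_gg(_rm_frame(cube))
        assert res["ptype"].p < 1e-6
        assert res["condition"].p > 0.01
        assert res["ptype"].gg_epsilon <= 1.0

    def test_missing_cells_error(self, rng):
        df = _rm_frame(rng.normal(size=(5, 2, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2x3_gg(df)
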