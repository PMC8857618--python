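"""Statistical procedures for the gaze/rating comparisons.

Self-contained implementations of the designs actually used in the
analyses: a mixed 2x2 ANOVA (scene as the "subject", one within- and one
between-"subjects" factor) with omega-squared effect sizes, a 2x3
repeated-measures ANOVA with Greenhouse-Geisser correction, paired
Wilcoxon signed-rank and t tests with explicit Bonferroni factors, Welch's
unequal-variance t test, Page's trend test for a hypothesised ordering of
repeated measures, Cook's-distance-screened correlation, and the minimal
detectable effect of a paired t test at given power.

Omega-squared here is the classical estimator
``(SS_effect - df_effect * MS_error) / (SS_total + MS_error)`` with each
effect's own error term; software packages differ in the variant they
report for mixed designs, so parity with any particular package's values
is approximate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "PairedTestResult",
    "PageResult",
    "PowerSpec",
    "CookScreen",
    "mixed_anova_2x2",
    "paired_wilcoxon",
    "paired_t",
    "welch_t",
    "pages_test",
    "cook_screened_correlation",
    "power_mde_paired_t",
    "gg_epsilon",
    "rm_anova_2x3_gg",
]


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df_num: float
    df_den: float
    p: float
    omega_squared: float | None = None
    gg_epsilon: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    effects: tuple[AnovaEffect, ...]
    ss: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p: float
    mean_difference: float
    ci95: tuple[float, float]
    df: float | None = None
    correction_applied: str = "none"


@dataclass(frozen=True)
class PageResult:
    L: float
    p: float
    n: int
    k: int
    method: str


@dataclass(frozen=True)
class PowerSpec:
    n: int
    alpha: float
    power: float
    mde_dz: float


@dataclass(frozen=True)
class CookScreen:
    threshold: float
    excluded_indices: tuple[int, ...]


# ---------------------------------------------------------------------------
# mixed 2 x 2 ANOVA


def mixed_anova_2x2(data: pd.DataFrame) -> AnovaResult:
    """Mixed ANOVA: one 2-level between factor, one 2-level within factor.

    ``data`` must have columns ``subject``, ``between``, ``within``,
    ``value``; each subject belongs to one between-group and contributes a
    value at both within-levels (balanced design required).

    Effects are named ``between``, ``within``, ``interaction``; the
    between effect is tested against subjects-within-groups, the within
    effect and the interaction against the within-by-subject residual.
    """
    req = {"subject", "between", "within", "value"}
    if not req.issubset(data.columns):
        raise ValueError(f"need columns {sorted(req)}")
    wide = data.pivot_table(
        index=["between", "subject"], columns="within", values="value"
    )
    if wide.isna().any().any():
        raise ValueError("missing cells: every subject needs both within-levels")
    if wide.shape[1] != 2:
        raise ValueError("within factor must have exactly 2 levels")
    groups = wide.index.get_level_values("between").unique()
    if len(groups) != 2:
        raise ValueError("between factor must have exactly 2 levels")
    sizes = [len(wide.loc[g]) for g in groups]
    if sizes[0] != sizes[1]:
        raise ValueError("balanced design required (equal group sizes)")

    y = wide.to_numpy()  # (N subjects, 2 within-levels)
    n_per = sizes[0]
    n_sub = y.shape[0]
    grand = y.mean()
    subj_means = y.mean(axis=1)
    within_means = y.mean(axis=0)
    group_of = wide.index.get_level_values("between")
    group_idx = np.array([list(groups).index(g) for g in group_of])
    group_means = np.array([subj_means[group_idx == i].mean() for i in range(2)])
    cell_means = np.array(
        [[y[group_idx == i, j].mean() for j in range(2)] for i in range(2)]
    )

    ss_total = ((y - grand) ** 2).sum()
    ss_between = 2 * n_per * ((group_means - grand) ** 2).sum()
    ss_subj_within_grp = 2 * (
        (subj_means - group_means[group_idx]) ** 2
    ).sum()
    ss_within = n_sub * ((within_means - grand) ** 2).sum()
    ss_inter = n_per * (
        (cell_means - group_means[:, None] - within_means[None, :] + grand) ** 2
    ).sum()
    ss_resid = ss_total - ss_between - ss_subj_within_grp - ss_within - ss_inter
    ss_resid = max(ss_resid, 0.0)

    df_between, df_subj = 1, n_sub - 2
    df_within, df_inter, df_resid = 1, 1, n_sub - 2
    ms_subj = ss_subj_within_grp / df_subj
    ms_resid = ss_resid / df_resid

    def effect(name, ss, df_num, ms_err, df_den):
        if ms_err == 0:
            f = 0.0 if ss == 0 else np.inf
        else:
            f = (ss / df_num) / ms_err
        p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
        om = (ss - df_num * ms_err) / (ss_total + ms_err) if (ss_total + ms_err) > 0 else 0.0
        return AnovaEffect(name, float(f), df_num, df_den, p, float(om))

    effects = (
        effect("between", ss_between, df_between, ms_subj, df_subj),
        effect("within", ss_within, df_within, ms_resid, df_resid),
        effect("interaction", ss_inter, df_inter, ms_resid, df_resid),
    )
    ss = {
        "between": ss_between,
        "subjects_within_groups": ss_subj_within_grp,
        "within": ss_within,
        "interaction": ss_inter,
        "residual": ss_resid,
        "total": ss_total,
    }
    return AnovaResult(effects=effects, ss=ss)


# ---------------------------------------------------------------------------
# paired / Welch tests


def _mean_ci(diff: np.ndarray) -> tuple[float, tuple[float, float]]:
    n = diff.size
    m = float(diff.mean())
    se = diff.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return m, (m - tcrit * se, m + tcrit * se)


def paired_wilcoxon(
    x, y, n_comparisons: int = 1, alternative: str = "two-sided"
) -> PairedTestResult:
    """Wilcoxon signed-rank on paired samples, Bonferroni-multiplied p.

    Zero differences are dropped (signed-rank convention); exact
    (enumeration) p for n <= 25, otherwise normal approximation with
    continuity correction and midranks for ties.  ``n_comparisons``
    multiplies the p value (capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    nz = diff[diff != 0]
    if nz.size == 0:
        m, ci = _mean_ci(diff) if diff.size > 1 else (0.0, (0.0, 0.0))
        return PairedTestResult(
            statistic=0.0, p=1.0, mean_difference=m, ci95=ci,
            correction_applied=f"bonferroni x{n_comparisons} (all differences zero)",
        )
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", correction=(method == "approx"),
        alternative=alternative, method=method,
    )
    m, ci = _mean_ci(diff)
    return PairedTestResult(
        statistic=float(res.statistic),
        p=float(min(1.0, res.pvalue * n_comparisons)),
        mean_difference=m,
        ci95=ci,
        correction_applied=f"bonferroni x{n_comparisons}",
    )


def paired_t(x, y, n_comparisons: int = 1) -> PairedTestResult:
    """Paired-samples t test with 95% CI of the mean difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired t needs equal-length samples with n >= 2")
    diff = x - y
    if diff.std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(x, y)
    m, ci = _mean_ci(diff)
    return PairedTestResult(
        statistic=float(res.statistic),
        p=float(min(1.0, res.pvalue * n_comparisons)),
        mean_difference=m,
        ci95=ci,
        df=float(x.size - 1),
        correction_applied=f"bonferroni x{n_comparisons}" if n_comparisons > 1 else "none",
    )


def welch_t(a, b) -> PairedTestResult:
    """Welch's unequal-variance t test between two independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch t needs n >= 2 per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    m = float(a.mean() - b.mean())
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if se == 0:
        raise ValueError("zero variance in both samples; t undefined")
    df = float(res.df)
    tcrit = stats.t.ppf(0.975, df)
    return PairedTestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        mean_difference=m,
        ci95=(m - tcrit * se, m + tcrit * se),
        df=df,
    )


# ---------------------------------------------------------------------------
# Page's trend test


def pages_test(matrix, ranks_increasing: bool = True) -> PageResult:
    """Page's L test for a monotone ordering of k repeated measures.

    Rows are subjects/raters, columns the k >= 3 conditions in the
    hypothesised *increasing* order (pass ``ranks_increasing=False`` to
    reverse).  Within-row midranks are used; ``L = sum_j j * R_j`` with
    ``R_j`` the column rank sums.  The one-sided p value against the
    ordered alternative comes from exact enumeration of all within-row
    rank permutations for n <= 8 and k <= 4 when rows are tie-free,
    otherwise from the normal approximation
    ``z = (L - n k (k+1)^2 / 4) / sd`` with the permutation variance of L.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x conditions)")
    n, k = m.shape
    if k < 3:
        raise ValueError("Page's test needs k >= 3 conditions")
    if not ranks_increasing:
        m = m[:, ::-1]
    ranks = np.apply_along_axis(stats.rankdata, 1, m)  # midranks
    col_sums = ranks.sum(axis=0)
    j = np.arange(1, k + 1)
    L = float((j * col_sums).sum())

    has_ties = any(np.unique(row).size < k for row in m)
    if n <= 8 and k <= 4 and not has_ties:
        # exact null: each row's ranks an independent uniform permutation
        perms = list(itertools.permutations(range(1, k + 1)))
        ls = np.array([float((j * np.asarray(p)).sum()) for p in perms])
        # distribution of the sum of n iid draws from ls
        dist = {0.0: 1.0}
        for _ in range(n):
            new: dict[float, float] = {}
            for tot, cnt in dist.items():
                for l in ls:
                    new[tot + l] = new.get(tot + l, 0.0) + cnt
            dist = new
        total = sum(dist.values())
        p = sum(c for tot, c in dist.items() if tot >= L) / total
        method = "exact"
    else:
        mean_l = n * k * (k + 1) ** 2 / 4.0
        # per-row permutation variance of sum_j j * r_j (tie-free value)
        var_row = (k**3 - k) ** 2 / (144.0 * (k - 1))
        z = (L - mean_l) / np.sqrt(n * var_row)
        p = float(stats.norm.sf(z))
        method = "normal"
    return PageResult(L=L, p=float(p), n=n, k=k, method=method)


# ---------------------------------------------------------------------------
# Cook's-distance-screened correlation


def cook_screened_correlation(x, y) -> dict:
    """Pearson correlation after excluding high-influence points.

    Fits ``y ~ x`` by OLS, computes Cook's distance per point, excludes
    points above 3x the mean distance, and reports the correlation (with
    Fisher-z 95% CI) on the retained points alongside the unscreened one.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    cooks = np.nan_to_num(model.get_influence().cooks_distance[0])
    threshold = 3.0 * float(np.mean(cooks))
    # a (near-)perfect fit leaves only round-off in the residuals, making
    # the distances meaningless ratios of noise
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    degenerate = model.ssr <= 1e-12 * max(ss_tot, 1.0)
    excluded = () if degenerate else tuple(
        int(i) for i in np.nonzero(cooks > threshold)[0]
    )
    keep = np.setdiff1d(np.arange(x.size), excluded)
    if keep.size < 4:
        raise ValueError("screening left fewer than 4 points")

    def corr(a, b):
        r = float(stats.pearsonr(a, b).statistic)
        n = a.size
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        hw = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
        t = r * np.sqrt((n - 2) / max(1e-300, 1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
        return r, n - 2, ci, p

    r, df, ci, p = corr(x[keep], y[keep])
    r_all, df_all, ci_all, p_all = corr(x, y)
    return {
        "r": r, "df": df, "ci95": ci, "p": p,
        "screen": CookScreen(threshold=threshold, excluded_indices=excluded),
        "r_unscreened": r_all, "df_unscreened": df_all,
        "ci95_unscreened": ci_all, "p_unscreened": p_all,
    }


# ---------------------------------------------------------------------------
# power


def paired_t_power(dz: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-tailed paired t test at effect size ``dz``."""
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2.0, df)
    ncp = dz * np.sqrt(n)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_mde_paired_t(n: int, alpha: float = 0.05, power: float = 0.95) -> PowerSpec:
    """Smallest Cohen's D_z detectable by a two-tailed paired t test.

    Root-finds the monotone power function in D_z at the given sample
    size and significance level.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if paired_t_power(0.0, n, alpha) >= power:
        raise ValueError("requested power attained at zero effect; degenerate")
    hi = 0.1
    while paired_t_power(hi, n, alpha) < power:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("requested power unattainable")
    dz = optimize.brentq(lambda d: paired_t_power(d, n, alpha) - power, 0.0, hi)
    return PowerSpec(n=n, alpha=alpha, power=power, mde_dz=float(dz))


# ---------------------------------------------------------------------------
# 2 x 3 repeated-measures ANOVA with Greenhouse-Geisser correction


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows sum to zero)."""
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from per-subject effect scores.

    ``scores`` is an (n, m) matrix of the m contrast variables of the
    effect per subject (already multiplied by an orthonormal contrast);
    epsilon = tr(S)^2 / (m * tr(S @ S)) with S their covariance, bounded
    to [1/m, 1].
    """
    s = np.cov(scores, rowvar=False)
    s = np.atleast_2d(s)
    m = s.shape[0]
    tr = np.trace(s)
    if tr <= 0:
        return 1.0
    eps = tr**2 / (m * np.trace(s @ s))
    return float(np.clip(eps, 1.0 / m, 1.0))


def rm_anova_2x3_gg(data: pd.DataFrame) -> AnovaResult:
    """Two-way fully repeated-measures ANOVA (2 x 3) with GG correction.

    ``data`` columns: ``subject``, ``condition`` (2 levels), ``ptype``
    (3 levels), ``value``; every subject must have all 6 cells.
    Greenhouse-Geisser epsilon is estimated for every effect and applied
    to the dfs of effects involving the 3-level factor (for the 2-level
    factor epsilon is identically 1).
    """
    req = {"subject", "condition", "ptype", "value"}
    if not req.issubset(data.columns):
        raise ValueError(f"need columns {sorted(req)}")
    conds = sorted(data["condition"].unique())
    ptypes = sorted(data["ptype"].unique())
    if len(conds) != 2 or len(ptypes) != 3:
        raise ValueError("design must be 2 (condition) x 3 (ptype)")
    wide = data.pivot_table(
        index="subject", columns=["condition", "ptype"], values="value"
    )
    if wide.isna().any().any() or wide.shape[1] != 6:
        raise ValueError("missing cells: every subject needs all 6 cells")
    cols = [(c, p) for c in conds for p in ptypes]
    y = wide[cols].to_numpy()  # (n, 6) ordered condition-major
    n = y.shape[0]
    cube = y.reshape(n, 2, 3)

    grand = cube.mean()
    m_subj = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))  # condition means
    m_b = cube.mean(axis=(0, 1))  # ptype means
    m_ab = cube.mean(axis=0)  # (2, 3)
    m_as = cube.mean(axis=2)  # (n, 2)
    m_bs = cube.mean(axis=1)  # (n, 3)

    ss_a = n * 3 * ((m_a - grand) ** 2).sum()
    ss_b = n * 2 * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = 3 * ((m_as - m_subj[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = 2 * ((m_bs - m_subj[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_subj = 6 * ((m_subj - grand) ** 2).sum()
    ss_total = ((cube - grand) ** 2).sum()
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    c_a = _orthonormal_contrasts(2)
    c_b = _orthonormal_contrasts(3)
    eps_a = 1.0
    eps_b = gg_epsilon(m_bs @ c_b.T)
    inter_scores = np.einsum("nab,xa,yb->nxy", cube, c_a, c_b).reshape(n, 2)
    eps_ab = gg_epsilon(inter_scores)

    def effect(name, ss, df_num, ss_err, df_err, eps):
        ms, ms_err = ss / df_num, ss_err / df_err
        f = 0.0 if ss == 0 else (np.inf if ms_err == 0 else ms / ms_err)
        p = float(stats.f.sf(f, df_num * eps, df_err * eps)) if np.isfinite(f) else 0.0
        om = (ss - df_num * ms_err) / (ss_total + ms_err) if (ss_total + ms_err) > 0 else 0.0
        return AnovaEffect(
            name, float(f), df_num * eps, df_err * eps, p, float(om), gg_epsilon=eps
        )

    effects = (
        effect("condition", ss_a, 1, ss_as, n - 1, eps_a),
        effect("ptype", ss_b, 2, ss_bs, 2 * (n - 1), eps_b),
        effect("interaction", ss_ab, 2, ss_abs, 2 * (n - 1), eps_ab),
    )
    ss = {
        "subject": ss_subj, "condition": ss_a, "ptype": ss_b,
        "interaction": ss_ab, "condition_x_subject": ss_as,
        "ptype_x_subject": ss_bs, "residual": ss_abs, "total": ss_total,
    }
    return AnovaResult(effects=effects, ss=ss)
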