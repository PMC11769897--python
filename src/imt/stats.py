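"""Parameter-level group and symptom statistics.

Implements the analysis battery applied to the fitted curve parameters:

* repeated-measures ANOVA with two 2-level within-subject factors (control
  condition, valence) and an optional between-subjects group factor,
  computed by the classical univariate sums-of-squares route via
  within-subject contrast scores (with 2-level factors sphericity holds
  automatically, so no Greenhouse-Geisser correction is needed);
* Tukey HSD post-hoc contrasts on the studentized range distribution;
* partial correlations (residualization) controlling for age, sex and
  psychoactive medication, with scale-wise Bonferroni correction;
* the Meng-Rosenthal-Rubin Z test for two dependent correlations sharing
  one variable;
* Cronbach's alpha for internal consistency and paired t-tests for
  test-retest stability.

Unbalanced group sizes are handled by effects coding (unweighted marginal
means, the convention of standard ANOVA software).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

__all__ = [
    "rm_anova",
    "tukey_posthoc",
    "partial_corr",
    "dependent_corr_diff",
    "bonferroni_threshold",
    "cronbach_alpha",
    "paired_ttest",
    "parameter_long_table",
    "rt_long_table",
    "correlation_battery",
    "format_anova_report",
]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _effects_design(groups: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Intercept + effects-coded (sum-to-zero) group columns."""
    levels = sorted(groups.unique())
    g = len(levels)
    X = np.ones((len(groups), g))
    for j, lev in enumerate(levels[:-1]):
        col = np.where(groups == lev, 1.0, 0.0)
        col = col - np.where(groups == levels[-1], 1.0, 0.0)
        X[:, j + 1] = col
    return X, levels


def _ols_f(y: np.ndarray, X: np.ndarray, cols: list[int]) -> tuple[float, int, int, float]:
    """Wald F-test that the coefficients in ``cols`` are jointly zero."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df2 = n - p
    s2 = float(resid @ resid) / df2
    XtX_inv = np.linalg.inv(X.T @ X)
    C = np.zeros((len(cols), p))
    for i, c in enumerate(cols):
        C[i, c] = 1.0
    cb = C @ beta
    mid = np.linalg.inv(C @ XtX_inv @ C.T)
    q = len(cols)
    if s2 <= 0:
        return math.inf, q, df2, 0.0
    F = float(cb @ mid @ cb) / (q * s2)
    p_val = float(sps.f.sf(F, q, df2))
    return F, q, df2, p_val


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    between: str | None = None,
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Univariate repeated-measures ANOVA for 2-level within factors.

    ``table`` is long: one row per subject x within-cell.  Returns a frame
    with columns effect, F, df1, df2, p.  With a between factor the error
    degrees of freedom are N - g for every within effect (e.g. 178 for
    N = 181 subjects in 3 groups, 257 for N = 258 with no between factor).
    """
    if not within:
        raise ValueError("at least one within factor required")
    for w in within:
        if table[w].nunique() != 2:
            raise ValueError(f"within factor {w} must have exactly 2 levels")

    wide = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    n_cells = int(np.prod([2] * len(within)))
    bad = wide.index[wide.isna().any(axis=1)].tolist()
    if bad or wide.shape[1] != n_cells:
        raise ValueError(f"incomplete within-factor crossing for subjects: {bad}")

    if between is not None:
        grp = table.groupby(subject)[between].agg(lambda s: s.iloc[0])
        grp = grp.loc[wide.index]
        if grp.nunique() < 2:
            raise ValueError("between factor needs >= 2 levels")
        counts = grp.value_counts()
        if (counts < 2).any():
            raise ValueError("need >= 2 subjects per group")
        X, levels = _effects_design(grp)
        group_cols = list(range(1, len(levels)))
    else:
        X = np.ones((wide.shape[0], 1))
        group_cols = []

    # within-subject contrast scores; F is invariant to contrast scaling
    cells = list(wide.columns)

    def contrast(signs: dict[str, int]) -> np.ndarray:
        w = np.ones(len(cells))
        for j, cell in enumerate(cells):
            key = cell if isinstance(cell, tuple) else (cell,)
            for fi, f in enumerate(within):
                lev_sorted = sorted(table[f].unique())
                if signs.get(f) is not None:
                    w[j] *= 1.0 if key[fi] == lev_sorted[0] else -1.0
        return wide.to_numpy() @ (w / len(cells))

    rows = []
    if between is not None:
        m = contrast({})
        F, df1, df2, p = _ols_f(m, X, group_cols)
        rows.append({"effect": between, "F": F, "df1": df1, "df2": df2, "p": p})

    effect_sets = []
    for r in range(1, len(within) + 1):
        for combo in combinations(within, r):
            effect_sets.append(combo)
    for combo in effect_sets:
        s = contrast({f: 1 for f in combo})
        name = ":".join(combo)
        F, df1, df2, p = _ols_f(s, X, [0])
        rows.append({"effect": name, "F": F, "df1": df1, "df2": df2, "p": p})
        if between is not None:
            F, df1, df2, p = _ols_f(s, X, group_cols)
            rows.append(
                {"effect": f"{between}:{name}", "F": F, "df1": df1, "df2": df2, "p": p}
            )
    return pd.DataFrame(rows)


def tukey_posthoc(
    table: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str = "subject_id",
) -> pd.DataFrame:
    """All pairwise Tukey(-Kramer) HSD contrasts on subject-level means.

    Observations are first averaged within subject (one value per subject),
    then compared across the levels of ``factor`` with studentized-range
    adjusted p-values.
    """
    per_subj = table.groupby(subject).agg({dv: "mean", factor: "first"})
    levels = sorted(per_subj[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor} has < 2 levels")
    groups = {lev: per_subj.loc[per_subj[factor] == lev, dv].to_numpy() for lev in levels}
    ns = {lev: len(v) for lev, v in groups.items()}
    k = len(levels)
    df_err = sum(ns.values()) - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_err
    rows = []
    for a, b in combinations(levels, 2):
        diff = groups[a].mean() - groups[b].mean()
        se = math.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(diff) / se if se > 0 else math.inf
        p_adj = float(studentized_range.sf(q, k, df_err)) if se > 0 else 0.0
        rows.append(
            {"contrast": f"{a} - {b}", "difference": diff, "q": q, "p_adj": min(p_adj, 1.0)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_corr(x, y, covariates=None) -> dict[str, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are regressed on the covariates (plus intercept); the
    correlation of the residuals is returned with a t-based p-value on
    n - 2 - k degrees of freedom.  With no covariates this reduces to the
    ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input variable")
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        Z = np.ones((len(x), 1))
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
        Z = np.column_stack([np.ones(len(x)), C])
    n = len(x)
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clamped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clamped * math.sqrt(df / (1.0 - r_clamped**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return {"r": r, "p": p, "n": n, "df": df}


def dependent_corr_diff(
    r_xy: float, r_xz: float, r_yz: float, n: int, two_sided: bool = False
) -> dict[str, float]:
    """Meng-Rosenthal-Rubin Z test for two dependent correlations.

    Tests whether x correlates differently with y than with z, given the
    y-z correlation, within one sample of size n.  Returns the signed Z and
    a one-sided p-value by default (``two_sided=True`` doubles it).
    """
    for r in (r_xy, r_xz, r_yz):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    z_xy = math.atanh(r_xy)
    z_xz = math.atanh(r_xz)
    r2bar = (r_xy**2 + r_xz**2) / 2.0
    f = min((1.0 - r_yz) / (2.0 * (1.0 - r2bar)), 1.0)
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    Z = (z_xy - z_xz) * math.sqrt((n - 3) / (2.0 * (1.0 - r_yz) * h))
    p = float(sps.norm.sf(abs(Z)))
    if two_sided:
        p = min(2.0 * p, 1.0)
    return {"Z": Z, "p": p}


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test alpha under Bonferroni correction (alpha / n_tests)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum item variances / total variance)."""
    M = np.asarray(items, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a subjects x items matrix with >= 2 of each")
    k = M.shape[1]
    item_vars = M.var(axis=0, ddof=1)
    total_var = M.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def paired_ttest(session1, session2) -> dict[str, float]:
    """Paired-samples t test with df = n - 1.

    Zero difference variance is handled by convention: t = 0 (p = 1) when
    the sessions are identical, +/-inf (p = 0) for a pure constant shift.
    """
    a = np.asarray(session1, dtype=float)
    b = np.asarray(session2, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("sessions must have equal length >= 2")
    d = b - a
    n = len(d)
    if d.var(ddof=1) == 0:
        if d.mean() == 0:
            return {"t": 0.0, "df": n - 1, "p": 1.0}
        return {"t": math.copysign(math.inf, d.mean()), "df": n - 1, "p": 0.0}
    res = sps.ttest_rel(b, a)
    return {"t": float(res.statistic), "df": n - 1, "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# pipeline-facing table builders
# ---------------------------------------------------------------------------


def parameter_long_table(
    estimates: pd.DataFrame, subjects: pd.DataFrame, measure: str
) -> pd.DataFrame:
    """Join fitted parameters with the subject table into a long table.

    One row per subject x condition with ``control`` and ``valence`` columns
    split out of the condition label and the chosen measure (e.g. ``bias``
    or ``sigma``) as the value column.
    """
    df = estimates.copy()
    parts = df["condition"].str.split("-", expand=True)
    df["control"], df["valence"] = parts[0], parts[1]
    df = df.merge(subjects, on="subject_id", how="left")
    cols = ["subject_id", "control", "valence", measure]
    extra = [c for c in subjects.columns if c != "subject_id"]
    return df[cols + extra]


def rt_long_table(trials: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Mean reaction time per subject x (control, valence) cell."""
    rt = (
        trials.groupby(["subject_id", "control", "valence"])["reaction_time"]
        .mean()
        .reset_index()
    )
    return rt.merge(subjects, on="subject_id", how="left")


def correlation_battery(
    estimates: pd.DataFrame,
    subjects: pd.DataFrame,
    measure: str,
    scales: list[str],
    covariates: list[str] = ("age", "sex", "medication"),
    alpha: float = 0.05,
    group: str | None = None,
) -> pd.DataFrame:
    """Partial correlations of each symptom scale with each condition.

    Covariates: age in years, sex and medication as binary indicators.
    Bonferroni correction is applied scale-wise: with the four conditions
    tested per scale the per-test threshold is alpha / 4 = 0.0125.
    """
    wide = estimates.pivot(index="subject_id", columns="condition", values=measure)
    df = wide.merge(subjects.set_index("subject_id"), left_index=True, right_index=True)
    if group is not None:
        df = df[df["group"] == group]
    cov_cols = []
    for c in covariates:
        if c == "sex":
            cov_cols.append((df["sex"].astype(str) == "F").astype(float).to_numpy())
        else:
            cov_cols.append(df[c].astype(float).to_numpy())
    cov = np.column_stack(cov_cols) if cov_cols else None
    conditions = list(wide.columns)
    thresh = bonferroni_threshold(alpha, len(conditions))
    rows = []
    for scale in scales:
        for cond in conditions:
            res = partial_corr(df[scale], df[cond], cov)
            rows.append(
                {
                    "scale": scale,
                    "condition": cond,
                    "measure": measure,
                    "r": res["r"],
                    "p": res["p"],
                    "n": res["n"],
                    "bonferroni_alpha": thresh,
                    "bonferroni_pass": res["p"] < thresh,
                }
            )
    return pd.DataFrame(rows)


def format_anova_report(anova: pd.DataFrame, dv: str) -> str:
    """Plain-text report in the conventional F(df1, df2) = ..., p = ... form."""
    lines = [f"Repeated-measures ANOVA on {dv}:"]
    for _, r in anova.iterrows():
        lines.append(
            f"  {r['effect']}: F({int(r['df1'])},{int(r['df2'])}) = {r['F']:.2f}, "
            f"p = {r['p']:.3g}"
        )
    return "\n".join(lines)
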