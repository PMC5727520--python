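"""Group-comparison statistics for ROI ratio and volume tables.

The input is a long-format table (one row per animal x timepoint x
hemisphere measurement).  The layer provides fixed-effects two-way ANOVA
with interaction (hemisphere x time), one-way ANOVA, a within-subject
repeated-measures ANOVA (subject as blocking factor), an unpaired t-test,
and Tukey HSD multiple-comparison adjustment based on the studentized
range distribution.  Ordinary linear-model fits are delegated to
statsmodels; the Tukey adjustment shares the pooled error term with the
unadjusted pairwise t-tests so that adjusted p >= unadjusted p holds
structurally.

No sphericity correction is applied to the repeated-measures ANOVA; this
is recorded in the result metadata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

ALPHA = 0.05

REQUIRED_COLUMNS = ("animal_id", "value")


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect F table plus an optional Tukey post-hoc table."""

    effects: pd.DataFrame  # columns: effect, df, df_resid, F, p
    posthoc: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def p_value(self, effect: str) -> float:
        row = self.effects.loc[self.effects["effect"] == effect]
        if row.empty:
            raise KeyError(f"no effect named {effect!r}: {list(self.effects['effect'])}")
        return float(row["p"].iloc[0])


def p_to_stars(p: float) -> str:
    """Significance stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def validate_group_table(
    table: pd.DataFrame, keys: tuple[str, ...], response: str = "value"
) -> pd.DataFrame:
    """Check finite responses and uniqueness of the key columns."""
    missing = [c for c in (*keys, response) if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    if not np.all(np.isfinite(table[response].to_numpy(dtype=float))):
        raise ValueError("responses must be finite")
    dup = table.duplicated(subset=list(keys))
    if dup.any():
        raise ValueError(f"duplicate rows for keys {keys}: {int(dup.sum())} duplicates")
    return table


def _zero_variance(values: np.ndarray) -> bool:
    return np.allclose(values, values[0], rtol=0.0, atol=1e-300) or np.ptp(values) == 0.0


def _effects_from_anova_lm(table_ss: pd.DataFrame, names: dict[str, str]) -> pd.DataFrame:
    resid_df = float(table_ss.loc["Residual", "df"])
    resid_ss = float(table_ss.loc["Residual", "sum_sq"])
    total_ss = float(table_ss["sum_sq"].sum())
    rows = []
    for term, label in names.items():
        ss = float(table_ss.loc[term, "sum_sq"])
        df = float(table_ss.loc[term, "df"])
        # guard the degenerate error terms statsmodels leaves as NaN
        if total_ss == 0.0 or ss <= 1e-12 * max(total_ss, 1.0):
            f_val, p = 0.0, 1.0
        elif resid_ss <= 1e-12 * total_ss:
            f_val, p = np.inf, 0.0
        else:
            f_val = (ss / df) / (resid_ss / resid_df)
            p = float(sps.f.sf(f_val, df, resid_df))
        rows.append({"effect": label, "df": df, "df_resid": resid_df, "F": f_val, "p": p})
    return pd.DataFrame(rows)


def two_way_anova(
    table: pd.DataFrame,
    response: str = "value",
    factors: tuple[str, str] = ("hemisphere", "timepoint"),
    posthoc_factor: str | None = None,
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction.

    Requires >=2 levels per factor and >=2 observations per cell; empty or
    singleton cells are reported by name.  When ``posthoc_factor`` is given
    a Tukey HSD table over that factor's levels is attached.
    """
    fa, fb = factors
    df = table[[response, fa, fb]].dropna().copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >=2 levels")
    cells = df.groupby([fa, fb], observed=True)[response].count()
    full_index = pd.MultiIndex.from_product([df[fa].unique(), df[fb].unique()])
    bad = [idx for idx in full_index if cells.get(idx, 0) < 2]
    if bad:
        raise ValueError(f"cells with fewer than 2 observations: {bad}")

    y = df[response].to_numpy(dtype=float)
    names = {
        f"C(Q('{fa}'))": fa,
        f"C(Q('{fb}'))": fb,
        f"C(Q('{fa}')):C(Q('{fb}'))": f"{fa}:{fb}",
    }
    if _zero_variance(y):
        resid_df = len(df) - df[fa].nunique() * df[fb].nunique()
        rows = [
            {"effect": label, "df": np.nan, "df_resid": resid_df, "F": 0.0, "p": 1.0}
            for label in names.values()
        ]
        effects = pd.DataFrame(rows)
    else:
        fit = smf.ols(f"Q('{response}') ~ C(Q('{fa}')) * C(Q('{fb}'))", data=df).fit()
        tbl = anova_lm(fit, typ=2)
        effects = _effects_from_anova_lm(tbl, names)

    posthoc = None
    if posthoc_factor is not None:
        posthoc = tukey_hsd(df, response=response, factor=posthoc_factor)
    return AnovaResult(effects=effects, posthoc=posthoc,
                       metadata={"model": "fixed-effects two-way with interaction"})


def one_way_anova(
    table: pd.DataFrame,
    response: str = "value",
    factor: str = "timepoint",
    posthoc: bool = True,
) -> AnovaResult:
    """One-way fixed-effects ANOVA with optional Tukey HSD post-hoc."""
    df = table[[response, factor]].dropna().copy()
    levels = df[factor].unique()
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >=2 levels")
    counts = df.groupby(factor, observed=True)[response].count()
    bad = counts[counts < 2]
    if len(bad):
        raise ValueError(f"groups with fewer than 2 observations: {list(bad.index)}")

    y = df[response].to_numpy(dtype=float)
    names = {f"C(Q('{factor}'))": factor}
    if _zero_variance(y):
        effects = pd.DataFrame(
            [{"effect": factor, "df": len(levels) - 1.0,
              "df_resid": float(len(df) - len(levels)), "F": 0.0, "p": 1.0}]
        )
    else:
        fit = smf.ols(f"Q('{response}') ~ C(Q('{factor}'))", data=df).fit()
        tbl = anova_lm(fit, typ=2)
        effects = _effects_from_anova_lm(tbl, names)
    ph = tukey_hsd(df, response=response, factor=factor) if posthoc else None
    return AnovaResult(effects=effects, posthoc=ph, metadata={"model": "one-way fixed-effects"})


def repeated_measures_anova(
    table: pd.DataFrame,
    response: str = "value",
    subject: str = "animal_id",
    within: str = "timepoint",
) -> AnovaResult:
    """Within-subject one-factor ANOVA with the subject as blocking factor.

    Every subject must be observed exactly once at every level; unbalanced
    panels are rejected.  No sphericity correction is applied.
    """
    df = table[[response, subject, within]].dropna().copy()
    if df[subject].nunique() < 2:
        raise ValueError("need >=2 subjects")
    if df[within].nunique() < 2:
        raise ValueError(f"factor {within!r} needs >=2 levels")
    counts = df.groupby([subject, within], observed=True)[response].count()
    pivot = counts.unstack(fill_value=0)
    if not (pivot.to_numpy() == 1).all():
        raise ValueError("unbalanced panel: every subject must have exactly one "
                         "observation per level")

    y = df[response].to_numpy(dtype=float)
    names = {f"C(Q('{within}'))": within, f"C(Q('{subject}'))": subject}
    if _zero_variance(y):
        n_s, n_w = df[subject].nunique(), df[within].nunique()
        effects = pd.DataFrame(
            [{"effect": within, "df": n_w - 1.0,
              "df_resid": float((n_s - 1) * (n_w - 1)), "F": 0.0, "p": 1.0},
             {"effect": subject, "df": n_s - 1.0,
              "df_resid": float((n_s - 1) * (n_w - 1)), "F": 0.0, "p": 1.0}]
        )
    else:
        fit = smf.ols(
            f"Q('{response}') ~ C(Q('{subject}')) + C(Q('{within}'))", data=df
        ).fit()
        tbl = anova_lm(fit, typ=2)
        effects = _effects_from_anova_lm(tbl, names)
    return AnovaResult(
        effects=effects,
        metadata={"model": "repeated-measures (subject blocking)",
                  "sphericity_correction": "none"},
    )


def tukey_hsd(
    table: pd.DataFrame, response: str = "value", factor: str = "timepoint"
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons over the factor levels.

    Uses the pooled within-group mean square (Tukey-Kramer standard errors
    for unequal group sizes).  Returns one row per level pair with the mean
    difference, the unadjusted pooled-t p-value and the studentized-range
    adjusted p-value.  With two levels the adjustment degenerates to the
    pooled t-test.
    """
    df = table[[response, factor]].dropna()
    groups = {lvl: g[response].to_numpy(dtype=float)
              for lvl, g in df.groupby(factor, observed=True)}
    levels = list(groups)
    k = len(levels)
    if k < 2:
        raise ValueError("need >=2 levels for pairwise comparisons")
    n_total = sum(len(v) for v in groups.values())
    df_resid = n_total - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the pooled error")
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_resid

    rows = []
    for a, b in itertools.combinations(levels, 2):
        va, vb = groups[a], groups[b]
        diff = va.mean() - vb.mean()
        se2 = mse * (1.0 / len(va) + 1.0 / len(vb))
        if se2 <= 0:
            p_un = p_adj = 1.0 if diff == 0 else 0.0
            t_obs = 0.0 if diff == 0 else np.inf
        else:
            t_obs = diff / np.sqrt(se2)
            p_un = float(2.0 * sps.t.sf(abs(t_obs), df_resid))
            q_obs = abs(t_obs) * np.sqrt(2.0)
            p_adj = float(sps.studentized_range.sf(q_obs, k, df_resid))
        p_adj = min(max(p_adj, p_un), 1.0)
        rows.append({"level_a": a, "level_b": b, "mean_diff": diff,
                     "t": t_obs, "p_unadjusted": p_un, "p_adjusted": p_adj,
                     "stars": p_to_stars(p_adj)})
    return pd.DataFrame(rows)


def two_group_ttest(
    table: pd.DataFrame,
    response: str = "value",
    group: str = "group",
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided unpaired t-test between exactly two groups.

    Equal-variance by default with a Welch option.  When both groups are
    degenerate (zero variance) with equal means the convention t=0, p=1 is
    returned; unequal degenerate means give p=0.
    """
    df = table[[response, group]].dropna()
    levels = df[group].unique()
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    a = df.loc[df[group] == levels[0], response].to_numpy(dtype=float)
    b = df.loc[df[group] == levels[1], response].to_numpy(dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
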