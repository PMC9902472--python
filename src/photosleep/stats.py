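"""The statistical layer: normality-gated comparisons and the mixed ANOVA.

Two-sample comparisons follow the normality-gated convention: each sample
(or, for paired data, the difference vector) is tested with Shapiro–Wilk
at α = 0.05; parametric tests (paired/unpaired Student's t) are used when
normality is not rejected, otherwise the Wilcoxon signed-rank or rank-sum
test. All tests are two-tailed.

Group-by-treatment designs (e.g. hM₃Dq vs tdTomato crossed with CNO vs
saline, measured within subject) are analysed with a balanced split-plot
(mixed-design) two-way ANOVA — group between subjects, treatment within —
followed by Tukey's HSD over the cell means. Within-subject contrasts use
the within-subject error term; contrasts crossing the between factor use
the pooled error (MS_subjects(group) + (b−1)·MS_within)/b with
Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss


@dataclass
class CompareResult:
    test_name: str
    statistic: float
    p: float
    n: tuple[int, ...]
    normality_p: tuple[float, ...]
    paired: bool


def auto_compare(x, y, paired: bool = False, alpha: float = 0.05) -> CompareResult:
    """Two-sample comparison with the Shapiro–Wilk normality gate.

    Parametric branch (paired or unpaired t-test) when normality is not
    rejected at ``alpha`` for every gated sample — the difference vector
    for paired data, each sample separately otherwise; non-parametric
    branch (Wilcoxon signed-rank / rank-sum) otherwise. Two-tailed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per sample")
    if paired and x.size != y.size:
        raise ValueError("paired comparison requires equal sample sizes")
    if x.std() == 0 and y.std() == 0:
        raise ValueError("both samples have zero variance")

    if paired:
        d = x - y
        if np.all(d == 0):
            return CompareResult("undefined (all differences zero)",
                                 float("nan"), float("nan"),
                                 (x.size, y.size), (float("nan"),), True)
        if d.std() == 0:
            norm_p = (0.0,)  # constant nonzero differences: not normal
        else:
            norm_p = (float(ss.shapiro(d).pvalue),)
        if norm_p[0] > alpha:
            res = ss.ttest_rel(x, y)
            name = "paired t-test"
        else:
            res = ss.wilcoxon(x, y)
            name = "Wilcoxon signed-rank"
    else:
        norm_p = tuple(
            float(ss.shapiro(v).pvalue) if v.std() > 0 else 0.0 for v in (x, y)
        )
        if all(p > alpha for p in norm_p):
            res = ss.ttest_ind(x, y)
            name = "unpaired t-test"
        else:
            res = ss.ranksums(x, y)
            name = "Wilcoxon rank-sum"
    return CompareResult(name, float(res.statistic), float(res.pvalue),
                         (x.size, y.size), norm_p, paired)


# ---------------------------------------------------------------------------
# mixed-design ANOVA + Tukey


@dataclass
class AnovaResult:
    table: pd.DataFrame  # effects x (SS, df, MS, F, p)
    cell_means: pd.DataFrame  # group x treatment
    cell_sem: pd.DataFrame
    tukey: pd.DataFrame  # pairwise cell contrasts
    n_subjects: dict[str, int] = field(default_factory=dict)


def _check_balanced(df: pd.DataFrame, subject: str, group: str, treatment: str):
    treatments = sorted(df[treatment].unique())
    for s, sub in df.groupby(subject):
        if sorted(sub[treatment].unique()) != treatments or len(sub) != len(treatments):
            raise ValueError(
                f"subject {s!r} does not have exactly one observation per "
                f"treatment level"
            )
        if sub[group].nunique() != 1:
            raise ValueError(f"subject {s!r} appears in more than one group")


def mixed_anova_tukey(
    table: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    treatment: str = "treatment",
    value: str = "value",
) -> AnovaResult:
    """Split-plot two-way ANOVA (group between, treatment within) + Tukey HSD.

    Requires every subject to be measured at every treatment level.
    Degenerates gracefully to a one-group repeated-measures analysis (the
    treatment F then equals the squared paired t statistic when there are
    two treatment levels).
    """
    df = table[[subject, group, treatment, value]].copy()
    if df[value].isna().any():
        raise ValueError("missing values in the response column")
    _check_balanced(df, subject, group, treatment)
    groups = sorted(df[group].unique())
    treatments = sorted(df[treatment].unique())
    a, b = len(groups), len(treatments)
    if b < 2:
        raise ValueError("need at least two treatment levels")
    n_per_group = {g: df.loc[df[group] == g, subject].nunique() for g in groups}
    if min(n_per_group.values()) < 3:
        raise ValueError("need at least 3 subjects per group")
    n_subj = sum(n_per_group.values())
    gm = df[value].mean()

    subj_means = df.groupby(subject)[value].mean()
    group_of = df.groupby(subject)[group].first()
    group_means = df.groupby(group)[value].mean()
    treat_means = df.groupby(treatment)[value].mean()
    cell_means = df.pivot_table(index=group, columns=treatment, values=value,
                                aggfunc="mean")
    cell_sem = df.pivot_table(index=group, columns=treatment, values=value,
                              aggfunc="sem")

    ss_total = float(((df[value] - gm) ** 2).sum())
    ss_between_subj = float(b * ((subj_means - gm) ** 2).sum())
    ss_group = float(b * sum(n_per_group[g] * (group_means[g] - gm) ** 2
                             for g in groups))
    ss_subj_within = ss_between_subj - ss_group
    ss_treat = float(n_subj * ((treat_means - gm) ** 2).sum())
    ss_cells = float(sum(n_per_group[g] * (cell_means.loc[g, t] - gm) ** 2
                         for g in groups for t in treatments))
    ss_inter = ss_cells - ss_group - ss_treat
    ss_error = ss_total - ss_between_subj - ss_treat - ss_inter

    df_group, df_subj = a - 1, n_subj - a
    df_treat = b - 1
    df_inter = (a - 1) * (b - 1)
    df_error = (n_subj - a) * (b - 1)
    ms_subj = ss_subj_within / df_subj
    ms_error = ss_error / df_error

    rows = []

    def add(effect, ss_, df_, ms_den, df_den):
        if df_ <= 0:
            rows.append((effect, ss_, df_, np.nan, np.nan, np.nan))
            return
        ms = ss_ / df_
        if ms_den <= 0:
            # degenerate (e.g. all observations identical): no variance at all
            F = 0.0 if ms <= 1e-300 else np.inf
        else:
            F = ms / ms_den
        rows.append((effect, ss_, df_, ms, F, float(ss.f.sf(F, df_, df_den))))

    add("group", ss_group, df_group, ms_subj, df_subj)
    rows.append(("subjects(group)", ss_subj_within, df_subj, ms_subj,
                 np.nan, np.nan))
    add("treatment", ss_treat, df_treat, ms_error, df_error)
    add("group x treatment", ss_inter, df_inter, ms_error, df_error)
    rows.append(("error(within)", ss_error, df_error, ms_error, np.nan, np.nan))
    anova = pd.DataFrame(rows, columns=["effect", "SS", "df", "MS", "F", "p"]
                         ).set_index("effect")

    # --- Tukey HSD over the a*b cell means -------------------------------
    k = a * b
    cells = [(g, t) for g in groups for t in treatments]
    # pooled error for contrasts crossing the between factor (Winer)
    ms_pool = (ms_subj + (b - 1) * ms_error) / b
    denom = ms_subj**2 / df_subj + ((b - 1) * ms_error) ** 2 / max(df_error, 1)
    if df_error > 0 and denom > 0:
        df_pool = (ms_pool * b) ** 2 / denom
    else:
        df_pool = df_subj + df_error
    contrasts = []
    for i in range(k):
        for j in range(i + 1, k):
            (g1, t1), (g2, t2) = cells[i], cells[j]
            m1 = cell_means.loc[g1, t1]
            m2 = cell_means.loc[g2, t2]
            n1, n2 = n_per_group[g1], n_per_group[g2]
            if g1 == g2:
                ms_use, df_use = ms_error, df_error
            else:
                ms_use, df_use = ms_pool, df_pool
            se_q = np.sqrt(ms_use / 2.0 * (1.0 / n1 + 1.0 / n2))
            q = abs(m1 - m2) / se_q if se_q > 0 else 0.0
            p_tukey = float(ss.studentized_range.sf(q, k, df_use))
            t_stat = q / np.sqrt(2.0)
            p_unadj = float(2.0 * ss.t.sf(t_stat, df_use))
            contrasts.append({
                "cell_a": f"{g1}:{t1}", "cell_b": f"{g2}:{t2}",
                "diff": float(m1 - m2), "se": float(se_q * np.sqrt(2.0)),
                "df": float(df_use), "q": float(q),
                "p_tukey": min(p_tukey, 1.0), "p_unadjusted": min(p_unadj, 1.0),
            })
    tukey = pd.DataFrame(contrasts)
    return AnovaResult(table=anova, cell_means=cell_means, cell_sem=cell_sem,
                       tukey=tukey, n_subjects=n_per_group)


@dataclass
class PearsonResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def pearson_test(x, y) -> PearsonResult:
    """Pearson correlation with two-tailed p and the least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = ss.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return PearsonResult(r=float(r), p=float(p), slope=float(slope),
                         intercept=float(intercept), n=int(x.size))
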