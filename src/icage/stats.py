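"""Statistical plan: mixed repeated-measures ANOVA, gated Bonferroni
post hocs, and pooled-variance two-sample t-tests (alpha = 0.05).

The ANOVA is the classical univariate two-way mixed decomposition with
one between-subjects factor (genotype) and one within-subjects factor
(day):

* F_between  = MS_between / MS_subjects(group)
* F_within   = MS_within / MS_within x subjects(group)
* F_interact = MS_interaction / MS_within x subjects(group)

Sums of squares use the weighted (sequential) decomposition, which is
exactly additive for complete within-subject data at any group sizes and
coincides with the SPSS Type III output for balanced groups. Subjects
with missing days are excluded listwise with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """The design has no residual variance (or too few subjects/levels)."""


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df1: int
    df2: int
    ms: float
    F: float
    p: float


@dataclass
class AnovaResult:
    """F/df/p for the three effects plus the full SS decomposition."""

    between: AnovaEffect      # genotype main effect
    within: AnovaEffect       # day main effect
    interaction: AnovaEffect  # genotype x day
    ss_subjects: float        # subjects within genotype
    ss_error_within: float    # day x subjects within genotype
    ss_total: float
    n_per_group: dict[str, int]
    k: int
    subjects_used: list[str]
    excluded: list[str] = field(default_factory=list)

    @property
    def effects(self) -> dict[str, AnovaEffect]:
        return {"genotype": self.between, "day": self.within,
                "genotype x day": self.interaction}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.name, e.F, e.df1, e.df2, e.p, e.ss, e.ms)
            for e in (self.between, self.within, self.interaction)
        ]
        return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p", "ss", "ms"])


def _pivot_complete(
    table: pd.DataFrame, dv: str, between: str, within: str, subject: str
) -> tuple[np.ndarray, np.ndarray, list, list[str], list[str]]:
    df = table[[subject, between, within, dv]].dropna(subset=[dv])
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="mean")
    levels = sorted(df[within].unique())
    complete = wide.dropna()
    excluded = sorted(set(wide.index.get_level_values(0)) - set(complete.index.get_level_values(0)))
    if excluded:
        warnings.warn(
            f"mixed_anova: excluding {len(excluded)} subject(s) with missing days: {excluded}",
            stacklevel=3,
        )
    y = complete[levels].to_numpy(dtype=float)
    groups = np.asarray(complete.index.get_level_values(1))
    subjects = [str(s) for s in complete.index.get_level_values(0)]
    return y, groups, levels, subjects, excluded


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    between: str = "genotype",
    within: str = "day",
    subject: str = "animal_id",
) -> AnovaResult:
    """Two-way mixed repeated-measures ANOVA on a long metric table."""
    y, groups, levels, subjects, excluded = _pivot_complete(table, dv, between, within, subject)
    k = len(levels)
    if k < 2:
        raise DegenerateDataError(f"need >=2 within levels, got {k}")
    labels = sorted(pd.unique(groups))
    n_per = {g: int((groups == g).sum()) for g in labels}
    if len(labels) < 2:
        raise DegenerateDataError("need >=2 between groups")
    if min(n_per.values()) < 2:
        raise DegenerateDataError(f"a group has <2 complete subjects: {n_per}")
    N = y.shape[0]
    a = len(labels)

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = y.mean(axis=1)
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    group_means = np.array([subj_means[groups == g].mean() for g in labels])
    ss_geno = float(k * sum(n_per[g] * (gm - grand) ** 2 for g, gm in zip(labels, group_means)))
    ss_subj = ss_between_subj - ss_geno

    day_means = y.mean(axis=0)
    ss_day = float(N * ((day_means - grand) ** 2).sum())
    cell = np.stack([y[groups == g].mean(axis=0) for g in labels])  # a x k
    ss_int = float(sum(
        n_per[g] * ((cell[i] - group_means[i] - day_means + grand) ** 2).sum()
        for i, g in enumerate(labels)
    ))
    ss_err = ss_total - ss_between_subj - ss_day - ss_int

    df_geno = (a - 1, N - a)
    df_day = (k - 1, (k - 1) * (N - a))
    df_int = ((a - 1) * (k - 1), (k - 1) * (N - a))
    ms_subj = ss_subj / df_geno[1]
    ms_err = ss_err / df_day[1]
    if ms_subj <= 0 or ms_err <= 0:
        raise DegenerateDataError("zero error variance; F is undefined")

    def eff(name: str, ss: float, df: tuple[int, int], ms_denom: float) -> AnovaEffect:
        ms = ss / df[0]
        F = ms / ms_denom
        p = float(sps.f.sf(F, df[0], df[1]))
        return AnovaEffect(name, ss, df[0], df[1], ms, F, p)

    return AnovaResult(
        between=eff("genotype", ss_geno, df_geno, ms_subj),
        within=eff("day", ss_day, df_day, ms_err),
        interaction=eff("genotype x day", ss_int, df_int, ms_err),
        ss_subjects=ss_subj,
        ss_error_within=ss_err,
        ss_total=ss_total,
        n_per_group=n_per,
        k=k,
        subjects_used=subjects,
        excluded=excluded,
    )


# ----------------------------------------------------------------------
# t-tests
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TResult:
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int

    @property
    def mean_difference(self) -> float:
        return self.mean_a - self.mean_b


def two_sample_ttest(values_a, values_b, equal_var: bool = True) -> TResult:
    """Student's unpaired t-test (pooled variance by default)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if equal_var:
        n1, n2 = len(a), len(b)
        df = n1 + n2 - 2
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
        if sp2 == 0:
            if a.mean() == b.mean():
                raise DegenerateDataError("zero pooled variance with equal means")
            t = math_inf_sign(a.mean() - b.mean())
            p = 0.0
        else:
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            p = float(2 * sps.t.sf(abs(t), df))
        return TResult(float(t), int(df), p, float(a.mean()), float(b.mean()), n1, n2)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    df = _welch_df(a, b)
    return TResult(float(t), int(round(df)), float(p), float(a.mean()), float(b.mean()), len(a), len(b))


def math_inf_sign(x: float) -> float:
    return float(np.inf if x > 0 else -np.inf)


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))


def paired_ttest(values_a, values_b) -> TResult:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired test needs two equal-length samples, n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        raise DegenerateDataError("zero variance of paired differences")
    t, p = sps.ttest_rel(a, b)
    return TResult(float(t), len(a) - 1, float(p), float(a.mean()), float(b.mean()), len(a), len(b))


# ----------------------------------------------------------------------
# Bonferroni post hocs
# ----------------------------------------------------------------------

POSTHOC_FAMILIES = ("genotype_within_day", "day_within_genotype")


@dataclass
class PosthocTable:
    rows: pd.DataFrame
    family: str
    m: int
    gate_met: bool
    reason: str = ""


def bonferroni_posthoc(
    table: pd.DataFrame,
    dv: str,
    anova_result: AnovaResult,
    family: str = "genotype_within_day",
    between: str = "genotype",
    within: str = "day",
    subject: str = "animal_id",
    alpha: float = ALPHA,
) -> PosthocTable:
    """Bonferroni-corrected post hocs, gated on a significant interaction.

    ``genotype_within_day``: unpaired genotype comparison at each day
    (m = number of days). ``day_within_genotype``: paired day-vs-day
    comparisons within each genotype (m = total pairs tested).
    """
    if family not in POSTHOC_FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {POSTHOC_FAMILIES}")
    empty = pd.DataFrame(columns=["comparison", "mean_difference", "p_raw", "p_adjusted", "significant"])
    if anova_result.interaction.p >= alpha:
        return PosthocTable(empty, family, 0, False, "gate not met: interaction p >= alpha")

    y, groups, levels, subjects, _ = _pivot_complete(table, dv, between, within, subject)
    labels = sorted(pd.unique(groups))
    comparisons: list[tuple[str, float, float]] = []
    if family == "genotype_within_day":
        g0, g1 = labels[0], labels[1]
        for j, lev in enumerate(levels):
            res = two_sample_ttest(y[groups == g0, j], y[groups == g1, j])
            comparisons.append((f"{g0} vs {g1} @ {within}={lev}", res.mean_difference, res.p))
    else:
        for g in labels:
            sub = y[groups == g]
            for j1, j2 in itertools.combinations(range(len(levels)), 2):
                res = paired_ttest(sub[:, j1], sub[:, j2])
                comparisons.append(
                    (f"{g}: {within}={levels[j1]} vs {within}={levels[j2]}", res.mean_difference, res.p)
                )
    m = len(comparisons)
    rows = pd.DataFrame(
        [
            (label, diff, p, min(1.0, m * p), min(1.0, m * p) < alpha)
            for label, diff, p in comparisons
        ],
        columns=["comparison", "mean_difference", "p_raw", "p_adjusted", "significant"],
    )
    return PosthocTable(rows, family, m, True)


# ----------------------------------------------------------------------
# Report assembly
# ----------------------------------------------------------------------

def effect_report(
    metric_table: pd.DataFrame,
    dvs: list[str],
    by_phase: bool = True,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """One row per (phase, dv, effect), shaped like a published ANOVA table.

    DVs that cannot be analysed for a phase (all-missing, degenerate,
    too few subjects) get a warning row with NaN statistics.
    """
    rows = []
    phases = metric_table["phase"].unique() if by_phase else [None]
    for phase in phases:
        sub = metric_table if phase is None else metric_table[metric_table["phase"] == phase]
        if sub["day"].nunique() < 2:
            continue
        for dv in dvs:
            if dv not in sub.columns:
                raise KeyError(f"dv column {dv!r} missing from the metric table")
            label = phase if phase is not None else "all"
            try:
                res = mixed_anova(sub, dv)
            except (DegenerateDataError, ValueError) as exc:
                rows.append((label, dv, "warning", np.nan, np.nan, np.nan, np.nan, str(exc)))
                continue
            for eff in (res.between, res.within, res.interaction):
                note = ""
                if eff.p < alpha:
                    note = "significant"
                elif eff.p < 0.10:
                    note = "trend"
                rows.append((label, dv, eff.name, eff.F, eff.df1, eff.df2, eff.p, note))
    return pd.DataFrame(rows, columns=["phase", "dv", "effect", "F", "df1", "df2", "p", "note"])
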