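"""Test-retest change statistics and group comparisons.

Change scores are expressed in adjusted-score percentage points (the
chance-corrected score times 100, the unit used throughout the study
report). Per group the module computes the one-sample t of the mean
change against zero (t = mean/sem, df = n-1, two-sided p), Cohen's d in
the standard one-sample convention d = mean/sd, and the same quantities
directly from printed summary moments (mean, sem, n) so a published
table can be verified without raw data. Across groups it runs a classic
one-way ANOVA (between/within sum-of-squares decomposition) with
Fisher's-LSD post hocs: pairwise t statistics built on the pooled
within-group mean square with its error df, reported with unadjusted
two-sided p-values per the LSD convention.

Percent change is computed per participant, 100*(t2 - t1)/t1, and then
averaged; the group-level ratio of means is NOT the mean of ratios and
is not used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

MODE_ABSOLUTE = "absolute"
MODE_PERCENT = "percent"


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float


@dataclass(frozen=True)
class ChangeStats:
    """Per-group change summary: n, mean, sem, sd, one-sample t/p, Cohen's d."""

    group_label: str
    n: int
    mean: float
    sem: float
    sd: float
    t: float
    p: float
    d: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    t: float
    p: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    group_labels: tuple[str, ...] = ()
    posthoc: tuple[PairwiseComparison, ...] = ()


def paired_change(
    test1_scores: Sequence[float],
    test2_scores: Sequence[float],
    mode: str = MODE_ABSOLUTE,
) -> np.ndarray:
    """Per-participant change vector, absolute (t2 - t1) or percent (100*(t2-t1)/t1).

    Percent mode drops participants with t1 == 0 (undefined ratio) with a
    warning.
    """
    t1 = np.asarray(test1_scores, dtype=float)
    t2 = np.asarray(test2_scores, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("test1 and test2 must pair up participant-by-participant")
    if mode == MODE_ABSOLUTE:
        return t2 - t1
    if mode == MODE_PERCENT:
        ok = t1 != 0
        n_bad = int((~ok).sum())
        if n_bad:
            warnings.warn(
                f"percent change undefined for {n_bad} participant(s) with baseline 0; excluded",
                stacklevel=2,
            )
        return 100.0 * (t2[ok] - t1[ok]) / t1[ok]
    raise ValueError(f"unknown mode {mode!r}")


def one_sample_t(changes: Sequence[float]) -> TTestResult:
    """One-sample two-sided t of the mean change against zero."""
    x = np.asarray(changes, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if m == 0.0:
            return TTestResult(0.0, 1.0, df)
        warnings.warn("zero variance with nonzero mean: infinite t", stacklevel=2)
        return TTestResult(math.copysign(math.inf, m), 0.0, df)
    t = m / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t, p, df)


def cohens_d(changes: Sequence[float]) -> float:
    """One-sample Cohen's d = mean / sd (sample sd, ddof=1)."""
    x = np.asarray(changes, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero sd: Cohen's d undefined", stacklevel=2)
        return math.nan
    return float(x.mean()) / sd


def summary_from_moments(mean: float, sem: float, n: int, group_label: str = "") -> ChangeStats:
    """Reconstruct the full change summary from printed (mean, sem, n).

    sd = sem*sqrt(n), t = mean/sem with df = n-1, d = mean/sd. This lets a
    published summary table be verified without participant-level data.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sem <= 0:
        raise ValueError("sem must be positive")
    sd = sem * math.sqrt(n)
    t = mean / sem
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return ChangeStats(group_label, int(n), float(mean), float(sem), sd, t, p, mean / sd)


def change_stats(changes: Sequence[float], group_label: str = "") -> ChangeStats:
    """Change summary computed from a raw per-participant change vector."""
    x = np.asarray(changes, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = float(x.std(ddof=1))
    sem = sd / math.sqrt(n)
    tt = one_sample_t(x)
    d = cohens_d(x) if sd > 0 else math.nan
    return ChangeStats(group_label, int(n), float(x.mean()), sem, sd, tt.t, tt.p, d)


def one_way_anova(
    groups: Sequence[Sequence[float]], group_labels: Sequence[str] | None = None
) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA (between/within SS decomposition)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 observations")
    labels = tuple(group_labels) if group_labels is not None else tuple(
        f"group{i + 1}" for i in range(k)
    )
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = float(np.concatenate(gs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_between = k - 1
    df_within = int(ns.sum()) - k
    ms_within = ss_within / df_within
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_between, df_within, 0.0, labels)
        warnings.warn("zero within-group variance: infinite F", stacklevel=2)
        return AnovaResult(math.inf, 0.0, df_between, df_within, 0.0, labels)
    F = (ss_between / df_between) / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F, p, df_between, df_within, ms_within, labels)


def lsd_posthoc(
    groups: Sequence[Sequence[float]],
    group_labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    anova: AnovaResult | None = None,
) -> list[PairwiseComparison]:
    """Fisher's LSD pairwise comparisons using the pooled ANOVA error term.

    p-values are unadjusted two-sided t probabilities on the within-group
    df, per the LSD convention (protection comes from requiring a
    significant omnibus F first).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if anova is None:
        anova = one_way_anova(gs, group_labels)
    labels = anova.group_labels
    out = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            diff = float(gs[i].mean() - gs[j].mean())
            se = math.sqrt(anova.ms_within * (1.0 / gs[i].size + 1.0 / gs[j].size))
            if se == 0.0:
                t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
                p = 1.0 if diff == 0.0 else 0.0
            else:
                t = diff / se
                p = 2.0 * float(sps.t.sf(abs(t), anova.df_within))
            out.append(PairwiseComparison(labels[i], labels[j], diff, t, p, p < alpha))
    return out


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Unpaired two-tailed Student's t (pooled variance; Welch via flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return TTestResult(float(res.statistic), float(res.pvalue), df)


# -- study report ----------------------------------------------------------

@dataclass
class GroupSummary:
    label: str
    n: int
    initial_mean: float
    initial_sem: float
    retest_mean: float
    retest_sem: float
    absolute: ChangeStats
    percent: ChangeStats


@dataclass
class StudyReport:
    """Table-shaped study summary: per-group rows plus the ANOVA block."""

    groups: list[GroupSummary]
    anova_absolute: AnovaResult | None
    anova_percent: AnovaResult | None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for g in self.groups:
            cols[g.label] = {
                "N": g.n,
                "Initial test mean": g.initial_mean,
                "Initial test sem": g.initial_sem,
                "Retest mean": g.retest_mean,
                "Retest sem": g.retest_sem,
                "Absolute improvement mean": g.absolute.mean,
                "Absolute improvement sem": g.absolute.sem,
                "Percent improvement mean": g.percent.mean,
                "Percent improvement sem": g.percent.sem,
                "SD (absolute)": g.absolute.sd,
                "SD (percent)": g.percent.sd,
                "p (absolute)": g.absolute.p,
                "p (percent)": g.percent.p,
                "t (absolute)": g.absolute.t,
                "t (percent)": g.percent.t,
                "d (absolute)": g.absolute.d,
                "d (percent)": g.percent.d,
            }
        return pd.DataFrame(cols)

    def to_text(self) -> str:
        def sig(x: float, k: int) -> str:
            if not math.isfinite(x):
                return str(x)
            if x == 0:
                return "0"
            from decimal import Decimal

            q = -int(math.floor(math.log10(abs(x)))) + (k - 1)
            return str(round(Decimal(x), q).normalize())

        lines = ["Performance by group (adjusted-score points; mean +/- sem)", ""]
        header = f"{'':<28}" + "".join(f"{g.label:>14}" for g in self.groups)
        lines.append(header)

        def row(name, values):
            lines.append(f"{name:<28}" + "".join(f"{v:>14}" for v in values))

        row("N", [g.n for g in self.groups])
        row("Initial test", [f"{g.initial_mean:.1f}+/-{g.initial_sem:.2f}" for g in self.groups])
        row("Retest", [f"{g.retest_mean:.1f}+/-{g.retest_sem:.2f}" for g in self.groups])
        row(
            "Abs. improvement",
            [f"{g.absolute.mean:.2f}+/-{g.absolute.sem:.2f}" for g in self.groups],
        )
        row(
            "Pct. improvement",
            [f"{g.percent.mean:.2f}+/-{g.percent.sem:.2f}" for g in self.groups],
        )
        row("SD (abs.)", [sig(g.absolute.sd, 3) for g in self.groups])
        row("SD (%)", [sig(g.percent.sd, 3) for g in self.groups])
        row("p (abs.)", [f"{g.absolute.p:.3f}" for g in self.groups])
        row("p (%)", [f"{g.percent.p:.3f}" for g in self.groups])
        row("t (abs.)", [sig(g.absolute.t, 2) for g in self.groups])
        row("t (%)", [sig(g.percent.t, 2) for g in self.groups])
        row("d (abs.)", [sig(g.absolute.d, 2) for g in self.groups])
        row("d (%)", [sig(g.percent.d, 2) for g in self.groups])
        for name, an in (("absolute", self.anova_absolute), ("percent", self.anova_percent)):
            if an is None:
                continue
            lines.append("")
            lines.append(
                f"One-way ANOVA ({name} change): F({an.df_between},{an.df_within})"
                f" = {an.F:.2f}, p = {an.p:.3f}"
            )
            for pc in an.posthoc:
                star = "*" if pc.significant else ""
                lines.append(
                    f"  LSD {pc.group_a} vs {pc.group_b}: diff = {pc.mean_diff:.2f},"
                    f" t = {pc.t:.2f}, p = {pc.p:.3f}{star}"
                )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def build_summary_table(
    group_scores: dict[str, tuple[Sequence[float], Sequence[float]]],
    alpha: float = 0.05,
) -> StudyReport:
    """Build the study report from per-group (initial, retest) score pairs.

    Scores are adjusted-score percentage points, paired by participant
    within each group. Groups with fewer than 2 participants are dropped
    with a warning (no df for a change test). The ANOVA block is emitted
    when at least two groups survive.
    """
    summaries: list[GroupSummary] = []
    warns: list[str] = []
    abs_vectors: list[np.ndarray] = []
    pct_vectors: list[np.ndarray] = []
    labels: list[str] = []
    for label, (t1, t2) in group_scores.items():
        t1 = np.asarray(t1, dtype=float)
        t2 = np.asarray(t2, dtype=float)
        if t1.size < 2:
            warns.append(f"group {label!r} has n={t1.size} < 2; omitted from the report")
            continue
        abs_ch = paired_change(t1, t2, MODE_ABSOLUTE)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pct_ch = paired_change(t1, t2, MODE_PERCENT)
        if pct_ch.size < t1.size:
            warns.append(
                f"group {label!r}: {t1.size - pct_ch.size} baseline-zero participant(s)"
                " excluded from percent change"
            )
        summaries.append(
            GroupSummary(
                label=label,
                n=int(t1.size),
                initial_mean=float(t1.mean()),
                initial_sem=float(t1.std(ddof=1) / math.sqrt(t1.size)),
                retest_mean=float(t2.mean()),
                retest_sem=float(t2.std(ddof=1) / math.sqrt(t2.size)),
                absolute=change_stats(abs_ch, label),
                percent=change_stats(pct_ch, label),
            )
        )
        labels.append(label)
        abs_vectors.append(abs_ch)
        pct_vectors.append(pct_ch)
    anova_abs = anova_pct = None
    if len(labels) >= 2:
        anova_abs = one_way_anova(abs_vectors, labels)
        anova_abs = AnovaResult(
            anova_abs.F,
            anova_abs.p,
            anova_abs.df_between,
            anova_abs.df_within,
            anova_abs.ms_within,
            anova_abs.group_labels,
            tuple(lsd_posthoc(abs_vectors, labels, alpha, anova_abs)),
        )
        anova_pct = one_way_anova(pct_vectors, labels)
        anova_pct = AnovaResult(
            anova_pct.F,
            anova_pct.p,
            anova_pct.df_between,
            anova_pct.df_within,
            anova_pct.ms_within,
            anova_pct.group_labels,
            tuple(lsd_posthoc(pct_vectors, labels, alpha, anova_pct)),
        )
    return StudyReport(summaries, anova_abs, anova_pct, warns)
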