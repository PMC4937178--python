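"""Split-plot (mixed) ANOVA, Tukey HSD follow-up, and Pearson correlation.

The study design behind this package is a pre/post intervention with a
between-subject factor (training arm) and a within-subject factor (time).
``mixed_anova`` computes the classical split-plot decomposition::

    SS_total = SS_group + SS_subjects(group)          (between-subject)
             + SS_time + SS_time:group + SS_error     (within-subject)

F tests use the subjects-within-group mean square for the group effect and
the within-subject error mean square for time and the interaction.  With two
within-subject levels sphericity holds trivially; with three or more, the
Greenhouse-Geisser epsilon is estimated from the pooled within-group
covariance and the conventional selection rule applies: GG correction when
ε < 0.75, Huynh-Feldt otherwise.  Corrected p-values come from the F
distribution with ε-deflated degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

EPSILON_RULE_THRESHOLD = 0.75   # GG below, HF at or above

__all__ = [
    "EffectResult",
    "AnovaResult",
    "mixed_anova",
    "tukey_posthoc",
    "PearsonResult",
    "pearson_r",
]


@dataclass(frozen=True)
class EffectResult:
    effect: str
    ss: float
    df_num: float
    df_den: float
    F: float
    p_uncorrected: float
    epsilon: "float | None"     # None when no correction applies (2 levels)
    correction: str             # "none", "GG", or "HF"
    p: float                    # corrected p-value (== p_uncorrected when "none")


@dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, EffectResult]
    ss_components: dict[str, float]
    n_subjects: int
    n_groups: int
    n_times: int
    degenerate: bool = False    # zero error variance somewhere

    @property
    def ss_total(self) -> float:
        return float(sum(self.ss_components.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": e.effect,
                "SS": e.ss,
                "df_num": e.df_num,
                "df_den": e.df_den,
                "F": e.F,
                "epsilon": e.epsilon,
                "correction": e.correction,
                "p": e.p,
            }
            for e in self.effects.values()
        ]
        return pd.DataFrame(rows)


def _pivot_wide(
    table: pd.DataFrame, outcome, subject: str, group: str, time: str, value: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    df = table
    if outcome is not None:
        if "outcome" not in df.columns:
            raise ValidationError("table has no 'outcome' column to filter on")
        df = df[df["outcome"] == outcome]
        if df.empty:
            raise ValidationError(f"no rows for outcome {outcome!r}")
    for col in (subject, group, time, value):
        if col not in df.columns:
            raise ValidationError(f"table lacks required column {col!r}")
    gmap = df.groupby(subject)[group].nunique()
    multi = gmap[gmap > 1]
    if len(multi):
        raise ValidationError(f"subjects in more than one group: {list(multi.index)}")
    dup = df.duplicated(subset=[subject, time])
    if dup.any():
        raise ValidationError(
            f"duplicate (subject, time) measurements for subjects "
            f"{sorted(df.loc[dup, subject].unique().tolist())}"
        )
    wide = df.pivot(index=subject, columns=time, values=value)
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        raise ValidationError(f"unbalanced design; subjects missing time levels: {incomplete}")
    times = np.sort(df[time].unique())
    wide = wide[times]
    groups_per_subject = df.groupby(subject)[group].first().reindex(wide.index).to_numpy()
    return wide.to_numpy(dtype=float), groups_per_subject, wide.index.to_numpy(), times


def _gg_epsilon(pooled_cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k repeated-measures covariance."""
    k = pooled_cov.shape[0]
    # orthonormal contrast basis of the (k-1)-dim difference space
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    e = c.T @ pooled_cov @ c
    tr = np.trace(e)
    denom = (k - 1) * np.trace(e @ e)
    if denom <= 0:
        return 1.0
    return float(tr**2 / denom)


def _hf_epsilon(eps_gg: float, n_subjects: int, n_groups: int, k: int) -> float:
    num = n_subjects * (k - 1) * eps_gg - 2.0
    den = (k - 1) * (n_subjects - n_groups - (k - 1) * eps_gg)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def _f_and_p(ss_effect: float, df_num: float, ss_err: float, df_den: float) -> tuple[float, float, bool]:
    """(F, p, degenerate).  Zero effect SS gives F=0, p=1 even at zero error SS."""
    if ss_effect <= 1e-12:
        return 0.0, 1.0, ss_err <= 1e-12
    if ss_err <= 1e-12:
        return float("inf"), 0.0, True
    F = (ss_effect / df_num) / (ss_err / df_den)
    return float(F), float(stats.f.sf(F, df_num, df_den)), False


def mixed_anova(
    table: pd.DataFrame,
    outcome: "str | None" = None,
    subject: str = "subject",
    group: str = "group",
    time: str = "time",
    value: str = "value",
) -> AnovaResult:
    """Two-way mixed (split-plot) ANOVA: between factor ``group``, within ``time``.

    Requires a balanced within-subject design (every subject observed at
    every time level) and at least two subjects per group.  With three or
    more time levels, sphericity corrections follow the ε rule (GG when
    ε < 0.75, else HF) and the corrected p-values are reported alongside the
    uncorrected ones.
    """
    Y, glabels, subjects, times = _pivot_wide(table, outcome, subject, group, time, value)
    n, k = Y.shape
    group_names = np.sort(pd.unique(glabels))
    g = len(group_names)
    if g < 1 or k < 2:
        raise ValidationError("need at least 1 group and 2 time levels")
    counts = np.array([(glabels == name).sum() for name in group_names])
    if (counts < 2).any():
        few = [str(nm) for nm, c in zip(group_names, counts) if c < 2]
        raise ValidationError(f"groups with fewer than 2 subjects: {few}")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    time_means = Y.mean(axis=0)
    group_means = np.array([subj_means[glabels == name].mean() for name in group_names])
    cell_means = np.array(
        [Y[glabels == name].mean(axis=0) for name in group_names]
    )  # g x k

    ss_between = k * float(np.sum((subj_means - grand) ** 2))
    ss_group = k * float(np.sum(counts * (group_means - grand) ** 2))
    ss_subj = ss_between - ss_group                       # subjects within groups
    ss_within = float(np.sum((Y - subj_means[:, None]) ** 2))
    ss_time = n * float(np.sum((time_means - grand) ** 2))
    inter_dev = cell_means - group_means[:, None] - time_means[None, :] + grand
    ss_inter = float(np.sum(counts[:, None] * inter_dev**2))
    ss_err = ss_within - ss_time - ss_inter

    df_group, df_subj = g - 1, n - g
    df_time = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err = (n - g) * (k - 1)

    eps: "float | None" = None
    correction = "none"
    eps_used = 1.0
    if k > 2:
        centered = np.vstack(
            [Y[glabels == name] - cell_means[i] for i, name in enumerate(group_names)]
        )
        pooled_cov = centered.T @ centered / (n - g)
        eps_gg = _gg_epsilon(pooled_cov)
        if eps_gg < EPSILON_RULE_THRESHOLD:
            correction, eps, eps_used = "GG", eps_gg, eps_gg
        else:
            correction = "HF"
            eps = eps_gg
            eps_used = _hf_epsilon(eps_gg, n, g, k)

    degenerate = False
    effects: dict[str, EffectResult] = {}

    F, p, d = _f_and_p(ss_group, df_group, ss_subj, df_subj) if g > 1 else (0.0, 1.0, False)
    degenerate |= d
    effects["group"] = EffectResult("group", ss_group, df_group, df_subj, F, p, None, "none", p)

    for name, ss, df_num in (("time", ss_time, df_time), ("time:group", ss_inter, df_inter)):
        if name == "time:group" and g < 2:
            continue
        F, p_unc, d = _f_and_p(ss, df_num, ss_err, df_err)
        degenerate |= d
        if correction == "none" or not np.isfinite(F) or F == 0.0:
            p_corr = p_unc
        else:
            p_corr = float(stats.f.sf(F, eps_used * df_num, eps_used * df_err))
        effects[name] = EffectResult(
            name, ss, df_num, df_err, F, p_unc,
            None if correction == "none" else eps, correction, p_corr,
        )

    ss_components = {
        "group": ss_group,
        "subjects(group)": ss_subj,
        "time": ss_time,
        "time:group": ss_inter,
        "error(within)": ss_err,
    }
    return AnovaResult(
        effects=effects,
        ss_components=ss_components,
        n_subjects=n,
        n_groups=g,
        n_times=k,
        degenerate=degenerate,
    )


def tukey_posthoc(
    table: pd.DataFrame,
    outcome: "str | None" = None,
    effect: str = "group",
    at_time: "str | None" = None,
    subject: str = "subject",
    group: str = "group",
    time: str = "time",
    value: str = "value",
) -> pd.DataFrame:
    """All pairwise group differences with studentized-range (Tukey HSD) p-values.

    By default each subject contributes their across-time mean; pass
    ``at_time`` to compare groups within a single time level.  Returns a tidy
    frame of ordered pairs (antisymmetric differences, symmetric p-values).
    """
    if effect != "group":
        raise ValidationError("only the group effect supports Tukey follow-up")
    df = table
    if outcome is not None and "outcome" in df.columns:
        df = df[df["outcome"] == outcome]
    if at_time is not None:
        df = df[df[time] == at_time]
        if df.empty:
            raise ValidationError(f"no rows at time {at_time!r}")
    per_subject = df.groupby([subject, group], observed=True)[value].mean().reset_index()
    names = np.sort(per_subject[group].unique())
    if len(names) < 2:
        raise ValidationError("Tukey follow-up needs at least 2 groups")
    samples = [per_subject.loc[per_subject[group] == nm, value].to_numpy() for nm in names]
    res = stats.tukey_hsd(*samples)
    means = [float(s.mean()) for s in samples]
    rows = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "diff": means[i] - means[j],
                    "p": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


def pearson_r(x, y) -> PearsonResult:
    """Product-moment correlation between two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return PearsonResult(r=float(r), p=float(p), n=len(x))
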