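"""First-principles statistical battery for the two-group longitudinal design.

Implements, from explicit sums-of-squares decompositions:

* pooled-variance independent-samples t-test (baseline group comparisons);
* two-way mixed (split-plot) ANOVA — group as the between-subject factor,
  timepoint as the within-subject factor — with the between-group effect
  tested against subjects-within-groups and the time/interaction effects
  against the within-subject residual;
* the pooled one-way time ANOVA: timepoint as a between-cell factor on the
  pooled observations, ignoring subject pairing.  Its error df is 4n - 4,
  which is the convention the source study's printed within-group
  statistics follow, so it is kept alongside the proper mixed
  decomposition;
* Tukey HSD over timepoint means via the studentized-range distribution;
* the effect size r = sqrt(F / (F + df2)).

Tail probabilities come from ``scipy.stats`` distribution objects; every
sum of squares is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._tables import TIMEPOINTS

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """Data carry no variance where the test requires some."""


class UnbalancedDesignError(ValueError):
    """A subject is missing one or more timepoints."""


@dataclass(frozen=True)
class MixedAnovaResult:
    """One effect line of an ANOVA table."""

    effect: str  # between_group | time | interaction | time_pooled
    F: float
    df1: int
    df2: int
    p: float
    r: float

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "r": self.r,
        }


@dataclass(frozen=True)
class PosthocResult:
    """One Tukey-adjusted pairwise comparison."""

    pair: tuple[str, str]
    diff: float
    q: float
    p_tukey: float

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "diff": self.diff,
            "q": self.q,
            "p_tukey": self.p_tukey,
        }


def effect_size_r(F: float, df2: int) -> float:
    """r = sqrt(F / (F + df2)); 0 when F = 0, increasing in F."""
    if F < 0:
        raise ValueError("F must be >= 0")
    return float(np.sqrt(F / (F + df2)))


def independent_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided pooled-variance t-test; df = n1 + n2 - 2.

    Raises
    ------
    DegenerateDataError
        If both samples have zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        raise DegenerateDataError("zero pooled variance with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


# ---------------------------------------------------------------------------
# data plumbing

def pivot_outcome(data, outcome: str) -> tuple[np.ndarray, np.ndarray]:
    """Subjects x timepoints matrix and group labels for one outcome.

    Accepts a tidy DataFrame (subject_id, group, time, outcome, value) or a
    list of LongitudinalRecord.

    Raises
    ------
    UnbalancedDesignError
        If any subject lacks a timepoint.
    """
    if isinstance(data, pd.DataFrame):
        sub = data[data["outcome"] == outcome]
        if sub.empty:
            raise ValueError(f"no rows for outcome {outcome!r}")
        wide = sub.pivot_table(
            index=["subject_id", "group"], columns="time", values="value", aggfunc="first"
        )
        missing = [t for t in TIMEPOINTS if t not in wide.columns]
        if missing or wide.isna().any().any():
            raise UnbalancedDesignError(f"missing timepoints for outcome {outcome!r}")
        wide = wide[list(TIMEPOINTS)]
        groups = np.array([g for _, g in wide.index])
        return wide.to_numpy(dtype=float), groups
    # list of records
    Y, groups = [], []
    for rec in data:
        vals = np.asarray(rec.outcomes[outcome], dtype=float)
        if vals.size != len(TIMEPOINTS) or np.isnan(vals).any():
            raise UnbalancedDesignError(f"{rec.subject_id}: missing timepoints")
        Y.append(vals)
        groups.append(rec.group)
    return np.asarray(Y), np.asarray(groups)


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA

def split_plot_decomposition(Y: np.ndarray, groups: np.ndarray) -> dict:
    """Sums of squares for the two-way mixed design (weighted cell totals).

    ``Y`` is subjects x timepoints; ``groups`` labels each row.  Returns all
    SS/df pieces; SS_total equals their sum exactly (checked by tests to
    1e-9 relative).
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    n_subj, t = Y.shape
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    N = n_subj * t
    G = Y.sum()
    C = G**2 / N  # correction term

    ss_total = float((Y**2).sum() - C)
    # between-subject partition
    subj_tot = Y.sum(axis=1)
    ss_subjects = float((subj_tot**2).sum() / t - C)
    ss_group = 0.0
    for g in labels:
        m = groups == g
        ss_group += Y[m].sum() ** 2 / (m.sum() * t)
    ss_group = float(ss_group - C)
    ss_subj_within = ss_subjects - ss_group
    # within-subject partition
    time_tot = Y.sum(axis=0)
    ss_time = float((time_tot**2).sum() / n_subj - C)
    ss_cells = 0.0
    for g in labels:
        m = groups == g
        ss_cells += (Y[m].sum(axis=0) ** 2 / m.sum()).sum()
    ss_cells = float(ss_cells - C)
    ss_interaction = ss_cells - ss_group - ss_time
    ss_error_within = ss_total - ss_cells - ss_subj_within

    a = len(labels)
    return {
        "ss_total": ss_total,
        "ss_group": ss_group,
        "ss_subj_within": ss_subj_within,
        "ss_time": ss_time,
        "ss_interaction": ss_interaction,
        "ss_error_within": ss_error_within,
        "df_group": a - 1,
        "df_subj_within": n_subj - a,
        "df_time": t - 1,
        "df_interaction": (a - 1) * (t - 1),
        "df_error_within": (n_subj - a) * (t - 1),
    }


def mixed_anova(data, outcome: str) -> list[MixedAnovaResult]:
    """Two-way mixed ANOVA (group x time) for one outcome.

    Returns the between-group, time and interaction effects, each with
    F, df pair, p and effect-size r.
    """
    Y, groups = pivot_outcome(data, outcome)
    return mixed_anova_matrix(Y, groups)


def mixed_anova_matrix(Y: np.ndarray, groups: np.ndarray) -> list[MixedAnovaResult]:
    """Mixed ANOVA on an already-pivoted subjects x timepoints matrix."""
    d = split_plot_decomposition(Y, groups)
    ms_subj = d["ss_subj_within"] / d["df_subj_within"]
    ms_err = d["ss_error_within"] / d["df_error_within"]

    def line(effect: str, ss: float, df1: int, ms_denom: float, df2: int) -> MixedAnovaResult:
        if ms_denom <= 0:
            F = 0.0 if ss <= 0 else np.inf
        else:
            F = (ss / df1) / ms_denom
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        return MixedAnovaResult(effect, float(F), df1, df2, p, effect_size_r(max(F, 0.0), df2))

    return [
        line("between_group", d["ss_group"], d["df_group"], ms_subj, d["df_subj_within"]),
        line("time", d["ss_time"], d["df_time"], ms_err, d["df_error_within"]),
        line("interaction", d["ss_interaction"], d["df_interaction"], ms_err, d["df_error_within"]),
    ]


# ---------------------------------------------------------------------------
# pooled one-way time ANOVA (the study's within-group convention)

def pooled_time_anova(group_data, outcome: str | None = None) -> MixedAnovaResult:
    """One-way ANOVA with timepoint as the factor on pooled observations.

    ``group_data`` is a subjects x timepoints matrix, a tidy DataFrame
    restricted to one group (then ``outcome`` selects rows), or a list of
    records from one group.  Error df = 4n - 4.
    """
    if isinstance(group_data, np.ndarray):
        Y = np.asarray(group_data, dtype=float)
    else:
        if outcome is None:
            raise ValueError("outcome required when passing tidy data")
        Y, groups = pivot_outcome(group_data, outcome)
        if len(set(groups)) != 1:
            raise ValueError("pooled_time_anova expects data from a single group")
    n, t = Y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = Y.mean()
    cell_means = Y.mean(axis=0)
    ss_between = float(n * ((cell_means - grand) ** 2).sum())
    ss_within = float(((Y - cell_means) ** 2).sum())
    df1, df2 = t - 1, t * n - t
    ms_within = ss_within / df2
    if ms_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
    else:
        F = (ss_between / df1) / ms_within
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return MixedAnovaResult("time_pooled", float(F), df1, df2, p, effect_size_r(max(F, 0.0), df2))


# ---------------------------------------------------------------------------
# Tukey HSD

def tukey_hsd(
    group_means_by_time: dict[str, float] | Sequence[float],
    mse: float,
    df_error: int,
    n_per_cell: int,
) -> list[PosthocResult]:
    """Tukey HSD over level means with a common cell size.

    The studentized-range statistic ``q = |m_i - m_j| / sqrt(mse / n)`` is
    referred to the studentized-range distribution with ``k`` levels and
    ``df_error`` error degrees of freedom.
    """
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if isinstance(group_means_by_time, dict):
        labels = list(group_means_by_time)
        means = [group_means_by_time[k] for k in labels]
    else:
        means = list(group_means_by_time)
        labels = [str(i) for i in range(len(means))]
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 levels")
    se = np.sqrt(mse / n_per_cell)
    out = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(np.clip(sps.studentized_range.sf(q, k, df_error), 0.0, 1.0))
        out.append(PosthocResult((labels[i], labels[j]), float(diff), float(q), p))
    return out
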