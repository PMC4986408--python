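"""Group summaries and one-way ANOVA across the four study cohorts.

A cohort table holds one bilateral-averaged value per subject and muscle
compartment, with subjects grouped into lean/obese x youth/aged cohorts.
Summaries are mean +/- SEM; between-group comparison is a one-way ANOVA
with explicit between/within mean-square bookkeeping, since the
between-groups mean square is itself a quantity of interest (it lets the
undisclosed per-group sample size be reconstructed from published group
means).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical cohort-table columns.
TABLE_COLUMNS = ("subject_id", "group", "compartment", "value")


@dataclass(frozen=True)
class AnovaTable:
    """One-way ANOVA bookkeeping for a k-group comparison.

    ``ms_between`` is the between-groups mean square
    ``sum n_i (mean_i - grand)^2 / (k - 1)``; ``ms_within`` the pooled
    within-group mean square.  ``degenerate`` flags the zero-within-variance
    case where F is infinite and p is reported as the limiting 0.
    """

    k: int
    group_sizes: tuple[int, ...]
    group_means: tuple[float, ...]
    grand_mean: float
    ms_between: float
    ms_within: float
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "group_sizes": list(self.group_sizes),
            "group_means": list(self.group_means),
            "grand_mean": self.grand_mean,
            "ms_between": self.ms_between,
            "ms_within": self.ms_within,
            "F": self.f_statistic,
            "p": self.p_value,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "degenerate": self.degenerate,
        }


def _as_groups(table: pd.DataFrame, value_col: str, group_col: str) -> dict[str, np.ndarray]:
    values = pd.to_numeric(table[value_col])
    if not np.isfinite(values).all():
        raise ValueError("cohort values must be finite")
    return {
        str(g): np.asarray(sub, dtype=np.float64)
        for g, sub in values.groupby(table[group_col], observed=True, sort=False)
    }


def group_summary(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group mean, SEM (sample s.d. / sqrt(n)) and n.

    Raises for any group with fewer than two subjects, where the SEM is
    undefined.
    """
    groups = _as_groups(table, value_col, group_col)
    if not groups:
        raise ValueError("empty cohort table")
    rows = []
    for g, vals in groups.items():
        n = len(vals)
        if n < 2:
            raise ValueError(f"group {g!r} has n={n} < 2; SEM undefined")
        rows.append(
            {
                "group": g,
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(n)),
                "n": n,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def one_way_anova(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
) -> AnovaTable:
    """Fixed-effects one-way ANOVA with explicit sums of squares.

    MS_between = sum n_i (mean_i - grand)^2 / (k - 1);
    MS_within  = sum_ij (y_ij - mean_i)^2 / (N - k);
    F = MS_between / MS_within, p from the F(k-1, N-k) distribution.
    """
    groups = _as_groups(table, value_col, group_col)
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs at least two groups")
    sizes, means = [], []
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        sizes.append(len(vals))
        means.append(float(vals.mean()))
    n_i = np.asarray(sizes, dtype=np.float64)
    ybar_i = np.asarray(means, dtype=np.float64)
    N = int(n_i.sum())
    grand = float(sum(v.sum() for v in groups.values()) / N)

    ss_between = float((n_i * (ybar_i - grand) ** 2).sum())
    ss_within = float(
        sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    )
    df_b, df_w = k - 1, N - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w

    if ms_within == 0.0:
        if ms_between == 0.0:
            f_stat, p, degenerate = 0.0, 1.0, False
        else:
            f_stat, p, degenerate = float("inf"), 0.0, True
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_b, df_w))
        degenerate = False
    return AnovaTable(
        k=k,
        group_sizes=tuple(sizes),
        group_means=tuple(means),
        grand_mean=grand,
        ms_between=ms_between,
        ms_within=ms_within,
        f_statistic=f_stat,
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        degenerate=degenerate,
    )


def ms_between_from_means(means: Sequence[float], n_per_group: int) -> float:
    """Between-groups mean square of a balanced design, from group means only.

    ``n * sum (mean_i - grand)^2 / (k - 1)`` — the quantity a published
    ANOVA line reports as its "mean squares".
    """
    m = np.asarray(means, dtype=np.float64)
    if len(m) < 2:
        raise ValueError("need at least two group means")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    grand = m.mean()
    return float(n_per_group * ((m - grand) ** 2).sum() / (len(m) - 1))


def reconcile_sample_size(
    printed_means: Sequence[float],
    printed_ms_between: float,
    n_range: tuple[int, int] = (2, 200),
) -> tuple[int, float]:
    """Infer the balanced per-group n behind a published mean square.

    Brute-force search over n in ``n_range`` minimizing
    ``|MS_between(means, n) - printed_ms_between|``; returns the argmin and
    its residual.
    """
    if printed_ms_between <= 0:
        raise ValueError("printed mean square must be positive")
    lo, hi = n_range
    best_n, best_res = lo, float("inf")
    for n in range(lo, hi + 1):
        res = abs(ms_between_from_means(printed_means, n) - printed_ms_between)
        if res < best_res:
            best_n, best_res = n, res
    return best_n, best_res
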