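"""Two-way repeated-measures ANOVA (condition x sensor pair) with Bonferroni
post hoc comparisons.

The design is fully within-subject: every subject contributes one value per
condition x pair cell (trial-averaged upstream). By default each effect is
tested against its own subject-interaction error term:

    F_condition = MS_condition / MS_(condition x subject)
    F_pair      = MS_pair      / MS_(pair x subject)
    F_interact  = MS_interact  / MS_(condition x pair x subject)

A secondary "pooled" error option tests every effect against the pooled
within-subject error (all three subject-interaction terms combined); the
degrees of freedom it produces are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


class UnbalancedDesignError(ValueError):
    pass


class DegenerateVarianceError(ValueError):
    pass


@dataclass(frozen=True)
class EffectResult:
    effect: str
    ss: float
    df_num: int
    df_den: int
    ms: float
    ms_error: float
    F: float
    p: float


@dataclass(frozen=True)
class PostHocComparison:
    family: str
    level_a: str
    level_b: str
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_adj: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    post_hoc: list[PostHocComparison]
    error_term: str
    alpha: float

    def effects_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects.values()])

    def post_hoc_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.post_hoc])


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * m); m defaults to len(p)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)


def _cell_array(data: pd.DataFrame, dv: str, subject: str, factors: tuple[str, str]):
    """Pivot a balanced long table to y[subject, A, B]; error on imbalance."""
    fa, fb = factors
    subjects = sorted(data[subject].unique())
    a_levels = sorted(data[fa].unique())
    b_levels = sorted(data[fb].unique())
    counts = data.groupby([subject, fa, fb]).size()
    expected = len(subjects) * len(a_levels) * len(b_levels)
    if len(counts) != expected or (counts != 1).any():
        seen = set(counts.index)
        missing = [
            (s, a, b)
            for s in subjects
            for a in a_levels
            for b in b_levels
            if (s, a, b) not in seen
        ]
        dup = counts[counts > 1].index.tolist()
        raise UnbalancedDesignError(
            f"design must have each subject x {fa} x {fb} cell exactly once; "
            f"missing={missing[:10]}, duplicated={dup[:10]}"
        )
    pivot = data.set_index([subject, fa, fb])[dv].sort_index()
    y = pivot.to_numpy().reshape(len(subjects), len(a_levels), len(b_levels))
    return y, subjects, a_levels, b_levels


def _rm_anova_ss(y: np.ndarray) -> dict[str, tuple[float, int]]:
    """Sums of squares and dfs for a fully-within s x a x b design."""
    s, a, b = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_subj = a * b * np.sum((m_s - grand) ** 2)
    ss_a = s * b * np.sum((m_a - grand) ** 2)
    ss_b = s * a * np.sum((m_b - grand) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    return {
        "subject": (ss_subj, s - 1),
        "A": (ss_a, a - 1),
        "B": (ss_b, b - 1),
        "AB": (ss_ab, (a - 1) * (b - 1)),
        "AS": (ss_as, (a - 1) * (s - 1)),
        "BS": (ss_bs, (b - 1) * (s - 1)),
        "ABS": (max(ss_abs, 0.0), (a - 1) * (b - 1) * (s - 1)),
        "total": (ss_total, s * a * b - 1),
    }


def two_way_rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    factors: tuple[str, str] = ("condition", "pair"),
    alpha: float = 0.05,
    error_term: str = "within",
    post_hoc: bool = True,
) -> AnovaResult:
    """Two-way repeated-measures ANOVA on a balanced long-format table.

    `factors` names the two within-subject columns (A, B). Post hoc paired
    t-tests are Bonferroni-corrected within their own family: all level pairs
    of A (collapsed over B) and all level pairs of B (collapsed over A).
    """
    if error_term not in ("within", "pooled"):
        raise ValueError("error_term must be 'within' or 'pooled'")
    y, subjects, a_levels, b_levels = _cell_array(data, dv, subject, factors)
    if y.shape[0] < 3:
        raise UnbalancedDesignError("need >= 3 subjects")
    ss = _rm_anova_ss(y)

    err_of = {"A": "AS", "B": "BS", "AB": "ABS"}
    pooled_ss = ss["AS"][0] + ss["BS"][0] + ss["ABS"][0]
    pooled_df = ss["AS"][1] + ss["BS"][1] + ss["ABS"][1]

    effects: dict[str, EffectResult] = {}
    names = {"A": factors[0], "B": factors[1], "AB": f"{factors[0]} x {factors[1]}"}
    for key, name in names.items():
        ss_eff, df_eff = ss[key]
        if error_term == "within":
            ss_err, df_err = ss[err_of[key]]
        else:
            ss_err, df_err = pooled_ss, pooled_df
        ms_err = ss_err / df_err
        if ms_err <= 0:
            raise DegenerateVarianceError(
                f"zero error variance for effect '{name}'; F undefined"
            )
        ms_eff = ss_eff / df_eff
        F = ms_eff / ms_err
        p = float(sps.f.sf(F, df_eff, df_err))
        effects[name] = EffectResult(
            effect=name, ss=ss_eff, df_num=df_eff, df_den=df_err,
            ms=ms_eff, ms_error=ms_err, F=F, p=p,
        )

    comparisons: list[PostHocComparison] = []
    if post_hoc:
        comparisons += _paired_family(y.mean(axis=2), a_levels, factors[0])
        comparisons += _paired_family(y.mean(axis=1), b_levels, factors[1])
    return AnovaResult(effects=effects, post_hoc=comparisons,
                       error_term=error_term, alpha=alpha)


def _paired_family(subject_by_level: np.ndarray, levels, family: str):
    """Bonferroni-corrected paired t-tests among factor levels (collapsed over
    the other factor); family size = number of level pairs."""
    pairs = list(combinations(range(len(levels)), 2))
    if not pairs:
        return []
    raw = []
    for i, j in pairs:
        diff = subject_by_level[:, i] - subject_by_level[:, j]
        t, p = sps.ttest_rel(subject_by_level[:, i], subject_by_level[:, j])
        raw.append((levels[i], levels[j], float(diff.mean()), float(t),
                    diff.size - 1, float(p)))
    adj = bonferroni([r[5] for r in raw], m=len(pairs))
    return [
        PostHocComparison(family=family, level_a=str(a), level_b=str(b),
                          mean_diff=d, t=t, df=df, p_raw=p, p_adj=float(pa))
        for (a, b, d, t, df, p), pa in zip(raw, adj)
    ]


def anova_input_from_subject_stats(
    subject_stats: pd.DataFrame, metric: str, direction: str
) -> pd.DataFrame:
    """Shape the per-subject aggregate table (one metric, one direction,
    adjacent pairs) into the long format expected by `two_way_rm_anova`."""
    sel = subject_stats[
        (subject_stats["direction"] == direction)
        & (subject_stats["sensor_m"] == subject_stats["sensor_n"] + 1)
    ]
    if len(sel) == 0:
        raise UnbalancedDesignError(f"no rows for direction {direction}")
    return pd.DataFrame(
        {
            "subject": sel["subject"].to_numpy(),
            "condition": sel["condition"].to_numpy(),
            "pair": [f"{n:02d}-{m:02d}" for n, m in zip(sel["sensor_n"], sel["sensor_m"])],
            "value": sel[metric].to_numpy(),
        }
    )
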