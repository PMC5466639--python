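"""Cohort-level tables and statistical comparisons.

Aggregates per-eye records into the study-style group tables (counts and
percentages of eyes with/without migrating HRF; per-group HRF volume
mean/SD/range) and runs the study's tests: Pearson chi-square on 2x2 tables
(group vs rest, no continuity correction by default), Kruskal-Wallis and
Mann-Whitney U rank tests, and Pearson correlation with R^2.

Percentages are rounded to one decimal, half away from zero, matching the
published table formatting.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import EyeRecord
from .params import GROUPS


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (numpy/python round are half-to-even)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        df = cohort.copy()
    else:
        df = pd.DataFrame([asdict(r) if isinstance(r, EyeRecord) else dict(r)
                           for r in cohort])
    if df.empty:
        raise ValueError("cohort is empty")
    unknown = set(df["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}; "
                         f"expected one of {GROUPS}")
    return df


def summarize_counts(cohort) -> pd.DataFrame:
    """Per-group (and overall) counts and percentages of eyes with migrating
    and with non-migrating HRF."""
    df = _as_frame(cohort)
    rows = []
    groups = [g for g in GROUPS if (df["group"] == g).any()]
    for name, sub in [(g, df[df["group"] == g]) for g in groups] + [("overall", df)]:
        n = len(sub)
        n_mig = int(sub["has_migrating_hrf"].sum())
        n_non = int(sub["has_nonmigrating_hrf"].sum())
        rows.append({
            "group": name,
            "n_eyes": n,
            "migrating_n": n_mig,
            "migrating_pct": round_half_away(100.0 * n_mig / n),
            "nonmigrating_n": n_non,
            "nonmigrating_pct": round_half_away(100.0 * n_non / n),
        })
    return pd.DataFrame(rows).set_index("group")


def summarize_volumes(cohort, column: str = "hrf_volume_mm3") -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and min-max range of HRF volume.

    Single-eye groups report SD 0 with sd_degenerate flagged; empty groups
    are omitted.
    """
    df = _as_frame(cohort)
    rows = []
    for g in [g for g in GROUPS if (df["group"] == g).any()]:
        v = df.loc[df["group"] == g, column].to_numpy(dtype=float)
        degenerate = len(v) < 2
        rows.append({
            "group": g,
            "n_eyes": len(v),
            "mean_mm3": float(v.mean()),
            "sd_mm3": 0.0 if degenerate else float(v.std(ddof=1)),
            "min_mm3": float(v.min()),
            "max_mm3": float(v.max()),
            "sd_degenerate": degenerate,
        })
    return pd.DataFrame(rows).set_index("group")


def chi_square_2x2(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table, df = 1.

    Continuity (Yates) correction off by default.  Zero margins are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    n = t.sum()
    (a, b), (c, d) = t
    det = a * d - b * c
    if correction:
        det = max(abs(det) - n / 2.0, 0.0)
    stat = n * det ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), 1, p


def chi_square_group_vs_rest(
    cohort,
    group,
    flag: str = "has_migrating_hrf",
    correction: bool = False,
) -> tuple[float, int, float]:
    """Chi-square of one group (or a combined list of groups) against the
    rest of the cohort on a presence flag."""
    df = _as_frame(cohort)
    groups = [group] if isinstance(group, str) else list(group)
    in_group = df["group"].isin(groups)
    pos = df[flag].astype(bool)
    table = [
        [int((in_group & pos).sum()), int((in_group & ~pos).sum())],
        [int((~in_group & pos).sum()), int((~in_group & ~pos).sum())],
    ]
    return chi_square_2x2(table, correction=correction)


def mann_whitney(
    x, y, alternative: str = "two-sided", exact_max_n: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U (of the first sample) with midrank ties.

    The p-value is exact by enumeration of all group assignments when
    n1 + n2 <= exact_max_n (valid under ties), otherwise the tie-corrected
    normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs at least one observation")
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= exact_max_n:
        mu = n1 * n2 / 2.0
        const = n1 * (n1 + 1) / 2.0
        us = np.array([sum(c) - const for c in combinations(ranks, n1)])
        if alternative == "less":
            p = np.mean(us <= u_obs)
        elif alternative == "greater":
            p = np.mean(us >= u_obs)
        else:
            p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
        return u_obs, float(p)
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; all-identical data gives (0, 1)."""
    if any(len(g) < 1 for g in groups):
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def pearson_r2(x, y) -> tuple[float, float, float]:
    """Pearson r, R^2 = r^2 and the two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r) ** 2, float(p)
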