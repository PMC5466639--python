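"""Cohort tables and statistics against hand values and brute-force oracles."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from polrpe import (EyeRecord, chi_square_2x2, chi_square_group_vs_rest,
                    kruskal_wallis, mann_whitney, pearson_r2,
                    summarize_counts, summarize_volumes)

#: (group, total eyes, eyes with migrating HRF, eyes with non-migrating HRF)
#: reconstructed from the published per-group tallies.
TABLE1 = [
    ("early_intermediate", 14, 5, 0),
    ("drusenoid_ped", 13, 11, 0),
    ("serous_ped", 24, 24, 0),
    ("remission", 22, 4, 7),
    ("fibrosis", 69, 4, 35),
    ("geographic_atrophy", 13, 4, 0),
]


def table1_cohort() -> list[EyeRecord]:
    records = []
    for group, total, mig, non in TABLE1:
        for i in range(total):
            records.append(EyeRecord(
                eye_id=f"{group}{i}", group=group,
                has_migrating_hrf=i < mig,
                has_nonmigrating_hrf=mig <= i < mig + non,
                hrf_volume_mm3=0.0))
    return records


def test_counts_reproduce_published_percentages():
    counts = summarize_counts(table1_cohort())
    assert counts.loc["overall", "n_eyes"] == 155
    assert counts.loc["overall", "migrating_n"] == 52
    assert counts.loc["overall", "migrating_pct"] == 33.5
    assert counts.loc["early_intermediate", "migrating_pct"] == 35.7
    assert counts.loc["drusenoid_ped", "migrating_pct"] == 84.6
    assert counts.loc["serous_ped", "migrating_pct"] == 100.0
    assert counts.loc["remission", "migrating_pct"] == 18.2
    assert counts.loc["remission", "nonmigrating_pct"] == 31.8
    assert counts.loc["fibrosis", "migrating_pct"] == 5.8
    assert counts.loc["fibrosis", "nonmigrating_pct"] == 50.7
    assert counts.loc["geographic_atrophy", "migrating_pct"] == 30.8


def test_counts_single_eye_and_unknown_group():
    rec = EyeRecord("e", "serous_ped", True, False, 0.0)
    counts = summarize_counts([rec])
    assert counts.loc["serous_ped", "migrating_pct"] == 100.0
    with pytest.raises(ValueError, match="unknown group"):
        summarize_counts([EyeRecord("e", "typo", True, False, 0.0)])


def _vol_records(group_vols: dict) -> list[EyeRecord]:
    return [EyeRecord(f"{g}{i}", g, False, False, v)
            for g, vols in group_vols.items() for i, v in enumerate(vols)]


def test_volume_summary_mean_sd_range():
    table = summarize_volumes(_vol_records({"serous_ped": [1e-4, 3e-4]}))
    row = table.loc["serous_ped"]
    assert row.mean_mm3 == pytest.approx(2e-4)
    assert row.sd_mm3 == pytest.approx(math.sqrt(2) * 1e-4)
    assert (row.min_mm3, row.max_mm3) == (1e-4, 3e-4)


def test_volume_summary_single_eye_flagged():
    table = summarize_volumes(_vol_records({"remission": [5e-5]}))
    row = table.loc["remission"]
    assert row.sd_mm3 == 0.0 and bool(row.sd_degenerate)


def test_volume_summary_matches_brute_force(rng):
    vols = rng.random(17).tolist()
    table = summarize_volumes(_vol_records({"fibrosis": vols}))
    v = np.array(vols)
    assert table.loc["fibrosis", "mean_mm3"] == pytest.approx(v.mean(), abs=1e-15)
    sd = math.sqrt(sum((x - v.mean()) ** 2 for x in v) / (len(v) - 1))
    assert table.loc["fibrosis", "sd_mm3"] == pytest.approx(sd, abs=1e-12)


def test_chi_square_reference_values():
    # equal proportions -> no association
    stat, df, p = chi_square_2x2([[10, 10], [5, 5]])
    assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
    # perfect association on balanced 2x2 -> statistic equals n
    stat, _, p = chi_square_2x2([[10, 0], [0, 10]])
    assert stat == pytest.approx(20.0, abs=1e-12)
    with pytest.raises(ValueError, match="margin"):
        chi_square_2x2([[0, 0], [3, 4]])


def _brute_chi2(table):
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            exp = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - exp) ** 2 / exp
    return stat


def test_chi_square_table1_serous_matches_brute_force():
    """Serous PED (24/24 migrating) vs the rest (28/131): Pearson statistic
    equals an expected-counts recomputation to 1e-10."""
    table = [[24, 0], [28, 103]]
    stat, df, p = chi_square_2x2(table)
    assert stat == pytest.approx(_brute_chi2(table), abs=1e-10)
    chi2_scipy = sps.chi2_contingency(np.array(table), correction=False)
    assert stat == pytest.approx(chi2_scipy.statistic, abs=1e-10)
    assert p == pytest.approx(chi2_scipy.pvalue, abs=1e-12)

    cohort = table1_cohort()
    stat2, _, _ = chi_square_group_vs_rest(cohort, "serous_ped")
    assert stat2 == pytest.approx(stat, abs=1e-10)
    # combined drusenoid+serous vs rest is also available
    stat3, _, p3 = chi_square_group_vs_rest(cohort, ["drusenoid_ped", "serous_ped"])
    assert stat3 > 0 and p3 < 0.05


def test_mann_whitney_symmetry_under_identical_multisets():
    x = [1.0, 2.0, 5.0]
    u, _ = mann_whitney(x, x)
    assert u == len(x) ** 2 / 2


def test_mann_whitney_exact_enumeration():
    # {1,2} vs {3,4}: U = 0 and exact one-sided p = 1/6 over C(4,2) splits
    u, p = mann_whitney([1, 2], [3, 4], alternative="less")
    assert u == 0.0
    assert p == pytest.approx(1 / 6, abs=1e-12)


def _brute_exact_mw(x, y, alternative):
    """Independent enumeration oracle with hand-rolled midranks."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    n1 = len(x)
    const = n1 * (n1 + 1) / 2
    u_obs = sum(ranks[:n1]) - const
    mu = n1 * len(y) / 2
    us = [sum(ranks[i] for i in c) - const
          for c in combinations(range(len(pooled)), n1)]
    if alternative == "less":
        return u_obs, sum(u <= u_obs for u in us) / len(us)
    if alternative == "greater":
        return u_obs, sum(u >= u_obs for u in us) / len(us)
    return u_obs, sum(abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us) / len(us)


@pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
def test_mann_whitney_matches_enumeration_oracle_with_ties(rng, alternative):
    for _ in range(5):
        x = rng.integers(0, 4, size=5).astype(float)
        y = rng.integers(0, 4, size=6).astype(float)
        u, p = mann_whitney(x, y, alternative=alternative)
        u_or, p_or = _brute_exact_mw(x, y, alternative)
        assert u == pytest.approx(u_or, abs=1e-10)
        assert p == pytest.approx(p_or, abs=1e-10)


def test_kruskal_identical_groups_and_reference():
    h, p = kruskal_wallis([1, 1], [1, 1], [1, 1])
    assert h == 0.0 and p == 1.0
    h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
    h_sp, p_sp = sps.kruskal([1, 2, 3], [4, 5, 6])
    assert h == pytest.approx(h_sp) and p == pytest.approx(p_sp)


def test_pearson_reference_values():
    x = np.arange(10, dtype=float)
    r, r2, p = pearson_r2(x, 2 * x + 1)
    assert r2 == pytest.approx(1.0)
    r, r2, p = pearson_r2([1, 2, 3], [1, 3, 2])
    assert r == pytest.approx(0.5, abs=1e-12)
    assert r2 == pytest.approx(0.25, abs=1e-12)
    with pytest.raises(ValueError, match="constant"):
        pearson_r2([1, 1, 1], [1, 2, 3])


def test_pearson_matches_brute_force(rng):
    x = rng.random(20)
    y = rng.random(20)
    r, r2, p = pearson_r2(x, y)
    rx, ry = x - x.mean(), y - y.mean()
    r_or = float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))
    assert r == pytest.approx(r_or, abs=1e-12)
    t = r_or * math.sqrt((20 - 2) / (1 - r_or ** 2))
    p_or = 2 * sps.t.sf(abs(t), df=18)
    assert p == pytest.approx(p_or, abs=1e-10)


def test_serous_coupling_yields_positive_hrf_ped_correlation():
    """At the study's serous-PED group size (n = 24) the generator's coupling
    of focus load to dome height yields a significant positive correlation
    between true HRF volume and PED volume for most seeds."""
    from polrpe import build_phantom

    wins = 0
    for seed in range(5):
        rng = np.random.SeedSequence(seed)
        hrf, ped = [], []
        for child in rng.spawn(24):
            ph = build_phantom(
                __import__("polrpe").DESK_PARAMS, "serous_ped", seed=child)
            n_vox = sum(len(ph.focus_voxels(f)[0]) for f in ph.foci)
            hrf.append(n_vox * ph.params.voxel_volume_um3 * 1e-9)
            ped.append(ph.discrete_ped_volume_mm3())
        r, r2, p = pearson_r2(hrf, ped)
        if r > 0 and p < 0.05:
            wins += 1
    assert wins >= 3
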