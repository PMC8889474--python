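"""Paired contrasts, Cohen's d_z, CI reconstruction, correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from vreye.stats import (
    dz_ci,
    dz_from_t,
    expected_dz_inflation,
    paired_contrast,
    pearson_r,
    run_contrast_table,
)


@pytest.mark.parametrize("t,n,expected", [
    (4.24, 31, 0.76),
    (5.05, 30, 0.92),
    (0.0, 31, 0.0),
])
def test_dz_from_t(t, n, expected):
    assert round(dz_from_t(t, n), 2) == expected


@pytest.mark.parametrize("d,n,lo,hi", [
    (0.76, 31, 0.36, 1.16),
    (-0.85, 31, -1.26, -0.44),
])
def test_dz_ci_reproduces_published_intervals(d, n, lo, hi):
    got = dz_ci(d, n)
    assert (round(got[0], 2), round(got[1], 2)) == (lo, hi)


def test_dz_ci_symmetric_at_zero():
    lo, hi = dz_ci(0.0, 31)
    assert lo == pytest.approx(-hi)
    assert hi == pytest.approx(1.96 * math.sqrt(1 / 31), abs=1e-9)


def _pairs_with_diff(n, mean, sd, rng):
    """Pairs whose differences have exactly the requested sample mean/sd."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    diff = mean + sd * z
    y = rng.normal(50, 5, size=n)
    return y + diff, y


def test_paired_contrast_identity_and_engineered_t():
    rng = np.random.default_rng(3)
    n = 31
    t_target = 4.24
    x, y = _pairs_with_diff(n, t_target / math.sqrt(n), 1.0, rng)
    es = paired_contrast(x, y)
    assert es.t == pytest.approx(t_target, abs=1e-9)
    assert es.df == 30
    assert es.d == pytest.approx(dz_from_t(es.t, es.n), abs=1e-12)
    assert round(es.d, 2) == 0.76
    assert (round(es.ci_low, 2), round(es.ci_high, 2)) == (0.36, 1.16)
    assert es.ci_low <= es.d <= es.ci_high
    assert np.sign(es.d) == np.sign(es.t)
    assert es.p < 0.001


def test_null_pairs_give_small_d():
    rng = np.random.default_rng(11)
    y = rng.normal(0, 1, 1000)
    x = y + rng.normal(0, 1, 1000)
    es = paired_contrast(x, y)
    assert abs(es.d) < 0.1


def test_zero_variance_differences_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        paired_contrast([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="zero-variance"):
        paired_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        paired_contrast([1.0, 2.0], [0.0, 0.5])


def test_pairwise_deletion_reflected_in_df():
    rng = np.random.default_rng(4)
    x = rng.normal(10, 2, 20)
    y = rng.normal(9, 2, 20)
    x[3] = np.nan
    es = paired_contrast(x, y)
    assert es.n == 19 and es.df == 18


def test_pearson_perfect_correlations():
    x = np.arange(10.0)
    assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pearson_r(x, -x)[0] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="zero variance"):
        pearson_r(x, np.ones_like(x))


def test_pearson_p_matches_permutation_oracle():
    """Analytic two-tailed p against a permutation distribution of |r|."""
    rng = np.random.default_rng(19)
    n = 30
    x = rng.normal(size=n)
    y = 0.4 * x + rng.normal(size=n)
    r, p = pearson_r(x, y)
    n_perm = 2000
    count = 0
    for _ in range(n_perm):
        rp, _ = pearson_r(x, rng.permutation(y))
        if abs(rp) >= abs(r):
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    se = math.sqrt(p * (1 - p) / n_perm)
    assert abs(p_perm - p) < 3 * se + 2 / n_perm


def test_expected_dz_inflation_near_known_value():
    # E[t]/delta for df=30 is ~1.026; factor must shrink toward 1 with n
    assert expected_dz_inflation(31) == pytest.approx(1.0259, abs=0.0005)
    assert expected_dz_inflation(301) < expected_dz_inflation(31)


def _toy_cohort(n=12, seed=0):
    rng = np.random.default_rng(seed)
    scenes = ("Driving", "Patio", "OutdoorBBQ")
    data = {
        "participant": [f"p{i}" for i in range(n)],
        "craving_active": rng.normal(45, 10, n),
        "craving_neutral": rng.normal(30, 10, n),
        "use_episodes": rng.lognormal(6, 1, n),
    }
    for s in scenes:
        data[f"fix_active_{s}"] = rng.normal(5000, 800, n)
        data[f"fix_neutral_{s}"] = rng.normal(4000, 800, n)
        data[f"pupil_active_{s}"] = rng.normal(3.9, 0.2, n)
        data[f"pupil_neutral_{s}"] = rng.normal(4.0, 0.2, n)
    for s in scenes + ("Bus", "WaitingRoom", "Library"):
        data[f"blink_count_{s}"] = rng.poisson(100, n).astype(float)
    df = pd.DataFrame(data)
    df["bias_ms"] = np.mean(
        [df[f"fix_active_{s}"] - df[f"fix_neutral_{s}"] for s in scenes], axis=0)
    return df


def test_contrast_battery_structure_and_deletion_bookkeeping():
    cohort = _toy_cohort()
    table = run_contrast_table(cohort)
    paired = table[table["kind"] == "paired"]
    names = set(paired["contrast"])
    assert "craving: Active vs Neutral scenes" in names
    assert "fixation: Active vs Neutral cues (pooled)" in names
    assert "pupil: Active vs Neutral cues (Patio)" in names
    assert "EBR: OutdoorBBQ vs Patio" in names
    assert (paired["df"] == paired["n"] - 1).all()
    assert {"pearson"} <= set(table["kind"])

    # drop one participant's pupil stream: only pupil dfs shrink
    cohort2 = cohort.copy()
    for s in ("Driving", "Patio", "OutdoorBBQ"):
        cohort2.loc[0, f"pupil_active_{s}"] = np.nan
    table2 = run_contrast_table(cohort2).set_index("contrast")
    table1 = table.set_index("contrast")
    for name in names:
        expected = table1.loc[name, "n"] - (1 if name.startswith("pupil") else 0)
        assert table2.loc[name, "n"] == expected


def test_holm_adjustment_is_monotone_and_conservative():
    table = run_contrast_table(_toy_cohort(), holm=True)
    paired = table[table["kind"] == "paired"]
    assert (paired["p_holm"] >= paired["p"] - 1e-12).all()
    assert (paired["p_holm"] <= 1.0).all()
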