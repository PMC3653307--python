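"""Tests for life-span grouping, binned averages, cubic fitting and the
annual interpolation grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genspm.cohort import CohortDesign, simulate_cohort, to_records
from genspm.model import allostatic_mean, feedback
from genspm.records import IndividualRecord
from genspm.trajectories import (
    BIN_MIDPOINTS,
    assign_lifespan_group,
    average_trajectory,
    fit_optimal_trajectory,
    interpolate_annual,
)


def _rec(rec_id, sex, event_age, event, ages=(60.0,), values=(200.0,), genotype=None):
    return IndividualRecord(
        id=rec_id, sex=sex, genotype=genotype,
        ages=np.array(ages, dtype=float), values=np.array(values, dtype=float),
        event_age=event_age, event=event,
    )


@pytest.mark.parametrize(
    "sex,event_age,event,expected",
    [
        ("F", 92.0, True, "LS90+"),
        ("F", 91.0, False, "LS90+"),
        ("F", 85.0, True, "LS80-89"),
        ("F", 79.0, True, "LS<80"),
        ("F", 84.0, False, None),  # censored below the threshold: excluded
        ("M", 86.0, False, "LS85+"),
        ("M", 87.0, True, "LS85+"),
        ("M", 80.0, True, "LS<85"),
        ("M", 80.0, False, None),
    ],
)
def test_lifespan_group_assignment(sex, event_age, event, expected):
    rec = _rec("x", sex, event_age, event, ages=(min(70.0, event_age),))
    assert assign_lifespan_group(rec) == expected


def test_lifespan_group_partitions_deaths():
    rng = np.random.default_rng(0)
    for _ in range(50):
        age = float(rng.uniform(41, 105))
        rec = _rec("x", "F", age, True, ages=(40.0,))
        assert assign_lifespan_group(rec) in {"LS90+", "LS80-89", "LS<80"}


def test_average_trajectory_single_observation():
    recs = [_rec("a", "F", 91.0, True, ages=(63.0,), values=(200.0,))]
    table = average_trajectory(recs, "LS90+")
    row = table[table["bin_mid"] == 62.5].iloc[0]
    assert row["mean"] == 200.0 and row["n"] == 1 and np.isnan(row["se"])
    assert (table[table["bin_mid"] != 62.5]["n"] == 0).all()


def test_average_trajectory_pooling_arithmetic():
    rng = np.random.default_rng(1)
    recs = [
        _rec(f"r{i}", "F", 92.0, True, ages=(61.0 + (i % 4), 66.0 + (i % 4)),
             values=tuple(rng.normal(200.0, 20.0, size=2)))
        for i in range(40)
    ]
    t1 = average_trajectory(recs, "LS90+")
    doubled = recs + [
        _rec(r.id + "_copy", r.sex, r.event_age, r.event, r.ages, r.values)
        for r in recs
    ]
    t2 = average_trajectory(doubled, "LS90+")
    sel = t1["n"] > 1
    np.testing.assert_allclose(t2["mean"][sel], t1["mean"][sel])
    np.testing.assert_allclose(
        t2["se"][sel], t1["se"][sel] / np.sqrt(2.0), rtol=0.02
    )


def test_binned_means_track_moment_recursion(chf_params):
    """Deathless long-lived cohort: bin means agree with the AR mean path."""
    gp = chf_params.noncarrier.replace(ln_a_mu0=-700.0, a_mu1=0.0, b_mu1=0.0)
    params = chf_params.replace(noncarrier=gp, carrier=gp)
    design = CohortDesign(n_individuals=2000, entry_age_range=(45, 45), max_age=95,
                          exam_gap_prob=0.0, sex="F", seed=13)
    records = to_records(simulate_cohort(design, params, fixed_genotype=1))
    table = average_trajectory(records, "LS90+")

    ages = np.arange(45, 96)
    m = np.empty(len(ages))
    v = np.empty(len(ages))
    m[0], v[0] = allostatic_mean(45, gp), gp.sigma0**2
    for j, t in enumerate(ages[:-1]):
        a = feedback(t, gp)
        m[j + 1] = m[j] + a * (m[j] - allostatic_mean(t, gp))
        v[j + 1] = (1 + a) ** 2 * v[j] + gp.sigma1**2
    for _, row in table.iterrows():
        if row["n"] < 100:
            continue
        sel = (ages >= row["bin_mid"] - 2.5) & (ages <= row["bin_mid"] + 2.5)
        expected = m[sel].mean()
        tol = 5 * np.sqrt(v[sel].mean() / row["n"]) + 1.0  # +1 for within-bin drift
        assert abs(row["mean"] - expected) < tol


def test_cubic_fit_recovers_exact_cubic():
    coeffs = (120.0, -1.5, 0.03, -0.0002)
    x = BIN_MIDPOINTS
    y = coeffs[0] + coeffs[1] * x + coeffs[2] * x**2 + coeffs[3] * x**3
    f, resid = fit_optimal_trajectory(x, y)
    np.testing.assert_allclose(f.coeffs, coeffs, rtol=1e-8, atol=1e-10)
    assert np.max(np.abs(resid)) < 1e-8


def test_cubic_fit_constant_and_rank_deficiency():
    f, _ = fit_optimal_trajectory(BIN_MIDPOINTS, np.full(len(BIN_MIDPOINTS), 7.0))
    np.testing.assert_allclose(f.coeffs, (7.0, 0.0, 0.0, 0.0), atol=1e-9)
    with pytest.raises(ValueError):
        fit_optimal_trajectory(BIN_MIDPOINTS[:3], np.array([1.0, 2.0, 3.0]))


def test_cubic_fit_unbiased_under_noise():
    true = np.array([150.0, 1.0, -0.01, 2e-5])
    x = BIN_MIDPOINTS
    design_mat = np.vander(x, 4, increasing=True)
    y0 = design_mat @ true
    rng = np.random.default_rng(42)
    est = np.empty((1000, 4))
    for r in range(1000):
        f, _ = fit_optimal_trajectory(x, y0 + rng.normal(0, 2.0, size=x.shape))
        est[r] = f.coeffs
    bias = est.mean(axis=0) - true
    mc_se = est.std(axis=0, ddof=1) / np.sqrt(1000)
    assert np.all(np.abs(bias) < 4 * mc_se)


def test_interpolation_examples():
    rec = _rec("a", "F", 63.0, True, ages=(60.0, 62.0), values=(100.0, 104.0))
    ann = interpolate_annual(rec)
    assert dict(zip(ann.ages.tolist(), ann.values.tolist()))[61] == pytest.approx(102.0)

    single = _rec("b", "F", 70.0, False, ages=(70.0,), values=(90.0,))
    ann = interpolate_annual(single)
    assert ann.ages.tolist() == [70] and ann.values.tolist() == [90.0]

    dense = _rec("c", "F", 65.0, True, ages=(60.0, 61.0, 62.0, 63.0, 64.0),
                 values=(1.0, 2.0, 3.0, 4.0, 5.0))
    ann = interpolate_annual(dense)
    np.testing.assert_allclose(ann.values[:5], dense.values)


def test_interpolation_carry_forward_bounded():
    rec = _rec("a", "F", 72.0, True, ages=(66.0, 70.0), values=(100.0, 110.0))
    ann = interpolate_annual(rec, censor_lag=2.0)
    assert ann.ages.tolist() == [66, 67, 68, 69, 70, 71]
    assert ann.values[-1] == 110.0  # carried forward into the final interval


def test_interpolation_rejects_duplicate_ages():
    rec = _rec("a", "F", 71.0, True, ages=(60.0, 60.0), values=(1.0, 2.0))
    with pytest.raises(ValueError):
        interpolate_annual(rec)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    start=st.integers(40, 70),
    gaps=st.lists(st.integers(1, 6), min_size=1, max_size=8),
    data=st.data(),
)
def test_interpolated_values_within_bracketing_measurements(start, gaps, data):
    ages = np.cumsum([start] + gaps).astype(float)
    values = np.array(
        data.draw(st.lists(st.floats(50, 250), min_size=len(ages), max_size=len(ages)))
    )
    rec = _rec("h", "F", float(ages[-1]) + 1.0, True, ages=ages, values=values)
    ann = interpolate_annual(rec)
    for t, v in zip(ann.ages, ann.values):
        left = values[ages <= t + 1e-9]
        right = values[ages >= t - 1e-9]
        if len(left) and len(right) and t <= ages[-1]:
            lo = min(left[-1], right[0])
            hi = max(left[-1], right[0])
            assert lo - 1e-9 <= v <= hi + 1e-9
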