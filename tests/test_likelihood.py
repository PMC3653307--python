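"""Likelihood tests: oracle equivalence, mixture contracts, monotonicity."""

import math

import numpy as np
import pytest

from genspm.likelihood import (
    loglik_given_g,
    loglik_marginal,
    pack,
    record_breakdown,
    total_loglik,
    total_loglik_single,
)
from genspm.model import OptimalTrajectory, TrajectoryPair, allostatic_mean
from genspm.records import IndividualRecord
from naive_reference import gp_dict, naive_loglik_given_g, naive_total_loglik


def _rec(rec_id, ages, values, event_age, event, genotype=None):
    return IndividualRecord(
        id=rec_id, sex="F", genotype=genotype,
        ages=np.array(ages, dtype=float), values=np.array(values, dtype=float),
        event_age=float(event_age), event=event,
    )


def test_total_loglik_matches_naive_oracle(small_mixed_cohort, chf_params,
                                           chf_trajectory_pair):
    """Criterion: vectorized total equals the scalar assembly to 1e-9 rel."""
    ours = total_loglik(small_mixed_cohort, chf_params, chf_trajectory_pair)
    naive = naive_total_loglik(small_mixed_cohort, chf_params, chf_trajectory_pair)
    assert ours == pytest.approx(naive, rel=1e-9)


def test_per_record_loglik_matches_naive_oracle(small_mixed_cohort, chf_params,
                                                chf_trajectory_pair):
    p = gp_dict(chf_params.noncarrier)
    f = chf_trajectory_pair.noncarrier
    for rec in small_mixed_cohort[:10]:
        ours = loglik_given_g(rec, chf_params.noncarrier, f)
        naive = naive_loglik_given_g(rec, p, f.coeffs, f.age_domain)
        assert ours == pytest.approx(naive, rel=1e-9)


def test_three_measurement_record_against_hand_assembly(chf_noncarrier):
    """Two-year-gap record: compare against explicit scalar factor products."""
    gp = chf_noncarrier
    f = OptimalTrajectory.from_allostatic(gp)
    rec = _rec("h", (60.0, 62.0, 64.0), (150.0, 160.0, 140.0), 65.0, True)
    p = gp_dict(gp)
    expected = naive_loglik_given_g(rec, p, f.coeffs, f.age_domain)
    assert loglik_given_g(rec, gp, f) == pytest.approx(expected, rel=1e-9)


def test_negligible_hazard_single_measurement_reduces_to_initial_term(chf_noncarrier):
    gp = chf_noncarrier.replace(ln_a_mu0=-700.0, a_mu1=0.0, b_mu1=0.0)
    f = OptimalTrajectory.from_allostatic(gp)
    rec = _rec("a", (60.0,), (150.0,), 60.0, False)
    expected = -0.5 * math.log(2 * math.pi * gp.sigma0**2) - (
        150.0 - float(allostatic_mean(60.0, gp))
    ) ** 2 / (2 * gp.sigma0**2)
    assert loglik_given_g(rec, gp, f) == pytest.approx(expected, rel=1e-12)


def test_marginal_degenerate_mixture(chf_params, chf_trajectory_pair):
    rec = _rec("a", (60.0, 62.0), (150.0, 160.0), 63.0, True)
    ll1 = loglik_given_g(rec, chf_params.noncarrier, chf_trajectory_pair.noncarrier)
    assert loglik_marginal(
        rec, chf_params.replace(p1=1.0), chf_trajectory_pair
    ) == pytest.approx(ll1, rel=1e-12)


def test_marginal_identical_components(chf_params, chf_trajectory_pair):
    same = chf_params.replace(carrier=chf_params.noncarrier)
    f_same = TrajectoryPair(chf_trajectory_pair.noncarrier, chf_trajectory_pair.noncarrier)
    rec = _rec("a", (60.0, 62.0), (150.0, 160.0), 63.0, True)
    ll = loglik_given_g(rec, same.noncarrier, f_same.noncarrier)
    for p1 in (0.1, 0.5, 0.9):
        assert loglik_marginal(rec, same.replace(p1=p1), f_same) == pytest.approx(
            ll, rel=1e-12
        )


def test_marginal_mixture_envelope(small_mixed_cohort, chf_params, chf_trajectory_pair):
    p1 = chf_params.p1
    for rec in small_mixed_cohort:
        if rec.genotype is not None:
            continue
        ll1 = loglik_given_g(rec, chf_params.noncarrier, chf_trajectory_pair.noncarrier)
        ll0 = loglik_given_g(rec, chf_params.carrier, chf_trajectory_pair.carrier)
        marg = loglik_marginal(rec, chf_params, chf_trajectory_pair)
        assert marg <= max(ll1, ll0) + 1e-12
        assert marg >= max(ll1 + math.log(p1), ll0 + math.log(1 - p1)) - 1e-12


def test_marginal_no_underflow_far_below_exp700(chf_params, chf_trajectory_pair):
    # a wildly improbable record: each component is below -700 on the log scale
    rec = _rec("far", tuple(np.arange(40.0, 80.0, 2.0)),
               tuple(np.full(20, 1500.0)), 80.0, True)
    marg = loglik_marginal(rec, chf_params, chf_trajectory_pair)
    assert np.isfinite(marg) and marg < -700


def test_total_additivity_and_permutation(small_mixed_cohort, chf_params,
                                          chf_trajectory_pair):
    rec = next(r for r in small_mixed_cohort if r.genotype == 1)
    single = total_loglik([rec], chf_params, chf_trajectory_pair)
    expected = loglik_given_g(
        rec, chf_params.noncarrier, chf_trajectory_pair.noncarrier
    ) + math.log(chf_params.p1)
    assert single == pytest.approx(expected, rel=1e-12)

    rng = np.random.default_rng(3)
    shuffled = list(small_mixed_cohort)
    rng.shuffle(shuffled)
    a = total_loglik(small_mixed_cohort, chf_params, chf_trajectory_pair)
    b = total_loglik(shuffled, chf_params, chf_trajectory_pair)
    assert a == pytest.approx(b, abs=1e-9)


def test_survival_block_penalizes_deviations_from_optimal(chf_noncarrier):
    gp = chf_noncarrier.replace(a_mu1=2e-5, b_mu1=0.0)
    # censored record: the survival block is purely -sum(mu), so a larger
    # deviation from the optimal trajectory must strictly lower it
    rec = _rec("a", tuple(np.arange(60.0, 76.0, 2.0)),
               tuple(np.full(8, 150.0)), 75.0, False)
    lls = []
    for shift in (0.0, 20.0, 40.0, 80.0):
        f = OptimalTrajectory((150.0 + shift, 0.0, 0.0, 0.0), (42.5, 92.5))
        lls.append(loglik_given_g(rec, gp, f))
    assert np.all(np.diff(lls) < 0)


def test_pack_rejects_invalid_records(chf_noncarrier):
    bad = _rec("bad", (60.0, 58.0), (1.0, 2.0), 61.0, True)
    with pytest.raises(ValueError, match="bad"):
        pack([bad])
    with pytest.raises(ValueError, match="empty"):
        pack([])
    # censored too long after the last measurement violates the study rule
    late = _rec("late", (60.0,), (150.0,), 66.0, False)
    with pytest.raises(ValueError, match="censor"):
        pack([late])


def test_record_breakdown_consistency(small_mixed_cohort, chf_params,
                                      chf_trajectory_pair):
    df = record_breakdown(small_mixed_cohort, chf_params, chf_trajectory_pair)
    assert len(df) == len(small_mixed_cohort)
    total = total_loglik(small_mixed_cohort, chf_params, chf_trajectory_pair)
    assert df["contribution"].sum() == pytest.approx(total, rel=1e-12)


def test_total_loglik_single_consistency(chf_params, chf_trajectory_pair):
    recs = [
        _rec("a", (60.0, 62.0), (150.0, 160.0), 63.0, True, genotype=1),
        _rec("b", (55.0, 57.0, 59.0), (140.0, 150.0, 145.0), 60.0, False, genotype=1),
    ]
    f = chf_trajectory_pair.noncarrier
    expected = sum(loglik_given_g(r, chf_params.noncarrier, f) for r in recs)
    assert total_loglik_single(recs, chf_params.noncarrier, f) == pytest.approx(
        expected, rel=1e-12
    )
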