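"""Tests of the synthetic-cohort generator against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from genspm.cohort import (
    CohortDesign,
    cohort_to_frame,
    simulate_cohort,
    simulate_mortality,
    simulate_path,
    to_records,
    truth_to_frame,
)
from genspm.model import OptimalTrajectory, TrajectoryPair, allostatic_mean, feedback


def _nullify_mortality(gp):
    return gp.replace(ln_a_mu0=-700.0, sigma2=0.0, a_mu1=0.0, b_mu1=0.0)


def test_noise_free_path_follows_deterministic_recursion(chf_noncarrier):
    # constant allostatic level: f1 is an exact fixed point of the dynamics
    gp = chf_noncarrier.replace(sigma0=1e-12, sigma1=1e-12, b_f1=0.0, c_f1=0.0)
    ages, y = simulate_path(gp, 40, 90, rng=0)
    np.testing.assert_allclose(y, np.full_like(y, gp.a_f1), atol=1e-8)
    # age-varying f1: the noise-free path is the mean recursion (tracks f1
    # with a lag set by the adaptive capacity, not f1 itself)
    gp = chf_noncarrier.replace(sigma0=1e-12, sigma1=1e-12)
    ages, y = simulate_path(gp, 40, 90, rng=0)
    m = allostatic_mean(ages[0], gp)
    for t, y_next in zip(ages[:-1], y[1:]):
        m = m + feedback(t, gp) * (m - allostatic_mean(t, gp))
        assert y_next == pytest.approx(m, abs=1e-8)


def test_deviation_shrinks_geometrically(chf_noncarrier):
    # constant f1 and constant feedback: deviation decays as d (1+a)^k
    gp = chf_noncarrier.replace(b_f1=0.0, c_f1=0.0, b_Y=0.0, sigma1=1e-300)
    ages, y = simulate_path(gp, 50, 70, rng=3)
    d0 = y[0] - gp.a_f1
    k = np.arange(len(ages))
    np.testing.assert_allclose(y - gp.a_f1, d0 * (1.0 + gp.a_Y) ** k, rtol=1e-9)


def test_latent_moments_match_ar_recursions(chf_params):
    """Sample mean/variance of 10,000 paths vs the one-step moment recursions."""
    gp = _nullify_mortality(chf_params.noncarrier)
    params = chf_params.replace(noncarrier=gp, carrier=gp)
    n = 10_000
    design = CohortDesign(
        n_individuals=n, entry_age_range=(50, 50), max_age=80,
        exam_gap_prob=0.0, exam_interval=1, sex="F", seed=77,
    )
    individuals = simulate_cohort(design, params, fixed_genotype=1)
    paths = np.array([ind.annual_path for ind in individuals])
    ages = individuals[0].annual_ages

    # independent moment-recursion oracle
    m = np.empty(len(ages))
    v = np.empty(len(ages))
    m[0], v[0] = allostatic_mean(ages[0], gp), gp.sigma0**2
    for j, t in enumerate(ages[:-1]):
        a = feedback(t, gp)
        m[j + 1] = m[j] + a * (m[j] - allostatic_mean(t, gp))
        v[j + 1] = (1 + a) ** 2 * v[j] + gp.sigma1**2

    sample_m = paths.mean(axis=0)
    sample_v = paths.var(axis=0, ddof=1)
    # mean within 4 standard errors, variance ratio within 4 SE of 1
    np.testing.assert_array_less(np.abs(sample_m - m), 4 * np.sqrt(v / n) + 1e-12)
    np.testing.assert_array_less(np.abs(sample_v / v - 1.0), 4 * np.sqrt(2.0 / (n - 1)))


def test_survival_matches_discrete_gompertz_closed_form(chf_params):
    """With mu1 = 0 and sigma2 = 0 the yearly death mechanism has an exact
    closed form: S(T) = exp(-sum_t a e^{bt}) over survived years."""
    gp = chf_params.noncarrier.replace(sigma2=0.0, a_mu1=0.0, b_mu1=0.0)
    params = chf_params.replace(noncarrier=gp, carrier=gp)
    n = 10_000
    t0 = 50
    design = CohortDesign(
        n_individuals=n, entry_age_range=(t0, t0), max_age=100,
        exam_gap_prob=0.0, sex="F", seed=99,
    )
    individuals = simulate_cohort(design, params, fixed_genotype=1)
    death_ages = np.array(
        [np.inf if ind.death_age is None else ind.death_age for ind in individuals]
    )
    for T in (55, 60, 65, 70, 80):
        ages = np.arange(t0, T)
        s_true = np.exp(-np.sum(np.exp(gp.ln_a_mu0 + gp.b_mu0 * ages)))
        s_obs = np.mean(death_ages > T)
        se = np.sqrt(s_true * (1 - s_true) / n)
        assert abs(s_obs - s_true) < 4 * se + 1e-12, f"age {T}: {s_obs} vs {s_true}"


def test_mortality_extremes(chf_params):
    gp0 = _nullify_mortality(chf_params.noncarrier)
    params0 = chf_params.replace(noncarrier=gp0, carrier=gp0)
    design = CohortDesign(n_individuals=200, max_age=95, sex="F", seed=5)
    inds = simulate_cohort(design, params0, fixed_genotype=1)
    assert all(ind.death_age is None for ind in inds)
    assert all(not ind.event for ind in inds)

    gp_hi = chf_params.noncarrier.replace(ln_a_mu0=5.0, b_mu0=1e-6)
    params_hi = chf_params.replace(noncarrier=gp_hi, carrier=gp_hi)
    f = OptimalTrajectory.from_allostatic(gp_hi)
    inds = simulate_cohort(design, params_hi, TrajectoryPair(f, f), fixed_genotype=1)
    assert all(ind.death_age == ind.annual_ages[0] + 1 for ind in inds)


def test_simulate_mortality_consistent_with_hazard(chf_noncarrier):
    gp = chf_noncarrier
    f = OptimalTrajectory.from_allostatic(gp)
    ages, y = simulate_path(gp, 45, 100, rng=11)
    death = simulate_mortality(ages, y, gp, f, rng=12)
    assert death is None or (45 < death <= 100)


def test_bit_reproducibility(chf_params):
    design = CohortDesign(n_individuals=150, sex="F", seed=2024)
    a = cohort_to_frame(simulate_cohort(design, chf_params))
    b = cohort_to_frame(simulate_cohort(design, chf_params))
    pd.testing.assert_frame_equal(a, b)
    c = cohort_to_frame(simulate_cohort(design.replace(seed=2025), chf_params))
    assert not a.equals(c)


def test_degenerate_designs(chf_params):
    with pytest.raises(ValueError):
        CohortDesign(n_individuals=0).validate()
    with pytest.raises(ValueError):
        CohortDesign(n_individuals=10, entry_age_range=(60, 40)).validate()

    # p1 = 1: everyone is a noncarrier
    params = chf_params.replace(p1=1.0)
    design = CohortDesign(n_individuals=100, sex="F", seed=8)
    inds = simulate_cohort(design, params)
    assert all(ind.true_genotype == 1 for ind in inds)

    # genotyping age beyond max_age: a purely non-genetic sample
    design = CohortDesign(n_individuals=100, max_age=90, genotyping_age=95,
                          sex="F", seed=9)
    inds = simulate_cohort(design, chf_params)
    assert not any(ind.genotype_observed for ind in inds)


def test_survival_dependent_genotyping_and_selection(chf_params):
    n = 5000
    design = CohortDesign(n_individuals=n, genotyping_age=78,
                          genotyped_fraction=0.5, max_age=110, sex="F", seed=31)
    inds = simulate_cohort(design, chf_params)
    truth = truth_to_frame(inds).drop_duplicates("id")
    event_ages = np.array([ind.event_age for ind in inds])
    observed = np.array([ind.genotype_observed for ind in inds])

    # genotyped subjects reached the genotyping age
    assert np.all(event_ages[observed] >= design.genotyping_age)
    # selection effect: genotyped subjects live longer on average
    assert event_ages[observed].mean() > event_ages.mean()

    # tabulation oracle: among survivors, genotyping is a fair 50% coin
    survivors = event_ages >= design.genotyping_age
    n_surv = int(survivors.sum())
    frac = observed[survivors].mean()
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n_surv)
    # carrier share among genotyped matches the share among survivors
    g = np.array([ind.true_genotype for ind in inds])
    p_surv = g[survivors].mean()
    p_obs = g[observed].mean()
    assert abs(p_obs - p_surv) < 3 * np.sqrt(p_surv * (1 - p_surv) / observed.sum())
    # and differential survival enriches noncarriers relative to p1 here
    assert truth["true_genotype"].eq("noncarrier").mean() == pytest.approx(
        chf_params.p1, abs=3 * np.sqrt(0.23 / n)
    )


def test_censoring_rule_bounds_event_gap(chf_params):
    design = CohortDesign(n_individuals=400, exam_gap_prob=0.4, sex="F", seed=55)
    records = to_records(simulate_cohort(design, chf_params))
    for rec in records:
        gap = rec.event_age - rec.ages[-1]
        assert gap <= design.censor_lag + 1e-9
        rec.validate(censor_lag=design.censor_lag)
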