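"""Deliberately naive scalar re-implementation of the model likelihood.

Pure-python ``math`` arithmetic with explicit loops, written directly from
the model definition and kept independent of the package's vectorized code
paths; used as the oracle in equivalence tests.
"""

import math


def naive_f1(t, p):
    return p["a_f1"] + p["b_f1"] * t + p["c_f1"] * t * t


def naive_feedback(t, p):
    return p["a_Y"] + p["b_Y"] * t


def naive_mu1(t, p):
    return max(0.0, p["a_mu1"] + p["b_mu1"] * t)


def naive_mu0(t, p):
    a = math.exp(p["ln_a_mu0"])
    b = p["b_mu0"]
    cum = a * (math.exp(b * t) - 1.0) / b if abs(b) > 1e-12 else a * t
    return a * math.exp(b * t) / (1.0 + p["sigma2"] ** 2 * cum)


def naive_cubic(t, coeffs, domain):
    t = min(max(t, domain[0]), domain[1])
    c0, c1, c2, c3 = coeffs
    return c0 + c1 * t + c2 * t * t + c3 * t * t * t


def naive_hazard(t, y, p, coeffs, domain):
    d = y - naive_cubic(t, coeffs, domain)
    return naive_mu0(t, p) + d * d * naive_mu1(t, p)


def _norm_logpdf(x, mean, var):
    return -0.5 * math.log(2.0 * math.pi * var) - (x - mean) ** 2 / (2.0 * var)


def _annual_values(ages, values, event_age, censor_lag):
    """Integer-age grid with linear interpolation and bounded carry-forward."""
    t0 = math.ceil(ages[0] - 1e-9)
    t1 = math.floor(ages[-1] + 1e-9)
    grid = {}
    if t1 < t0:
        t0 = t1 = round(ages[0])
        grid[t0] = values[0]
    else:
        for t in range(t0, t1 + 1):
            j = 0
            while j < len(ages) - 1 and ages[j + 1] < t:
                j += 1
            if t <= ages[0]:
                grid[t] = values[0]
            else:
                w = (t - ages[j]) / (ages[j + 1] - ages[j])
                grid[t] = values[j] + w * (values[j + 1] - values[j])
    t_end = min(math.ceil(event_age - 1e-9) - 1,
                math.floor(ages[-1] + censor_lag + 1e-9))
    for t in range(t1 + 1, t_end + 1):
        grid[t] = values[-1]
    return grid


def naive_loglik_given_g(record, p, coeffs, domain, censor_lag=2.0):
    """Scalar assembly of the three likelihood blocks for one genotype."""
    ages = [round(a) for a in record.ages]
    values = list(record.values)
    ll = _norm_logpdf(values[0], naive_f1(ages[0], p), p["sigma0"] ** 2)
    for j in range(len(ages) - 1):
        m, v = values[j], 0.0
        for t in range(ages[j], ages[j + 1]):
            a_t = naive_feedback(t, p)
            m = m + a_t * (m - naive_f1(t, p))
            v = (1.0 + a_t) ** 2 * v + p["sigma1"] ** 2
        ll += _norm_logpdf(values[j + 1], m, v)
    grid = _annual_values([float(a) for a in record.ages], values,
                          record.event_age, censor_lag)
    t_entry = min(grid) if grid else None
    t_final = math.ceil(record.event_age - 1e-9) - 1
    if t_entry is not None and t_final >= t_entry:
        for t in range(t_entry, t_final):
            ll -= naive_hazard(t, grid.get(t, values[-1]), p, coeffs, domain)
        mu_last = naive_hazard(t_final, grid.get(t_final, values[-1]), p, coeffs, domain)
        if record.event:
            ll += math.log(1.0 - math.exp(-mu_last))
        else:
            ll -= mu_last
    return ll


def gp_dict(gp):
    """GenotypeParams -> plain dict for the naive functions."""
    from genspm.model import PARAM_FIELDS

    return {f: getattr(gp, f) for f in PARAM_FIELDS}


def naive_total_loglik(records, params, f_pair, censor_lag=2.0):
    p1 = params.p1
    d1 = gp_dict(params.noncarrier)
    d0 = gp_dict(params.carrier)
    f1c, f1d = f_pair.noncarrier.coeffs, f_pair.noncarrier.age_domain
    f0c, f0d = f_pair.carrier.coeffs, f_pair.carrier.age_domain
    total = 0.0
    for rec in records:
        if rec.genotype == 1:
            total += naive_loglik_given_g(rec, d1, f1c, f1d, censor_lag) + math.log(p1)
        elif rec.genotype == 0:
            total += naive_loglik_given_g(rec, d0, f0c, f0d, censor_lag) + math.log(1.0 - p1)
        else:
            l1 = naive_loglik_given_g(rec, d1, f1c, f1d, censor_lag)
            l0 = naive_loglik_given_g(rec, d0, f0c, f0d, censor_lag)
            mx = max(l1 + math.log(p1), l0 + math.log(1.0 - p1))
            total += mx + math.log(
                math.exp(l1 + math.log(p1) - mx) + math.exp(l0 + math.log(1.0 - p1) - mx)
            )
    return total
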