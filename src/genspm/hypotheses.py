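"""Nested-model hypotheses on aging-related characteristics, tested by
likelihood ratio.

Six null-hypothesis families compare carriers and noncarriers or probe the
age dynamics of single components:

- ``baseline_equal`` (a): the gamma-Gompertz baselines coincide
  (ties ln_a_mu0, b_mu0 and sigma2; df = 3)
- ``no_quadratic_hazard`` (b): mu1(t) = 0 for one stratum (df = 2)
- ``age_constant_ushape`` (c): b_mu1 = 0 for one stratum (df = 1)
- ``adaptive_equal`` (d): the feedback coefficients coincide (df = 2)
- ``no_adaptive_decline`` (e): b_Y = 0 for one stratum (df = 1; a boundary
  null because b_Y >= 0)
- ``allostatic_equal`` (f): the mean allostatic trajectories coincide (df = 3)

Whether the baseline-equality null should tie sigma2 along with the Gompertz
parameters is a modeling choice; the plain free-parameter count (df = 3) is
the default here and composing custom restrictions is supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .estimation import FitOptions, FitResult, fit
from .model import ModelParams, TrajectoryPair

__all__ = [
    "Restriction",
    "LRTResult",
    "HYPOTHESES",
    "build_restriction",
    "compose",
    "lrt",
    "battery",
    "battery_table",
    "significance_marker",
]


@dataclass(frozen=True)
class Restriction:
    """A parameter-tying/zeroing map defining a nested null model."""

    hypothesis: str
    ties: tuple  # field names tied carrier := noncarrier
    zeros: tuple  # (stratum, field) pairs fixed at zero
    df: int
    boundary: bool = False


_STRATA = ("noncarrier", "carrier")

#: hypothesis id -> (tied fields, zeroed fields, per-stratum?, boundary?)
HYPOTHESES = {
    "baseline_equal": (("ln_a_mu0", "b_mu0", "sigma2"), (), False, False),
    "no_quadratic_hazard": ((), ("a_mu1", "b_mu1"), True, False),
    "age_constant_ushape": ((), ("b_mu1",), True, False),
    "adaptive_equal": (("a_Y", "b_Y"), (), False, False),
    "no_adaptive_decline": ((), ("b_Y",), True, True),
    "allostatic_equal": (("a_f1", "b_f1", "c_f1"), (), False, False),
}

_ALIASES = {
    "a": "baseline_equal",
    "b": "no_quadratic_hazard",
    "c": "age_constant_ushape",
    "d": "adaptive_equal",
    "e": "no_adaptive_decline",
    "f": "allostatic_equal",
}


def build_restriction(hypothesis: str, stratum: str | None = None) -> Restriction:
    """Resolve a hypothesis id (full name or letter a-f) to a Restriction.

    Per-stratum hypotheses (b, c, e) apply to one genotype at a time and
    require ``stratum`` ("noncarrier" or "carrier").
    """
    hyp = _ALIASES.get(hypothesis, hypothesis)
    if hyp not in HYPOTHESES:
        raise KeyError(f"unknown hypothesis {hypothesis!r}; known: {sorted(HYPOTHESES)}")
    ties, zero_fields, per_stratum, boundary = HYPOTHESES[hyp]
    if per_stratum:
        if stratum not in _STRATA:
            raise ValueError(
                f"hypothesis {hyp!r} applies per genotype; stratum must be one of {_STRATA}"
            )
        zeros = tuple((stratum, f) for f in zero_fields)
        name = f"{hyp}[{stratum}]"
    else:
        if stratum is not None:
            raise ValueError(f"hypothesis {hyp!r} is not per-stratum")
        zeros = ()
        name = hyp
    df = len(ties) + len(zeros)
    return Restriction(name, tuple(ties), zeros, df, boundary)


def compose(*restrictions: Restriction) -> Restriction:
    """Combine disjoint restrictions; degrees of freedom add."""
    ties, zeros, names = [], [], []
    boundary = False
    for r in restrictions:
        ties.extend(r.ties)
        zeros.extend(r.zeros)
        names.append(r.hypothesis)
        boundary = boundary or r.boundary
    if len(set(ties)) != len(ties) or len(set(zeros)) != len(zeros):
        raise ValueError("composed restrictions overlap; df would not be additive")
    return Restriction("+".join(names), tuple(ties), tuple(zeros),
                       len(ties) + len(zeros), boundary)


@dataclass
class LRTResult:
    hypothesis: str
    loglik_general: float
    loglik_restricted: float
    statistic: float
    df: int
    p_value: float
    p_value_mixture: float | None
    boundary: bool
    converged: bool
    restricted_fit: FitResult


def _restricted_init(params: ModelParams, restriction: Restriction) -> ModelParams:
    nc, c = params.noncarrier, params.carrier
    c = c.replace(**{f: getattr(nc, f) for f in restriction.ties})
    for stratum, f_name in restriction.zeros:
        if stratum == "noncarrier":
            nc = nc.replace(**{f_name: 0.0})
        else:
            c = c.replace(**{f_name: 0.0})
    return params.replace(noncarrier=nc, carrier=c)


def lrt(
    data,
    f_pair: TrajectoryPair,
    general_fit: FitResult,
    hypothesis: str,
    stratum: str | None = None,
    options: FitOptions | None = None,
    fixed: dict | None = None,
    censor_lag: float = 2.0,
) -> LRTResult:
    """Refit under the null restriction and apply the likelihood-ratio test.

    The restricted fit is warm-started from the general estimates with the
    restriction imposed.  For the boundary null (e) a 50:50 chi-bar-square
    mixture p-value is reported alongside the naive chi-square one; the
    naive value is the headline number.
    """
    restriction = build_restriction(hypothesis, stratum)
    init = _restricted_init(general_fit.params, restriction)
    res = fit(data, f_pair, init, options=options, fixed=fixed,
              restriction=restriction, censor_lag=censor_lag)
    stat = 2.0 * (general_fit.loglik - res.loglik)
    ok = stat >= -1e-3 and res.converged
    stat_c = max(stat, 0.0)
    p = float(chi2.sf(stat_c, restriction.df))
    p_mix = None
    if restriction.boundary and restriction.df == 1:
        p_mix = float(0.5 * chi2.sf(stat_c, 1))
    return LRTResult(
        hypothesis=restriction.hypothesis,
        loglik_general=general_fit.loglik,
        loglik_restricted=res.loglik,
        statistic=stat,
        df=restriction.df,
        p_value=p,
        p_value_mixture=p_mix,
        boundary=restriction.boundary,
        converged=ok,
        restricted_fit=res,
    )


def battery(
    data,
    f_pair: TrajectoryPair,
    general_fit: FitResult,
    options: FitOptions | None = None,
    fixed: dict | None = None,
    hypotheses=None,
    censor_lag: float = 2.0,
) -> list:
    """Run the full test battery (per-stratum hypotheses for both strata)."""
    out = []
    for hyp in hypotheses or list(HYPOTHESES):
        hyp = _ALIASES.get(hyp, hyp)
        per_stratum = HYPOTHESES[hyp][2]
        if per_stratum:
            for stratum in _STRATA:
                out.append(lrt(data, f_pair, general_fit, hyp, stratum,
                               options=options, fixed=fixed, censor_lag=censor_lag))
        else:
            out.append(lrt(data, f_pair, general_fit, hyp,
                           options=options, fixed=fixed, censor_lag=censor_lag))
    return out


def significance_marker(p: float) -> str:
    """P-value band markers used in the summary table."""
    if p < 0.0001:
        return "†"
    if p < 0.001:
        return "§"
    if p < 0.01:
        return "#"
    if p < 0.05:
        return "*"
    return ""


def battery_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "hypothesis": r.hypothesis,
                "loglik_general": r.loglik_general,
                "loglik_restricted": r.loglik_restricted,
                "statistic": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "p_value_mixture": np.nan if r.p_value_mixture is None else r.p_value_mixture,
                "marker": significance_marker(r.p_value),
                "boundary": r.boundary,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)
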