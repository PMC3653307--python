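"""Parametric building blocks of the stochastic process model of aging.

The model couples the age dynamics of a physiological variable ``Y_t``
(total cholesterol, diastolic blood pressure, ...) with mortality.  The
latent dynamics follow a mean-reverting diffusion

    dY_t = a(t, G) (Y_t - f1(t, G)) dt + sigma1 dW_t,
    Y_{t0} ~ N(f1(t0, G), sigma0^2),

where ``f1`` is the *mean allostatic trajectory* (the curve homeostatic
regulation forces the variable toward), and ``a(t, G) = a_Y + b_Y t`` is the
negative feedback coefficient whose absolute value is the *adaptive
capacity*; its decline with age models homeostenosis.  The mortality rate
conditional on the variable is U-shaped around an "optimal" trajectory
``f(t, G)``:

    mu(t, Y_t, G) = mu0(t, G) + (Y_t - f(t, G))^2 mu1(t, G),

with a gamma-Gompertz (logistic) baseline ``mu0`` allowing old-age mortality
deceleration and an age-linear sensitivity ``mu1``.  Every coefficient is
indexed by a binary genotype ``G`` (1 = noncarrier, 0 = carrier of the risk
allele), with carrier status distributed Bernoulli: P(G = 1) = p1.

All functions here are pure and vectorized over age; they are shared by the
cohort simulator and the likelihood so that both sides of the analysis use
literally the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

__all__ = [
    "PARAM_FIELDS",
    "DISPLAY_SCALE",
    "GenotypeParams",
    "ModelParams",
    "OptimalTrajectory",
    "TrajectoryPair",
    "feedback",
    "allostatic_mean",
    "mu1",
    "gompertz",
    "gompertz_cumulative",
    "baseline_hazard",
    "hazard",
]

#: canonical parameter order used by the estimation machinery
PARAM_FIELDS = (
    "ln_a_mu0",
    "b_mu0",
    "sigma2",
    "a_mu1",
    "b_mu1",
    "a_Y",
    "b_Y",
    "a_f1",
    "b_f1",
    "c_f1",
    "sigma0",
    "sigma1",
)

#: natural value = printed (display) value * factor.  Published tables print
#: mu1 coefficients and the feedback slope rescaled for legibility.
DISPLAY_SCALE = {"a_mu1": 1e-4, "b_mu1": 1e-5, "b_Y": 1e-3}


@dataclass(frozen=True)
class GenotypeParams:
    """The 12 scalar parameters of one genotype stratum (natural scale).

    Units, writing ``u`` for the physiological variable's unit (mg/dL for
    cholesterol, mmHg for blood pressure):

    - ``ln_a_mu0``: log scale of the Gompertz baseline (hazard in 1/year)
    - ``b_mu0``: Gompertz slope, 1/year
    - ``sigma2``: gamma-frailty heterogeneity (enters squared), dimensionless
    - ``a_mu1``, ``b_mu1``: intercept/slope of the U-shape sensitivity,
      1/(year u^2) and 1/(year^2 u^2)
    - ``a_Y`` (< 0), ``b_Y`` (>= 0): feedback intercept/slope, 1/year, 1/year^2
    - ``a_f1``, ``b_f1``, ``c_f1``: quadratic mean allostatic trajectory,
      u, u/year, u/year^2
    - ``sigma0``: initial-condition SD, u
    - ``sigma1``: diffusion SD, u/sqrt(year)
    """

    ln_a_mu0: float
    b_mu0: float
    sigma2: float
    a_mu1: float
    b_mu1: float
    a_Y: float
    b_Y: float
    a_f1: float
    b_f1: float
    c_f1: float
    sigma0: float
    sigma1: float

    def validate(self, t_min: float = 30.0, t_max: float = 95.0) -> "GenotypeParams":
        """Check invariants over the configured age span; return self.

        The feedback must stay negative (mean reversion) across
        ``[t_min, t_max]``; the default upper bound is 95 years, beyond which
        survivorship under any realistic hazard is negligible.
        """
        if not self.a_Y < 0:
            raise ValueError(f"feedback intercept a_Y must be negative, got {self.a_Y}")
        if self.b_Y < 0:
            raise ValueError(f"feedback slope b_Y must be nonnegative, got {self.b_Y}")
        if self.a_Y + self.b_Y * t_max >= 0:
            raise ValueError(
                f"feedback a(t) = a_Y + b_Y t reaches zero inside [{t_min}, {t_max}] "
                f"(zero crossing at t = {-self.a_Y / self.b_Y:.1f}); mean reversion lost"
            )
        if not self.sigma0 > 0:
            raise ValueError("sigma0 must be positive")
        if not self.sigma1 > 0:
            raise ValueError("sigma1 must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, vec: Iterable[float]) -> "GenotypeParams":
        vec = np.asarray(list(vec), dtype=float)
        if vec.shape != (len(PARAM_FIELDS),):
            raise ValueError(f"expected {len(PARAM_FIELDS)} parameters, got {vec.shape}")
        return cls(**dict(zip(PARAM_FIELDS, vec.tolist())))

    @classmethod
    def from_display(cls, mapping: dict) -> "GenotypeParams":
        """Build from a dict of printed (display-scale) values.

        Published tables multiply ``a_mu1`` by 1e4, ``b_mu1`` by 1e5 and
        ``b_Y`` by 1e3; this converter undoes that so internal computation is
        always on the natural scale.
        """
        vals = {}
        for f in PARAM_FIELDS:
            v = float(mapping[f])
            vals[f] = v * DISPLAY_SCALE.get(f, 1.0)
        return cls(**vals)

    def to_display(self) -> dict:
        return {
            f: getattr(self, f) / DISPLAY_SCALE.get(f, 1.0) for f in PARAM_FIELDS
        }

    def replace(self, **kwargs) -> "GenotypeParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ModelParams:
    """Both genotype strata plus the mixing probability P(G=1) = p1.

    ``noncarrier`` is the G = 1 stratum and ``carrier`` the G = 0 stratum,
    following the coding in which G = 1 marks absence of the risk allele.
    """

    noncarrier: GenotypeParams
    carrier: GenotypeParams
    p1: float

    def validate(self, strict_p1: bool = True, **kwargs) -> "ModelParams":
        if strict_p1 and not (0.0 < self.p1 < 1.0):
            raise ValueError(f"p1 must lie strictly in (0, 1), got {self.p1}")
        if not (0.0 < self.p1 <= 1.0):
            raise ValueError(f"p1 must lie in (0, 1], got {self.p1}")
        self.noncarrier.validate(**kwargs)
        self.carrier.validate(**kwargs)
        return self

    def for_genotype(self, g: int) -> GenotypeParams:
        if g == 1:
            return self.noncarrier
        if g == 0:
            return self.carrier
        raise ValueError(f"genotype must be 0 (carrier) or 1 (noncarrier), got {g}")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# parametric components
# ---------------------------------------------------------------------------

def feedback(t, gp: GenotypeParams):
    """Negative feedback coefficient a(t) = a_Y + b_Y t (1/year).

    Its absolute value is the adaptive capacity; b_Y > 0 means the capacity
    declines with age.
    """
    return gp.a_Y + gp.b_Y * np.asarray(t, dtype=float)


def allostatic_mean(t, gp: GenotypeParams):
    """Mean allostatic trajectory f1(t) = a_f1 + b_f1 t + c_f1 t^2."""
    t = np.asarray(t, dtype=float)
    return gp.a_f1 + t * (gp.b_f1 + t * gp.c_f1)


def mu1(t, gp: GenotypeParams):
    """U-shape sensitivity mu1(t) = max(0, a_mu1 + b_mu1 t).

    The linear form is clamped at zero so the nonnegativity of the quadratic
    hazard term holds at every age even for parameter sets whose fitted line
    goes negative at some ages.
    """
    t = np.asarray(t, dtype=float)
    return np.maximum(gp.a_mu1 + gp.b_mu1 * t, 0.0)


def gompertz(t, gp: GenotypeParams):
    """Unfrailty Gompertz hazard mu0^0(t) = a e^{b t}, a = exp(ln_a_mu0)."""
    t = np.asarray(t, dtype=float)
    return np.exp(gp.ln_a_mu0 + gp.b_mu0 * t)


def gompertz_cumulative(t, gp: GenotypeParams):
    """Integral of the Gompertz hazard from age 0 to t (closed form)."""
    t = np.asarray(t, dtype=float)
    a = np.exp(gp.ln_a_mu0)
    b = gp.b_mu0
    if abs(b) > 1e-12:
        return a * np.expm1(b * t) / b
    return a * t


def baseline_hazard(t, gp: GenotypeParams):
    """Gamma-Gompertz (logistic) baseline hazard.

    mu0(t) = a e^{bt} / (1 + sigma2^2 * integral_0^t a e^{bu} du).  For
    sigma2 = 0 this is the plain Gompertz curve; sigma2 > 0 produces
    deceleration of the hazard at the oldest ages.
    """
    denom = 1.0 + gp.sigma2**2 * gompertz_cumulative(t, gp)
    if np.any(denom <= 0):
        raise ValueError("invalid gamma-Gompertz parameters: nonpositive denominator")
    return gompertz(t, gp) / denom


@dataclass(frozen=True)
class OptimalTrajectory:
    """Cubic "optimal" trajectory f(t) minimizing mortality risk.

    Operationally a cubic polynomial fitted to 5-year-bin average
    trajectories of long-lived individuals.  The cubic is trusted only on
    ``age_domain`` (the fitted bin-midpoint range); outside it evaluation
    clamps to the boundary value, because cubics diverge quickly beyond the
    data.
    """

    coeffs: tuple  # ascending powers: (c0, c1, c2, c3)
    age_domain: tuple = (42.5, 92.5)

    def __post_init__(self):
        if len(self.coeffs) != 4:
            raise ValueError("OptimalTrajectory needs exactly 4 cubic coefficients")
        if not self.age_domain[0] < self.age_domain[1]:
            raise ValueError("age_domain must be an increasing interval")

    def __call__(self, t):
        tc = np.clip(np.asarray(t, dtype=float), self.age_domain[0], self.age_domain[1])
        c0, c1, c2, c3 = self.coeffs
        return c0 + tc * (c1 + tc * (c2 + tc * c3))

    @classmethod
    def from_allostatic(cls, gp: GenotypeParams, age_domain=(42.5, 92.5)) -> "OptimalTrajectory":
        """Degenerate cubic equal to the quadratic allostatic mean f1.

        Used as the default risk-minimizing trajectory for simulation designs
        where no empirically fitted trajectory is supplied.
        """
        return cls((gp.a_f1, gp.b_f1, gp.c_f1, 0.0), tuple(age_domain))


@dataclass(frozen=True)
class TrajectoryPair:
    """Optimal trajectories for the two genotype strata."""

    noncarrier: OptimalTrajectory
    carrier: OptimalTrajectory

    def for_genotype(self, g: int) -> OptimalTrajectory:
        if g == 1:
            return self.noncarrier
        if g == 0:
            return self.carrier
        raise ValueError(f"genotype must be 0 or 1, got {g}")

    @classmethod
    def from_params(cls, params: ModelParams, age_domain=(42.5, 92.5)) -> "TrajectoryPair":
        return cls(
            OptimalTrajectory.from_allostatic(params.noncarrier, age_domain),
            OptimalTrajectory.from_allostatic(params.carrier, age_domain),
        )


def hazard(t, y, gp: GenotypeParams, f: OptimalTrajectory):
    """Total mortality rate mu(t, y) = mu0(t) + (y - f(t))^2 mu1(t)."""
    y = np.asarray(y, dtype=float)
    dev = y - f(t)
    return baseline_hazard(t, gp) + dev * dev * mu1(t, gp)
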