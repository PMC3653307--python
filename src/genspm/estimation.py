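"""Maximum-likelihood estimation of the joint model.

Optimization runs on a transformed scale: log for the standard deviations
sigma0 and sigma1, a softplus map with a floor at zero for the frailty
parameter sigma2 (boundary maximum-likelihood estimates at sigma2 = 0 are
expected and must not crash), logit for the mixing probability p1, identity
for everything else.  On top of the transform the optimizer rescales each
coordinate by a characteristic magnitude so the numerically differentiated
L-BFGS-B search is well conditioned despite parameters spanning ten orders
of magnitude.

The same machinery supports fixing parameters at given values (profiling,
calibration studies) and tying carrier parameters to noncarrier ones
(restricted fits for likelihood-ratio tests).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .likelihood import _as_packed, total_loglik, total_loglik_single
from .model import (
    PARAM_FIELDS,
    GenotypeParams,
    ModelParams,
    OptimalTrajectory,
    TrajectoryPair,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "transform_params",
    "untransform_params",
    "transform_genotype",
    "untransform_genotype",
    "fit",
    "fit_single",
    "profile_loglik",
    "moment_init",
]

SIGMA2_FLOOR = 1e-12

_LOG_FIELDS = {"sigma0", "sigma1"}
_SOFTPLUS_FIELDS = {"sigma2"}

#: transformed-scale box constraints per field
_BOUNDS = {
    "ln_a_mu0": (-30.0, 3.0),
    "b_mu0": (-0.5, 0.5),
    "sigma2": (-40.0, 5.0),
    "a_mu1": (-0.05, 0.05),
    "b_mu1": (-0.005, 0.005),
    "a_Y": (-1.9, -1e-5),
    "b_Y": (0.0, 0.02),
    "a_f1": (-1e4, 1e4),
    "b_f1": (-100.0, 100.0),
    "c_f1": (-5.0, 5.0),
    "sigma0": (-12.0, 12.0),
    "sigma1": (-12.0, 12.0),
    "p1": (-12.0, 12.0),
}

#: characteristic magnitudes for optimizer conditioning (z = x / scale)
_SCALES = {
    "ln_a_mu0": 1.0,
    "b_mu0": 0.02,
    "sigma2": 2.0,
    "a_mu1": 1e-4,
    "b_mu1": 1e-5,
    "a_Y": 0.02,
    "b_Y": 2e-4,
    "a_f1": 20.0,
    "b_f1": 0.5,
    "c_f1": 0.01,
    "sigma0": 0.1,
    "sigma1": 0.1,
    "p1": 0.5,
}


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-y))


def _transform_field(name: str, value: float) -> float:
    if name in _LOG_FIELDS:
        if value <= 0:
            raise ValueError(f"{name} must be positive to transform, got {value}")
        return float(np.log(value))
    if name in _SOFTPLUS_FIELDS:
        return float(_softplus_inv(max(value, SIGMA2_FLOOR)))
    if name == "p1":
        if not 0.0 < value < 1.0:
            raise ValueError(f"p1 must be interior to (0, 1) to transform, got {value}")
        return float(np.log(value) - np.log1p(-value))
    return float(value)


def _untransform_field(name: str, x: float) -> float:
    if name in _LOG_FIELDS:
        return float(np.exp(x))
    if name in _SOFTPLUS_FIELDS:
        return float(_softplus(x))
    if name == "p1":
        return float(1.0 / (1.0 + np.exp(-x)))
    return float(x)


def transform_genotype(gp: GenotypeParams) -> np.ndarray:
    return np.array([_transform_field(f, getattr(gp, f)) for f in PARAM_FIELDS])


def untransform_genotype(vec) -> GenotypeParams:
    vec = np.asarray(vec, dtype=float)
    return GenotypeParams(
        **{f: _untransform_field(f, v) for f, v in zip(PARAM_FIELDS, vec)}
    )


def transform_params(params: ModelParams) -> np.ndarray:
    """25-vector: 12 noncarrier, 12 carrier, logit p1 (bijective round trip)."""
    return np.concatenate(
        [
            transform_genotype(params.noncarrier),
            transform_genotype(params.carrier),
            [_transform_field("p1", params.p1)],
        ]
    )


def untransform_params(vec) -> ModelParams:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (25,):
        raise ValueError(f"expected a 25-vector, got shape {vec.shape}")
    return ModelParams(
        noncarrier=untransform_genotype(vec[:12]),
        carrier=untransform_genotype(vec[12:24]),
        p1=_untransform_field("p1", vec[24]),
    )


# ---------------------------------------------------------------------------
# free-parameter bookkeeping
# ---------------------------------------------------------------------------

def _joint_names():
    return (
        [f"noncarrier.{f}" for f in PARAM_FIELDS]
        + [f"carrier.{f}" for f in PARAM_FIELDS]
        + ["p1"]
    )


def _field_of(name: str) -> str:
    return name.split(".")[-1]


class _ParamSpace:
    """Maps the optimizer's free vector to the full transformed vector."""

    def __init__(self, names, fixed=None, ties=None):
        self.names = list(names)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.fixed = dict(fixed or {})  # index -> transformed value
        self.ties = dict(ties or {})  # target index -> source index
        bad = set(self.fixed) & set(self.ties)
        if bad:
            raise ValueError(f"parameters both fixed and tied: {sorted(bad)}")
        self.free_idx = [
            i for i in range(len(self.names)) if i not in self.fixed and i not in self.ties
        ]
        self.scales = np.array([_SCALES[_field_of(self.names[i])] for i in self.free_idx])
        self.bounds = [
            tuple(np.array(_BOUNDS[_field_of(self.names[i])]) / _SCALES[_field_of(self.names[i])])
            for i in self.free_idx
        ]

    @property
    def n_free(self) -> int:
        return len(self.free_idx)

    def expand(self, z) -> np.ndarray:
        x = np.empty(len(self.names))
        x[self.free_idx] = np.asarray(z) * self.scales
        for i, v in self.fixed.items():
            x[i] = v
        for tgt, src in self.ties.items():
            x[tgt] = x[src]
        return x

    def reduce(self, x_full) -> np.ndarray:
        x_full = np.asarray(x_full, dtype=float)
        z = x_full[self.free_idx] / self.scales
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(z, lo, hi)


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 1
    jitter: float = 0.5  # SD of start perturbations in scaled units
    maxiter: int = 400
    ftol: float = 1e-10
    eps: float = 1e-6  # finite-difference step in scaled units
    seed: int = 0

    def replace(self, **kwargs) -> "FitOptions":
        return replace(self, **kwargs)


@dataclass
class FitResult:
    params: object  # ModelParams (joint fit) or GenotypeParams (single stratum)
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    starts: list
    seed: int
    boundary: list


_BIG = 1e15


def _maximize(space: _ParamSpace, negll_full, x0_full, options: FitOptions):
    rng = np.random.default_rng(options.seed)

    def fun(z):
        try:
            val = negll_full(space.expand(z))
        except (ValueError, FloatingPointError, OverflowError):
            return _BIG
        if not np.isfinite(val):
            return _BIG
        return val

    z0 = space.reduce(x0_full)
    f0 = fun(z0)
    if not np.isfinite(f0) or f0 >= _BIG:
        raise ValueError("non-finite likelihood at the initial parameters")
    if z0.size == 0:  # fully constrained: nothing to optimize
        from types import SimpleNamespace

        res = SimpleNamespace(x=z0, fun=f0, success=True, nit=0, jac=None,
                              status=0, message="fully constrained")
        return res, [{"start": 0, "loglik": -f0, "nit": 0, "status": 0,
                      "message": "fully constrained"}]
    starts, results = [], []
    for s in range(options.n_starts):
        z_start = z0 if s == 0 else np.clip(
            z0 + options.jitter * rng.standard_normal(z0.shape),
            [b[0] for b in space.bounds],
            [b[1] for b in space.bounds],
        )
        res = minimize(
            fun,
            z_start,
            method="L-BFGS-B",
            bounds=space.bounds,
            options={
                "maxiter": options.maxiter,
                "ftol": options.ftol,
                "eps": options.eps,
            },
        )
        results.append(res)
        starts.append(
            {"start": s, "loglik": -float(res.fun), "nit": int(res.nit),
             "status": int(res.status), "message": str(res.message)}
        )
    best = min(results, key=lambda r: r.fun)
    return best, starts


def _boundary_hits(space: _ParamSpace, z_opt, params) -> list:
    hits = []
    lo = np.array([b[0] for b in space.bounds])
    hi = np.array([b[1] for b in space.bounds])
    for k, i in enumerate(space.free_idx):
        name = space.names[i]
        if z_opt[k] - lo[k] < 1e-6 or hi[k] - z_opt[k] < 1e-6:
            hits.append(name)
        elif _field_of(name) == "sigma2":
            gp = getattr(params, name.split(".")[0]) if "." in name else params
            if gp.sigma2 < 1e-6:
                hits.append(name)
    return hits


def _prepare_fixed(fixed, names):
    out = {}
    index = {n: i for i, n in enumerate(names)}
    for name, val in (fixed or {}).items():
        if name not in index:
            raise KeyError(f"unknown parameter {name!r}")
        out[index[name]] = _transform_field(_field_of(name), float(val))
    return out


def fit_single(
    data,
    f: OptimalTrajectory,
    init: GenotypeParams,
    options: FitOptions | None = None,
    fixed: dict | None = None,
    censor_lag: float = 2.0,
) -> FitResult:
    """Maximize the one-stratum likelihood over the 12 genotype parameters.

    ``fixed`` maps field names (e.g. ``"sigma2"``) to natural-scale values
    held constant during optimization.
    """
    options = options or FitOptions()
    pc = _as_packed(data, censor_lag)
    space = _ParamSpace(PARAM_FIELDS, fixed=_prepare_fixed(fixed, PARAM_FIELDS))

    def negll(x_full):
        return -total_loglik_single(pc, untransform_genotype(x_full), f)

    best, starts = _maximize(space, negll, transform_genotype(init), options)
    x_opt = space.expand(best.x)
    params = untransform_genotype(x_opt)
    return FitResult(
        params=params,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_iter=int(best.nit),
        grad_norm=float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan,
        starts=starts,
        seed=options.seed,
        boundary=_boundary_hits(space, best.x, params),
    )


def fit(
    data,
    f_pair: TrajectoryPair,
    init: ModelParams,
    options: FitOptions | None = None,
    fixed: dict | None = None,
    restriction=None,
    censor_lag: float = 2.0,
) -> FitResult:
    """Maximize the joint 25-parameter likelihood (both strata plus p1).

    ``fixed`` maps names like ``"carrier.sigma2"`` or ``"p1"`` to values;
    ``restriction`` (from :mod:`genspm.hypotheses`) ties carrier parameters
    to noncarrier ones and/or zeroes parameters for nested-model fits.
    """
    options = options or FitOptions()
    pc = _as_packed(data, censor_lag)
    names = _joint_names()
    index = {n: i for i, n in enumerate(names)}
    fixed_t = _prepare_fixed(fixed, names)
    ties = {}
    if restriction is not None:
        for f_name in restriction.ties:
            ties[index[f"carrier.{f_name}"]] = index[f"noncarrier.{f_name}"]
        for stratum, f_name in restriction.zeros:
            fixed_t[index[f"{stratum}.{f_name}"]] = _transform_field(f_name, 0.0)
    space = _ParamSpace(names, fixed=fixed_t, ties=ties)

    def negll(x_full):
        return -total_loglik(pc, untransform_params(x_full), f_pair)

    best, starts = _maximize(space, negll, transform_params(init), options)
    params = untransform_params(space.expand(best.x))
    return FitResult(
        params=params,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_iter=int(best.nit),
        grad_norm=float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan,
        starts=starts,
        seed=options.seed,
        boundary=_boundary_hits(space, best.x, params),
    )


def profile_loglik(
    data,
    f_pair: TrajectoryPair,
    params: ModelParams,
    name: str,
    grid,
    options: FitOptions | None = None,
    fixed: dict | None = None,
    censor_lag: float = 2.0,
):
    """Profile curve: likelihood maximized over all other free parameters.

    Returns ``(grid, logliks)`` as arrays; the curve peaks at the
    unconstrained MLE of the profiled parameter.
    """
    grid = np.asarray(grid, dtype=float)
    lls = np.empty(grid.shape)
    for i, val in enumerate(grid):
        all_fixed = dict(fixed or {})
        all_fixed[name] = float(val)
        res = fit(data, f_pair, params, options=options, fixed=all_fixed,
                  censor_lag=censor_lag)
        lls[i] = res.loglik
    return grid, lls


# ---------------------------------------------------------------------------
# method-of-moments initialization
# ---------------------------------------------------------------------------

def _gompertz_mle(entry, exit_age, death):
    """Two-parameter Gompertz fit to (left-truncated) survival data."""
    entry = np.asarray(entry, dtype=float)
    exit_age = np.asarray(exit_age, dtype=float)
    death = np.asarray(death, dtype=bool)

    def nll(v):
        lna, b = v
        if abs(b) < 1e-8:
            b = 1e-8
        cum = (np.exp(lna) / b) * (np.exp(b * exit_age) - np.exp(b * entry))
        ll = np.sum(death * (lna + b * exit_age)) - np.sum(cum)
        return -ll

    res = minimize(nll, np.array([-9.0, 0.08]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    return float(res.x[0]), float(res.x[1])


def moment_init(records, censor_lag: float = 2.0) -> ModelParams:
    """Cheap data-driven starting values for the full model.

    The allostatic trajectory comes from a pooled quadratic fit; sigma0 from
    the spread of first measurements around it; the feedback intercept from
    a lag regression of increments on deviations; sigma1 from the residual
    increment variance; the baseline hazard from a plain Gompertz survival
    fit; the mixing probability from the genotyped fraction.  Both strata
    start from the same values.
    """
    records = list(records)
    if not records:
        raise ValueError("empty dataset")
    ages = np.concatenate([r.ages for r in records])
    values = np.concatenate([r.values for r in records])
    c2, c1, c0 = np.polyfit(ages, values, 2)

    def f1(t):
        return c0 + t * (c1 + t * c2)

    first_resid = np.array([r.values[0] - f1(r.ages[0]) for r in records])
    sigma0 = max(float(np.std(first_resid)), 1e-3)

    pair_dt, pair_dy, pair_d = [], [], []
    for r in records:
        if r.n_measurements < 2:
            continue
        pair_dt.append(np.diff(r.ages))
        pair_dy.append(np.diff(r.values))
        pair_d.append(r.values[:-1] - f1(r.ages[:-1]))
    if pair_dt:
        dt = np.concatenate(pair_dt)
        dy = np.concatenate(pair_dy)
        d = np.concatenate(pair_d)
        den = float(np.sum((d * dt) ** 2))
        a_hat = float(np.clip(np.sum(dy * d * dt) / den if den else -0.1, -0.9, -0.01))
        resid_sq = (dy - a_hat * d * dt) ** 2 / dt
        sigma1 = max(float(np.sqrt(np.mean(resid_sq))), 1e-3)
    else:
        a_hat, sigma1 = -0.1, sigma0 / 4.0

    entry = np.array([r.ages[0] for r in records])
    exit_age = np.array([r.event_age for r in records])
    death = np.array([r.event for r in records])
    ln_a, b = _gompertz_mle(entry, exit_age, death)

    gp = GenotypeParams(
        ln_a_mu0=ln_a,
        b_mu0=b,
        sigma2=1e-6,
        a_mu1=0.0,
        b_mu1=0.0,
        a_Y=a_hat,
        b_Y=1e-5,
        a_f1=float(c0),
        b_f1=float(c1),
        c_f1=float(c2),
        sigma0=sigma0,
        sigma1=sigma1,
    )
    genotyped = [r.genotype for r in records if r.genotype is not None]
    p1 = float(np.mean([g == 1 for g in genotyped])) if genotyped else 0.5
    p1 = float(np.clip(p1, 0.05, 0.95))
    return ModelParams(noncarrier=gp, carrier=gp, p1=p1)
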