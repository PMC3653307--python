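"""Joint log-likelihood of trajectories and survival.

For a subject with known genotype the likelihood factorizes into three
blocks mirroring the generative law exactly:

(i)   an initial Gaussian term: the first measurement is distributed
      N(f1(t_first), sigma0^2);
(ii)  Gaussian transition terms between consecutive *measurement* occasions,
      obtained by composing the one-year autoregression
      m(t+1) = m(t) + a(t) (m(t) - f1(t)),  v(t+1) = (1 + a(t))^2 v(t) + sigma1^2
      across the inter-measurement gap (interpolated points carry no density
      of their own: they are deterministic functions of the measurements);
(iii) survival terms on the annual grid: each survived year [t, t+1)
      contributes -mu(t, Yhat(t)) with the interpolated trajectory Yhat, and
      an observed death contributes log(1 - exp(-mu)) on its final year.

Subjects with known genotype additionally contribute the Bernoulli genotype
factor log p1 (noncarrier) or log(1 - p1) (carrier), which is what makes p1
identifiable from both subsamples.  Subjects without genotype contribute the
p1-weighted mixture of the two genotype-specific likelihoods, evaluated on
the log scale with no underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    GenotypeParams,
    ModelParams,
    OptimalTrajectory,
    TrajectoryPair,
    allostatic_mean,
    feedback,
    hazard,
)
from .records import IndividualRecord
from .trajectories import interpolate_annual

__all__ = [
    "PackedCohort",
    "pack",
    "loglik_given_g",
    "loglik_marginal",
    "total_loglik",
    "total_loglik_single",
    "record_breakdown",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def _log_weights(p1: float):
    """log p1 and log(1 - p1), tolerating the degenerate mixtures p1 = 0, 1."""
    with np.errstate(divide="ignore"):
        return float(np.log(p1)) if p1 > 0 else -np.inf, float(np.log1p(-p1)) if p1 < 1 else -np.inf


@dataclass
class PackedCohort:
    """Flat-array view of a dataset for fast repeated likelihood evaluation."""

    n: int
    ids: list
    genotype: np.ndarray  # int8; -1 = unknown
    init_t: np.ndarray
    init_y: np.ndarray
    pair_rec: np.ndarray
    pair_t0: np.ndarray
    pair_y0: np.ndarray
    pair_y1: np.ndarray
    pair_gap: np.ndarray
    max_gap: int
    py_rec: np.ndarray
    py_t: np.ndarray
    py_y: np.ndarray
    term_rec: np.ndarray
    term_t: np.ndarray
    term_y: np.ndarray
    term_death: np.ndarray


def pack(records, censor_lag: float = 2.0) -> PackedCohort:
    """Validate, interpolate and flatten records into a PackedCohort.

    Measurement ages are rounded to the nearest integer year for the annual
    transition composition (exam schedules are annual-grid based; sub-year
    offsets are not modeled).
    """
    records = list(records)
    if not records:
        raise ValueError("empty dataset")
    failures = []
    ids, genos = [], []
    init_t, init_y = [], []
    pr, pt0, py0, py1, pg = [], [], [], [], []
    hr, ht, hy = [], [], []
    tr, tt, ty, td = [], [], [], []
    for r, rec in enumerate(records):
        try:
            rec.validate(censor_lag=censor_lag)
            ann = interpolate_annual(rec, censor_lag=censor_lag)
        except ValueError as e:
            failures.append(str(e))
            continue
        r_idx = len(ids)
        ids.append(rec.id)
        genos.append(-1 if rec.genotype is None else int(rec.genotype))
        m_ages = np.round(rec.ages).astype(int)
        if np.any(np.diff(m_ages) <= 0):
            failures.append(f"record {rec.id}: measurements closer than one year")
            ids.pop(), genos.pop()
            continue
        init_t.append(m_ages[0])
        init_y.append(rec.values[0])
        for j in range(len(m_ages) - 1):
            pr.append(r_idx)
            pt0.append(m_ages[j])
            py0.append(rec.values[j])
            py1.append(rec.values[j + 1])
            pg.append(m_ages[j + 1] - m_ages[j])
        # annual hazard grid: intervals [t, t+1) from entry to the event
        t_entry = int(ann.ages[0])
        t_final = int(np.ceil(rec.event_age - 1e-9)) - 1  # last interval start
        if t_final >= t_entry:
            lut = dict(zip(ann.ages.tolist(), ann.values.tolist()))
            for t in range(t_entry, t_final):
                hr.append(r_idx)
                ht.append(t)
                hy.append(lut.get(t, rec.values[-1]))
            tr.append(r_idx)
            tt.append(t_final)
            ty.append(lut.get(t_final, rec.values[-1]))
            td.append(bool(rec.event))
    if failures:
        raise ValueError(
            f"{len(failures)} invalid record(s):\n" + "\n".join(failures[:10])
        )
    pg = np.asarray(pg, dtype=int)
    return PackedCohort(
        n=len(ids),
        ids=ids,
        genotype=np.asarray(genos, dtype=np.int8),
        init_t=np.asarray(init_t, dtype=float),
        init_y=np.asarray(init_y, dtype=float),
        pair_rec=np.asarray(pr, dtype=int),
        pair_t0=np.asarray(pt0, dtype=float),
        pair_y0=np.asarray(py0, dtype=float),
        pair_y1=np.asarray(py1, dtype=float),
        pair_gap=pg,
        max_gap=int(pg.max()) if pg.size else 0,
        py_rec=np.asarray(hr, dtype=int),
        py_t=np.asarray(ht, dtype=float),
        py_y=np.asarray(hy, dtype=float),
        term_rec=np.asarray(tr, dtype=int),
        term_t=np.asarray(tt, dtype=float),
        term_y=np.asarray(ty, dtype=float),
        term_death=np.asarray(td, dtype=bool),
    )


def _as_packed(data, censor_lag: float = 2.0) -> PackedCohort:
    if isinstance(data, PackedCohort):
        return data
    return pack(data, censor_lag=censor_lag)


def loglik_vector(pc: PackedCohort, gp: GenotypeParams, f: OptimalTrajectory) -> np.ndarray:
    """Per-record log-likelihood under one genotype's parameters."""
    ll = (
        -0.5 * (_LOG2PI + 2.0 * np.log(gp.sigma0))
        - (pc.init_y - allostatic_mean(pc.init_t, gp)) ** 2 / (2.0 * gp.sigma0**2)
    )
    if pc.pair_rec.size:
        m = pc.pair_y0.copy()
        v = np.zeros_like(m)
        s1sq = gp.sigma1**2
        for k in range(pc.max_gap):
            act = pc.pair_gap > k
            t = pc.pair_t0 + k
            a = feedback(t, gp)
            m_new = m + a * (m - allostatic_mean(t, gp))
            v_new = (1.0 + a) ** 2 * v + s1sq
            m = np.where(act, m_new, m)
            v = np.where(act, v_new, v)
        ll_pairs = -0.5 * (_LOG2PI + np.log(v)) - (pc.pair_y1 - m) ** 2 / (2.0 * v)
        ll = ll + np.bincount(pc.pair_rec, weights=ll_pairs, minlength=pc.n)
    if pc.py_rec.size:
        mu = hazard(pc.py_t, pc.py_y, gp, f)
        ll = ll + np.bincount(pc.py_rec, weights=-mu, minlength=pc.n)
    if pc.term_rec.size:
        mu_t = np.maximum(hazard(pc.term_t, pc.term_y, gp, f), 1e-300)
        contrib = np.where(pc.term_death, np.log(-np.expm1(-mu_t)), -mu_t)
        ll = ll + np.bincount(pc.term_rec, weights=contrib, minlength=pc.n)
    if not np.all(np.isfinite(ll)):
        bad = [pc.ids[i] for i in np.nonzero(~np.isfinite(ll))[0][:5]]
        raise FloatingPointError(f"non-finite log-likelihood for records {bad}")
    return ll


def loglik_given_g(
    record: IndividualRecord,
    gp: GenotypeParams,
    f: OptimalTrajectory,
    censor_lag: float = 2.0,
) -> float:
    """Log-likelihood of a single record conditional on its genotype."""
    pc = pack([record], censor_lag=censor_lag)
    return float(loglik_vector(pc, gp, f)[0])


def loglik_marginal(
    record: IndividualRecord,
    params: ModelParams,
    f_pair: TrajectoryPair,
    censor_lag: float = 2.0,
) -> float:
    """Genotype-marginalized log-likelihood for a non-genotyped record.

    log( p1 exp(ll_noncarrier) + (1 - p1) exp(ll_carrier) ), evaluated via
    logaddexp so likelihoods far below exp(-700) do not underflow.
    """
    if record.genotype is not None:
        raise ValueError(f"record {record.id}: genotype is known; use loglik_given_g")
    ll1 = loglik_given_g(record, params.noncarrier, f_pair.noncarrier, censor_lag)
    ll0 = loglik_given_g(record, params.carrier, f_pair.carrier, censor_lag)
    lw1, lw0 = _log_weights(params.p1)
    return float(np.logaddexp(lw1 + ll1, lw0 + ll0))


def total_loglik(data, params: ModelParams, f_pair: TrajectoryPair | None = None,
                 censor_lag: float = 2.0) -> float:
    """Joint log-likelihood of genotyped and non-genotyped subsamples."""
    pc = _as_packed(data, censor_lag)
    if f_pair is None:
        f_pair = TrajectoryPair.from_params(params)
    ll1 = loglik_vector(pc, params.noncarrier, f_pair.noncarrier)
    ll0 = loglik_vector(pc, params.carrier, f_pair.carrier)
    g = pc.genotype
    lw1, lw0 = _log_weights(params.p1)
    total = 0.0
    n1 = int(np.sum(g == 1))
    n0 = int(np.sum(g == 0))
    if n1:
        total += ll1[g == 1].sum() + n1 * lw1
    if n0:
        total += ll0[g == 0].sum() + n0 * lw0
    unk = g == -1
    if unk.any():
        total += np.logaddexp(lw1 + ll1[unk], lw0 + ll0[unk]).sum()
    return float(total)


def total_loglik_single(data, gp: GenotypeParams, f: OptimalTrajectory,
                        censor_lag: float = 2.0) -> float:
    """Log-likelihood of a one-stratum dataset (no genotype mixing factor)."""
    pc = _as_packed(data, censor_lag)
    return float(loglik_vector(pc, gp, f).sum())


def record_breakdown(records, params: ModelParams, f_pair: TrajectoryPair | None = None,
                     censor_lag: float = 2.0) -> pd.DataFrame:
    """Per-record log-likelihood table for debugging model fits."""
    pc = pack(records, censor_lag=censor_lag)
    if f_pair is None:
        f_pair = TrajectoryPair.from_params(params)
    ll1 = loglik_vector(pc, params.noncarrier, f_pair.noncarrier)
    ll0 = loglik_vector(pc, params.carrier, f_pair.carrier)
    g = pc.genotype
    lw1, lw0 = _log_weights(params.p1)
    contrib = np.where(
        g == 1,
        ll1 + lw1,
        np.where(g == 0, ll0 + lw0, np.logaddexp(lw1 + ll1, lw0 + ll0)),
    )
    return pd.DataFrame(
        {
            "id": pc.ids,
            "genotype": g,
            "loglik_noncarrier": ll1,
            "loglik_carrier": ll0,
            "contribution": contrib,
        }
    )
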