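"""Descriptive machinery: life-span groups, binned average trajectories,
cubic "optimal" trajectories, and one-year interpolation of measurements.

The life-span grouping reproduces the convention of cohort analyses where
the sex-specific survival function reaches ~0.2 around age 90 for women and
85 for men: women split into survivors to 90+, deaths at 80-89 and deaths
before 80; men into survivors to 85+ and deaths before 85.  Censored
subjects count only toward the long-lived group (a censored age below the
threshold says nothing about eventual life span), so they receive no group
below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import OptimalTrajectory
from .records import IndividualRecord

__all__ = [
    "BIN_EDGES",
    "BIN_MIDPOINTS",
    "AnnualTrajectory",
    "assign_lifespan_group",
    "average_trajectory",
    "fit_optimal_trajectory",
    "interpolate_annual",
]

#: 5-year bins 40-44 ... 85-89 plus open-ended 90+
BIN_EDGES = np.arange(40, 95, 5)
BIN_MIDPOINTS = np.array([42.5, 47.5, 52.5, 57.5, 62.5, 67.5, 72.5, 77.5, 82.5, 87.5, 92.5])

_FEMALE_LONGLIVED = 90.0
_MALE_LONGLIVED = 85.0


def assign_lifespan_group(record: IndividualRecord, sex: str | None = None):
    """Life-span group label, or None for censored below the threshold.

    Females: ``LS90+`` (survived to 90, deaths or censored), ``LS80-89`` and
    ``LS<80`` (deaths only).  Males: ``LS85+`` and ``LS<85`` (deaths only).
    """
    sex = (sex or record.sex).upper()
    t = record.event_age
    if t is None or not np.isfinite(t):
        raise ValueError(f"record {record.id}: missing survival information")
    if sex == "F":
        if t >= _FEMALE_LONGLIVED:
            return "LS90+"
        if not record.event:
            return None
        return "LS80-89" if t >= 80.0 else "LS<80"
    if sex == "M":
        if t >= _MALE_LONGLIVED:
            return "LS85+"
        return None if not record.event else "LS<85"
    raise ValueError(f"unknown sex label {sex!r}")


def _bin_index(ages: np.ndarray) -> np.ndarray:
    """5-year bin index from exact age; ages are floored to integer years."""
    floored = np.floor(ages).astype(int)
    idx = (floored - 40) // 5
    idx[floored >= 90] = len(BIN_MIDPOINTS) - 1
    idx[floored < 40] = -1
    return idx


def average_trajectory(
    records,
    group: str,
    sex: str | None = None,
    person_level: bool = False,
) -> pd.DataFrame:
    """Per-bin mean +- SE of pooled person-exam measurements in one group.

    Returns a frame with one row per 5-year bin (``bin_mid``, ``mean``,
    ``se``, ``n``); empty bins carry n = 0 and NaN statistics, a single
    observation yields an undefined (NaN) SE.  ``person_level=True`` averages
    within person first and pools person means instead of person-exams.
    """
    ages, values = [], []
    matched = 0
    for rec in records:
        if assign_lifespan_group(rec, sex) != group:
            continue
        matched += 1
        if person_level:
            idx = _bin_index(rec.ages)
            for b in np.unique(idx[idx >= 0]):
                sel = idx == b
                ages.append(BIN_MIDPOINTS[b])
                values.append(float(np.mean(rec.values[sel])))
        else:
            ages.extend(rec.ages.tolist())
            values.extend(rec.values.tolist())
    if matched == 0:
        raise ValueError(f"no individuals in life-span group {group!r}")
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    idx = _bin_index(ages)
    rows = []
    for b, mid in enumerate(BIN_MIDPOINTS):
        sel = values[idx == b]
        n = sel.size
        mean = float(np.mean(sel)) if n else np.nan
        se = float(np.std(sel, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"bin_mid": mid, "mean": mean, "se": se, "n": int(n)})
    return pd.DataFrame(rows)


def fit_optimal_trajectory(bin_mids, means, age_domain=None):
    """Unweighted OLS cubic through (bin midpoint, bin mean) pairs.

    Returns ``(OptimalTrajectory, residuals)``.  Requires at least four
    nonempty bins, otherwise the cubic is rank deficient.
    """
    x = np.asarray(bin_mids, dtype=float)
    y = np.asarray(means, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(
            f"cubic fit needs >= 4 nonempty bins, got {x.size}"
        )
    coeffs_desc = np.polyfit(x, y, 3)
    coeffs = tuple(coeffs_desc[::-1].tolist())
    domain = tuple(age_domain) if age_domain is not None else (float(x.min()), float(x.max()))
    f = OptimalTrajectory(coeffs, domain)
    residuals = y - f(x)
    return f, residuals


@dataclass
class AnnualTrajectory:
    """A subject's measurements evaluated on a one-year age grid."""

    ages: np.ndarray  # integer ages
    values: np.ndarray


def interpolate_annual(record: IndividualRecord, censor_lag: float = 2.0) -> AnnualTrajectory:
    """Linear interpolation of measurements onto integer ages.

    Values at integer ages between the first and last measurement come from
    linear interpolation of the adjacent measurements.  Between the last
    measurement and the survival event the last observed value is carried
    forward for at most ``censor_lag`` years so hazard terms exist on the
    final intervals; the censoring rule bounds this gap by construction.
    """
    record.validate(censor_lag=censor_lag)
    t0 = int(np.ceil(record.ages[0] - 1e-9))
    t1 = int(np.floor(record.ages[-1] + 1e-9))
    if t1 < t0:  # single measurement strictly between integer ages
        t0 = t1 = int(np.round(record.ages[0]))
        base_ages = np.array([t0])
        base_vals = np.array([record.values[0]])
    else:
        base_ages = np.arange(t0, t1 + 1)
        base_vals = np.interp(base_ages, record.ages, record.values)
    # carry the last value toward the event, never beyond last + censor_lag
    t_end = int(np.ceil(record.event_age - 1e-9)) - 1
    t_end = min(t_end, int(np.floor(record.ages[-1] + censor_lag + 1e-9)))
    if t_end > base_ages[-1]:
        extra = np.arange(base_ages[-1] + 1, t_end + 1)
        base_ages = np.concatenate([base_ages, extra])
        base_vals = np.concatenate([base_vals, np.full(extra.shape, record.values[-1])])
    return AnnualTrajectory(base_ages.astype(int), base_vals)
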