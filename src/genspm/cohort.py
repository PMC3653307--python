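"""Synthetic cohort generator with the observation design of a long-running
biennial-exam longitudinal study.

The generator draws a latent annual path for each subject under the
mean-reverting dynamics, kills subjects year by year from the U-shaped
hazard, observes the variable at biennial exams (with missed exams), and
reveals genotype only for subjects who survive to a genotyping age — the
same survival-dependent missingness that arises when DNA is collected at a
late exam.  Every downstream stage of the analysis is therefore testable
against a known generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

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
from .records import IndividualRecord, genotype_label

__all__ = [
    "CohortDesign",
    "SimulatedIndividual",
    "simulate_path",
    "simulate_mortality",
    "simulate_cohort",
    "to_records",
    "cohort_to_frame",
    "truth_to_frame",
]


@dataclass(frozen=True)
class CohortDesign:
    """Observation design of the synthetic study.

    Ages are integer years.  The entry exam is always observed (subjects are
    measured on enrollment); each later scheduled exam is independently
    missed with probability ``exam_gap_prob``.  Genotype is revealed only
    for subjects whose follow-up reaches ``genotyping_age`` (thinned by
    ``genotyped_fraction``) unless ``genotype_mcar`` switches the
    missingness to completely-at-random for null testing.
    """

    n_individuals: int
    entry_age_range: tuple = (40, 50)
    exam_interval: int = 2
    exam_gap_prob: float = 0.1
    max_age: int = 110
    genotyping_age: int = 78
    genotyped_fraction: float = 0.5
    censor_lag: float = 2.0
    genotype_mcar: bool = False
    sex: str = "F"
    seed: int | None = None

    def validate(self) -> "CohortDesign":
        if self.n_individuals <= 0:
            raise ValueError("empty cohort: n_individuals must be positive")
        lo, hi = self.entry_age_range
        if not lo <= hi:
            raise ValueError("degenerate entry_age_range")
        if not (0 <= self.exam_gap_prob <= 1 and 0 <= self.genotyped_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.exam_interval < 1:
            raise ValueError("exam_interval must be >= 1 year")
        if not lo < self.max_age:
            raise ValueError("entry ages must precede max_age")
        if self.censor_lag < 0:
            raise ValueError("censor_lag must be nonnegative")
        return self

    def replace(self, **kwargs) -> "CohortDesign":
        return replace(self, **kwargs)


@dataclass
class SimulatedIndividual:
    """One simulated subject, including the latent truth."""

    id: str
    sex: str
    true_genotype: int
    genotype_observed: bool
    annual_ages: np.ndarray
    annual_path: np.ndarray
    exam_ages: np.ndarray
    exam_values: np.ndarray
    event_age: float
    event: bool  # True = observed death
    death_age: float | None  # latent death age (None = survived to max_age)


def simulate_path(gp: GenotypeParams, t0: float, t_max: float, rng) -> tuple:
    """One latent path on the annual grid t0, t0+1, ..., t_max.

    Euler discretization with a one-year step:
    Y(t0) ~ N(f1(t0), sigma0^2);
    Y(t+1) = Y(t) + a(t) (Y(t) - f1(t)) + sigma1 Z_t.
    """
    rng = np.random.default_rng(rng)
    if not t0 < t_max:
        raise ValueError("t0 must precede t_max")
    gp.validate(t_min=t0)
    ages = np.arange(int(t0), int(t_max) + 1)
    y = np.empty(ages.shape, dtype=float)
    y[0] = allostatic_mean(ages[0], gp) + gp.sigma0 * rng.standard_normal()
    for j in range(len(ages) - 1):
        t = ages[j]
        y[j + 1] = (
            y[j]
            + feedback(t, gp) * (y[j] - allostatic_mean(t, gp))
            + gp.sigma1 * rng.standard_normal()
        )
    return ages, y


def simulate_mortality(ages, path, gp: GenotypeParams, f: OptimalTrajectory, rng):
    """Draw a death age along a latent path, or None if the path is outlived.

    Death in the year [t, t+1) occurs with probability 1 - exp(-mu(t, Y(t)))
    (the rate integrated over the one-year interval); a death is recorded at
    the end of the interval, t + 1.
    """
    rng = np.random.default_rng(rng)
    ages = np.asarray(ages)
    mu = hazard(ages[:-1], np.asarray(path)[:-1], gp, f)
    p_death = -np.expm1(-mu)
    u = rng.random(p_death.shape)
    hit = u < p_death
    if not hit.any():
        return None
    return float(ages[:-1][hit.argmax()] + 1)


def _split_by_genotype(G, arr1, arr0):
    """Elementwise choice between the two genotype strata."""
    return np.where(G == 1, arr1, arr0)


def simulate_cohort(
    design: CohortDesign,
    params: ModelParams,
    f_pair: TrajectoryPair | None = None,
    rng=None,
    fixed_genotype: int | None = None,
) -> list:
    """Simulate a full cohort under the generative model and study design.

    Fully vectorized over subjects; bit-reproducible for a fixed
    ``design.seed`` (or an explicitly passed generator).  With
    ``fixed_genotype`` the Bernoulli(p1) genotype draw is bypassed, which is
    how single-genotype recovery cohorts are produced.
    """
    design.validate()
    params.validate(strict_p1=False)
    if f_pair is None:
        f_pair = TrajectoryPair.from_params(params)
    rng = np.random.default_rng(design.seed if rng is None else rng)

    n = design.n_individuals
    lo, hi = design.entry_age_range
    t0 = rng.integers(int(lo), int(hi) + 1, size=n)
    if fixed_genotype is not None:
        G = np.full(n, int(fixed_genotype))
    else:
        G = (rng.random(n) < params.p1).astype(int)

    grid = np.arange(int(lo), int(design.max_age) + 1)
    A = len(grid)
    z_init = rng.standard_normal(n)
    z_step = rng.standard_normal((n, A - 1))
    u_death = rng.random((n, A - 1))
    u_gap = rng.random((n, A))
    u_geno = rng.random(n)

    gp1, gp0 = params.noncarrier, params.carrier
    sigma0 = _split_by_genotype(G, gp1.sigma0, gp0.sigma0)
    sigma1 = _split_by_genotype(G, gp1.sigma1, gp0.sigma1)

    # latent paths, column by column over the common age grid
    Y = np.full((n, A), np.nan)
    entry_col = t0 - grid[0]
    f1_entry = _split_by_genotype(G, allostatic_mean(t0, gp1), allostatic_mean(t0, gp0))
    Y[np.arange(n), entry_col] = f1_entry + sigma0 * z_init
    for j in range(A - 1):
        t = grid[j]
        started = entry_col <= j
        a_t = _split_by_genotype(G, feedback(t, gp1), feedback(t, gp0))
        f1_t = _split_by_genotype(G, allostatic_mean(t, gp1), allostatic_mean(t, gp0))
        y_now = Y[:, j]
        y_next = y_now + a_t * (y_now - f1_t) + sigma1 * z_step[:, j]
        at_entry = entry_col == j + 1
        Y[:, j + 1] = np.where(started, y_next, Y[:, j + 1])
        Y[np.arange(n)[at_entry], j + 1] = (f1_entry + sigma0 * z_init)[at_entry]

    # mortality along the latent path
    mu = np.zeros((n, A - 1))
    for j in range(A - 1):
        t = grid[j]
        mu1_ = hazard(t, np.nan_to_num(Y[:, j]), gp1, f_pair.noncarrier)
        mu0_ = hazard(t, np.nan_to_num(Y[:, j]), gp0, f_pair.carrier)
        mu[:, j] = _split_by_genotype(G, mu1_, mu0_)
    p_death = -np.expm1(-mu)
    active = entry_col[:, None] <= np.arange(A - 1)[None, :]
    dies = active & (u_death < p_death)
    died = dies.any(axis=1)
    first = dies.argmax(axis=1)
    death_age = np.where(died, grid[0] + first + 1, np.nan)

    individuals = []
    width = len(str(n))
    for i in range(n):
        gp = params.for_genotype(int(G[i]))
        last_alive = int(death_age[i]) - 1 if died[i] else int(design.max_age)
        exam_sched = np.arange(int(t0[i]), last_alive + 1, design.exam_interval)
        keep = u_gap[i, exam_sched - grid[0]] >= design.exam_gap_prob
        keep[0] = True  # enrollment exam always measured
        exam_ages = exam_sched[keep]
        cols = exam_ages - grid[0]
        exam_values = Y[i, cols]
        last_exam = float(exam_ages[-1])

        if died[i] and death_age[i] - last_exam <= design.censor_lag + 1e-9:
            event, event_age = True, float(death_age[i])
        elif died[i]:
            # death too long after the last observation: censor at
            # last observation + censor_lag, per the two-year rule
            event, event_age = False, last_exam + design.censor_lag
        else:
            event = False
            event_age = min(last_exam + design.censor_lag, float(design.max_age))

        if design.genotype_mcar:
            observed = bool(u_geno[i] < design.genotyped_fraction)
        else:
            observed = bool(
                event_age >= design.genotyping_age
                and u_geno[i] < design.genotyped_fraction
            )

        path_end = int(death_age[i]) if died[i] else int(design.max_age)
        sl = slice(entry_col[i], path_end - grid[0] + 1)
        individuals.append(
            SimulatedIndividual(
                id=f"S{i:0{width}d}",
                sex=design.sex,
                true_genotype=int(G[i]),
                genotype_observed=observed,
                annual_ages=grid[sl].copy(),
                annual_path=Y[i, sl].copy(),
                exam_ages=exam_ages.astype(float),
                exam_values=exam_values.copy(),
                event_age=float(event_age),
                event=event,
                death_age=float(death_age[i]) if died[i] else None,
            )
        )
    return individuals


def to_records(individuals) -> list:
    """Observable view of a simulated cohort (drops the latent truth)."""
    out = []
    for ind in individuals:
        out.append(
            IndividualRecord(
                id=ind.id,
                sex=ind.sex,
                genotype=ind.true_genotype if ind.genotype_observed else None,
                ages=ind.exam_ages,
                values=ind.exam_values,
                event_age=ind.event_age,
                event=ind.event,
            )
        )
    return out


def cohort_to_frame(individuals) -> pd.DataFrame:
    """Long-format person-exam table (the on-disk exchange format)."""
    rows = []
    for ind in individuals:
        label = genotype_label(ind.true_genotype) if ind.genotype_observed else "unknown"
        for age, val in zip(ind.exam_ages, ind.exam_values):
            rows.append(
                {
                    "id": ind.id,
                    "sex": ind.sex,
                    "genotype": label,
                    "exam_age": float(age),
                    "value": float(val),
                    "event_age": ind.event_age,
                    "event": int(ind.event),
                }
            )
    return pd.DataFrame(rows)


def truth_to_frame(individuals) -> pd.DataFrame:
    """Truth sidecar: latent annual paths and true genotypes."""
    rows = []
    for ind in individuals:
        for age, val in zip(ind.annual_ages, ind.annual_path):
            rows.append(
                {
                    "id": ind.id,
                    "true_genotype": genotype_label(ind.true_genotype),
                    "genotype_observed": int(ind.genotype_observed),
                    "age": int(age),
                    "latent_value": float(val),
                    "death_age": np.nan if ind.death_age is None else ind.death_age,
                }
            )
    return pd.DataFrame(rows)
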