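"""Simulation studies: parameter-recovery experiments and likelihood-ratio
type-I-error calibration.

These are the package's own validation experiments: cohorts are generated
from the bundled reference parameter sets (or a designed calibration set),
refitted by maximum likelihood, and the estimates compared with the
generative truth.  Warm-starting at the truth keeps runtimes bounded; the
optimizer still moves to the data's own maximum, so recovered values carry
the full sampling variability of the estimator.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2

from .cohort import CohortDesign, simulate_cohort, to_records
from .config import reference_params
from .estimation import FitOptions, FitResult, fit, fit_single
from .hypotheses import build_restriction
from .likelihood import pack
from .model import GenotypeParams, ModelParams, OptimalTrajectory, TrajectoryPair

__all__ = [
    "recovery_design",
    "single_genotype_recovery",
    "replicate_estimates_single",
    "mixed_recovery",
    "replicate_p1_estimates",
    "calibration_null_params",
    "lrt_size",
]


def recovery_design(n: int, seed: int, sex: str = "F", **overrides) -> CohortDesign:
    """Standard recovery-study design: entry 40-50, biennial exams, max 110."""
    kwargs = dict(
        n_individuals=n,
        entry_age_range=(40, 50),
        exam_interval=2,
        exam_gap_prob=0.1,
        max_age=110,
        genotyping_age=78,
        genotyped_fraction=0.5,
        sex=sex,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


def _spawn_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % 2**31)


def single_genotype_recovery(
    variable: str,
    sex: str,
    n: int,
    seed: int,
    options: FitOptions | None = None,
) -> FitResult:
    """Simulate a noncarrier-only cohort from the reference set and refit.

    The 12 genotype parameters are estimated jointly; the optimal trajectory
    is held fixed at the generative one (it is an input of the model, fitted
    separately from long-lived averages in real analyses).
    """
    truth = reference_params(variable, sex)
    gp = truth.noncarrier
    f = OptimalTrajectory.from_allostatic(gp)
    design = recovery_design(n, seed, sex)
    individuals = simulate_cohort(
        design, truth, TrajectoryPair(f, f), fixed_genotype=1
    )
    pc = pack(to_records(individuals), censor_lag=design.censor_lag)
    options = options or FitOptions(maxiter=600)
    return fit_single(pc, f, gp, options=options)


def replicate_estimates_single(
    variable: str,
    sex: str,
    n_reps: int,
    n: int,
    seed: int,
    options: FitOptions | None = None,
) -> dict:
    """Replicate single-genotype fits on independent seeds.

    Returns ``{field: array of estimates}`` across replicates, the raw
    material for replicate standard errors.
    """
    from .model import PARAM_FIELDS

    estimates = {f: [] for f in PARAM_FIELDS}
    for r in range(n_reps):
        res = single_genotype_recovery(
            variable, sex, n, _spawn_seed(seed, 1, r), options=options
        )
        for f in PARAM_FIELDS:
            estimates[f].append(getattr(res.params, f))
    return {f: np.asarray(v) for f, v in estimates.items()}


def mixed_recovery(
    variable: str,
    sex: str,
    n: int,
    seed: int,
    options: FitOptions | None = None,
) -> FitResult:
    """Mixed-genotype cohort with survival-dependent genotyping; joint fit.

    Genotype is revealed only for survivors to the genotyping age (thinned
    50%), so the naive carrier fraction among genotyped subjects is biased
    by differential survival; the joint likelihood corrects for this and the
    p1 estimate should recover the generative mixing probability.
    """
    truth = reference_params(variable, sex)
    f_pair = TrajectoryPair.from_params(truth)
    design = recovery_design(n, seed, sex)
    individuals = simulate_cohort(design, truth, f_pair)
    pc = pack(to_records(individuals), censor_lag=design.censor_lag)
    options = options or FitOptions(maxiter=600)
    return fit(pc, f_pair, truth, options=options)


def replicate_p1_estimates(
    variable: str,
    sex: str,
    n_reps: int,
    n: int,
    seed: int,
    options: FitOptions | None = None,
) -> np.ndarray:
    out = []
    for r in range(n_reps):
        res = mixed_recovery(variable, sex, n, _spawn_seed(seed, 2, r), options=options)
        out.append(res.params.p1)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# likelihood-ratio calibration
# ---------------------------------------------------------------------------

def calibration_null_params(hypothesis: str) -> ModelParams:
    """Generative truth for type-I-error studies, with the null imposed.

    A designed interior, identifiable parameter point (not one of the
    reference sets): strong gamma heterogeneity so sigma2 is identified from
    old-age mortality deceleration, feedback decline well inside the b_Y >= 0
    boundary, and low enough mortality that follow-up reaches old ages.
    """
    noncarrier = GenotypeParams(
        ln_a_mu0=-9.0, b_mu0=0.11, sigma2=1.2,
        a_mu1=-3e-5, b_mu1=1.2e-6,
        a_Y=-0.28, b_Y=2.0e-3,
        a_f1=80.0, b_f1=0.35, c_f1=-0.004,
        sigma0=9.0, sigma1=5.0,
    )
    carrier = GenotypeParams(
        ln_a_mu0=-8.6, b_mu0=0.10, sigma2=1.0,
        a_mu1=-2e-5, b_mu1=1.0e-6,
        a_Y=-0.22, b_Y=1.5e-3,
        a_f1=85.0, b_f1=0.30, c_f1=-0.0035,
        sigma0=10.0, sigma1=5.5,
    )
    restriction = build_restriction(hypothesis)
    if restriction.zeros:
        raise ValueError("calibration supports two-stratum tying nulls only")
    carrier = carrier.replace(
        **{f: getattr(noncarrier, f) for f in restriction.ties}
    )
    return ModelParams(noncarrier=noncarrier, carrier=carrier, p1=0.6)


_CALIB_FREE = {
    "baseline_equal": ("ln_a_mu0", "b_mu0", "sigma2"),
    "adaptive_equal": ("a_Y", "b_Y"),
    "allostatic_equal": ("a_f1", "b_f1", "c_f1"),
}


def lrt_size(
    hypothesis: str,
    n_reps: int,
    n: int = 250,
    seed: int = 0,
    alpha: float = 0.05,
    maxiter: int = 120,
) -> dict:
    """Empirical rejection rate of a tying null under data generated from it.

    Nuisance parameters are held at their generative values and only the
    tested component is free in both the general and the restricted fit
    (a classical likelihood-ratio setting with known nuisance, so the
    chi-square reference applies).  Genotype missingness is
    completely-at-random with full typing so small cohorts carry genotype
    information.
    """
    truth = calibration_null_params(hypothesis)
    restriction = build_restriction(hypothesis)
    free = _CALIB_FREE[hypothesis]
    f_pair = TrajectoryPair.from_params(truth)
    fixed = {"p1": truth.p1}
    for stratum in ("noncarrier", "carrier"):
        gp = getattr(truth, stratum)
        for f_name in GenotypeParams.__dataclass_fields__:
            if f_name not in free:
                fixed[f"{stratum}.{f_name}"] = getattr(gp, f_name)
    options = FitOptions(maxiter=maxiter)
    crit = chi2.isf(alpha, restriction.df)
    stats = []
    for r in range(n_reps):
        design = recovery_design(
            n, _spawn_seed(seed, 3, r), genotype_mcar=True, genotyped_fraction=1.0,
            max_age=105, exam_gap_prob=0.0,
        )
        individuals = simulate_cohort(design, truth, f_pair)
        pc = pack(to_records(individuals), censor_lag=design.censor_lag)
        general = fit(pc, f_pair, truth, options=options, fixed=fixed)
        restricted = fit(pc, f_pair, truth, options=options, fixed=fixed,
                         restriction=restriction)
        stats.append(2.0 * (general.loglik - restricted.loglik))
    stats = np.asarray(stats)
    rejections = int(np.sum(np.maximum(stats, 0.0) > crit))
    return {
        "hypothesis": hypothesis,
        "n_reps": n_reps,
        "rejections": rejections,
        "rate": rejections / n_reps,
        "statistics": stats,
        "df": restriction.df,
    }
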