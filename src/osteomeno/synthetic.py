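"""Synthetic cross-sectional BMD cohorts with a known ground truth.

The aggregated clinical tables the calibration protocol expects are compiled
from published cross-sectional studies and are not redistributable, so this
module emulates their statistical structure: a handful of studies, each
reporting mean BMD with SD and cohort size at irregular times since
menopause onset. Per time point the study mean is the ground-truth model
trajectory plus Gaussian noise with standard error ``noise_sd / sqrt(n)``
(independent across points — a cross-sectional, not longitudinal, design),
and each study carries its own raw baseline BMD so the curation pipeline's
normalization step is genuinely exercised.

Defaults mirror the aggregated clinical series: observation times spanning
0–30 years with denser early coverage, observation noise of 0.05 on
normalized BMD (the scale of the published error bars), and cohorts of ~100
women (published cohorts range from 20 to ~300).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bmd_data import BMDObservationSeries, StudyDataset, aggregate, normalize_study
from .calibration import (
    SURGICAL_FREE,
    FitResult,
    TAU_UPPER_DEFAULT,
    fit_surgical,
)
from .errors import DomainError
from .model import EstrogenModel
from .parameters import DAYS_PER_YEAR, NaturalParameters, SurgicalParameters
from .simulation import SimulationConfig, Trajectory, simulate

__all__ = [
    "DEFAULT_OBSERVATION_TIMES",
    "SyntheticCohortSpec",
    "truth_trajectory",
    "generate_study",
    "generate_cohort",
    "RecoveryReport",
    "recovery_experiment",
]

#: Years since onset; mirrors the coverage of the published series.
DEFAULT_OBSERVATION_TIMES = (0, 1, 2, 3, 5, 8, 10, 12, 15, 20, 25, 30)

#: Cohort sizes of the six published surgical-menopause lumbar-spine series
#: (women per study); studies cycle through these when no explicit
#: ``n_per_point`` is given.
DEFAULT_COHORT_SIZES = (67, 20, 53, 210, 102, 141)


@dataclass
class SyntheticCohortSpec:
    """Ground truth, observation design, and noise model for one cohort."""

    natural: NaturalParameters
    surgical: Optional[SurgicalParameters] = None
    estrogen_variant: str = "surgical"  # "natural" or "surgical"
    observation_times: tuple[float, ...] = DEFAULT_OBSERVATION_TIMES
    noise_sd: float = 0.05          #: SD of one woman's normalized BMD
    n_per_point: int | Sequence[int] | None = None  #: None: published sizes
    n_studies: int = 6
    seed: int = 0
    baseline_range: tuple[float, float] = (0.9, 1.25)  #: raw BMD scale, g/cm²
    site: str = "L2-L4"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.estrogen_variant not in ("natural", "surgical"):
            raise DomainError("estrogen_variant must be 'natural' or 'surgical'")
        if self.estrogen_variant == "surgical" and self.surgical is None:
            raise DomainError("surgical variant requires surgical parameters")
        times = np.asarray(self.observation_times, dtype=float)
        if times.min() < -30 or times.max() > 30:
            raise DomainError("observation times must lie within the simulated span")
        self.observation_times = tuple(times)

    def cohort_sizes(self, study_index: int = 0) -> np.ndarray:
        """Cohort size at each observation time for the given study."""
        per_point = self.n_per_point
        if per_point is None:
            per_point = DEFAULT_COHORT_SIZES[study_index % len(DEFAULT_COHORT_SIZES)]
        n = np.broadcast_to(
            np.asarray(per_point, dtype=float), (len(self.observation_times),)
        )
        if (n < 1).any():
            raise DomainError("cohort sizes must be >= 1")
        return n

    def estrogen_model(self) -> EstrogenModel:
        if self.estrogen_variant == "natural":
            return EstrogenModel.natural(self.natural.t_m, self.natural.tau_E)
        return EstrogenModel.surgical(
            self.natural.t_m, self.surgical.kappa_E, self.surgical.k_syn
        )


def truth_trajectory(spec: SyntheticCohortSpec) -> Trajectory:
    """Noise-free ground-truth trajectory covering the observation times."""
    horizon = max(max(spec.observation_times), 1.0)
    cfg = SimulationConfig(t_end=spec.natural.t_m + horizon * DAYS_PER_YEAR)
    s = spec.surgical if spec.estrogen_variant == "surgical" else None
    return simulate(spec.natural, s, spec.estrogen_model(), cfg)


def generate_study(
    spec: SyntheticCohortSpec,
    rng: Optional[np.random.Generator] = None,
    study_id: str = "synthetic-1",
    truth: Optional[Trajectory] = None,
    study_index: int = 0,
) -> StudyDataset:
    """Draw one synthetic study (raw units, needing normalization).

    The per-point study mean is truth + N(0, noise_sd/sqrt(n)), scaled by a
    study-specific baseline BMD; the recorded SD is ``noise_sd`` times the
    baseline (one woman's spread, not the standard error).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    traj = truth if truth is not None else truth_trajectory(spec)
    times = np.asarray(spec.observation_times, dtype=float)
    n = spec.cohort_sizes(study_index)
    r = np.asarray(traj.relative_at(times), dtype=float)
    baseline = rng.uniform(*spec.baseline_range)
    means = (r + rng.normal(0.0, 1.0, size=r.shape) * spec.noise_sd / np.sqrt(n))
    points = pd.DataFrame({
        "time_years": times,
        "mean_bmd": means * baseline,
        "sd": np.full_like(times, spec.noise_sd * baseline),
        "n": n,
    })
    mtype = "surgical" if spec.estrogen_variant == "surgical" else "natural"
    return StudyDataset(
        study_id=study_id, site=spec.site, menopause_type=mtype, points=points
    )


def generate_cohort(spec: SyntheticCohortSpec) -> list[StudyDataset]:
    """Draw ``n_studies`` independent studies; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    truth = truth_trajectory(spec)
    return [
        generate_study(
            spec, rng=rng, study_id=f"synthetic-{i + 1}", truth=truth,
            study_index=i,
        )
        for i in range(spec.n_studies)
    ]


def curated_series(
    studies: Sequence[StudyDataset], bin_width: float = 1.0
) -> BMDObservationSeries:
    """Normalize each study and pool them (the standard curation path)."""
    return aggregate([normalize_study(d) for d in studies], bin_width=bin_width)


@dataclass
class RecoveryReport:
    """Outcome of a generate -> curate -> fit round trip."""

    fit: FitResult
    truth: dict[str, float]
    relative_errors: dict[str, float]  #: |est - true| / |true| (abs err if true == 0)
    trajectory_rmse_percent: float     #: fitted vs true relative BMD, x100


def recovery_experiment(
    spec: SyntheticCohortSpec,
    horizon_years: float = 15.0,
    tau_upper: float = TAU_UPPER_DEFAULT,
    free_parameters: tuple[str, ...] = SURGICAL_FREE,
    n_starts: int = 5,
    fit_seed: Optional[int] = None,
) -> RecoveryReport:
    """Generate a cohort, curate it, refit the surgery parameters, and
    compare the estimates and the refitted trajectory with the truth.

    ``free_parameters`` selects which surgery parameters the fit frees;
    the rest are conditioned on their true values (see
    :func:`osteomeno.calibration.fit_surgical`).
    """
    if spec.surgical is None:
        raise DomainError("recovery_experiment needs a surgical ground truth")
    studies = generate_cohort(spec)
    series = curated_series(studies)
    result = fit_surgical(
        series,
        spec.natural,
        spec.surgical,
        horizon_years=horizon_years,
        tau_upper=tau_upper,
        free_parameters=free_parameters,
        n_starts=n_starts,
        seed=fit_seed if fit_seed is not None else spec.seed,
    )

    truth = {k: float(getattr(spec.surgical, k)) for k in free_parameters}
    rel_err = {
        k: (abs(result.estimates[k] - v) / abs(v)) if v != 0
        else abs(result.estimates[k])
        for k, v in truth.items()
    }

    times = np.asarray(spec.observation_times, dtype=float)
    times = times[times <= horizon_years]
    true_traj = truth_trajectory(spec)
    fitted = spec.surgical.replace(**result.estimates)
    fit_spec = SyntheticCohortSpec(
        natural=spec.natural, surgical=fitted,
        estrogen_variant=spec.estrogen_variant,
        observation_times=tuple(times), noise_sd=0.0, seed=spec.seed,
    )
    fit_traj = truth_trajectory(fit_spec)
    diff = np.asarray(fit_traj.relative_at(times)) - np.asarray(
        true_traj.relative_at(times)
    )
    return RecoveryReport(
        fit=result,
        truth=truth,
        relative_errors=rel_err,
        trajectory_rmse_percent=float(np.sqrt(np.mean(diff**2)) * 100.0),
    )
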