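"""End-to-end experiment drivers.

Each driver reproduces one of the study's computational experiments from a
single config and writes a self-describing bundle: result CSV/JSON tables, a
figure, and a manifest (parameter values, seed, tolerances, package version)
sufficient to re-run bit-identically.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .bmd_data import BMDObservationSeries, read_studies, normalize_study, aggregate
from .calibration import FitResult, TAU_UPPER_DEFAULT, fit_natural, fit_surgical
from .errors import DomainError
from .model import EstrogenModel
from .parameters import (
    NaturalParameters,
    SurgicalParameters,
    natural_defaults,
    surgical_long_term,
    surgical_short_term,
)
from .simulation import sensitivity_envelope, simulate
from .steady_state import alpha_sweep, steady_bmd_rate
from .synthetic import SyntheticCohortSpec, generate_cohort

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]

logger = logging.getLogger(__name__)

EXPERIMENTS = (
    "natural_refit",
    "surgical_fit_short",
    "surgical_fit_long",
    "no_new_effects",
    "alpha_sweep",
    "sensitivity",
)


@dataclass
class ExperimentConfig:
    """Which experiment to run, on which inputs, writing where."""

    experiment: str
    output_dir: Path
    natural_params: Optional[Path] = None     #: YAML; packaged default if None
    surgical_params: Optional[Path] = None    #: YAML; packaged default if None
    data_file: Optional[Path] = None          #: study CSV; synthetic if None
    horizon_years: Optional[float] = None
    seed: int = 0
    noise_sd: float = 0.05
    n_starts: int = 1
    tau_upper: float = TAU_UPPER_DEFAULT
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise DomainError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        self.output_dir = Path(self.output_dir)
        for attr in ("natural_params", "surgical_params", "data_file"):
            v = getattr(self, attr)
            if v is not None:
                v = Path(v)
                if not v.exists():
                    raise DomainError(f"{attr} file not found: {v}")
                setattr(self, attr, v)


def _load_params(cfg: ExperimentConfig, long_term: bool = False):
    p = (NaturalParameters.load(cfg.natural_params)
         if cfg.natural_params else natural_defaults())
    if cfg.surgical_params:
        s = SurgicalParameters.load(cfg.surgical_params)
    else:
        s = surgical_long_term() if long_term else surgical_short_term()
    return p, s


def _load_or_generate_series(
    cfg: ExperimentConfig, p, s, variant: str
) -> BMDObservationSeries:
    if cfg.data_file is not None:
        studies = [
            d for d in read_studies(cfg.data_file)
            if d.menopause_type == variant
        ]
        if not studies:
            raise DomainError(f"no {variant!r} studies in {cfg.data_file}")
    else:
        spec = SyntheticCohortSpec(
            natural=p,
            surgical=s if variant == "surgical" else None,
            estrogen_variant=variant,
            noise_sd=cfg.noise_sd,
            seed=cfg.seed,
        )
        studies = generate_cohort(spec)
    return aggregate([normalize_study(d) for d in studies])


def _write_manifest(cfg: ExperimentConfig, p, s, extra: dict) -> None:
    manifest = {
        "package_version": _pkg_version,
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "solver_tolerances": {"abs_tol": 1e-8, "rel_tol": 1e-8},
        "natural_parameters": p.to_dict(),
        "surgical_parameters": s.to_dict() if s is not None else None,
        "data_file": str(cfg.data_file) if cfg.data_file else None,
        **extra,
    }
    with open(cfg.output_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _save_fit(result: FitResult, outdir: Path, name: str = "fit") -> None:
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(dataclasses.asdict(result), fh, indent=2)


def _save_traj(traj, outdir: Path, name: str) -> None:
    traj.to_frame().to_csv(outdir / f"{name}.csv", index=False)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the named protocol; returns the in-memory result bundle."""
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    long_term = cfg.experiment == "surgical_fit_long"
    p, s = _load_params(cfg, long_term=long_term)
    bundle: dict = {}

    if cfg.experiment == "natural_refit":
        series = _load_or_generate_series(cfg, p, None, "natural")
        result = fit_natural(
            series, p, horizon_years=cfg.horizon_years or 20.0,
            n_starts=cfg.n_starts, seed=cfg.seed,
        )
        p_fit = p.replace(**result.estimates)
        traj = simulate(p_fit, None, EstrogenModel.natural(p.t_m, p.tau_E))
        _save_fit(result, cfg.output_dir)
        _save_traj(traj, cfg.output_dir, "trajectory")
        series.to_frame().to_csv(cfg.output_dir / "data.csv", index=False)
        bundle = {"fit": result, "trajectory": traj, "data": series}

    elif cfg.experiment in ("surgical_fit_short", "surgical_fit_long"):
        horizon = cfg.horizon_years or (30.0 if long_term else 15.0)
        series = _load_or_generate_series(cfg, p, s, "surgical")
        result = fit_surgical(
            series, p, s, horizon_years=horizon, tau_upper=cfg.tau_upper,
            n_starts=cfg.n_starts, seed=cfg.seed,
        )
        s_fit = s.replace(**result.estimates)
        e = EstrogenModel.surgical(p.t_m, s.kappa_E, s.k_syn)
        traj = simulate(p, s_fit, e)
        residual = pd.DataFrame({
            "time_years": series.times_years,
            "observed": series.mean_normalized_bmd,
            "model": np.asarray(traj.relative_at(np.clip(
                series.times_years, None, 30.0))),
        })
        residual["residual"] = residual["model"] - residual["observed"]
        residual.to_csv(cfg.output_dir / "residuals.csv", index=False)
        _save_fit(result, cfg.output_dir)
        _save_traj(traj, cfg.output_dir, "trajectory")
        bundle = {"fit": result, "trajectory": traj, "data": series}

    elif cfg.experiment == "no_new_effects":
        zero = s.replace(eta_surg=0.0, omega_surg=0.0)
        e_surg = EstrogenModel.surgical(p.t_m, s.kappa_E, s.k_syn)
        e_nat = EstrogenModel.natural(p.t_m, p.tau_E)
        traj_surg = simulate(p, zero, e_surg)
        traj_nat = simulate(p, None, e_nat)
        _save_traj(traj_surg, cfg.output_dir, "sudden_estrogen_loss")
        _save_traj(traj_nat, cfg.output_dir, "natural_decline")
        bundle = {"sudden_estrogen_loss": traj_surg, "natural_decline": traj_nat}
        if cfg.make_figures:
            _figure_compare(bundle, cfg.output_dir)

    elif cfg.experiment == "alpha_sweep":
        sweep = alpha_sweep(p, s.estrogen_plateau)
        for ref_alpha in (0.8, 0.94):
            sweep.attrs[f"rate_at_alpha_{ref_alpha}"] = steady_bmd_rate(
                p, E=s.estrogen_plateau, alpha=ref_alpha
            )
        sweep.to_csv(cfg.output_dir / "alpha_sweep.csv", index=False)
        bundle = {"sweep": sweep}
        if cfg.make_figures:
            _figure_sweep(sweep, cfg.output_dir)

    elif cfg.experiment == "sensitivity":
        e = EstrogenModel.surgical(p.t_m, s.kappa_E, s.k_syn)
        env = sensitivity_envelope(p, s, e, fraction=0.25)
        for name in ("nominal", "upper", "lower"):
            _save_traj(getattr(env, name), cfg.output_dir, name)
        bundle = {"envelope": env}

    _write_manifest(cfg, p, s, {"horizon_years": cfg.horizon_years})
    logger.info("experiment %s written to %s", cfg.experiment, cfg.output_dir)
    return bundle


def _figure_compare(bundle: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .plots import plot_relative_bmd

    fig, ax = plt.subplots(figsize=(6, 4))
    plot_relative_bmd(
        list(bundle.values()), list(bundle.keys()), ax=ax
    )
    fig.tight_layout()
    fig.savefig(outdir / "relative_bmd.png", dpi=150)
    plt.close(fig)


def _figure_sweep(sweep, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .plots import plot_alpha_sweep

    fig, ax = plt.subplots(figsize=(6, 4))
    plot_alpha_sweep(sweep, ax=ax)
    fig.tight_layout()
    fig.savefig(outdir / "alpha_sweep.png", dpi=150)
    plt.close(fig)
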