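"""Time integration of the full model and trajectory containers.

Simulations run from 30 years before menopause onset (initialized at the
premenopausal equilibrium) to up to 30 years after. The onset ``t_m`` is a
genuine discontinuity of the surgical rates, so the integrator is run in two
segments, ``[t_start, t_m]`` and ``[t_m, t_end]``, with the post-onset
segment evaluating the surgery terms on their right-hand branch; the adaptive
solver therefore never steps across the jump.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, IntegrationError
from .model import STATE_VARS, EstrogenModel, rhs
from .parameters import DAYS_PER_YEAR, NaturalParameters, SurgicalParameters
from .steady_state import premenopausal_steady_state

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "simulate",
    "relative_bmd_at",
    "sensitivity_envelope",
    "SensitivityEnvelope",
]

_MONTH = DAYS_PER_YEAR / 12.0


@dataclass(frozen=True)
class SimulationConfig:
    """Integration window, tolerances, and output grid (times in days).

    Defaults follow the study design: 30 years before onset to 30 years
    after, absolute/relative tolerances of 1e-8, monthly output.
    """

    t_start: Optional[float] = None   # default: t_m - 30 years
    t_end: Optional[float] = None     # default: t_m + 30 years
    abs_tol: float = 1e-8
    rel_tol: float = 1e-8
    output_grid: Optional[np.ndarray] = None  # default: monthly
    method: str = "RK45"
    resorption_inhibition: bool = False

    def resolve(self, t_m: float) -> tuple[float, float, np.ndarray]:
        t0 = self.t_start if self.t_start is not None else t_m - 30 * DAYS_PER_YEAR
        t1 = self.t_end if self.t_end is not None else t_m + 30 * DAYS_PER_YEAR
        if not t0 < t_m < t1:
            raise DomainError("require t_start < t_m < t_end")
        if self.abs_tol <= 0 or self.rel_tol <= 0:
            raise DomainError("solver tolerances must be > 0")
        if self.output_grid is not None:
            grid = np.asarray(self.output_grid, dtype=float)
            if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
                raise DomainError("output_grid must be strictly increasing")
        else:
            n = int(round((t1 - t0) / _MONTH))
            grid = t0 + _MONTH * np.arange(n + 1)
            grid[-1] = t1
        return t0, t1, grid


@dataclass
class Trajectory:
    """Solution sampled on the output grid.

    ``states`` has one row per time, columns ordered as
    :data:`osteomeno.model.STATE_VARS`. ``bmd`` is ``BMC0 * Bd`` and
    ``relative_bmd`` is ``bmd`` normalized by its value at menopause onset
    (the convention used for comparing with clinical series).
    """

    times: np.ndarray
    states: np.ndarray
    bmd: np.ndarray
    relative_bmd: np.ndarray
    t_m: float
    bmd_at_onset: float
    _interp: Optional[PchipInterpolator] = field(default=None, repr=False)

    def years_since_onset(self) -> np.ndarray:
        return (self.times - self.t_m) / DAYS_PER_YEAR

    def relative_at(self, years_since_onset) -> np.ndarray | float:
        """Monotone-cubic interpolation of relative BMD at the given years."""
        t = self.t_m + np.asarray(years_since_onset, dtype=float) * DAYS_PER_YEAR
        lo, hi = self.times[0], self.times[-1]
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise DomainError(
                "requested time outside the simulated span "
                f"[{(lo - self.t_m) / DAYS_PER_YEAR:.2f}, "
                f"{(hi - self.t_m) / DAYS_PER_YEAR:.2f}] years since onset"
            )
        if self._interp is None:
            self._interp = PchipInterpolator(self.times, self.relative_bmd)
        out = self._interp(np.clip(t, lo, hi))
        return float(out) if np.isscalar(years_since_onset) else out

    def component(self, name: str) -> np.ndarray:
        return self.states[:, STATE_VARS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "time_years_since_onset", self.years_since_onset())
        df["BMD"] = self.bmd
        df["relative_BMD"] = self.relative_bmd
        return df


def _integrate_segment(t0, t1, y0, t_eval, p, s, e, cfg, post_branch):
    sol = solve_ivp(
        lambda t, y: rhs(
            t, y, p, s, e,
            resorption_inhibition=cfg.resorption_inhibition,
            post_branch_at_onset=post_branch,
        ),
        (t0, t1),
        y0,
        method=cfg.method,
        t_eval=t_eval,
        rtol=cfg.rel_tol,
        atol=cfg.abs_tol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else t0
        raise IntegrationError(
            f"integration failed at t = {t_fail:g} days: {sol.message}", t_fail
        )
    return sol


def simulate(
    p: NaturalParameters,
    s: Optional[SurgicalParameters],
    e: EstrogenModel,
    cfg: Optional[SimulationConfig] = None,
) -> Trajectory:
    """Integrate the model from the premenopausal equilibrium.

    The initial state is recomputed from ``p`` (so calibration can vary
    thresholds freely); estrogen at the start is 1 for the menopause
    variants, or the fixed level for a constant law.

    Returns a :class:`Trajectory` sampled on the configured output grid,
    which always includes ``t_m`` so onset normalization is exact.
    """
    cfg = cfg or SimulationConfig()
    t0, t1, grid = cfg.resolve(p.t_m)

    E0 = e.level if e.variant == "constant" else 1.0
    y0 = premenopausal_steady_state(p, E=E0, cross_check=False).state.as_array()

    grid = np.unique(np.concatenate([grid, [p.t_m]]))
    pre_mask = grid <= p.t_m
    sol1 = _integrate_segment(
        t0, p.t_m, y0, grid[pre_mask], p, s, e, cfg, post_branch=False
    )
    y_tm = sol1.y[:, -1]
    sol2 = _integrate_segment(
        p.t_m, t1, y_tm, grid[~pre_mask], p, s, e, cfg, post_branch=True
    )

    times = np.concatenate([sol1.t, sol2.t])
    states = np.concatenate([sol1.y, sol2.y], axis=1).T
    bmd = p.BMC0 * states[:, STATE_VARS.index("Bd")]
    bmd_onset = float(p.BMC0 * y_tm[STATE_VARS.index("Bd")])
    if bmd_onset == 0.0:
        raise IntegrationError("BMD at onset is zero; cannot normalize", p.t_m)
    return Trajectory(
        times=times,
        states=states,
        bmd=bmd,
        relative_bmd=bmd / bmd_onset,
        t_m=p.t_m,
        bmd_at_onset=bmd_onset,
    )


def relative_bmd_at(traj: Trajectory, years_since_onset) -> np.ndarray | float:
    """Relative BMD at the requested years since onset (interpolated)."""
    return traj.relative_at(years_since_onset)


class SensitivityEnvelope(NamedTuple):
    nominal: Trajectory
    upper: Trajectory
    lower: Trajectory


def sensitivity_envelope(
    p: NaturalParameters,
    s: SurgicalParameters,
    e: EstrogenModel,
    cfg: Optional[SimulationConfig] = None,
    fraction: float = 0.25,
) -> SensitivityEnvelope:
    """Trajectories under ±``fraction`` perturbation of the surgery effects.

    The *upper* member strengthens and prolongs the surgical response
    (fold-increases up by ``fraction``, relaxation rate ``tau`` down by
    ``fraction``); the *lower* member is the opposite. ``tau = 0`` stays 0.
    """
    if s is None:
        raise DomainError("sensitivity_envelope requires surgical parameters")
    if fraction < 0:
        raise DomainError("fraction must be >= 0")
    up = s.replace(
        eta_surg=s.eta_surg * (1 + fraction),
        omega_surg=s.omega_surg * (1 + fraction),
        tau=s.tau * (1 - fraction),
    )
    lo = s.replace(
        eta_surg=s.eta_surg * (1 - fraction),
        omega_surg=s.omega_surg * (1 - fraction),
        tau=s.tau * (1 + fraction),
    )
    return SensitivityEnvelope(
        nominal=simulate(p, s, e, cfg),
        upper=simulate(p, up, e, cfg),
        lower=simulate(p, lo, e, cfg),
    )
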