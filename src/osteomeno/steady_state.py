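"""Premenopausal equilibrium and steady bone-density change rates.

With bone density held at its reference value (it feeds back into nothing),
the cell/sclerostin subsystem at fixed estrogen E has a *triangular* steady
state that can be read off in closed form:

    B  = 1 / (eta_B + omega_B)              (osteoblast influx is 1, scaled)
    S  = omega_B * B / eta_S
    Sc = alpha * f⁻(E, e_Sc) * S / kappa_Sc
    PB = 1 / (omega_PB * f⁻(Sc, sc_PB))
    PC = 1 / (omega_PC * f⁻(E, e_PC) * f⁺(Sc, sc_PC))
    C  = 1 / eta_C

``alpha`` is a control multiplier on sclerostin production (1 = nominal) used
by the sensitivity sweep: evaluating the density equation at the re-solved
equilibrium as ``alpha`` varies maps sclerostin production onto a constant
rate of bone-density change. The closed form is the primary method; a
numerical root solve of the same equations, started from the closed form, is
retained as a cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConvergenceError, DomainError
from .model import (
    BoneState,
    EstrogenModel,
    hill_activation,
    hill_inhibition,
    rhs,
)
from .parameters import DAYS_PER_YEAR, NaturalParameters

__all__ = [
    "SteadyStateResult",
    "premenopausal_steady_state",
    "steady_bmd_rate",
    "alpha_sweep",
]

#: Per-component relative residual tolerance for a valid equilibrium.
RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class SteadyStateResult:
    """Equilibrium of the cell/sclerostin subsystem with Bd fixed at 1."""

    state: BoneState
    residual_norm: float
    method: str  # "closed_form" or "root_solve"


def _cascade(p: NaturalParameters, E: float, alpha: float) -> np.ndarray:
    B = 1.0 / (p.eta_B + p.omega_B)
    S = p.omega_B * B / p.eta_S
    Sc = alpha * hill_inhibition(E, p.e_Sc) * S / p.kappa_Sc
    PB = 1.0 / (p.omega_PB * hill_inhibition(Sc, p.sc_PB))
    PC = 1.0 / (
        p.omega_PC * hill_inhibition(E, p.e_PC) * hill_activation(Sc, p.sc_PC)
    )
    C = 1.0 / p.eta_C
    return np.array([PB, PC, C, B, S, Sc])


def _subsystem_residual(
    x: np.ndarray, p: NaturalParameters, E: float, alpha: float
) -> np.ndarray:
    """Time derivatives of the six dynamic species at fixed estrogen."""
    PB, PC, C, B, S, Sc = x
    pc_flux = (
        p.omega_PC * hill_inhibition(E, p.e_PC) * hill_activation(Sc, p.sc_PC) * PC
    )
    pb_flux = p.omega_PB * hill_inhibition(Sc, p.sc_PB) * PB
    return np.array([
        1.0 - pb_flux,
        1.0 - pc_flux,
        pc_flux - p.eta_C * C,
        pb_flux - (p.eta_B + p.omega_B) * B,
        p.omega_B * B - p.eta_S * S,
        alpha * hill_inhibition(E, p.e_Sc) * S - p.kappa_Sc * Sc,
    ])


def _relative_residual(
    x: np.ndarray, p: NaturalParameters, E: float, alpha: float
) -> float:
    """Residual scaled per component by its gross turnover flux."""
    res = _subsystem_residual(x, p, E, alpha)
    PB, PC, C, B, S, Sc = x
    scales = np.array([
        1.0,
        1.0,
        max(1.0, p.eta_C * C),
        max(1.0, (p.eta_B + p.omega_B) * B),
        max(p.omega_B * B, p.eta_S * S),
        max(alpha * hill_inhibition(E, p.e_Sc) * S, p.kappa_Sc * Sc),
    ])
    return float(np.max(np.abs(res) / scales))


def premenopausal_steady_state(
    p: NaturalParameters,
    E: float = 1.0,
    alpha: float = 1.0,
    cross_check: bool = True,
) -> SteadyStateResult:
    """Equilibrium of the cell/sclerostin subsystem at fixed estrogen.

    Parameters
    ----------
    p
        Baseline parameter set.
    E
        Fixed normalized estrogen level (1 = premenopausal).
    alpha
        Multiplier on sclerostin production (sensitivity sweeps).
    cross_check
        Also run a numerical root solve started at the closed form and
        require agreement to 1e-10 relative.

    Returns
    -------
    SteadyStateResult
        State with ``Bd = 1`` and the scaled residual norm.
    """
    if E <= 0 or alpha <= 0:
        raise DomainError("E and alpha must be > 0")
    x = _cascade(p, E, alpha)
    resid = _relative_residual(x, p, E, alpha)
    if resid > RESIDUAL_TOL:
        raise ConvergenceError(
            f"closed-form equilibrium residual {resid:.3e} exceeds {RESIDUAL_TOL}"
        )
    if cross_check:
        sol = optimize.root(
            _subsystem_residual, x, args=(p, E, alpha), method="hybr",
            options={"xtol": 1e-13},
        )
        rel_gap = float(np.max(np.abs(sol.x - x) / np.abs(x)))
        root_resid = _relative_residual(sol.x, p, E, alpha)
        if not sol.success or root_resid > RESIDUAL_TOL:
            raise ConvergenceError(
                f"root-solve cross-check failed (residual {root_resid:.3e})"
            )
        if rel_gap > RESIDUAL_TOL:
            raise ConvergenceError(
                f"closed-form and root-solve equilibria disagree by {rel_gap:.3e}"
            )
    state = BoneState(*x, Bd=1.0)
    return SteadyStateResult(state=state, residual_norm=resid, method="closed_form")


def steady_bmd_rate(
    p: NaturalParameters,
    E: float = 1.0,
    alpha: float = 1.0,
    *,
    resorption_inhibition: bool = False,
) -> float:
    """Constant bone-density change rate at the re-solved equilibrium, %/yr.

    Evaluates the density equation at the equilibrium cell levels obtained
    with sclerostin production scaled by ``alpha`` and estrogen fixed at
    ``E``; the rate is expressed as percent of the reference density
    (Bd = 1) per year.
    """
    res = premenopausal_steady_state(p, E=E, alpha=alpha, cross_check=False)
    st = res.state
    coupling = (
        hill_inhibition(st.C, p.r_Omega)
        if resorption_inhibition
        else hill_activation(st.C, p.r_Omega)
    )
    rate_per_day = (
        p.lambda_B * st.B * hill_inhibition(st.Sc, p.sc_Omega)
        * (1.0 + p.nu_Omega * coupling)
        - p.lambda_C * st.C
    )
    return rate_per_day * DAYS_PER_YEAR * 100.0


def alpha_sweep(
    p: NaturalParameters,
    E_post: float,
    alphas: Optional[np.ndarray] = None,
    *,
    resorption_inhibition: bool = False,
) -> pd.DataFrame:
    """Steady bone-density change versus relative sclerostin production.

    ``E_post`` is the fixed post-menopausal estrogen level (the surgical
    plateau ``k_syn / kappa_E``). The x-axis column ``relative_production``
    rescales ``alpha`` to sclerostin production relative to the premenopausal
    level: ``alpha * f⁻(E_post, e_Sc) / f⁻(1, e_Sc)``.
    """
    if alphas is None:
        alphas = np.linspace(0.7, 1.2, 101)
    rel = hill_inhibition(E_post, p.e_Sc) / hill_inhibition(1.0, p.e_Sc)
    rates = [
        steady_bmd_rate(
            p, E=E_post, alpha=float(a),
            resorption_inhibition=resorption_inhibition,
        )
        for a in alphas
    ]
    return pd.DataFrame({
        "alpha": np.asarray(alphas, dtype=float),
        "relative_production": np.asarray(alphas, dtype=float) * rel,
        "bmd_rate_pct_per_year": np.asarray(rates, dtype=float),
    })


def equilibrium_rhs_residual(
    p: NaturalParameters, E: float = 1.0
) -> np.ndarray:
    """Full-model derivative vector at the equilibrium (diagnostic).

    The first six components vanish at a valid equilibrium; the density
    component reports the constant formation/resorption imbalance.
    """
    st = premenopausal_steady_state(p, E=E, cross_check=False).state
    e = EstrogenModel.constant(E)
    return rhs(0.0, st.as_array(), p, None, e)
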