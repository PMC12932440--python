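"""Core model: Hill interactions, estrogen laws, and the ODE right-hand side.

The model tracks seven scaled quantities inside a basic multicellular unit
(BMU): preosteoblasts ``PB``, preosteoclasts ``PC``, osteoclasts ``C``,
osteoblasts ``B``, osteocytes ``S``, sclerostin ``Sc``, and bone density
``Bd`` (1 = premenopausal reference). Precursor pools are replenished at a
scaled basal rate of one per day; differentiation and apoptosis are regulated
by saturating Hill-type activation/repression terms in estrogen and
sclerostin. Estrogen is an algebraic input, not a state: it declines
hyperbolically after natural menopause and exponentially to a low plateau
after surgical menopause (first-order clearance with residual zero-order
synthesis). Surgery additionally boosts osteocyte apoptosis and osteoclast
differentiation by fold-factors that relax back to baseline at rate ``tau``.

Bone mineral density is ``BMD = BMC0 * Bd``. The density equation couples
osteoblast-driven formation (inhibited by sclerostin, modulated by the
resorption factor ``R = C``) against osteoclast-driven resorption; density
feeds back into no other equation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional

import numpy as np

from .errors import DomainError, ModelEvaluationError
from .parameters import NaturalParameters, SurgicalParameters

__all__ = [
    "STATE_VARS",
    "BoneState",
    "EstrogenModel",
    "hill_activation",
    "hill_inhibition",
    "estrogen_level",
    "estrogen_kinetics_from_physiology",
    "omega_t",
    "eta_t",
    "rhs",
]

#: State-vector component order used throughout the package.
STATE_VARS = ("PB", "PC", "C", "B", "S", "Sc", "Bd")


class BoneState(NamedTuple):
    """The 7-component scaled state of the BMU model."""

    PB: float
    PC: float
    C: float
    B: float
    S: float
    Sc: float
    Bd: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, y) -> "BoneState":
        return cls(*map(float, y))


def hill_activation(X: float, threshold: float) -> float:
    """Saturating activation f⁺(X, k) = X / (X + k), in [0, 1).

    ``threshold`` is the half-saturation constant: f⁺(k, k) = 1/2.
    """
    if threshold <= 0:
        raise DomainError("hill threshold must be > 0")
    if X < 0:
        raise DomainError("hill argument must be >= 0")
    return X / (X + threshold)


def hill_inhibition(X: float, threshold: float) -> float:
    """Saturating repression f⁻(X, k) = k / (X + k), in (0, 1].

    Complements :func:`hill_activation`: f⁺ + f⁻ = 1 at any (X, k).
    """
    if threshold <= 0:
        raise DomainError("hill threshold must be > 0")
    if X < 0:
        raise DomainError("hill argument must be >= 0")
    return threshold / (X + threshold)


@dataclass(frozen=True)
class EstrogenModel:
    """Algebraic estrogen law, normalized to the pre-menopausal level.

    Variants
    --------
    ``natural``
        E = 1 for t <= t_m, then 1 / (1 + (t - t_m)/tau_E) (hyperbolic
        decline with characteristic time ``tau_E`` in days).
    ``surgical``
        E = 1 for t <= t_m, then first-order clearance at rate ``kappa_E``
        toward the plateau ``k_syn / kappa_E`` set by residual synthesis.
    ``constant``
        E = ``level`` at all times (steady-state analyses).
    """

    variant: Literal["natural", "surgical", "constant"]
    t_m: float = 0.0
    tau_E: float = 0.0
    kappa_E: float = 0.0
    k_syn: float = 0.0
    level: float = 1.0

    def __post_init__(self):
        if self.variant == "natural" and self.tau_E <= 0:
            raise DomainError("natural estrogen law requires tau_E > 0")
        if self.variant == "surgical":
            if self.kappa_E <= 0:
                raise DomainError("surgical estrogen law requires kappa_E > 0")
            if not 0 <= self.k_syn / self.kappa_E <= 1:
                raise DomainError("estrogen plateau k_syn/kappa_E must be in [0, 1]")
        if self.variant == "constant" and not 0 < self.level <= 1:
            raise DomainError("constant estrogen level must be in (0, 1]")

    @classmethod
    def natural(cls, t_m: float, tau_E_days: float) -> "EstrogenModel":
        return cls(variant="natural", t_m=t_m, tau_E=tau_E_days)

    @classmethod
    def surgical(cls, t_m: float, kappa_E: float, k_syn: float) -> "EstrogenModel":
        return cls(variant="surgical", t_m=t_m, kappa_E=kappa_E, k_syn=k_syn)

    @classmethod
    def constant(cls, level: float = 1.0) -> "EstrogenModel":
        return cls(variant="constant", level=level)

    @classmethod
    def for_parameters(
        cls,
        p: NaturalParameters,
        s: Optional[SurgicalParameters] = None,
        variant: str | None = None,
    ) -> "EstrogenModel":
        """Convenience: the estrogen law matching a parameter set."""
        if variant is None:
            variant = "surgical" if s is not None else "natural"
        if variant == "natural":
            return cls.natural(p.t_m, p.tau_E)
        if variant == "surgical":
            if s is None:
                raise DomainError("surgical estrogen law needs SurgicalParameters")
            return cls.surgical(p.t_m, s.kappa_E, s.k_syn)
        raise DomainError(f"unknown estrogen variant {variant!r}")


def estrogen_level(model: EstrogenModel, t: float) -> float:
    """Normalized estrogen concentration at time ``t`` (days).

    Both menopause variants equal 1 up to and including ``t_m`` and are
    continuous from the left there; values stay in (0, 1].
    """
    if model.variant == "constant":
        return model.level
    if t <= model.t_m:
        return 1.0
    dt = t - model.t_m
    if model.variant == "natural":
        return 1.0 / (1.0 + dt / model.tau_E)
    plateau = model.k_syn / model.kappa_E
    return (1.0 - plateau) * math.exp(-model.kappa_E * dt) + plateau


def estrogen_kinetics_from_physiology(
    half_life_min: float, pre_conc: float, post_conc: float
) -> tuple[float, float, float]:
    """Estrogen clearance/synthesis rates from physiological measurements.

    Parameters
    ----------
    half_life_min
        Circulating estrogen half-life in minutes.
    pre_conc, post_conc
        Serum estrogen before surgery and at the post-surgical plateau
        (same units, e.g. pg/mL); ``post_conc`` must be lower.

    Returns
    -------
    (kappa_E, k_syn, plateau)
        First-order degradation rate in day⁻¹, the zero-order synthesis rate
        ``kappa_E * plateau`` in day⁻¹, and the normalized plateau
        ``post_conc / pre_conc``.
    """
    if half_life_min <= 0 or pre_conc <= 0 or post_conc <= 0:
        raise DomainError("all physiological inputs must be > 0")
    if post_conc >= pre_conc:
        raise DomainError("post-surgery estrogen must be below the pre-surgery level")
    kappa_E = math.log(2.0) / (half_life_min / (24.0 * 60.0))
    plateau = post_conc / pre_conc
    return kappa_E, kappa_E * plateau, plateau


def _surge_factor(
    t: float,
    t_m: float,
    fold: float,
    tau: float,
    include_onset: bool,
) -> float:
    past_onset = t >= t_m if include_onset else t > t_m
    if not past_onset or fold == 0.0:
        return 1.0
    return 1.0 + fold * math.exp(-tau * (t - t_m))


def omega_t(
    t: float,
    p: NaturalParameters,
    s: Optional[SurgicalParameters] = None,
    *,
    post_branch_at_onset: bool = False,
) -> float:
    """Time-dependent preosteoclast -> osteoclast differentiation rate.

    Equals ``omega_PC`` before menopause onset (and always, without surgical
    effects); jumps to ``omega_PC * (1 + omega_surg)`` just after onset and
    relaxes back at rate ``tau`` (``tau = 0``: permanent). At exactly ``t_m``
    the pre-menopause value applies unless ``post_branch_at_onset`` is set
    (used by the integrator on the post-onset segment).
    """
    if s is None:
        return p.omega_PC
    return p.omega_PC * _surge_factor(
        t, p.t_m, s.omega_surg, s.tau, post_branch_at_onset
    )


def eta_t(
    t: float,
    p: NaturalParameters,
    s: Optional[SurgicalParameters] = None,
    *,
    post_branch_at_onset: bool = False,
) -> float:
    """Time-dependent osteocyte apoptosis rate; mirrors :func:`omega_t`."""
    if s is None:
        return p.eta_S
    return p.eta_S * _surge_factor(
        t, p.t_m, s.eta_surg, s.tau, post_branch_at_onset
    )


def rhs(
    t: float,
    y: np.ndarray,
    p: NaturalParameters,
    s: Optional[SurgicalParameters],
    e: EstrogenModel,
    *,
    resorption_inhibition: bool = False,
    post_branch_at_onset: bool = False,
) -> np.ndarray:
    """Right-hand side d(state)/dt of the seven model equations.

    ``y`` is ordered as :data:`STATE_VARS`. The resorption factor in the
    density equation is the osteoclast level, ``R = C``, entering through an
    activating Hill term by default; ``resorption_inhibition=True`` switches
    to the repressive coupling f⁻(R, r_Omega) for exploration.

    The six cell/signal components are evaluated at ``max(value, 0)``:
    adaptive solvers probe internal stages outside the admissible region
    (most aggressively when the trajectory sits on the equilibrium and the
    step size grows past the stiffness limit), and the right-hand side must
    stay defined there. Accepted solution values are unaffected.
    """
    PB, PC, C, B, S, Sc = (max(v, 0.0) for v in y[:6])
    E = estrogen_level(e, t)

    w = omega_t(t, p, s, post_branch_at_onset=post_branch_at_onset)
    h = eta_t(t, p, s, post_branch_at_onset=post_branch_at_onset)

    pc_flux = w * hill_inhibition(E, p.e_PC) * hill_activation(Sc, p.sc_PC) * PC
    pb_flux = p.omega_PB * hill_inhibition(Sc, p.sc_PB) * PB

    r_coupling = (
        hill_inhibition(C, p.r_Omega)
        if resorption_inhibition
        else hill_activation(C, p.r_Omega)
    )
    formation = (
        p.lambda_B * B * hill_inhibition(Sc, p.sc_Omega)
        * (1.0 + p.nu_Omega * r_coupling)
    )

    # STATE_VARS order: PB, PC, C, B, S, Sc, Bd.
    out = np.empty(7)
    out[0] = 1.0 - pb_flux                          # preosteoblasts
    out[1] = 1.0 - pc_flux                          # preosteoclasts
    out[2] = pc_flux - p.eta_C * C                  # osteoclasts
    out[3] = pb_flux - (p.eta_B + p.omega_B) * B    # osteoblasts
    out[4] = p.omega_B * B - h * S                  # osteocytes
    out[5] = hill_inhibition(E, p.e_Sc) * S - p.kappa_Sc * Sc  # sclerostin
    out[6] = formation - p.lambda_C * C             # bone density

    if not np.isfinite(out).all():
        bad = [STATE_VARS[i] for i in np.flatnonzero(~np.isfinite(out))]
        raise ModelEvaluationError(
            f"non-finite derivative in equation(s) {bad} at t={t:g}"
        )
    return out
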