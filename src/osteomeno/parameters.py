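"""Parameter sets for the menopausal bone-remodeling model.

Two flat parameter containers cover the model:

* :class:`NaturalParameters` — the rates and Hill thresholds of the baseline
  (premenopausal / natural-menopause) model, all in units of day⁻¹ or
  dimensionless scaled-species units.
* :class:`SurgicalParameters` — the post-oophorectomy estrogen kinetics plus
  the three surgery-effect parameters (fold-increases of osteocyte apoptosis
  and osteoclast differentiation and their shared relaxation rate).

Packaged defaults live in YAML files under ``osteomeno/data``; keys are named
after the model symbols. In YAML the estrogen decline time ``tau_E`` is given
in years (the conventional clinical unit) and converted to days on ingestion;
everything inside the package uses days.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import DomainError

__all__ = [
    "DAYS_PER_YEAR",
    "NaturalParameters",
    "SurgicalParameters",
    "natural_defaults",
    "surgical_short_term",
    "surgical_long_term",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.0

#: Reference steady-state osteoclast level commonly quoted for this parameter
#: set; inconsistent with eta_C (the equations give C* = 1/eta_C ≈ 9.1e3).
_REFERENCE_OSTEOCLAST_LEVEL = 42.0


@dataclass(frozen=True)
class NaturalParameters:
    """Baseline model parameters (rates in day⁻¹, thresholds dimensionless).

    ``tau_E`` and ``t_m`` are stored in **days**. Construct from a YAML/dict
    config (where ``tau_E`` is in years) via :meth:`from_dict` or
    :meth:`load`.
    """

    omega_PC: float  #: differentiation rate preosteoclast -> osteoclast
    omega_PB: float  #: differentiation rate preosteoblast -> osteoblast
    omega_B: float   #: differentiation rate osteoblast -> osteocyte
    eta_B: float     #: osteoblast apoptosis rate
    eta_C: float     #: osteoclast apoptosis rate
    eta_S: float     #: osteocyte apoptosis rate (baseline)
    lambda_B: float  #: first-order bone formation rate
    lambda_C: float  #: first-order bone resorption rate
    kappa_Sc: float  #: sclerostin degradation rate
    tau_E: float     #: characteristic time of natural estrogen decline [days]
    e_PC: float      #: estrogen threshold inhibiting PC -> C differentiation
    e_Sc: float      #: estrogen threshold inhibiting sclerostin production
    sc_PC: float     #: sclerostin threshold activating PC -> C
    sc_PB: float     #: sclerostin threshold inhibiting PB -> B
    sc_Omega: float  #: sclerostin threshold inhibiting bone formation
    r_Omega: float   #: resorption-factor threshold in the density equation
    nu_Omega: float  #: maximum relative effect of resorption on formation
    BMC0: float = 0.8      #: bone mineral content scale, BMD = BMC0 * Bd
    t_m: float = 10950.0   #: menopause onset on the simulation clock [days]

    _RATES = (
        "omega_PC", "omega_PB", "omega_B", "eta_B", "eta_C", "eta_S",
        "lambda_B", "lambda_C", "kappa_Sc",
    )
    _THRESHOLDS = ("e_PC", "e_Sc", "sc_PC", "sc_PB", "sc_Omega", "r_Omega")

    def __post_init__(self) -> None:
        for name in self._RATES:
            if getattr(self, name) < 0:
                raise DomainError(f"rate {name} must be >= 0")
        for name in self._THRESHOLDS:
            if getattr(self, name) <= 0:
                raise DomainError(f"threshold {name} must be > 0")
        if self.nu_Omega < 0:
            raise DomainError("nu_Omega must be >= 0")
        if not 0 < self.BMC0 <= 1:
            raise DomainError("BMC0 must lie in (0, 1]")
        if self.tau_E <= 0:
            raise DomainError("tau_E must be > 0")

    @classmethod
    def from_dict(cls, cfg: dict) -> "NaturalParameters":
        """Build from a flat config dict; ``tau_E`` is interpreted in years."""
        cfg = dict(cfg)
        cfg["tau_E"] = float(cfg["tau_E"]) * DAYS_PER_YEAR
        return cls(**{k: float(v) for k, v in cfg.items()})

    def to_dict(self) -> dict:
        """Flat dict with ``tau_E`` back in years (the config convention)."""
        d = dataclasses.asdict(self)
        d["tau_E"] = self.tau_E / DAYS_PER_YEAR
        return d

    @classmethod
    def load(cls, path: str | Path) -> "NaturalParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "NaturalParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SurgicalParameters:
    """Surgical-menopause parameters: estrogen kinetics and surgery effects.

    ``tau = 0`` makes the surgery-induced fold-increases permanent; larger
    ``tau`` means they relax back to baseline faster.
    """

    kappa_E: float     #: estrogen degradation rate post-surgery [day⁻¹]
    k_syn: float       #: residual estrogen synthesis rate post-surgery [day⁻¹]
    eta_surg: float    #: peak fold-increase of osteocyte apoptosis
    omega_surg: float  #: peak fold-increase of osteoclast differentiation
    tau: float         #: relaxation rate of the surgery effects [day⁻¹]

    def __post_init__(self) -> None:
        if self.kappa_E <= 0:
            raise DomainError("kappa_E must be > 0")
        if not 0 <= self.k_syn / self.kappa_E <= 1:
            raise DomainError("k_syn/kappa_E (estrogen plateau) must be in [0, 1]")
        if self.eta_surg < 0 or self.omega_surg < 0:
            raise DomainError("fold-increases eta_surg/omega_surg must be >= 0")
        if self.tau < 0:
            raise DomainError("tau must be >= 0 (0 means a permanent effect)")

    @property
    def estrogen_plateau(self) -> float:
        """Normalized long-run estrogen level after surgery, k_syn / kappa_E."""
        return self.k_syn / self.kappa_E

    @classmethod
    def from_dict(cls, cfg: dict) -> "SurgicalParameters":
        return cls(**{k: float(v) for k, v in cfg.items()})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def load(cls, path: str | Path) -> "SurgicalParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "SurgicalParameters":
        return dataclasses.replace(self, **changes)


def _packaged(name: str) -> dict:
    with resources.files("osteomeno.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def natural_defaults() -> NaturalParameters:
    """Packaged baseline parameter set (natural-menopause calibration)."""
    p = NaturalParameters.from_dict(_packaged("natural.yaml"))
    implied_c = 1.0 / p.eta_C
    if abs(implied_c - _REFERENCE_OSTEOCLAST_LEVEL) / implied_c > 0.5:
        logger.warning(
            "steady-state osteoclast level implied by eta_C is 1/eta_C = %.3g, "
            "far from the reference initial-condition value %.3g quoted for "
            "this parameter set; the model equations take precedence and the "
            "reference value is not used.",
            implied_c, _REFERENCE_OSTEOCLAST_LEVEL,
        )
    return p


def surgical_short_term() -> SurgicalParameters:
    """Packaged surgical parameters calibrated to <= 15-year data."""
    return SurgicalParameters.from_dict(_packaged("surgical_short_term.yaml"))


def surgical_long_term() -> SurgicalParameters:
    """Packaged surgical parameters calibrated to 30-year data (tau = 0)."""
    return SurgicalParameters.from_dict(_packaged("surgical_long_term.yaml"))
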