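"""Estimation of the gas-exchange parameters from tissue and blood data.

The four governing parameters of the trumpet model with axial diffusion are
the total maximum volumetric fluxes of CO out of the airway and alveolar
tissue, ``J_aw`` and ``J_A`` (pl/s), and the corresponding total diffusing
capacities ``D_aw`` and ``D_A`` (pl s^-1 ppb^-1).  For healthy subjects they
can be estimated from membrane morphometry (Fick's law across a planar
membrane) and from blood carboxyhemoglobin via the Haldane relation.

Unit conventions
----------------
Concentrations and partial pressures are mole fractions in ppb (nmol/mol);
fluxes are picolitres of gas per second.  Two identities make the arithmetic
constant-free downstream: ``1 pl = 1e-9 cm^3`` (so 1 ppb of gas in 1 cm^3 is
1 pl) and ``1 atm = 1e9 ppb``.  The membrane permeation coefficient is quoted
in cm^2 min^-1 atm^-1, hence a diffusing capacity computed as
``A_M * K / dx`` (dx in cm) carries cm^3 min^-1 atm^-1 and converts to
pl s^-1 ppb^-1 by the factor ``(1e9 pl/cm^3) / (60 s/min) / (1e9 ppb/atm)
= 1/60``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TissueBloodParams",
    "ExchangeParams",
    "CO_DIFFUSIVITY_AIR",
    "NO_DIFFUSIVITY_AIR",
    "diffusing_capacity",
    "haldane_mcap_pco",
    "max_flux",
    "estimate_exchange_params",
    "equilibrium_concentration",
]

#: Molecular diffusivity of CO in air at body conditions (cm^2/s).
CO_DIFFUSIVITY_AIR = 0.21
#: Molecular diffusivity of NO in air (cm^2/s).
NO_DIFFUSIVITY_AIR = 0.23

# pl s^-1 ppb^-1 per cm^3 min^-1 atm^-1 (see module docstring)
_PL_PER_CM3 = 1e9
_PPB_PER_ATM = 1e9
_SECONDS_PER_MINUTE = 60.0
CM3_MIN_ATM_TO_PL_S_PPB = _PL_PER_CM3 / _SECONDS_PER_MINUTE / _PPB_PER_ATM

_MMHG_PER_ATM = 760.0
MMHG_TO_PPB = _PPB_PER_ATM / _MMHG_PER_ATM

_UM_TO_CM = 1e-4


class PhysiologyError(ValueError):
    """Invalid physiological input."""


@dataclass(frozen=True)
class TissueBloodParams:
    """Tissue, membrane and blood properties used for parameter estimation.

    Defaults are representative healthy non-smoker values.

    Parameters
    ----------
    A_M_aw, A_M_A : float
        Airway and alveolar membrane areas (cm^2).
    dx_aw, dx_A : float
        Airway tissue and alveolar membrane thicknesses (um).
    K_CO : float
        CO permeation coefficient of lung tissue at 37 C (cm^2 min^-1 atm^-1).
    COHb : float
        Carboxyhemoglobin saturation (%).
    mcapO2Hb : float
        Mean pulmonary capillary oxyhemoglobin saturation (%).
    mcapPO2 : float
        Mean pulmonary capillary O2 partial pressure (mmHg).
    M : float
        Haldane equilibrium constant for COHb formation (dimensionless).
    airway_blood_fraction : float
        Ratio of airway-proximal (bronchial) to pulmonary blood volume; the
        airway maximum flux is reduced by this factor (default 0.1,
        ~1% vs ~10% of total systemic circulation).
    """

    A_M_aw: float = 9100.0
    dx_aw: float = 20.0
    A_M_A: float = 1.30e6
    dx_A: float = 0.6
    K_CO: float = 2.15e-5
    COHb: float = 0.56
    mcapO2Hb: float = 97.0
    mcapPO2: float = 90.0
    M: float = 220.0
    airway_blood_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "A_M_aw", "dx_aw", "A_M_A", "dx_A", "K_CO",
            "COHb", "mcapO2Hb", "mcapPO2", "M", "airway_blood_fraction",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise PhysiologyError(f"{name} must be strictly positive")
        for name in ("COHb", "mcapO2Hb"):
            if getattr(self, name) > 100.0:
                raise PhysiologyError(f"{name} is a % saturation and must be <= 100")


@dataclass(frozen=True)
class ExchangeParams:
    """The four exchange parameters plus the gas-phase diffusivity.

    ``J_aw``/``J_A`` are *total* maximum fluxes (pl/s) and ``D_aw``/``D_A``
    *total* diffusing capacities (pl s^-1 ppb^-1); the axial distribution is
    carried by the grid source weights.  ``D_gas`` is the molecular
    diffusivity of the species in air (cm^2/s).
    """

    J_aw: float
    D_aw: float
    J_A: float
    D_A: float
    D_gas: float = CO_DIFFUSIVITY_AIR

    def __post_init__(self) -> None:
        for name in ("J_aw", "D_aw", "J_A", "D_A", "D_gas"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise PhysiologyError(f"{name} must be finite and non-negative")

    @classmethod
    def no_healthy(cls) -> "ExchangeParams":
        """Literature reference values for exhaled NO in healthy adults
        (Shin & George, J Appl Physiol 2002)."""
        return cls(J_aw=640.0, D_aw=4.2, J_A=3638.0, D_A=1467.0,
                   D_gas=NO_DIFFUSIVITY_AIR)

    @property
    def alveolar_equilibrium(self) -> float:
        """Alveolar equilibrium concentration J_A / D_A (ppb)."""
        return equilibrium_concentration(self.J_A, self.D_A)

    @property
    def airway_tissue_equilibrium(self) -> float:
        """Airway-tissue equilibrium concentration J_aw / D_aw (ppb)."""
        return equilibrium_concentration(self.J_aw, self.D_aw)

    def scaled(self, **multipliers: float) -> "ExchangeParams":
        """Return a copy with named fields multiplied (e.g. ``J_A=1.05``)."""
        unknown = set(multipliers) - {"J_aw", "D_aw", "J_A", "D_A", "D_gas"}
        if unknown:
            raise PhysiologyError(f"unknown exchange parameters: {sorted(unknown)}")
        return replace(
            self, **{k: getattr(self, k) * v for k, v in multipliers.items()}
        )


def diffusing_capacity(A_M: float, K: float, dx_um: float) -> float:
    """Membrane diffusing capacity from morphometry, in pl s^-1 ppb^-1.

    ``D = A_M * K / dx`` with the membrane thickness converted um -> cm and
    the result converted from cm^3 min^-1 atm^-1 (see module docstring).
    """
    if dx_um <= 0:
        raise PhysiologyError("invalid membrane thickness (must be > 0)")
    if A_M <= 0 or K <= 0:
        raise PhysiologyError("membrane area and permeation coefficient must be > 0")
    return A_M * K / (dx_um * _UM_TO_CM) * CM3_MIN_ATM_TO_PL_S_PPB


def haldane_mcap_pco(COHb: float, mcapPO2: float, mcapO2Hb: float, M: float) -> float:
    """Mean capillary CO partial pressure from the Haldane relation, in ppb.

    ``mcapP_CO = COHb * mcapPO2 / (mcapO2Hb * M)`` in mmHg, converted to a
    ppb mole fraction at 1 atm = 760 mmHg.
    """
    if mcapO2Hb <= 0 or M <= 0:
        raise PhysiologyError("mcapO2Hb and M must be strictly positive")
    if COHb < 0 or mcapPO2 < 0:
        raise PhysiologyError("COHb and mcapPO2 must be non-negative")
    return MMHG_TO_PPB * COHb * mcapPO2 / (mcapO2Hb * M)


def max_flux(D: float, mcapPCO: float, blood_fraction: float = 1.0) -> float:
    """Total maximum volumetric flux (pl/s): the Fick flux at zero gas-phase
    concentration, optionally reduced by a relative blood-volume fraction."""
    if D < 0 or mcapPCO < 0 or blood_fraction < 0:
        raise PhysiologyError("inputs must be non-negative")
    return blood_fraction * D * mcapPCO


def estimate_exchange_params(
    params: TissueBloodParams | None = None,
    D_gas: float = CO_DIFFUSIVITY_AIR,
) -> ExchangeParams:
    """Estimate the four exchange parameters from tissue/blood properties.

    Composes the morphometric diffusing capacities, the Haldane capillary
    partial pressure and the maximum-flux relation; the airway flux is
    reduced by the airway blood-volume fraction.
    """
    params = params or TissueBloodParams()
    D_A = diffusing_capacity(params.A_M_A, params.K_CO, params.dx_A)
    D_aw = diffusing_capacity(params.A_M_aw, params.K_CO, params.dx_aw)
    mcapPCO = haldane_mcap_pco(params.COHb, params.mcapPO2, params.mcapO2Hb, params.M)
    return ExchangeParams(
        J_aw=max_flux(D_aw, mcapPCO, params.airway_blood_fraction),
        D_aw=D_aw,
        J_A=max_flux(D_A, mcapPCO),
        D_A=D_A,
        D_gas=D_gas,
    )


def equilibrium_concentration(J: float, D: float) -> float:
    """Equilibrium gas-phase concentration J/D (ppb), the level at which the
    net trans-membrane flux vanishes."""
    if D <= 0:
        raise PhysiologyError("equilibrium concentration undefined for D <= 0")
    if J < 0:
        raise PhysiologyError("maximum flux must be non-negative")
    return J / D
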