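"""Physical constants, scenario transforms, and cytotoxicity lookups.

Single source of truth for every symbol used by the thermal, transport
and pharmacokinetic stages. Internal unit system is SI (mol/m³, Pa, m,
s, K); perfusate doses and IC50 values cross the API boundary in µM
with 1 µM = 1e-3 mol/m³.

The tumor baseline corresponds to an untreated 2 mm peritoneal nodule:
microvascular density 200 1/cm (S/V = 2.0e4 1/m), interstitial fluid
pressure 1.4 kPa. Bevacizumab-induced vascular normalization is modelled
as a pure transform of these parameters at the two studied doses
(0.5 and 5 mg/kg); extracellular-matrix stiffness (collagen fiber
density 4 % vs 32 %) as a transform of the effective diffusivity and
microvascular density.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "UM_TO_MOL_M3",
    "MOL_M3_TO_UM",
    "TissueThermalProperties",
    "TransportParameters",
    "PKRateConstants",
    "CytotoxicityTable",
    "ScenarioSpec",
    "load_parameter_presets",
    "thermal_properties",
    "transport_defaults",
    "pk_rate_constants",
    "cytotoxicity_table",
    "ic50_at_temperature",
    "washout_factor",
    "apply_bevacizumab",
    "apply_stiffness",
    "perfusion_rate_si",
]

#: 1 µM expressed in mol/m³.
UM_TO_MOL_M3 = 1.0e-3
MOL_M3_TO_UM = 1.0e3

Region = Literal["tumor", "normal"]


@dataclass(frozen=True)
class TissueThermalProperties:
    """Organ-specific constants of the bioheat equation.

    ``w_b`` is the blood perfusion rate in 1/s, converted from the
    tabulated mL/min/kg via the tissue density (see
    :func:`perfusion_rate_si`).
    """

    organ_name: str
    w_b: float  # 1/s
    rho_t: float  # kg/m³
    k_t: float  # W/m/K
    c_t: float  # J/kg/K

    def __post_init__(self) -> None:
        for f in ("w_b", "rho_t", "k_t", "c_t"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be strictly positive")


@dataclass(frozen=True)
class TransportParameters:
    """Constants of the interstitial drug-transport model for one region.

    All SI: L_p [m/Pa/s], S_over_V [1/m], P_c [m/s], pressures [Pa],
    D [m²/s], beta [1/s]. ``c_osm`` is the osmotic partition
    coefficient and ``sigma`` the reflection coefficient, both
    dimensionless in [0, 1].
    """

    L_p: float
    S_over_V: float
    P_c: float
    P_v: float
    P_i: float
    pi_v: float
    pi_i: float
    c_osm: float
    sigma: float
    D: float
    beta: float
    region: Region = "tumor"

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_osm <= 1.0):
            raise ValueError("c_osm must lie in [0, 1]")
        if not (0.0 <= self.sigma <= 1.0):
            raise ValueError("sigma must lie in [0, 1]")
        for f in ("L_p", "S_over_V", "P_c", "D", "beta"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass(frozen=True)
class PKRateConstants:
    """Two-compartment rate constants, stored in 1/h as tabulated."""

    K12: float
    K21: float
    Ke: float
    V_blood: float = 1.6e-5  # m³, rat scale (64 mL/kg x 250 g); not tabulated

    def __post_init__(self) -> None:
        if min(self.K12, self.K21, self.Ke) < 0:
            raise ValueError("rate constants must be non-negative")
        if not self.V_blood > 0:
            raise ValueError("V_blood must be positive")

    def per_second(self) -> tuple[float, float, float]:
        return self.K12 / 3600.0, self.K21 / 3600.0, self.Ke / 3600.0


@dataclass(frozen=True)
class CytotoxicityTable:
    """Temperature-dependent oxaliplatin IC50 and thermal enhancement ratio.

    The TER row is stored verbatim from the source measurements; it is
    deliberately never recomputed as a ratio of the mean IC50 values
    (the tabulated TER is a mean of per-cell-line ratios and differs
    from the ratio of means).
    """

    temperatures: tuple[float, ...]
    ic50: tuple[float, ...]  # µM
    ter: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures)
        i = np.asarray(self.ic50)
        if t.shape != i.shape or t.shape != np.asarray(self.ter).shape:
            raise ValueError("grid/ic50/ter lengths differ")
        if not np.all(np.diff(i) < 0):
            raise ValueError("IC50 must be strictly decreasing with temperature")
        if abs(self.ter[0] - 1.0) > 1e-12:
            raise ValueError("TER at the normothermic reference must be 1.0")


@dataclass(frozen=True)
class ScenarioSpec:
    """One treatment arm of the study.

    ``bevacizumab_dose`` in mg/kg (0 = untreated control),
    ``oxaliplatin_dose_um`` the perfusate concentration in µM,
    ``permeability_multiplier`` a factor on the baseline microvascular
    permeability P_c (vascular pore-size sweep), ``collagen_density``
    an optional extracellular-matrix preset.
    """

    bevacizumab_dose: float = 0.0
    collagen_density: Literal["low", "high"] | None = None
    permeability_multiplier: float = 1.0
    oxaliplatin_dose_um: float = 160.0
    modality: Literal["IPEC", "HIPEC"] = "HIPEC"
    catheter_setup: int = 1

    def __post_init__(self) -> None:
        if self.bevacizumab_dose not in (0, 0.5, 5):
            raise ValueError("bevacizumab_dose must be 0, 0.5 or 5 mg/kg")
        if not self.permeability_multiplier > 0:
            raise ValueError("permeability_multiplier must be positive")
        if self.catheter_setup not in (1, 2):
            raise ValueError("catheter_setup must be 1 or 2")
        if self.modality not in ("IPEC", "HIPEC"):
            raise ValueError("modality must be IPEC or HIPEC")

    def resolve_tumor_parameters(self, base: TransportParameters) -> TransportParameters:
        """Fully resolved tumor-region parameters for this arm.

        Order: collagen preset, then the pore-size multiplier on the
        baseline P_c, then the vascular-normalization transform (which
        scales the already-multiplied P_c at the 5 mg/kg dose).
        Host-tissue parameters are never touched by any transform.
        """
        p = base
        if self.collagen_density is not None:
            p = apply_stiffness(p, self.collagen_density)
        if self.permeability_multiplier != 1.0:
            p = dataclasses.replace(p, P_c=p.P_c * self.permeability_multiplier)
        return apply_bevacizumab(p, self.bevacizumab_dose)


# ---------------------------------------------------------------------------
# preset loading

_PRESETS_CACHE: dict | None = None


def load_parameter_presets() -> dict:
    """Load the shipped parameter presets (cached)."""
    global _PRESETS_CACHE
    if _PRESETS_CACHE is None:
        with resources.files("hipecpk.data").joinpath("parameters.yaml").open() as fh:
            _PRESETS_CACHE = yaml.safe_load(fh)
    return _PRESETS_CACHE


def perfusion_rate_si(w_b_ml_min_kg: float, rho_t: float) -> float:
    """Convert a perfusion rate from mL blood /min/kg tissue to 1/s.

    1/s = (mL/min/kg) x 1e-6 m³/mL / 60 s x rho_t kg/m³. The inverse
    conversion divides by the same factor, so the mapping round-trips.
    """
    return w_b_ml_min_kg * 1.0e-6 / 60.0 * rho_t


def thermal_properties(organ: str) -> TissueThermalProperties:
    """Thermal constants for one organ, perfusion converted to 1/s."""
    table = load_parameter_presets()["thermal_properties"]
    if organ not in table:
        raise KeyError(f"unknown organ {organ!r}")
    row = table[organ]
    return TissueThermalProperties(
        organ_name=organ,
        w_b=perfusion_rate_si(row["w_b"], row["rho_t"]),
        rho_t=row["rho_t"],
        k_t=row["k_t"],
        c_t=row["c_t"],
    )


def transport_defaults(region: Region) -> TransportParameters:
    """Default transport parameters for the tumor or normal region."""
    if region not in ("tumor", "normal"):
        raise ValueError("region must be 'tumor' or 'normal'")
    row = load_parameter_presets()["transport"][region]
    return TransportParameters(region=region, **{k: float(v) for k, v in row.items()})


def pk_rate_constants() -> PKRateConstants:
    row = load_parameter_presets()["pk_rate_constants"]
    return PKRateConstants(**{k: float(v) for k, v in row.items()})


def cytotoxicity_table() -> CytotoxicityTable:
    row = load_parameter_presets()["cytotoxicity"]
    return CytotoxicityTable(
        temperatures=tuple(row["temperatures_c"]),
        ic50=tuple(row["ic50_um"]),
        ter=tuple(row["ter"]),
    )


# ---------------------------------------------------------------------------
# operations


def ic50_at_temperature(table: CytotoxicityTable, T: float) -> float:
    """Oxaliplatin IC50 [µM] at temperature ``T`` [°C].

    Piecewise-linear interpolation on the measured grid; temperatures
    outside 37–43 °C clamp to the nearest grid endpoint. Full precision
    is returned; round for display.
    """
    if not np.isfinite(T):
        raise ValueError("temperature must be finite")
    return float(np.interp(T, table.temperatures, table.ic50))


def washout_factor(T: float) -> float:
    """Hyperthermic washout reduction factor y(T), dimensionless.

    Empirical linear fit to the oxaliplatin concentration–temperature
    profile: y = −0.04715·T[°C] + 2.744555, clamped to be non-negative.
    Equals 1 at 37 °C (to 5e-6) and ≈0.717 at 43 °C: mild hyperthermia
    reduces transvascular drug washout.
    """
    if not np.isfinite(T):
        raise ValueError("temperature must be finite")
    return max(0.0, -0.04715 * T + 2.744555)


def apply_bevacizumab(base: TransportParameters, dose: float) -> TransportParameters:
    """Vascular-normalization transform at a bevacizumab dose [mg/kg].

    0.5 mg/kg: microvascular density −45 % (S/V ×0.55), hydraulic
    conductivity and permeability unchanged, IFP stays 1.4 kPa.
    5 mg/kg: MVD −65 % (S/V ×0.35), L_p and P_c ×0.78 (−22 % vascular
    leakage), IFP lowered to 0.25 kPa. Dose 0 is the identity. Pure
    function; host ("normal") parameters are never transformed.
    """
    if dose == 0:
        return base
    if base.region != "tumor":
        raise ValueError("bevacizumab transform applies to tumor parameters only")
    if dose == 0.5:
        return dataclasses.replace(base, S_over_V=base.S_over_V * 0.55, P_i=1400.0)
    if dose == 5:
        return dataclasses.replace(
            base,
            S_over_V=base.S_over_V * 0.35,
            L_p=base.L_p * 0.78,
            P_c=base.P_c * 0.78,
            P_i=250.0,
        )
    raise ValueError(f"unsupported bevacizumab dose {dose!r} (use 0, 0.5 or 5 mg/kg)")


def apply_stiffness(
    base: TransportParameters, collagen_density: Literal["low", "high"]
) -> TransportParameters:
    """Extracellular-matrix stiffness preset (collagen fiber density).

    High density (32 %) halves the effective diffusivity and uses the
    low microvascular-density preset S/V = 1.0e4 1/m; low density (4 %)
    keeps the default diffusivity with S/V = 2.0e4 1/m. Pure function
    of the shipped defaults, so the presets are mutually invertible.
    """
    if base.region != "tumor":
        raise ValueError("stiffness transform applies to tumor parameters only")
    defaults = transport_defaults("tumor")
    if collagen_density == "low":
        return dataclasses.replace(base, D=defaults.D, S_over_V=2.0e4)
    if collagen_density == "high":
        return dataclasses.replace(base, D=defaults.D * 0.5, S_over_V=1.0e4)
    raise ValueError(f"unknown collagen density {collagen_density!r}")
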