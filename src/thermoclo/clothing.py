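"""Clothing-microclimate physics: air gap, fabric, outer surface, evaporation.

A clothed segment exchanges heat with the environment through three stages:

1. skin -> inner fabric surface, across the air gap (ease allowance): still-
   air conduction or, above a Rayleigh-number threshold of 10^3, natural
   convection in a vertical enclosure (Catton's correlation), in parallel
   with surface-to-surface radiation;
2. inner -> outer fabric surface: conduction through the fabric's intrinsic
   resistance R_f;
3. outer surface -> environment: natural convection (quarter-power vertical-
   plate correlation) plus radiation to the mean radiant temperature.

Bare segments (head, hands, feet) lose sensible heat directly through a
combined coefficient h_t referenced to the operative temperature.
Evaporative loss at the skin uses the Lewis relation through the clothing's
vapour path; latent heat bypasses the dry clothing nodes.

All interfaces speak degC; radiant terms convert to kelvin internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

N_SEGMENTS = 16
CLO_SI = 0.155            # m2 K/W per clo
KELVIN = 273.15
RA_CONDUCTION_LIMIT = 1.0e3
RA_CORRELATION_LIMIT = 1.0e10

__all__ = [
    "Fabric", "Garment", "Environment", "AirProperties", "SurfaceCoefficients",
    "saturation_vapor_pressure", "clothing_area_factor", "total_insulation",
    "intrinsic_insulation", "clo_convert", "clo_invert",
    "evaporative_coefficient", "max_evaporation", "diffusion_loss",
    "skin_evaporation", "total_heat_transfer_coefficient",
    "sensible_exchange_bare", "operative_temperature", "rayleigh_number",
    "nusselt_enclosure", "gap_coefficient", "skin_to_inner_flux",
    "fabric_flux", "outer_convective_coefficient", "outer_to_env_flux",
    "clothing_derivatives", "radiant_exchange_factor",
    "CLO_SI", "RA_CONDUCTION_LIMIT",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AirProperties:
    """Physical properties of the gap/boundary air plus physical constants.

    Evaluated once at a fixed film temperature (default 300 K); the few-
    kelvin temperature spans here do not warrant per-step property updates.
    """

    k_a: float = 0.0263       # W/(m K)
    Pr: float = 0.707
    beta: float = 1.0 / 300.0  # 1/K
    alpha: float = 2.25e-5     # m2/s
    nu: float = 1.589e-5       # m2/s
    mu: float = 1.846e-5       # Pa s
    rho: float = 1.1614        # kg/m3
    c_p: float = 1007.0        # J/(kg K)
    g: float = 9.81            # m/s2
    sigma: float = 5.670374419e-8  # W/(m2 K^4)
    LR: float = 16.5           # Lewis ratio, K/kPa

    @property
    def C_nc(self) -> float:
        """Volumetric heat capacity of air, J/(m3 K)."""
        return self.rho * self.c_p

    @classmethod
    def standard(cls) -> "AirProperties":
        return cls()


@dataclass(frozen=True)
class Fabric:
    """Fabric thermal/vapour properties (defaults: the plain-cotton shirting
    of the reference experiment: 126 g/m2, 0.312 mm, 0.155 clo)."""

    fiber: str = "cotton"
    areal_density: float = 0.126        # kg/m2
    thickness: float = 0.312e-3         # m
    insulation_clo: float = 0.155       # clo
    i_cl: float = 0.34                  # vapour permeation efficiency
    specific_heat: float = 1300.0       # J/(kg K)
    emissivity: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 < self.i_cl <= 1.0):
            raise ValueError("vapour permeation efficiency must be in (0, 1]")
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError("fabric emissivity must be in (0, 1]")
        if self.insulation_clo <= 0.0 or self.areal_density <= 0.0:
            raise ValueError("fabric insulation and areal density must be positive")

    @property
    def R_f(self) -> float:
        """Intrinsic thermal resistance, m2 K/W."""
        return clo_invert(self.insulation_clo)

    def mass(self, A_cl: float) -> float:
        """Fabric mass covering a clothing area A_cl, kg."""
        return self.areal_density * A_cl


@dataclass
class Garment:
    """Per-segment air-gap thicknesses plus the fabric.

    ``gap`` is an array of 16 gap thicknesses in metres (entries on bare
    segments are ignored); ``f_cl`` the per-segment clothing area factors.
    """

    gap: np.ndarray
    fabric: Fabric
    f_cl: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.gap = np.asarray(self.gap, dtype=float)
        self.f_cl = np.asarray(self.f_cl, dtype=float)
        if self.gap.shape != (N_SEGMENTS,) or self.f_cl.shape != (N_SEGMENTS,):
            raise ValueError("gap and f_cl must have one entry per segment")
        if np.any(self.f_cl < 1.0):
            raise ValueError("clothing area factors must be >= 1")

    @classmethod
    def uniform(cls, gap_thickness: float, registry, fabric: Fabric | None = None,
                name: str = "custom") -> "Garment":
        """Apply one average gap thickness to every clothed segment."""
        if gap_thickness <= 0.0:
            raise ValueError("gap thickness must be positive")
        fabric = fabric or Fabric()
        gap = np.where(registry.clothed, gap_thickness, np.nan)
        f_cl = registry.A_cl / registry.A_n
        return cls(gap=gap, fabric=fabric, f_cl=f_cl, name=name)

    def validate_clothed(self, clothed_mask: np.ndarray) -> None:
        g = self.gap[clothed_mask]
        if np.any(~np.isfinite(g)) or np.any(g <= 0.0):
            raise ValueError("air-gap thickness must be positive on clothed segments")


@dataclass(frozen=True)
class Environment:
    """Ambient conditions: temperatures degC, air speed m/s, RH fraction."""

    T_a: float = 25.0
    T_r: float = 20.0
    v: float = 0.25
    RH: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.RH <= 1.0):
            raise ValueError("relative humidity must be a fraction in [0, 1]")
        if self.v < 0.0:
            raise ValueError("air speed must be non-negative")

    @property
    def p_a(self) -> float:
        """Ambient vapour pressure, kPa (<= saturation by construction)."""
        return self.RH * saturation_vapor_pressure(self.T_a)


@dataclass
class SurfaceCoefficients:
    """Per-segment skin/outer-surface transfer coefficients, W/(m2 K) (h_e in
    W/(m2 kPa)).  ``h_c``/``h_r`` are inputs (manikin-style defaults); the
    rest are derived per state."""

    h_c: np.ndarray
    h_r: np.ndarray
    skin_emissivity: float = 0.95

    def __post_init__(self) -> None:
        self.h_c = np.asarray(self.h_c, dtype=float)
        self.h_r = np.asarray(self.h_r, dtype=float)
        if self.h_c.shape != (N_SEGMENTS,) or self.h_r.shape != (N_SEGMENTS,):
            raise ValueError("h_c and h_r must have one entry per segment")
        if np.any(self.h_c < 0) or np.any(self.h_r < 0):
            raise ValueError("surface coefficients must be non-negative")
        if not (0.0 < self.skin_emissivity <= 1.0):
            raise ValueError("skin emissivity must be in (0, 1]")


# ---------------------------------------------------------------------------
# psychrometrics and insulation arithmetic
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(T):
    """Saturated water-vapour pressure over liquid water, kPa.

    Magnus-type correlation p = 0.61078 exp(17.27 T / (T + 237.3)), T in
    degC; within ~1% of steam-table values over the physiological range
    (and at the boiling point).  Valid for -20 <= T <= 110 degC.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < -20.0) or np.any(T > 110.0):
        raise ValueError("saturation_vapor_pressure: T outside [-20, 110] degC")
    out = 0.61078 * np.exp(17.27 * T / (T + 237.3))
    return float(out) if out.ndim == 0 else out


def clothing_area_factor(A_cl, A_n):
    """f_cl = A_cl / A_n, the clothed-to-nude area ratio."""
    A_cl = np.asarray(A_cl, dtype=float)
    A_n = np.asarray(A_n, dtype=float)
    if np.any(A_cl <= 0.0) or np.any(A_n <= 0.0):
        raise ValueError("areas must be positive")
    out = A_cl / A_n
    return float(out) if out.ndim == 0 else out


def total_insulation(T_skin: float, T_ambient: float, dry_heat_loss: float) -> float:
    """Total dry insulation I_T = (T_skin - T_ambient)/q, m2 K/W."""
    if dry_heat_loss <= 0.0:
        raise ValueError("dry heat loss must be positive")
    return (T_skin - T_ambient) / dry_heat_loss


def intrinsic_insulation(I_T: float, I_a: float, f_cl: float) -> float:
    """Intrinsic clothing insulation I_cl = I_T - I_a/f_cl, m2 K/W."""
    if f_cl < 1.0:
        raise ValueError("clothing area factor must be >= 1")
    return I_T - I_a / f_cl


def clo_convert(I_si: float) -> float:
    """m2 K/W -> clo (1 clo = 0.155 m2 K/W)."""
    return I_si / CLO_SI


def clo_invert(I_clo: float) -> float:
    """clo -> m2 K/W; exact inverse of :func:`clo_convert`."""
    return I_clo * CLO_SI


# ---------------------------------------------------------------------------
# evaporation
# ---------------------------------------------------------------------------

def evaporative_coefficient(I_cl_clo, i_cl, h_c, f_cl, LR: float = 16.5):
    """Skin-to-environment evaporative coefficient, W/(m2 kPa).

    Serial vapour resistance through clothing and the outer air layer:
    h_e = LR i_cl / (0.155 I_cl + i_cl/(h_c f_cl)).  Limits: I_cl -> 0
    recovers the bare-skin Lewis relation LR h_c f_cl; i_cl -> 0 gives an
    impermeable ensemble (h_e -> 0).
    """
    I_cl_clo = np.asarray(I_cl_clo, dtype=float)
    denom = CLO_SI * I_cl_clo + np.divide(
        i_cl, np.asarray(h_c, dtype=float) * f_cl)
    if np.any(denom <= 0.0):
        raise ValueError("degenerate evaporative resistance (zero denominator)")
    out = LR * i_cl / denom
    return float(out) if out.ndim == 0 else out


def max_evaporation(h_e, T_skin, p_a, A_n):
    """E_max = h_e (p_sat(T_skin) - p_a) A_n, W, floored at 0."""
    out = np.maximum(
        np.asarray(h_e, dtype=float)
        * (saturation_vapor_pressure(T_skin) - p_a)
        * np.asarray(A_n, dtype=float), 0.0)
    return float(out) if out.ndim == 0 else out


def diffusion_loss(E_sw, E_max):
    """Skin water-vapour diffusion E_b = 0.06 (1 - E_sw/E_max) E_max, W.

    Diffusion wets 6% of the maximum evaporative capacity of the non-sweat-
    wetted skin fraction; 0 when E_max = 0.
    """
    E_sw = np.asarray(E_sw, dtype=float)
    E_max = np.asarray(E_max, dtype=float)
    if np.any(E_sw < -1e-12) or np.any(E_sw > E_max + 1e-9):
        raise ValueError("require 0 <= E_sw <= E_max")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(E_max > 0.0, E_sw / np.where(E_max > 0.0, E_max, 1.0), 1.0)
    out = 0.06 * (1.0 - frac) * E_max
    return float(out) if out.ndim == 0 else out


def skin_evaporation(E_sw, E_max):
    """Total evaporative loss E = E_b + E_sw, W; never exceeds E_max."""
    out = diffusion_loss(E_sw, E_max) + np.asarray(E_sw, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# bare-segment sensible path
# ---------------------------------------------------------------------------

def total_heat_transfer_coefficient(I_cl_clo, h_c, h_r, f_cl):
    """Total skin-to-environment coefficient h_t, W/(m2 K).

    Serial resistance h_t = 1/(0.155 I_cl + 1/((h_c + h_r) f_cl)); the nude
    limit (I_cl = 0, f_cl = 1) is h_c + h_r.
    """
    h = (np.asarray(h_c, dtype=float) + np.asarray(h_r, dtype=float)) * f_cl
    if np.any(h <= 0.0):
        raise ValueError("h_c + h_r must be positive")
    out = 1.0 / (CLO_SI * np.asarray(I_cl_clo, dtype=float) + 1.0 / h)
    return float(out) if out.ndim == 0 else out


def sensible_exchange_bare(T_skin, t_o, h_t, A_n):
    """Sensible skin-environment exchange Q_t = h_t (T_skin - t_o) A_n, W."""
    out = (np.asarray(h_t, dtype=float) * (np.asarray(T_skin, dtype=float) - t_o)
           * np.asarray(A_n, dtype=float))
    return float(out) if out.ndim == 0 else out


def operative_temperature(T_a, T_r, h_c, h_r):
    """Convection/radiation-weighted mean of air and mean radiant temperature."""
    h_c = np.asarray(h_c, dtype=float)
    h_r = np.asarray(h_r, dtype=float)
    if np.any(h_c + h_r <= 0.0):
        raise ValueError("h_c + h_r must be positive")
    out = (h_c * T_a + h_r * T_r) / (h_c + h_r)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# air-gap natural convection and radiation
# ---------------------------------------------------------------------------

def rayleigh_number(dT, L_char, air: AirProperties | None = None):
    """Gap Rayleigh number Ra = g beta max(dT, 0) L^3/(alpha nu)."""
    air = air or AirProperties.standard()
    L = np.asarray(L_char, dtype=float)
    if np.any(L <= 0.0):
        raise ValueError("characteristic length must be positive")
    out = (air.g * air.beta * np.maximum(np.asarray(dT, dtype=float), 0.0)
           * L ** 3 / (air.alpha * air.nu))
    return float(out) if out.ndim == 0 else out


def nusselt_enclosure(Ra, Pr, H_over_L):
    """Nusselt number for a vertical air enclosure.

    Nu = 1 (pure conduction) for Ra <= 10^3; for 10^3 < Ra <= 10^10 Catton's
    correlation Nu = 0.22 (Pr/(0.2 + Pr) Ra)^0.28 (H/L)^(-1/4), floored at 1
    so convection never predicts less transfer than conduction.
    """
    Ra = np.asarray(Ra, dtype=float)
    if np.any(Ra < 0.0):
        raise ValueError("Rayleigh number must be non-negative")
    if np.any(Ra > RA_CORRELATION_LIMIT):
        raise ValueError("Rayleigh number above correlation range (10^10)")
    if Pr <= 0.0 or np.any(np.asarray(H_over_L, dtype=float) <= 0.0):
        raise ValueError("Pr and H/L must be positive")
    branch = 0.22 * (Pr / (0.2 + Pr) * Ra) ** 0.28 * np.asarray(
        H_over_L, dtype=float) ** -0.25
    out = np.where(Ra <= RA_CONDUCTION_LIMIT, 1.0, np.maximum(branch, 1.0))
    return float(out) if out.ndim == 0 else out


def gap_coefficient(Nu, k_a, L_nc):
    """Air-gap heat-transfer coefficient h_nc = Nu k_a / L_nc, W/(m2 K)."""
    L = np.asarray(L_nc, dtype=float)
    if np.any(L <= 0.0):
        raise ValueError("gap thickness must be positive")
    out = np.asarray(Nu, dtype=float) * k_a / L
    return float(out) if out.ndim == 0 else out


def radiant_exchange_factor(e_n, e_f):
    """Parallel-plate emissivity coupling 1/(1/e_n + 1/e_f - 1)."""
    if not (0.0 < e_n <= 1.0 and 0.0 < e_f <= 1.0):
        raise ValueError("emissivities must be in (0, 1]")
    return 1.0 / (1.0 / e_n + 1.0 / e_f - 1.0)


def skin_to_inner_flux(T_skin, T_inner, h_nc, A_n, e_n=0.95, e_f=0.90,
                       sigma=5.670374419e-8, split=False):
    """Total sensible skin -> inner-clothing flux across the gap, W.

    Q_nc = A_n [h_nc (T_skin - T_inner) + sigma (T_skin^4 - T_inner^4) F],
    with kelvin in the radiant term and F the parallel-plate emissivity
    factor.  ``split=True`` returns (conductive/convective, radiant) parts.
    """
    A_n = np.asarray(A_n, dtype=float)
    Ts = np.asarray(T_skin, dtype=float)
    Ti = np.asarray(T_inner, dtype=float)
    conv = A_n * np.asarray(h_nc, dtype=float) * (Ts - Ti)
    F = radiant_exchange_factor(e_n, e_f)
    rad = A_n * sigma * ((Ts + KELVIN) ** 4 - (Ti + KELVIN) ** 4) * F
    if split:
        return conv, rad
    out = conv + rad
    return float(out) if np.ndim(out) == 0 else out


def fabric_flux(T_inner, T_outer, R_f, A_cl):
    """Conduction through the fabric Q_f = A_cl (T5 - T6)/R_f, W."""
    if R_f <= 0.0:
        raise ValueError("fabric resistance must be positive")
    out = (np.asarray(A_cl, dtype=float)
           * (np.asarray(T_inner, dtype=float) - np.asarray(T_outer, dtype=float))
           / R_f)
    return float(out) if np.ndim(out) == 0 else out


def outer_convective_coefficient(T_outer, T_a, H, air: AirProperties | None = None):
    """Natural-convection coefficient at the outer clothing surface, W/(m2 K).

    Vertical-plate quarter-power law Nu = 0.518 (c_p rho^2 g beta |dT| H^3 /
    (k_a mu))^(1/4), h_a = Nu k_a / H; zero at dT = 0.
    """
    air = air or AirProperties.standard()
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0.0):
        raise ValueError("segment height must be positive")
    dT = np.abs(np.asarray(T_outer, dtype=float) - T_a)
    gr_like = (air.c_p * air.rho ** 2 * air.g * air.beta * dT * H ** 3
               / (air.k_a * air.mu))
    out = 0.518 * gr_like ** 0.25 * air.k_a / H
    return float(out) if np.ndim(out) == 0 else out


def outer_to_env_flux(T_outer, T_a, T_r, h_a, e_f, sigma, A_cl, split=False):
    """Outer-surface loss Q_a = A_cl [h_a (T6 - T_a) + sigma e_f (T6^4 - T_r^4)], W.

    Convection to the air temperature; radiation to the mean radiant
    temperature (kelvin internally).
    """
    A_cl = np.asarray(A_cl, dtype=float)
    To = np.asarray(T_outer, dtype=float)
    conv = A_cl * np.asarray(h_a, dtype=float) * (To - T_a)
    rad = A_cl * sigma * e_f * ((To + KELVIN) ** 4 - (T_r + KELVIN) ** 4)
    if split:
        return conv, rad
    out = conv + rad
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# clothing-layer balances
# ---------------------------------------------------------------------------

def clothing_derivatives(state, garment: Garment, env: Environment, registry,
                         air: AirProperties | None = None,
                         surface: SurfaceCoefficients | None = None):
    """d/dt of the inner (layer 5) and outer (layer 6) clothing temperatures.

    Inner (gap air film): A_n L_nc C_nc dT5/dt = Q_nc - Q_f.
    Outer (fabric shell): A_cl m_f c_f dT6/dt = Q_f - Q_a  (m_f per m2).
    Returns (dT5, dT6, diag) with K/s arrays over the 16 segments (NaN on
    bare segments) and a dict of the fluxes used.  Raises on a garment whose
    clothed segments lack a positive gap.
    """
    air = air or AirProperties.standard()
    e_n = surface.skin_emissivity if surface is not None else 0.95
    mask = registry.clothed
    garment.validate_clothed(mask)

    T4 = state.T[:, 3]
    T5 = state.T[:, 4]
    T6 = state.T[:, 5]
    L = garment.gap
    dT_gap = T4 - T5

    Ra = np.where(mask, rayleigh_number(np.where(mask, dT_gap, 0.0),
                                        np.where(mask, L, 1.0), air), 0.0)
    Nu = nusselt_enclosure(Ra, air.Pr, np.where(mask, registry.H / np.where(mask, L, 1.0), 1.0))
    h_nc = np.where(mask, gap_coefficient(Nu, air.k_a, np.where(mask, L, 1.0)), 0.0)

    conv, rad = skin_to_inner_flux(T4, T5, h_nc, registry.A_n, e_n,
                                   garment.fabric.emissivity, air.sigma, split=True)
    Q_nc = np.where(mask, conv + rad, 0.0)
    Q_f = np.where(mask, fabric_flux(T5, T6, garment.fabric.R_f, registry.A_cl), 0.0)
    h_a = outer_convective_coefficient(T6, env.T_a, registry.H, air)
    Q_a = np.where(mask, outer_to_env_flux(T6, env.T_a, env.T_r, h_a,
                                           garment.fabric.emissivity, air.sigma,
                                           registry.A_cl), 0.0)

    C_inner = registry.A_n * np.where(mask, L, np.nan) * air.C_nc          # J/K
    C_outer = registry.A_cl * garment.fabric.areal_density * garment.fabric.specific_heat
    dT5 = np.where(mask, (Q_nc - Q_f) / C_inner, np.nan)
    dT6 = np.where(mask, (Q_f - Q_a) / C_outer, np.nan)
    diag = {"Q_nc": Q_nc, "Q_nc_conv": np.where(mask, conv, 0.0),
            "Q_nc_rad": np.where(mask, rad, 0.0), "Q_f": Q_f, "Q_a": Q_a,
            "h_nc": h_nc, "h_a": np.where(mask, h_a, 0.0), "Ra": Ra, "Nu": Nu,
            "C_inner": C_inner, "C_outer": np.where(mask, C_outer, np.nan)}
    return dT5, dT6, diag
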