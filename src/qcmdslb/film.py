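"""Closed-form QCM-D film physics.

A quartz crystal oscillating in liquid reports two observables per overtone
``n``: the overtone-normalized frequency shift ``dF = F_n/n`` (Hz) and the
dissipation shift ``dD`` (dimensionless, reported here in units of 1e-6).
Because every trace is referenced to a baseline recorded in the same liquid,
the solvent (Kanazawa) terms of the film equations cancel and only the
film contribution remains.

For a rigid film the Sauerbrey relation applies::

    m_f = -C * dF,        C = 17.8 ng/cm^2/Hz at F0 = 5 MHz

and ``dD = 0``.  For a soft (viscoelastic) film with storage modulus G' and
loss modulus G'' the thin-film limit of the Voigt model gives::

    dF = -(m_f/C) * [1 - (2/rho_f) (eta_L/delta_L)^2 G'' / (G'^2 + G''^2)]
    dD =  (m_f/m_q) * (4/rho_f) (eta_L/delta_L)^2 G'  / (G'^2 + G''^2)

where ``delta_L = sqrt(eta_L / (pi n F0 rho_L))`` is the acoustic decay
length in the liquid.  The overtone dependence enters only through
``delta_L(n)``: rigid films look identical on every overtone, soft films
split across overtones — the experimental fingerprint separating a
supported lipid bilayer (SLB) from a supported layer of intact vesicles.

Unit conventions (package-wide): dF in Hz (normalized), dD in 1e-6, areal
mass in ng/cm^2, thickness in nm, density in g/cm^3, moduli in Pa, time in
minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

# unit conversions
_NGCM2_TO_KGM2 = 1e-8     # 1 ng/cm^2 = 1e-8 kg/m^2
_GCM3_TO_KGM3 = 1e3
_M_TO_NM = 1e9
# 1 ng/cm^2 of material at 1 g/cm^3 is a 0.01 nm slab
_NM_PER_NGCM2_AT_UNIT_RHO = 0.01


@dataclass(frozen=True)
class PhysicalConstants:
    """Crystal and liquid properties.

    Defaults are a 5 MHz crystal (Sauerbrey coefficient 17.8 ng/cm^2/Hz)
    immersed in water at 23 C.  The areal mass of the quartz crystal is not
    independent: m_q = C * F0 (0.89 kg/m^2 for the defaults).
    """

    f0_hz: float = 5.0e6
    sauerbrey_c: float = 17.8       # ng/cm^2/Hz
    eta_l: float = 9.32e-4          # Pa s, water 23 C
    rho_l: float = 0.9975           # g/cm^3, water 23 C
    rho_film: float = 1.0           # g/cm^3

    def __post_init__(self) -> None:
        for name in ("f0_hz", "sauerbrey_c", "eta_l", "rho_l", "rho_film"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def m_q_ng_cm2(self) -> float:
        """Areal mass of the quartz crystal, ng/cm^2 (= C * F0)."""
        return self.sauerbrey_c * self.f0_hz

    @property
    def m_q_kg_m2(self) -> float:
        return self.m_q_ng_cm2 * _NGCM2_TO_KGM2


#: water at 23 C (default experimental temperature)
WATER_23C = PhysicalConstants()
#: water at 25 C
WATER_25C = PhysicalConstants(eta_l=8.9e-4, rho_l=0.997)
#: water at 35 C (the elevated-temperature runs)
WATER_35C = PhysicalConstants(eta_l=7.19e-4, rho_l=0.9940)


@dataclass(frozen=True)
class ViscoelasticFilm:
    """A homogeneous viscoelastic film: areal mass, density, Voigt moduli."""

    m_f: float                      # ng/cm^2
    rho_f: float = 1.0              # g/cm^3
    g_storage: float = 1e6         # Pa
    g_loss: float = 0.0            # Pa

    def __post_init__(self) -> None:
        if self.m_f < 0:
            raise InvalidParameterError("m_f must be >= 0")
        if not self.rho_f > 0:
            raise InvalidParameterError("rho_f must be > 0")
        if not self.g_storage > 0:
            raise InvalidParameterError("g_storage must be > 0")
        if self.g_loss < 0:
            raise InvalidParameterError("g_loss must be >= 0")


def sauerbrey_mass(df_hz: float, constants: PhysicalConstants = WATER_23C) -> float:
    """Areal mass (ng/cm^2) of a rigid film from a normalized frequency shift.

    m = -C * dF; a negative shift (mass added) yields a positive mass, and a
    positive shift yields a negative mass, signaling mass loss.
    """
    return -constants.sauerbrey_c * df_hz


def sauerbrey_thickness(
    df_hz: float, rho: float = 1.0, constants: PhysicalConstants = WATER_23C
) -> float:
    """Rigid-film thickness h = -C dF / rho, in nm.

    ``rho`` is the film density in g/cm^3.
    """
    if not rho > 0:
        raise InvalidParameterError("rho must be > 0")
    return sauerbrey_mass(df_hz, constants) / rho * _NM_PER_NGCM2_AT_UNIT_RHO


def bilayer_thickness_corrected(
    df_asymp_hz: float,
    hydration_mass: float = 102.0,
    rho: float = 1.0,
    constants: PhysicalConstants = WATER_23C,
) -> tuple[float, bool]:
    """Bilayer thickness after subtracting the substrate hydration layer.

    The Sauerbrey mass at the asymptotic shift includes the ~102 ng/cm^2
    water layer between substrate and bilayer; subtracting it leaves the
    lipid bilayer itself.  Returns ``(thickness_nm, clipped)`` where
    ``clipped`` is True if the subtraction went negative (thickness then 0).
    """
    if not rho > 0:
        raise InvalidParameterError("rho must be > 0")
    net = sauerbrey_mass(df_asymp_hz, constants) - hydration_mass
    if net < 0:
        return 0.0, True
    return net / rho * _NM_PER_NGCM2_AT_UNIT_RHO, False


def decay_length(n: int, constants: PhysicalConstants = WATER_23C) -> float:
    """Acoustic decay length delta_L in the liquid at overtone n, in nm.

    delta_L = sqrt(eta_L / (pi n F0 rho_L)); strictly decreasing in n, so
    higher overtones probe closer to the crystal surface.
    """
    if n < 1:
        raise InvalidParameterError("overtone number must be >= 1")
    rho_si = constants.rho_l * _GCM3_TO_KGM3
    delta_m = math.sqrt(constants.eta_l / (math.pi * n * constants.f0_hz * rho_si))
    return delta_m * _M_TO_NM


def rigid_film_response(
    m_f: float, n: int = 3, constants: PhysicalConstants = WATER_23C
) -> tuple[float, float]:
    """(dF, dD) of a rigid film: the pure Sauerbrey limit.

    Normalized dF = -m_f/C is overtone-independent and dD = 0; ``n`` is
    accepted for interface symmetry with :func:`viscoelastic_film_response`.
    """
    if m_f < 0:
        raise InvalidParameterError("m_f must be >= 0")
    decay_length(n, constants)  # validates n
    return -m_f / constants.sauerbrey_c, 0.0


def viscoelastic_film_response(
    film: ViscoelasticFilm, n: int = 3, constants: PhysicalConstants = WATER_23C
) -> tuple[float, float]:
    """(dF in Hz, dD in 1e-6) of a viscoelastic film at overtone n.

    Thin-film Voigt limit with the solvent terms differenced away.  As
    G' -> infinity the output converges to :func:`rigid_film_response`;
    softer films show positive dD and an overtone-dependent dF.
    """
    if film.g_storage == 0 and film.g_loss == 0:
        raise InvalidParameterError("G' = G'' = 0: loss fraction undefined")
    delta_m = decay_length(n, constants) / _M_TO_NM
    shear_sq = (constants.eta_l / delta_m) ** 2          # Pa^2 s^2 / m^2
    rho_f_si = film.rho_f * _GCM3_TO_KGM3
    denom = film.g_storage**2 + film.g_loss**2
    corr = (2.0 / rho_f_si) * shear_sq * film.g_loss / denom
    df = -(film.m_f / constants.sauerbrey_c) * (1.0 - corr)
    m_f_si = film.m_f * _NGCM2_TO_KGM2
    dd = (m_f_si / constants.m_q_kg_m2) * (4.0 / rho_f_si) * shear_sq * film.g_storage / denom
    return df, dd * 1e6


def dissipation_from_moduli(g_storage: float, g_loss: float) -> float:
    """Dissipation factor D = G'' / (2 pi G'), dimensionless."""
    if not g_storage > 0:
        raise InvalidParameterError("g_storage must be > 0")
    return g_loss / (2.0 * math.pi * g_storage)
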