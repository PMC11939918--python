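"""Synthetic multi-overtone QCM-D traces from a kinetic vesicle-fusion model.

Surface state is tracked as two coverages: intact vesicles ``theta_v`` and
bilayer ``theta_b``.  Vesicles adsorb Langmuir-style while lipid flows;
rupture is gated by a critical total coverage (vesicle-vesicle stress is
needed to break PC-type vesicles on silica) and converts vesicle coverage to
bilayer coverage one-for-one::

    d theta_v/dt = k_ads (1 - theta_v - theta_b) [t < t_flow_end]
                   - k_rup theta_v [theta_v + theta_b >= theta_crit, cap]
    d theta_b/dt = + k_rup theta_v [gated as above]

The cap limits cumulative rupture to ``rupture_fraction`` of cumulative
adsorption, which produces partial-SLB end states.

The acoustic response composes the film physics: the intact-vesicle layer
(mass ``theta_v * m_vesicle_sat``, lipid plus trapped water) is rendered
through the viscoelastic film model and the bilayer (``theta_b * m_bilayer``)
through the rigid Sauerbrey model.  The effective vesicle-layer moduli
stiffen with vesicle crowding, ``G_eff = G0 / (1 - theta_v)``: a sparse
layer of wobbly vesicles dissipates strongly per unit mass, a close-packed
one approaches a rigid slab.  A direct consequence is that during the
adsorption phase the ratio dD/dF is linear in dF with a common
zero-dissipation intercept at ``-m_vesicle_sat / C`` for every overtone —
the geometry the deformed-height extrapolation relies on — so the
generator's ground-truth deformed-vesicle height is ``m_vesicle_sat / rho``.

Presets are calibrated against the magnitudes of the study's summary table
(e.g. ``dopc_fig2`` targets dF_min ~ -56.5 Hz, dF_asymp ~ -25.1 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError, UnknownPresetError
from .film import (
    PhysicalConstants,
    ViscoelasticFilm,
    WATER_23C,
    rigid_film_response,
    viscoelastic_film_response,
)
from .trace import QcmdTrace

_SUBSTEPS = 10          # internal Euler substeps per sampling interval
_CROWDING_FLOOR = 1e-3  # keeps the stiffening factor finite at full coverage


@dataclass(frozen=True)
class KineticParams:
    """Rates of the two-compartment surface kinetics (times in minutes)."""

    k_ads: float            # adsorption rate constant, 1/min
    theta_crit: float       # critical coverage triggering rupture
    k_rup: float            # rupture rate constant, 1/min
    rupture_fraction: float = 1.0   # max fraction of adsorbed vesicles that rupture
    t_flow_end: float = math.inf    # lipid-flow stop, min after flow start

    def __post_init__(self) -> None:
        if self.k_ads < 0 or self.k_rup < 0:
            raise InvalidParameterError("rates must be >= 0")
        if not (0.0 < self.theta_crit <= 1.0):
            raise InvalidParameterError("theta_crit must be in (0, 1]")
        if not (0.0 <= self.rupture_fraction <= 1.0):
            raise InvalidParameterError("rupture_fraction must be in [0, 1]")


@dataclass(frozen=True)
class FilmComposition:
    """Acoustic masses and moduli of the two surface species.

    ``m_vesicle_sat`` is the areal mass of a saturated intact-vesicle layer
    including intra- and inter-vesicle water (the two are lumped), so it
    also fixes the deformed vesicle height m_vesicle_sat / rho.
    """

    m_vesicle_sat: float          # ng/cm^2
    m_bilayer: float              # ng/cm^2 (bilayer + hydration layer)
    g_storage_vesicle: float = 1.0e6   # Pa
    g_loss_vesicle: float = 3.0e5      # Pa
    rho_f: float = 1.0            # g/cm^3

    def __post_init__(self) -> None:
        if not (self.m_vesicle_sat > self.m_bilayer > 0):
            raise InvalidParameterError(
                "need m_vesicle_sat > m_bilayer > 0 (water-filled vesicles "
                "are heavier than the final bilayer)"
            )
        if not self.g_storage_vesicle > 0 or self.g_loss_vesicle < 0:
            raise InvalidParameterError("vesicle moduli out of range")


@dataclass(frozen=True)
class SimulationConfig:
    kinetics: KineticParams
    film: FilmComposition
    overtones: tuple[int, ...] = (3, 7, 11)
    dt: float = 0.02              # min
    duration: float = 13.0        # min
    lipid_start: float = 1.0      # min of pre-flow baseline in the trace
    noise_sd_f: float = 0.2       # Hz
    noise_sd_d: float = 0.05      # 1e-6 units
    seed: int = 0
    constants: PhysicalConstants = WATER_23C

    def __post_init__(self) -> None:
        if not self.overtones:
            raise InvalidParameterError("overtone list must not be empty")
        if not self.dt > 0 or not self.duration > self.dt:
            raise InvalidParameterError("need dt > 0 and duration > dt")
        if self.noise_sd_f < 0 or self.noise_sd_d < 0:
            raise InvalidParameterError("noise standard deviations must be >= 0")


def simulate_coverage(
    kinetics: KineticParams, time: np.ndarray, substeps: int = _SUBSTEPS
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the coverage ODEs on ``time`` (minutes from flow start).

    Negative times are allowed (pre-flow baseline) and leave the surface
    empty.  Returns ``(theta_v, theta_b)`` sampled at ``time``.
    """
    t = np.asarray(time, dtype=float)
    if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
        raise InvalidParameterError("time grid must be 1-D strictly increasing")
    theta_v = np.zeros_like(t)
    theta_b = np.zeros_like(t)
    tv = tb = 0.0
    cum_ads = cum_rup = 0.0
    triggered = False
    for i in range(1, len(t)):
        h = (t[i] - t[i - 1]) / substeps
        tt = t[i - 1]
        for _ in range(substeps):
            flowing = 0.0 <= tt < kinetics.t_flow_end
            ads = kinetics.k_ads * (1.0 - tv - tb) if flowing else 0.0
            if tv + tb >= kinetics.theta_crit:
                triggered = True
            rup = kinetics.k_rup * tv if triggered else 0.0
            d_ads = min(ads * h, max(0.0, 1.0 - tv - tb))
            d_rup = rup * h
            # at most rupture_fraction of everything ever adsorbed may rupture
            allowed = kinetics.rupture_fraction * (cum_ads + d_ads) - cum_rup
            d_rup = min(d_rup, max(0.0, allowed), tv + d_ads)
            tv = tv + d_ads - d_rup
            tb = tb + d_rup
            cum_ads += d_ads
            cum_rup += d_rup
            tt += h
        theta_v[i] = tv
        theta_b[i] = tb
    return theta_v, theta_b


def _crowding_stiffened_film(
    m_v: float, theta_v: float, film: FilmComposition
) -> ViscoelasticFilm:
    stiffen = 1.0 / max(1.0 - theta_v, _CROWDING_FLOOR)
    return ViscoelasticFilm(
        m_f=m_v,
        rho_f=film.rho_f,
        g_storage=film.g_storage_vesicle * stiffen,
        g_loss=film.g_loss_vesicle * stiffen,
    )


def noise_free_response(
    config: SimulationConfig,
) -> tuple[np.ndarray, dict[int, np.ndarray], dict[int, np.ndarray], np.ndarray, np.ndarray]:
    """Deterministic part of the simulated trace.

    Returns ``(time, df, dd, theta_v, theta_b)`` with time in trace
    coordinates (0 at the start of the recording, flow starts at
    ``lipid_start``).
    """
    n_samples = int(round(config.duration / config.dt)) + 1
    time = np.arange(n_samples) * config.dt
    theta_v, theta_b = simulate_coverage(config.kinetics, time - config.lipid_start)
    df: dict[int, np.ndarray] = {n: np.zeros(n_samples) for n in config.overtones}
    dd: dict[int, np.ndarray] = {n: np.zeros(n_samples) for n in config.overtones}
    for i in range(n_samples):
        m_v = theta_v[i] * config.film.m_vesicle_sat
        m_b = theta_b[i] * config.film.m_bilayer
        for n in config.overtones:
            f_b, d_b = rigid_film_response(m_b, n, config.constants)
            if m_v > 0:
                ves = _crowding_stiffened_film(m_v, theta_v[i], config.film)
                f_v, d_v = viscoelastic_film_response(ves, n, config.constants)
            else:
                f_v = d_v = 0.0
            df[n][i] = f_v + f_b
            dd[n][i] = d_v + d_b
    return time, df, dd, theta_v, theta_b


def simulate_trace(config: SimulationConfig) -> QcmdTrace:
    """Simulate a trace: noise-free response plus i.i.d. Gaussian noise.

    Deterministic for a fixed ``config.seed``.
    """
    trace, _ = simulate_with_truth(config)
    return trace


def simulate_with_truth(config: SimulationConfig) -> tuple[QcmdTrace, dict]:
    """Simulate and also return generator ground truth for validation.

    The truth dict carries the coverage trajectories, the noise-free
    per-overtone extrema/asymptotes, and the true deformed height
    ``m_vesicle_sat / rho`` (nm).
    """
    time, df0, dd0, theta_v, theta_b = noise_free_response(config)
    rng = np.random.default_rng(config.seed)
    df = {}
    dd = {}
    for n in config.overtones:
        df[n] = df0[n] + rng.normal(0.0, config.noise_sd_f, len(time))
        dd[n] = dd0[n] + rng.normal(0.0, config.noise_sd_d, len(time))
    flow_end = config.lipid_start + config.kinetics.t_flow_end
    events = (
        ("lipid_start", config.lipid_start),
        ("lipid_end", flow_end),
        ("rinse", flow_end),
    )
    trace = QcmdTrace(
        time=time, df=df, dd=dd, events=events,
        baseline_window=(max(0.0, config.lipid_start - 1.0), config.lipid_start),
    )
    truth = {
        "theta_v": theta_v,
        "theta_b": theta_b,
        "df_noise_free": df0,
        "dd_noise_free": dd0,
        "df_min": {n: float(df0[n].min()) for n in config.overtones},
        "t_df_min": {
            n: float(time[int(np.argmin(df0[n]))] - config.lipid_start)
            for n in config.overtones
        },
        "df_final": {n: float(df0[n][-1]) for n in config.overtones},
        "dd_max": {n: float(dd0[n].max()) for n in config.overtones},
        "dd_final": {n: float(dd0[n][-1]) for n in config.overtones},
        "h_true_nm": config.film.m_vesicle_sat / config.film.rho_f * 0.01,
        "m_vesicle_sat": config.film.m_vesicle_sat,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# presets

def _preset_configs() -> dict[str, SimulationConfig]:
    return {
        # single-component DOPC forming a complete SLB; calibrated to the
        # summary-table row with t_ads 2.1 min, dF_min -56.5 Hz,
        # dF_asymp -25.1 Hz and a -113 Hz extrapolation intercept (h 20.1 nm).
        "dopc_fig2": SimulationConfig(
            kinetics=KineticParams(
                k_ads=0.36, theta_crit=0.53, k_rup=1.9,
                rupture_fraction=1.0, t_flow_end=6.5,
            ),
            film=FilmComposition(
                m_vesicle_sat=2011.0, m_bilayer=494.0,
                g_storage_vesicle=1.0e6, g_loss_vesicle=3.0e5,
            ),
            duration=13.0, seed=1103,
        ),
        # 5-component mixture with hyperosmotic dilution buffer: complete,
        # rigid SLB ending near -30 Hz with near-zero dissipation.
        "slb": SimulationConfig(
            kinetics=KineticParams(
                k_ads=0.55, theta_crit=0.45, k_rup=2.2,
                rupture_fraction=1.0, t_flow_end=6.5,
            ),
            film=FilmComposition(
                m_vesicle_sat=1940.0, m_bilayer=545.0,
                g_storage_vesicle=1.1e6, g_loss_vesicle=3.3e5,
            ),
            duration=13.0, seed=1106,
        ),
        # small vesicles, isosmotic: substantial but incomplete rupture,
        # soft final film near -43 Hz with dissipation ~2.4e-6.
        "partial": SimulationConfig(
            kinetics=KineticParams(
                k_ads=0.28, theta_crit=0.52, k_rup=1.2,
                rupture_fraction=0.82, t_flow_end=8.0,
            ),
            film=FilmComposition(
                m_vesicle_sat=2520.0, m_bilayer=500.0,
                g_storage_vesicle=6.9e5, g_loss_vesicle=2.1e5,
            ),
            duration=18.0, seed=1109,
        ),
        # phosphate buffer, no osmotic stress: vesicles never rupture and a
        # soft supported-vesicle layer plateaus near -95 Hz, dD ~ 17e-6.
        "slv": SimulationConfig(
            kinetics=KineticParams(
                k_ads=0.082, theta_crit=1.0, k_rup=0.0,
                rupture_fraction=0.0, t_flow_end=15.0,
            ),
            film=FilmComposition(
                m_vesicle_sat=2760.0, m_bilayer=450.0,
                g_storage_vesicle=1.39e5, g_loss_vesicle=4.2e4,
            ),
            duration=22.0, seed=1112,
        ),
    }


PRESET_NAMES = tuple(_preset_configs())


def scenario_presets(name: str) -> SimulationConfig:
    """A fully specified, seeded config for one of the named scenarios."""
    presets = _preset_configs()
    if name not in presets:
        raise UnknownPresetError(
            f"unknown preset {name!r}; valid names: {', '.join(presets)}"
        )
    return presets[name]
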