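"""Trace feature extraction, phase-plot data, and deformed-vesicle height.

Six scalars summarize a vesicle-fusion trace (all from one overtone,
default the 7th):

* ``t_ads``   — minutes from lipid-flow start to the frequency minimum
  (critical vesicle coverage);
* ``dF_min``  — that minimum, Hz;
* ``dD_max``  — maximum dissipation shift, reached near (not exactly at)
  the frequency minimum;
* ``t_rup``   — minutes from the frequency minimum to entering the terminal
  plateau band; infinite when no rupture occurred;
* ``dF_asymp``, ``dD_asymp`` — means over the detected terminal plateau.

Rupture releases intra-vesicle water, so a ruptured trace recovers from
``dF_min`` toward a less negative asymptote; when the asymptote equals the
minimum within a tolerance the trace is classified unruptured and
``t_rup = inf``.

The deformed-vesicle height uses the multi-overtone extrapolation of
Reviakine and coworkers: over the adsorption phase, the ratio dD/dF plotted
against dF is close to linear for each overtone and the per-overtone lines
share a zero-dissipation intercept; the Sauerbrey relation applied at that
intercept gives the acoustic thickness of the (deformed) vesicle layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import (
    ExtrapolationError,
    InvalidParameterError,
    PlateauNotFoundError,
)
from .film import PhysicalConstants, WATER_23C
from .trace import QcmdTrace

DEFAULT_OVERTONE = 7


@dataclass(frozen=True)
class FeatureParams:
    """Tunables of the feature-extraction heuristics."""

    overtone: int = DEFAULT_OVERTONE
    smooth_window: int = 5            # samples, centered moving median
    plateau_slope_tol: float = 0.5    # Hz/min on the smoothed trace
    plateau_min_span: float = 2.0     # min
    slope_half_window: float = 0.5    # min, for the local slope estimate
    band_tol: float = 1.0             # Hz, plateau entry band for t_rup
    no_rupture_eps: float = 2.0       # Hz, |dF_asymp - dF_min| below => unruptured
    ratio_floor: float = 5.0          # Hz, exclude |dF| below this from the fit
    min_fit_points: int = 10
    min_slope: float = 1e-6           # 1e-6/Hz per Hz, below => unstable intercept


@dataclass(frozen=True)
class TraceFeatures:
    t_ads: float          # min
    df_min: float         # Hz
    dd_max: float         # 1e-6
    t_rup: float          # min, +inf when unruptured
    df_asymp: float       # Hz
    dd_asymp: float       # 1e-6
    overtone_used: int
    ruptured: bool


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(y, dtype=float)
    return median_filter(np.asarray(y, dtype=float), size=window, mode="nearest")


def _local_slopes(t: np.ndarray, y: np.ndarray, half_window: float) -> np.ndarray:
    """Local least-squares slope over a centered window (noise-robust)."""
    from scipy.ndimage import uniform_filter1d

    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(half_window / dt)))
    size = 2 * w + 1

    def mean(a):
        return uniform_filter1d(a, size=size, mode="nearest")

    cov = mean(t * y) - mean(t) * mean(y)
    var = mean(t * t) - mean(t) ** 2
    slopes = cov / np.maximum(var, 1e-12)
    # edge windows are degenerate; reuse the nearest full-window estimate
    if len(slopes) > 2 * w:
        slopes[:w] = slopes[w]
        slopes[-w:] = slopes[-w - 1]
    return slopes


def _terminal_plateau(
    t: np.ndarray, fs: np.ndarray, params: FeatureParams
) -> int:
    """Index where the terminal flat segment begins; raises if too short."""
    slopes = _local_slopes(t, fs, params.slope_half_window)
    ok = np.abs(slopes) < params.plateau_slope_tol
    if not ok[-1]:
        raise PlateauNotFoundError(
            "trace still drifting at its end; extend the recording"
        )
    start = len(t) - 1
    while start > 0 and ok[start - 1]:
        start -= 1
    if t[-1] - t[start] < params.plateau_min_span:
        raise PlateauNotFoundError(
            f"terminal plateau spans {t[-1] - t[start]:.2f} min "
            f"(< {params.plateau_min_span} min required)"
        )
    return start


def extract_features(
    trace: QcmdTrace,
    overtone: int | None = None,
    params: FeatureParams | None = None,
) -> TraceFeatures:
    """Extract the six summary scalars from a baseline-corrected trace."""
    params = params or FeatureParams()
    n = overtone if overtone is not None else params.overtone
    df, dd = trace.series(n)
    t = trace.time
    fs = _smooth(df, params.smooth_window)
    ds = _smooth(dd, params.smooth_window)
    start = trace.lipid_start
    active = t >= start
    if not active.any():
        raise InvalidParameterError("lipid_start beyond the end of the trace")
    idx_active = np.flatnonzero(active)
    i_min = idx_active[int(np.argmin(fs[active]))]
    df_min = float(fs[i_min])
    t_ads = float(t[i_min] - start)
    dd_max = float(ds[active].max())

    p = _terminal_plateau(t, fs, params)
    p = max(p, i_min)  # the plateau cannot pre-date the minimum
    df_asymp = float(df[p:].mean())
    dd_asymp = float(dd[p:].mean())

    ruptured = abs(df_asymp - df_min) >= params.no_rupture_eps
    if ruptured:
        after = np.flatnonzero(
            (t > t[i_min]) & (np.abs(fs - df_asymp) <= params.band_tol)
        )
        i_band = int(after[0]) if len(after) else p
        t_rup = float(t[i_band] - t[i_min])
    else:
        t_rup = math.inf
        df_asymp = float(np.mean(df[p:]))
    return TraceFeatures(
        t_ads=t_ads, df_min=df_min, dd_max=dd_max, t_rup=t_rup,
        df_asymp=df_asymp, dd_asymp=dd_asymp, overtone_used=n,
        ruptured=ruptured,
    )


def phase_plot(
    trace: QcmdTrace, overtone: int | None = None, stride: int = 1
) -> np.ndarray:
    """Time-ordered (dF, dD) pairs at evenly spaced samples.

    Point spacing encodes rate: widely separated consecutive points mean the
    film was changing quickly.  ``stride = 1`` returns every sample.
    """
    if stride < 1:
        raise InvalidParameterError("stride must be >= 1")
    n = overtone if overtone is not None else DEFAULT_OVERTONE
    df, dd = trace.series(n)
    return np.column_stack([df[::stride], dd[::stride]])


@dataclass(frozen=True)
class DeformedHeight:
    """Result of the multi-overtone zero-dissipation extrapolation."""

    h_nm: float
    intercept_hz: float                    # aggregated (mean) intercept
    intercepts: dict[int, float]           # per-overtone dF-axis intercepts
    spread_hz: float                       # max - min across overtones


def deformed_height(
    trace: QcmdTrace,
    overtones: tuple[int, ...] | None = None,
    window: tuple[float, float] | None = None,
    rho: float = 1.0,
    constants: PhysicalConstants = WATER_23C,
    params: FeatureParams | None = None,
) -> DeformedHeight:
    """Deformed-vesicle height from the dD/dF-vs-dF extrapolation.

    For each overtone, a least-squares line is fitted to dD/dF against dF
    over the adsorption window (default: lipid-flow start to the frequency
    minimum), excluding samples with ``|dF|`` below ``params.ratio_floor``.
    The dF-axis crossing of each line (where dissipation vanishes) is the
    rigid-equivalent frequency shift of the vesicle layer; the per-overtone
    intercepts are aggregated by unweighted mean and converted to a
    thickness with the Sauerbrey relation, h = -C * dF_intercept / rho.
    """
    params = params or FeatureParams()
    if not rho > 0:
        raise InvalidParameterError("rho must be > 0")
    ns = overtones if overtones is not None else trace.overtones
    if len(ns) < 2:
        raise InvalidParameterError("need >= 2 overtones for the extrapolation")
    if window is None:
        feats = extract_features(trace, params=params)
        window = (trace.lipid_start, trace.lipid_start + feats.t_ads)
    lo, hi = window
    in_win = (trace.time >= lo) & (trace.time <= hi)
    intercepts: dict[int, float] = {}
    for n in ns:
        df, dd = trace.series(n)
        fs = _smooth(df, params.smooth_window)[in_win]
        ds = _smooth(dd, params.smooth_window)[in_win]
        usable = np.abs(fs) >= params.ratio_floor
        if usable.sum() < params.min_fit_points:
            raise ExtrapolationError(
                f"overtone {n}: only {int(usable.sum())} usable samples "
                f"(need {params.min_fit_points})"
            )
        x = fs[usable]
        y = ds[usable] / fs[usable]
        slope, offset = np.polyfit(x, y, 1)
        if abs(slope) < params.min_slope:
            raise ExtrapolationError(
                f"overtone {n}: fitted slope {slope:.2e} too small for a "
                "stable zero-dissipation intercept"
            )
        intercepts[n] = float(-offset / slope)
    vals = np.array(list(intercepts.values()))
    intercept = float(vals.mean())
    h = -constants.sauerbrey_c * intercept / rho * 0.01  # ng/cm^2 -> nm at rho
    return DeformedHeight(
        h_nm=h,
        intercept_hz=intercept,
        intercepts=intercepts,
        spread_hz=float(vals.max() - vals.min()),
    )
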