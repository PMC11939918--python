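"""Rates, outcome classification, osmotic-condition labels, and summaries.

The apparent kinetic rates come straight from the extracted features::

    R_ads = -dF_min / t_ads
    R_rup = -(dF_min - dF_asymp) / t_rup      (0 when t_rup = inf)

both in Hz/min.  The final film is classified from its asymptotic state:
a complete rigid supported lipid bilayer (SLB) shows |dF_asymp| in the
~26-30 Hz range with dissipation below ~0.5e-6; a partial SLB with embedded
intact vesicles shows ~42-46 Hz with dissipation above 1e-6; a supported
layer of vesicles (SLV) shows 55 Hz and above.  The default decision
boundaries (36 Hz, 50 Hz, dD 1.0e-6) sit between those observed bands and
are configurable.

Osmotic conditions follow the ideal van't Hoff picture: each buffer's
osmolarity is the dissociation-weighted sum of its solute concentrations,
and the exterior-minus-interior difference labels the vesicle environment
hyperosmotic (water leaves, vesicles deflate — promotes rupture),
hypoosmotic, or isosmotic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import (
    AnalysisStageError,
    InconsistentFeaturesError,
    InvalidParameterError,
    UnknownSpeciesError,
)
from .features import (
    DeformedHeight,
    FeatureParams,
    TraceFeatures,
    deformed_height,
    extract_features,
)
from .film import (
    PhysicalConstants,
    WATER_23C,
    bilayer_thickness_corrected,
    sauerbrey_mass,
)
from .trace import QcmdTrace


def adsorption_rate(df_min: float, t_ads: float) -> float:
    """R_ads = -dF_min / t_ads, Hz/min (positive for mass uptake)."""
    if not t_ads > 0:
        raise InvalidParameterError("t_ads must be > 0")
    return -df_min / t_ads


def rupture_rate(df_min: float, df_asymp: float, t_rup: float) -> float:
    """R_rup = -(dF_min - dF_asymp) / t_rup, Hz/min; exactly 0 when t_rup = inf."""
    if df_asymp < df_min:
        raise InconsistentFeaturesError(
            "dF_asymp below dF_min: rupture cannot make the film heavier"
        )
    if math.isinf(t_rup):
        return 0.0
    if not t_rup > 0:
        raise InvalidParameterError("t_rup must be > 0 or +inf")
    return -(df_min - df_asymp) / t_rup


class Outcome(str, Enum):
    SLB = "SLB"
    PARTIAL_SLB_SLV = "PARTIAL_SLB_SLV"
    SLV = "SLV"


@dataclass(frozen=True)
class ClassificationBoundaries:
    """Decision boundaries between the observed outcome bands (see module doc)."""

    slb_max_abs_df: float = 36.0   # Hz
    slv_min_abs_df: float = 50.0   # Hz
    slb_max_dd: float = 1.0        # 1e-6


def classify_outcome(
    df_asymp: float,
    dd_asymp: float,
    ruptured: bool | None = None,
    boundaries: ClassificationBoundaries = ClassificationBoundaries(),
) -> Outcome:
    """Classify the final film from its asymptotic frequency/dissipation.

    The decision uses the asymptotic bands only; ``ruptured`` is accepted
    for interface completeness (an unruptured trace lands in the SLV band
    by construction whenever the vesicle layer is substantial).
    """
    if not (math.isfinite(df_asymp) and math.isfinite(dd_asymp)):
        raise InvalidParameterError("asymptotic features must be finite")
    mag = abs(df_asymp)
    if mag <= boundaries.slb_max_abs_df and dd_asymp <= boundaries.slb_max_dd:
        return Outcome.SLB
    if mag >= boundaries.slv_min_abs_df:
        return Outcome.SLV
    return Outcome.PARTIAL_SLB_SLV


# ---------------------------------------------------------------------------
# buffers and osmotic conditions

#: ideal van't Hoff particle counts per mM of nominal solute
DISSOCIATION_COUNTS: dict[str, int] = {
    "NaCl": 2,
    "CaCl2": 3,
    "MgCl2": 3,
    "phosphate": 2,   # treated as a 1:1 salt; identical in compared buffer pairs
    "Tris": 1,
}


@dataclass(frozen=True)
class BufferSpec:
    """A named buffer: list of (solute, concentration mM) and pH."""

    name: str
    species: tuple[tuple[str, float], ...]
    ph: float = 7.0

    def __post_init__(self) -> None:
        for solute, conc in self.species:
            if conc < 0:
                raise InvalidParameterError(f"{solute}: concentration must be >= 0")

    def osmolarity(self, registry: dict[str, int] | None = None) -> float:
        """Ideal osmolarity, mOsm."""
        reg = registry or DISSOCIATION_COUNTS
        total = 0.0
        for solute, conc in self.species:
            if solute not in reg:
                raise UnknownSpeciesError(
                    f"no dissociation count registered for {solute!r}"
                )
            total += reg[solute] * conc
        return total


#: the six buffer systems used across the experiments
BUFFERS: dict[str, BufferSpec] = {
    "B1": BufferSpec("B1", (("phosphate", 20.0), ("NaCl", 100.0)), ph=7.8),
    "B2": BufferSpec("B2", (("phosphate", 20.0), ("NaCl", 100.0)), ph=7.0),
    "B3": BufferSpec("B3", (("Tris", 10.0), ("NaCl", 150.0), ("CaCl2", 2.0)), ph=7.4),
    "B4": BufferSpec(
        "B4", (("phosphate", 20.0), ("NaCl", 100.0), ("MgCl2", 2.5)), ph=7.0
    ),
    "B5": BufferSpec(
        "B5", (("phosphate", 20.0), ("NaCl", 250.0), ("MgCl2", 2.5)), ph=7.0
    ),
    "B6": BufferSpec("B6", (("phosphate", 20.0),), ph=7.0),
}


class OsmoticLabel(str, Enum):
    HYPOOSMOTIC = "hypoosmotic"
    ISOSMOTIC = "isosmotic"
    HYPEROSMOTIC = "hyperosmotic"


@dataclass(frozen=True)
class OsmoticCondition:
    label: OsmoticLabel
    delta_mosm: float        # exterior - interior
    nacl_equivalent_mm: float  # delta / 2 (one NaCl gives two particles)


def osmotic_condition(
    interior: BufferSpec,
    exterior: BufferSpec,
    threshold_mosm: float = 10.0,
    registry: dict[str, int] | None = None,
) -> OsmoticCondition:
    """Label the osmotic condition of vesicles with ``interior`` buffer inside.

    Positive delta (salt higher outside) is hyperosmotic; the label is
    antisymmetric under swapping the buffers.
    """
    delta = exterior.osmolarity(registry) - interior.osmolarity(registry)
    if delta > threshold_mosm:
        label = OsmoticLabel.HYPEROSMOTIC
    elif delta < -threshold_mosm:
        label = OsmoticLabel.HYPOOSMOTIC
    else:
        label = OsmoticLabel.ISOSMOTIC
    return OsmoticCondition(label=label, delta_mosm=delta, nacl_equivalent_mm=delta / 2.0)


@dataclass(frozen=True)
class ExperimentConditions:
    """One experimental system: vesicles, buffers, temperature, flow schedule."""

    vesicle_diameter_nm: float
    hydration: BufferSpec
    dilution: BufferSpec
    rinse: BufferSpec
    temperature_c: float = 23.0
    flow_schedule_min: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.vesicle_diameter_nm > 0:
            raise InvalidParameterError("vesicle diameter must be > 0")
        if any(b < a for a, b in zip(self.flow_schedule_min,
                                     self.flow_schedule_min[1:])):
            raise InvalidParameterError("flow schedule times must be non-decreasing")


# ---------------------------------------------------------------------------
# summary records

#: column order of the summary record (mirrors the study's summary table)
RECORD_COLUMNS = (
    "t_ads_min", "dF_min_hz", "dD_max_1e6", "t_rup_min",
    "dF_asymp_hz", "dD_asymp_1e6", "R_ads_hz_min", "R_rup_hz_min", "h_nm",
    "sauerbrey_mass_ng_cm2", "bilayer_thickness_nm", "outcome",
    "osmotic_adsorption", "osmotic_rinse",
)


def summarize_experiment(
    trace: QcmdTrace,
    conditions: ExperimentConditions | None = None,
    params: FeatureParams | None = None,
    boundaries: ClassificationBoundaries = ClassificationBoundaries(),
    constants: PhysicalConstants = WATER_23C,
    rho: float = 1.0,
) -> dict:
    """Run the full per-trace analysis and emit one flat record.

    Stages: feature extraction, deformed-vesicle height, rates, Sauerbrey
    mass, classification, and (when conditions are given) osmotic labels for
    the adsorption (hydration vs dilution) and rinse (dilution vs rinse)
    steps.  Errors are re-raised tagged with the failing stage.
    """
    params = params or FeatureParams()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise AnalysisStageError(name, exc) from exc

    feats: TraceFeatures = stage("extract_features", extract_features, trace, params=params)
    height: DeformedHeight = stage(
        "deformed_height", deformed_height, trace,
        rho=rho, constants=constants, params=params,
    )
    r_ads = stage("adsorption_rate", adsorption_rate, feats.df_min, feats.t_ads)
    r_rup = stage("rupture_rate", rupture_rate, feats.df_min, feats.df_asymp, feats.t_rup)
    mass = sauerbrey_mass(feats.df_asymp, constants)
    outcome = classify_outcome(feats.df_asymp, feats.dd_asymp, feats.ruptured, boundaries)
    record = {
        "t_ads_min": feats.t_ads,
        "dF_min_hz": feats.df_min,
        "dD_max_1e6": feats.dd_max,
        "t_rup_min": feats.t_rup,
        "dF_asymp_hz": feats.df_asymp,
        "dD_asymp_1e6": feats.dd_asymp,
        "R_ads_hz_min": r_ads,
        "R_rup_hz_min": r_rup,
        "h_nm": height.h_nm,
        "sauerbrey_mass_ng_cm2": mass,
        "bilayer_thickness_nm": None,
        "outcome": outcome.value,
        "osmotic_adsorption": None,
        "osmotic_rinse": None,
    }
    if outcome is Outcome.SLB:
        thickness, _clipped = bilayer_thickness_corrected(
            feats.df_asymp, rho=rho, constants=constants
        )
        record["bilayer_thickness_nm"] = thickness
    if conditions is not None:
        record["osmotic_adsorption"] = osmotic_condition(
            conditions.hydration, conditions.dilution
        ).label.value
        record["osmotic_rinse"] = osmotic_condition(
            conditions.dilution, conditions.rinse
        ).label.value
    return record


def record_to_json_safe(record: dict) -> dict:
    """Replace non-JSON floats (inf) with the string "inf"."""
    out = {}
    for k, v in record.items():
        if isinstance(v, float) and math.isinf(v):
            out[k] = "inf"
        else:
            out[k] = v
    return out
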