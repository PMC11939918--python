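"""Packaged fixtures: the study's experimental-conditions and summary tables.

``load_conditions_table`` (buffers, vesicle sizes, flow schedules, one row
per experimental system) and ``load_summary_table`` (the six extracted
features plus rates and deformed heights for all 17 runs).  Unicode minus
signs are normalized to ASCII; an unruptured run's t_rup is parsed to +inf.

One known transcription note: the summary row for figure 11D prints its
asymptotic frequency shift without a minus sign in the source; the fixture
stores the physically required negative value (see docs/methods.md).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import BUFFERS, ExperimentConditions


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("qcmdslb.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_conditions_table() -> pd.DataFrame:
    """Experimental systems: vesicle size, buffers, flow schedule, temperature."""
    return _read_csv("table1.csv")


def load_summary_table() -> pd.DataFrame:
    """Per-run features, rates and deformed heights (t_rup 'inf' -> +inf)."""
    df = _read_csv("table2.csv")
    df["t_rup_min"] = df["t_rup_min"].astype(float)  # 'inf' parses to +inf
    return df


def conditions_for(figure: str) -> ExperimentConditions:
    """Build :class:`ExperimentConditions` for a conditions-table row code."""
    tab = load_conditions_table()
    row = tab[tab["figure"] == figure]
    if row.empty:
        raise KeyError(f"no experimental system {figure!r}")
    r = row.iloc[0]
    return ExperimentConditions(
        vesicle_diameter_nm=float(r["vesicle_diameter_nm"]),
        hydration=BUFFERS[r["hydration_buffer"]],
        dilution=BUFFERS[r["dilution_buffer"]],
        rinse=BUFFERS[r["rinse_buffer"]],
        temperature_c=float(r["temperature_c"]),
        flow_schedule_min=(float(r["lipid_flow_start_min"]),
                           float(r["lipid_flow_end_min"])),
    )
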