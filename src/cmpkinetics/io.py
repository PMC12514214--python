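"""CSV/JSON readers and writers for kinetics series, trajectories and fits.

The on-disk formats are deliberately plain: comma-separated UTF-8 CSV with
a mandatory header ('.' decimal separator) for time series and simulator
trajectories, JSON for every parameter set and fit result. Floats written
to JSON are rounded to 12 significant digits so repeated runs with the
same seed produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic import KineticsSeries
from .systemdynamics import Trajectory

__all__ = [
    "read_kinetics_csv",
    "write_kinetics_csv",
    "write_trajectory_csv",
    "write_json",
    "round_floats",
]

logger = logging.getLogger("cmpkinetics")


class KineticsParseError(ValueError):
    """CSV content that cannot be interpreted as a kinetics series."""


def read_kinetics_csv(path, provenance: str = "measured") -> KineticsSeries:
    """Read a (time_s, area_um2) series; extra columns are ignored.

    Errors cite the offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "area_um2"):
        if col not in df.columns:
            raise KineticsParseError(f"{path}: missing required column {col!r}")
    times = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
    areas = pd.to_numeric(df["area_um2"], errors="coerce").to_numpy(dtype=float)
    for name, values in (("time_s", times), ("area_um2", areas)):
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise KineticsParseError(
                f"{path}: non-numeric {name} at row {bad[0] + 1}"
            )
    bad_area = np.flatnonzero(areas <= 0)
    if bad_area.size:
        raise KineticsParseError(
            f"{path}: non-positive area_um2 at row {bad_area[0] + 1}"
        )
    non_monotone = np.flatnonzero(np.diff(times) <= 0)
    if non_monotone.size:
        raise KineticsParseError(
            f"{path}: time_s not strictly increasing at row {non_monotone[0] + 2}"
        )
    return KineticsSeries(times=times, areas=areas, provenance=provenance)


def write_kinetics_csv(series: KineticsSeries, path) -> None:
    """Write a series as time_s,area_um2 (full float precision)."""
    pd.DataFrame({"time_s": series.times, "area_um2": series.areas}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    """Write a simulator trajectory with its flow decomposition."""
    trajectory.to_frame().to_csv(path, index=False, float_format="%.17g")


def round_floats(obj, sig: int = 12):
    """Recursively round floats to ``sig`` significant digits (JSON
    reproducibility)."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    return obj


def write_json(obj: dict, path, sig: int = 12) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(round_floats(obj, sig), fh, indent=2, sort_keys=True)
        fh.write("\n")
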