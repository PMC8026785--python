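"""Delimited-text readers/writers for blood tables, TAC tables and reports.

Formats (CSV, header required, decimal point):

* blood table: ``time_min, whole_blood_kBq_cc, plasma_kBq_cc``
* parent-fraction table: ``time_min, parent_fraction``
* TAC table: ``frame_start_min, frame_end_min`` then one column per region
* fit report: one row per region × method with micro/macro parameters,
  standard errors and flags (CSV and JSON mirrors)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blood import BloodSeries
from .errors import DomainError
from .kinetic import FitResult, FrameSchedule, TimeActivityCurve

__all__ = [
    "read_blood_table",
    "write_blood_table",
    "read_parent_fraction_table",
    "write_parent_fraction_table",
    "read_tac_table",
    "write_tac_table",
    "fit_report_frame",
    "write_fit_report",
]

BLOOD_COLUMNS = ["time_min", "whole_blood_kBq_cc", "plasma_kBq_cc"]
PF_COLUMNS = ["time_min", "parent_fraction"]


def read_blood_table(path) -> BloodSeries:
    df = pd.read_csv(path)
    missing = [c for c in BLOOD_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"blood table missing columns: {missing}")
    return BloodSeries(
        times=df["time_min"].to_numpy(float),
        whole_blood=df["whole_blood_kBq_cc"].to_numpy(float),
        plasma=df["plasma_kBq_cc"].to_numpy(float),
    )


def write_blood_table(blood: BloodSeries, path) -> None:
    pd.DataFrame(
        {
            "time_min": blood.times,
            "whole_blood_kBq_cc": blood.whole_blood,
            "plasma_kBq_cc": blood.plasma,
        }
    ).to_csv(path, index=False)


def read_parent_fraction_table(path) -> list:
    df = pd.read_csv(path)
    missing = [c for c in PF_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"parent-fraction table missing columns: {missing}")
    return list(zip(df["time_min"].astype(float), df["parent_fraction"].astype(float)))


def write_parent_fraction_table(samples, path) -> None:
    df = pd.DataFrame(samples, columns=PF_COLUMNS)
    df.to_csv(path, index=False)


def read_tac_table(path) -> dict:
    """TAC table -> {region: TimeActivityCurve}; all regions share the frames."""
    df = pd.read_csv(path)
    for col in ("frame_start_min", "frame_end_min"):
        if col not in df.columns:
            raise DomainError(f"TAC table missing column {col!r}")
    frames = FrameSchedule(
        df["frame_start_min"].to_numpy(float), df["frame_end_min"].to_numpy(float)
    )
    regions = [c for c in df.columns if c not in ("frame_start_min", "frame_end_min")]
    if not regions:
        raise DomainError("TAC table has no region columns")
    return {
        r: TimeActivityCurve(region=r, frames=frames, values=df[r].to_numpy(float))
        for r in regions
    }


def write_tac_table(tacs: dict, path) -> None:
    tac0 = next(iter(tacs.values()))
    data = {
        "frame_start_min": tac0.frames.start_times,
        "frame_end_min": tac0.frames.end_times,
    }
    for name, tac in tacs.items():
        if len(tac.values) != len(tac0.frames):
            raise DomainError("all regions must share one frame schedule")
        data[name] = tac.values
    pd.DataFrame(data).to_csv(path, index=False)


def _fit_row(fr: FitResult, method: str) -> dict:
    p = fr.params
    return {
        "region": fr.region,
        "method": method,
        "K1": p.K1,
        "k2": p.k2,
        "k3": p.k3,
        "k4": p.k4,
        "VT": fr.VT if fr.VT is not None else np.nan,
        "VND": fr.VND,
        "BPND": fr.BPND if fr.BPND is not None else np.nan,
        "VT_percent_se": fr.macro_se.get("VT_percent", np.nan),
        "rss": fr.rss,
        "aic": fr.aic,
        "converged": fr.converged,
        "reliable": fr.reliable,
        "irreversible_limit": fr.irreversible_limit,
    }


def fit_report_frame(results: dict) -> pd.DataFrame:
    """Flatten {method: {region: FitResult-like}} into one row per region × method.

    Graphical results (with a ``VT`` attribute but no microparameters) are
    accepted alongside compartment fits.
    """
    rows = []
    for method, per_region in results.items():
        for region, res in per_region.items():
            if isinstance(res, FitResult):
                rows.append(_fit_row(res, method))
            else:  # graphical fit
                rows.append(
                    {
                        "region": region,
                        "method": method,
                        "K1": np.nan,
                        "k2": np.nan,
                        "k3": np.nan,
                        "k4": np.nan,
                        "VT": res.VT,
                        "VND": np.nan,
                        "BPND": np.nan,
                        "VT_percent_se": np.nan,
                        "rss": np.nan,
                        "aic": np.nan,
                        "converged": True,
                        "reliable": True,
                        "irreversible_limit": False,
                    }
                )
    return pd.DataFrame(rows)


def write_fit_report(results: dict, csv_path, json_path=None) -> pd.DataFrame:
    df = fit_report_frame(results)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(json.loads(df.to_json(orient="records")), indent=2)
        )
    return df
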