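"""Plain-text readers and writers for the pipeline's data layouts.

Formats
-------
Recording:
    ``<name>.csv`` — first column ``time_ms``, one column per command
    step headed by its voltage in mV; ``<name>.json`` sidecar with
    capacitance, depolarisation onsets, test voltage, and metadata
    (pH, protocol, seed).  P/6 subsweeps, when present, are written to
    ``<name>.p6.csv`` with columns ``step_mv, sub, t0, t1, ...``.
Seahorse plates:
    tidy CSV ``well, group, time_min, ecar_mpH_min, injection_index``.
Fluorescence plates:
    tidy CSV ``well, role, wavelength, value`` with roles
    treated/vehicle/background.
Electrode series:
    CSV ``index, block, type, known_ph, voltage_mv, label`` with type in
    {measurement, calibration, bath}; bath rows carry each block's
    junction-potential offset reading.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationPoint, CalibrationSeries, FluorescencePlate, Measurement
from .ecar import SeahorsePlate
from .ephys import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_seahorse",
    "read_seahorse",
    "write_fluorescence",
    "read_fluorescence",
    "write_electrode_series",
    "read_electrode_series",
]


# ---------------------------------------------------------------------------
# Recordings


def write_recording(rec: Recording, base_path: str | Path) -> None:
    base = Path(base_path)
    df = pd.DataFrame(
        {"time_ms": rec.time_ms}
        | {f"{v:g}": rec.sweeps[i] for i, v in enumerate(rec.command_mv)}
    )
    df.to_csv(base.with_suffix(".csv"), index=False)
    sidecar = {
        "capacitance_pf": rec.capacitance_pf,
        "depol_onset_ms": rec.depol_onset_ms,
        "prepulse_onset_ms": rec.prepulse_onset_ms,
        "test_mv": rec.test_mv,
        "meta": rec.meta,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if rec.subsweeps is not None:
        rows = []
        for i, v in enumerate(rec.command_mv):
            for j in range(rec.subsweeps.shape[1]):
                rows.append([v, j, *rec.subsweeps[i, j]])
        cols = ["step_mv", "sub", *[f"t{k}" for k in range(rec.time_ms.size)]]
        pd.DataFrame(rows, columns=cols).to_csv(base.with_suffix(".p6.csv"), index=False)


def read_recording(base_path: str | Path, meta_path: str | Path | None = None) -> Recording:
    base = Path(base_path)
    df = pd.read_csv(base.with_suffix(".csv"))
    meta_file = Path(meta_path) if meta_path is not None else base.with_suffix(".json")
    sidecar = json.loads(meta_file.read_text())
    command = np.array([float(c) for c in df.columns[1:]])
    sweeps = df.iloc[:, 1:].to_numpy().T
    subsweeps = None
    p6_path = base.with_suffix(".p6.csv")
    if p6_path.exists():
        p6 = pd.read_csv(p6_path)
        subsweeps = np.stack(
            [
                p6[np.isclose(p6["step_mv"], v)].iloc[:, 2:].to_numpy()
                for v in command
            ]
        )
    return Recording(
        time_ms=df["time_ms"].to_numpy(),
        sweeps=sweeps,
        command_mv=command,
        capacitance_pf=sidecar["capacitance_pf"],
        depol_onset_ms=sidecar["depol_onset_ms"],
        prepulse_onset_ms=sidecar.get("prepulse_onset_ms"),
        test_mv=sidecar.get("test_mv"),
        subsweeps=subsweeps,
        meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Seahorse plates


def write_seahorse(plate: SeahorsePlate, path: str | Path) -> None:
    rows = []
    for group, wells in (("treated", plate.treated), ("control", plate.control)):
        for w, trace in enumerate(np.atleast_2d(wells)):
            for t, val in zip(plate.times_min, trace):
                rows.append([f"{group[0]}{w}", group, t, val, plate.injection_index])
    pd.DataFrame(
        rows, columns=["well", "group", "time_min", "ecar_mpH_min", "injection_index"]
    ).to_csv(path, index=False)


def read_seahorse(path: str | Path) -> SeahorsePlate:
    df = pd.read_csv(path)
    times = np.sort(df["time_min"].unique())

    def block(group: str) -> np.ndarray:
        sub = df[df["group"] == group]
        wells = sorted(sub["well"].unique())
        return np.stack(
            [
                sub[sub["well"] == w].sort_values("time_min")["ecar_mpH_min"].to_numpy()
                for w in wells
            ]
        )

    return SeahorsePlate(
        times_min=times,
        treated=block("treated"),
        control=block("control"),
        injection_index=int(df["injection_index"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# Fluorescence plates


def write_fluorescence(
    treated: FluorescencePlate, vehicle: FluorescencePlate, path: str | Path
) -> None:
    rows = []
    for role, plate in (("treated", treated), ("vehicle", vehicle)):
        for wl, vals in ((340, plate.f340), (380, plate.f380)):
            rows += [[f"{role[0]}{i}", role, wl, v] for i, v in enumerate(vals)]
        for wl, vals in ((340, plate.bg340), (380, plate.bg380)):
            rows += [
                [f"{role[0]}bg{i}", f"{role}_background", wl, v]
                for i, v in enumerate(vals)
            ]
    pd.DataFrame(rows, columns=["well", "role", "wavelength", "value"]).to_csv(
        path, index=False
    )


def read_fluorescence(path: str | Path) -> tuple[FluorescencePlate, FluorescencePlate]:
    df = pd.read_csv(path)

    def plate(role: str) -> FluorescencePlate:
        def grab(r: str, wl: int) -> np.ndarray:
            sel = df[(df["role"] == r) & (df["wavelength"] == wl)]
            return sel.sort_values("well")["value"].to_numpy()

        return FluorescencePlate(
            f340=grab(role, 340),
            f380=grab(role, 380),
            bg340=grab(f"{role}_background", 340),
            bg380=grab(f"{role}_background", 380),
        )

    return plate("treated"), plate("vehicle")


# ---------------------------------------------------------------------------
# Electrode series


def write_electrode_series(series: CalibrationSeries, path: str | Path) -> None:
    rows = []
    idx = 0
    for block in sorted(series.offsets):
        rows.append([idx, block, "bath", "", series.offsets[block], ""])
        idx += 1
        for p in (q for q in series.points if q.block == block):
            rows.append([idx, block, "calibration", p.known_ph, p.voltage_mv, ""])
            idx += 1
        for m in (q for q in series.measurements if q.block == block):
            rows.append([idx, block, "measurement", "", m.voltage_mv, m.label or ""])
            idx += 1
    pd.DataFrame(
        rows, columns=["index", "block", "type", "known_ph", "voltage_mv", "label"]
    ).to_csv(path, index=False)


def read_electrode_series(path: str | Path) -> CalibrationSeries:
    df = pd.read_csv(path, keep_default_na=False)
    series = CalibrationSeries()
    for _, row in df.iterrows():
        block = int(row["block"])
        kind = row["type"]
        if kind == "bath":
            series.offsets[block] = float(row["voltage_mv"])
        elif kind == "calibration":
            series.points.append(
                CalibrationPoint(block, float(row["known_ph"]), float(row["voltage_mv"]))
            )
        elif kind == "measurement":
            label = str(row["label"]) or None
            series.measurements.append(
                Measurement(block, float(row["voltage_mv"]), label)
            )
        else:
            raise ValueError(f"unknown row type {kind!r}")
    return series
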