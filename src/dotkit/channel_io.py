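"""Channel-recording I/O: SNIRF (HDF5) and a documented CSV dialect.

The SNIRF support covers the subset of the format the pipeline needs —
``/nirs/data1`` time series with its measurement list, probe wavelengths
and optode positions, and stim groups — written and read with h5py.

CSV dialect (three files sharing a stem):
  ``<stem>.data.csv``          time x measurement, first column ``time_s``,
                               remaining headers ``S<s>_D<d>_<wl>``
  ``<stem>.measurements.csv``  the measurement-list table
  ``<stem>.paradigm.csv``      columns ``onset_s``, ``condition``
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .light_model import MEASUREMENT_COLUMNS
from .preprocess import PARADIGM_COLUMNS, ChannelRecording

__all__ = ["write_snirf", "read_snirf", "write_csv", "read_csv"]


def write_snirf(rec: ChannelRecording, path: str | Path,
                source_pos_mm: np.ndarray | None = None,
                detector_pos_mm: np.ndarray | None = None) -> Path:
    """Write a recording as a minimal SNIRF file."""
    path = Path(path)
    wavelengths = sorted(np.unique(rec.measurements["wavelength_nm"]))
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=rec.data)
        data.create_dataset("time", data=rec.times)
        for i, row in enumerate(rec.measurements.itertuples(), start=1):
            ml = data.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=int(row.source))
            ml.create_dataset("detectorIndex", data=int(row.detector))
            ml.create_dataset(
                "wavelengthIndex",
                data=int(wavelengths.index(row.wavelength_nm)) + 1)
            ml.create_dataset("dataType", data=1)  # CW amplitude
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths))
        if source_pos_mm is not None:
            probe.create_dataset("sourcePos3D", data=np.asarray(source_pos_mm))
        if detector_pos_mm is not None:
            probe.create_dataset("detectorPos3D",
                                 data=np.asarray(detector_pos_mm))
        for k, (cond, grp) in enumerate(
                rec.paradigm.groupby("condition", sort=True), start=1):
            stim = nirs.create_group(f"stim{k}")
            stim.create_dataset("name", data=str(cond))
            onsets = grp["onset_s"].to_numpy(dtype=float)
            # columns: onset, duration, amplitude
            stim.create_dataset(
                "data",
                data=np.column_stack([onsets, np.zeros_like(onsets),
                                      np.ones_like(onsets)]))
    return path


def _read_scalar(ds) -> float:
    v = ds[()]
    return float(v.item() if hasattr(v, "item") else v)


def read_snirf(path: str | Path, unit: str = "intensity") -> ChannelRecording:
    """Read a minimal SNIRF file back into a ChannelRecording."""
    with h5py.File(Path(path), "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        if len(time) < 2:
            raise ValueError("SNIRF time vector too short to infer rate")
        fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = np.asarray(nirs["probe"]["wavelengths"], dtype=float)
        rows = []
        i = 1
        while f"measurementList{i}" in data:
            ml = data[f"measurementList{i}"]
            wl = wavelengths[int(_read_scalar(ml["wavelengthIndex"])) - 1]
            rows.append((int(_read_scalar(ml["sourceIndex"])),
                         int(_read_scalar(ml["detectorIndex"])),
                         float(wl), np.nan, np.nan, True))
            i += 1
        measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
        stim_rows = []
        k = 1
        while f"stim{k}" in nirs:
            stim = nirs[f"stim{k}"]
            name = stim["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            for onset in np.atleast_2d(np.asarray(stim["data"]))[:, 0]:
                stim_rows.append((float(onset), str(name)))
            k += 1
        paradigm = pd.DataFrame(sorted(stim_rows), columns=PARADIGM_COLUMNS)
    return ChannelRecording(series, fs, measurements, paradigm=paradigm,
                            unit=unit)


def _column_name(row) -> str:
    wl = row.wavelength_nm
    wl_txt = f"{wl:g}"
    return f"S{int(row.source)}_D{int(row.detector)}_{wl_txt}"


def write_csv(rec: ChannelRecording, stem: str | Path) -> list[Path]:
    """Write the three-file CSV dialect; returns the paths written."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    cols = [_column_name(r) for r in rec.measurements.itertuples()]
    data = pd.DataFrame(rec.data, columns=cols)
    data.insert(0, "time_s", rec.times)
    paths = [
        Path(f"{stem}.data.csv"),
        Path(f"{stem}.measurements.csv"),
        Path(f"{stem}.paradigm.csv"),
    ]
    data.to_csv(paths[0], index=False)
    rec.measurements.to_csv(paths[1], index=False)
    rec.paradigm.to_csv(paths[2], index=False)
    return paths


def read_csv(stem: str | Path, unit: str = "intensity") -> ChannelRecording:
    """Read the three-file CSV dialect back into a ChannelRecording."""
    stem = Path(stem)
    data = pd.read_csv(f"{stem}.data.csv")
    measurements = pd.read_csv(f"{stem}.measurements.csv")
    paradigm = pd.read_csv(f"{stem}.paradigm.csv")
    time = data["time_s"].to_numpy(dtype=float)
    if len(time) < 2:
        raise ValueError("need at least two samples to infer the rate")
    fs = 1.0 / float(np.median(np.diff(time)))
    series = data.drop(columns="time_s").to_numpy(dtype=float)
    return ChannelRecording(series, fs, measurements, paradigm=paradigm,
                            unit=unit)
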