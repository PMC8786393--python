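"""Channel-space preprocessing of fNIRS time series.

The standard chain is: prune channels by signal level (dB) -> convert raw
intensity to optical density -> (optional external motion correction via the
artifact hook) -> reject stimulus triggers contaminated by residual motion
artifacts -> band-pass filter.  Before reconstruction, the mean over
low-noise channels is regressed out per wavelength (global signal
regression) and the data are down-sampled.

Motion-artifact detection and targeted-PCA correction are published
third-party algorithms and are not re-implemented; ``reject_triggers``
accepts externally computed artifact intervals instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ChannelRecording",
    "prune_channels",
    "intensity_to_od",
    "bandpass",
    "reject_triggers",
    "global_signal_regression",
    "resample",
]

UNIT_INTENSITY = "intensity"
UNIT_OD = "od"

PARADIGM_COLUMNS = ["onset_s", "condition"]


@dataclass
class ChannelRecording:
    """Multi-channel optical time series with measurement metadata.

    ``data`` is time x measurement, ordered as ``measurements`` (a
    measurement-list DataFrame; see :mod:`dotkit.light_model`).  ``paradigm``
    holds stimulus onsets in seconds with condition labels.  ``good_meas``
    flags low-noise measurements; ``unit`` tags the data as raw
    ``"intensity"`` or ``"od"``.
    """

    data: np.ndarray
    fs: float
    measurements: pd.DataFrame
    paradigm: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    good_meas: np.ndarray = field(default=None)  # type: ignore[assignment]
    unit: str = UNIT_INTENSITY

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be time x measurement")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] != len(self.measurements):
            raise ValueError("data columns must match measurement list length")
        if self.paradigm is None:
            self.paradigm = pd.DataFrame(columns=PARADIGM_COLUMNS)
        if len(self.paradigm):
            t_end = self.n_frames / self.fs
            onsets = self.paradigm["onset_s"].to_numpy(dtype=float)
            if onsets.min() < 0 or onsets.max() > t_end:
                raise ValueError("trigger times must lie within the recording")
        if self.good_meas is None:
            self.good_meas = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.good_meas = np.asarray(self.good_meas, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_measurements(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs

    def with_data(self, data: np.ndarray, **kw) -> "ChannelRecording":
        return replace(self, data=np.asarray(data, dtype=float), **kw)


def _require_unit(rec: ChannelRecording, unit: str, op: str) -> None:
    if rec.unit != unit:
        raise ValueError(f"{op} expects {unit} data, got {rec.unit!r}")


def prune_channels(rec: ChannelRecording, low_db: float = 80.0,
                   high_db: float = 130.0, reference: float = 1.0,
                   ) -> ChannelRecording:
    """Flag measurements whose mean signal level falls outside [low, high] dB.

    Level is 20*log10(mean intensity / reference).  Defaults 80 and 130 dB.
    Pruning only updates ``good_meas``; no data are removed.
    """
    _require_unit(rec, UNIT_INTENSITY, "prune_channels")
    means = rec.data.mean(axis=0)
    if np.any(means <= 0):
        bad = np.flatnonzero(means <= 0)
        raise ValueError(f"non-positive mean intensity in channels {bad}")
    level_db = 20.0 * np.log10(means / reference)
    good = (level_db >= low_db) & (level_db <= high_db)
    return replace(rec, good_meas=rec.good_meas & good)


def intensity_to_od(rec: ChannelRecording) -> ChannelRecording:
    """Convert raw intensity to optical density: OD(t) = -ln(I(t)/mean(I)).

    Natural log with the per-channel temporal mean as baseline; OD is scale
    invariant, so gains cancel.
    """
    _require_unit(rec, UNIT_INTENSITY, "intensity_to_od")
    if np.any(rec.data <= 0):
        t, ch = np.argwhere(rec.data <= 0)[0]
        raise ValueError(
            f"non-positive intensity in channel {ch} at frame {t}")
    od = -np.log(rec.data / rec.data.mean(axis=0))
    return rec.with_data(od, unit=UNIT_OD)


def bandpass(rec: ChannelRecording, f_hp: float = 0.016, f_lp: float = 0.5,
             order: int = 3) -> ChannelRecording:
    """Zero-phase Butterworth band-pass (defaults 0.016-0.5 Hz).

    Applied forward and backward (filtfilt) so the pass band has unit gain
    and no phase distortion; DC is removed.
    """
    nyq = rec.fs / 2.0
    if not 0 < f_hp < f_lp:
        raise ValueError("need 0 < f_hp < f_lp")
    if f_lp >= nyq:
        raise ValueError(f"low-pass cutoff {f_lp} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [f_hp, f_lp], btype="bandpass", fs=rec.fs,
                        output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=0))


def reject_triggers(rec: ChannelRecording,
                    artifact_intervals: np.ndarray | list,
                    window_s: tuple[float, float] = (-1.0, 18.0),
                    ) -> ChannelRecording:
    """Drop stimulus triggers whose response window overlaps an artifact.

    A trigger at time t is removed iff any artifact interval [a0, a1]
    intersects [t + window[0], t + window[1]] (default -1 to +18 s, closed
    endpoints).  Artifact intervals come from an external motion-artifact
    detector; a point artifact may be given as (a, a).
    """
    intervals = np.asarray(artifact_intervals, dtype=float).reshape(-1, 2)
    if len(rec.paradigm) == 0 or len(intervals) == 0:
        return replace(rec, paradigm=rec.paradigm.copy())
    w0, w1 = window_s
    onsets = rec.paradigm["onset_s"].to_numpy(dtype=float)
    lo, hi = onsets + w0, onsets + w1
    # closed-interval overlap: a0 <= hi and a1 >= lo
    hit = ((intervals[:, 0][None, :] <= hi[:, None])
           & (intervals[:, 1][None, :] >= lo[:, None])).any(axis=1)
    return replace(rec, paradigm=rec.paradigm.loc[~hit].reset_index(drop=True))


def global_signal_regression(rec: ChannelRecording) -> ChannelRecording:
    """Remove the mean-over-good-channels signal from every channel.

    For each wavelength separately, the global signal g is the mean over
    good measurements at that wavelength; each channel is regressed on
    [1, g] by least squares and replaced by its residual, which is exactly
    orthogonal to g.  Acts as a surrogate for systemic physiology shared
    across the array.
    """
    _require_unit(rec, UNIT_OD, "global_signal_regression")
    out = rec.data.copy()
    wavelengths = np.unique(rec.measurements["wavelength_nm"].to_numpy())
    for wl in wavelengths:
        cols = np.flatnonzero(
            np.isclose(rec.measurements["wavelength_nm"].to_numpy(), wl))
        good_cols = cols[rec.good_meas[cols]]
        if good_cols.size == 0:
            raise ValueError(f"no good measurements at {wl} nm for GSR")
        g = rec.data[:, good_cols].mean(axis=1)
        x = np.column_stack([np.ones_like(g), g])
        beta, *_ = np.linalg.lstsq(x, rec.data[:, cols], rcond=None)
        out[:, cols] = rec.data[:, cols] - x @ beta
    return rec.with_data(out)


def resample(rec: ChannelRecording, target_fs: float = 25.0,
             ) -> ChannelRecording:
    """Anti-aliased down-sampling (default 25 Hz) via polyphase filtering.

    Paradigm times are in seconds and are unchanged.  Up-sampling is
    refused; ``target_fs == fs`` is the identity.
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"refusing to up-sample from {rec.fs} to {target_fs} Hz")
    if np.isclose(target_fs, rec.fs):
        return replace(rec)
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=0)
    return rec.with_data(data, fs=rec.fs * frac.numerator / frac.denominator)
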