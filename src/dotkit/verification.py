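"""Channel-vs-image agreement checks.

Reconstruction quality is verified by placing a small sphere (default 2 cm
diameter) at the cortical maximum of each channel's sensitivity volume,
averaging the reconstructed chromophore time series over the sphere, and
correlating it with the channel-space time series.  A correlation above the
acceptance criterion (default r > 0.25) marks the channel as verified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .light_model import SensitivityModel, restrict_to_good_vox

__all__ = [
    "SphereROI",
    "sphere_at_channel_max",
    "extract_mean_timeseries",
    "correlate_channel_image",
    "verification_report",
]

DEFAULT_CRITERION = 0.25
DEFAULT_DIAMETER_MM = 20.0


@dataclass
class SphereROI:
    """Sphere of voxels around a channel's cortical sensitivity maximum.

    ``center_flat`` and ``members_flat`` index the flattened full volume;
    ``members_cols`` are the corresponding columns within good_vox for
    time-series extraction.
    """

    channel: int
    center_flat: int
    diameter_mm: float
    members_flat: np.ndarray
    members_cols: np.ndarray

    def __post_init__(self) -> None:
        if self.center_flat not in self.members_flat:
            raise ValueError("sphere center must be a member voxel")


def sphere_at_channel_max(sensitivity_volume: np.ndarray,
                          cortex_mask: np.ndarray,
                          model: SensitivityModel,
                          channel: int = 0,
                          diameter_mm: float = DEFAULT_DIAMETER_MM,
                          ) -> SphereROI:
    """Place a sphere at the cortical maximum of a channel's sensitivity.

    The sensitivity volume is restricted to the cortex mask (so the maximum
    cannot fall in scalp or skull); the sphere's members are the voxels
    within ``diameter_mm / 2`` of the center, intersected with the mask and
    with the model's retained voxels.  Ties in the argmax break to the first
    voxel in linear (Fortran) order.
    """
    mask_gv = restrict_to_good_vox(cortex_mask.astype(bool), model.good_vox)
    if not mask_gv.any():
        raise ValueError("cortex mask contains no retained voxels")
    sens_gv = restrict_to_good_vox(np.asarray(sensitivity_volume, dtype=float),
                                   model.good_vox)
    masked = np.where(mask_gv, sens_gv, -np.inf)
    if masked.max() <= 0:
        raise ValueError("sensitivity is zero everywhere in the cortex mask")
    center_col = int(np.argmax(masked))
    coords = model.good_vox_coords_mm()
    dist = np.linalg.norm(coords - coords[center_col], axis=1)
    members = np.flatnonzero((dist <= diameter_mm / 2.0) & mask_gv)
    return SphereROI(
        channel=channel,
        center_flat=int(model.good_vox[center_col]),
        diameter_mm=diameter_mm,
        members_flat=model.good_vox[members],
        members_cols=members,
    )


def extract_mean_timeseries(series: np.ndarray, roi: SphereROI) -> np.ndarray:
    """Unweighted mean of the (time x voxel) series over the sphere's voxels."""
    if roi.members_cols.size == 0:
        raise ValueError("empty ROI")
    return np.asarray(series)[:, roi.members_cols].mean(axis=1)


def correlate_channel_image(channel_series: np.ndarray,
                            image_series: np.ndarray,
                            criterion: float = DEFAULT_CRITERION,
                            ) -> tuple[float, bool]:
    """Pearson correlation between channel and image series; pass iff r > criterion."""
    a = np.asarray(channel_series, dtype=float)
    b = np.asarray(image_series, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length (resample first)")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    return r, r > criterion


def verification_report(rows: list[dict],
                        criterion: float = DEFAULT_CRITERION) -> pd.DataFrame:
    """Tabulate per-(channel, chromophore, run) correlations with pass flags.

    Each row dict needs keys ``channel``, ``chromophore``, ``r`` (and
    optionally ``run``).  Adds a ``passed`` column and attaches summary
    attrs: counts and the mean r of the passing subset.
    """
    df = pd.DataFrame(rows)
    if "run" not in df:
        df["run"] = 0
    df["criterion"] = criterion
    df["passed"] = df["r"] > criterion
    df.attrs["n_total"] = int(len(df))
    df.attrs["n_passed"] = int(df["passed"].sum())
    df.attrs["mean_r_passing"] = (
        float(df.loc[df["passed"], "r"].mean()) if df["passed"].any()
        else float("nan"))
    return df
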