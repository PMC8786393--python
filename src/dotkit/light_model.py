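"""Sensitivity-volume vectorization and NIFTI head-model I/O.

Each measurement (source-detector pair at one wavelength) has a 3D
sensitivity volume describing how an absorption change in each voxel
perturbs that measurement.  For reconstruction the volumes are stacked into
a single matrix ``A`` (measurements x voxels), keeping only voxels whose
sensitivity exceeds a fraction of the global maximum for at least one
measurement.  The retained voxels' indices into the flattened full volume
are stored in ``good_vox`` so images can be re-embedded.

Voxel linearization is column-major over (x, y, z) — Fortran order —
throughout; ``good_vox`` is 0-based in memory and 1-based on text export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "HeadVolume",
    "SensitivityModel",
    "make_measurement_list",
    "vectorize_sensitivity",
    "restrict_to_good_vox",
    "embed_to_volume",
    "read_nifti",
    "write_nifti",
    "read_nifti_sensitivity",
]

FLAT_ORDER = "F"

#: labels in a segmented head volume
LABEL_BACKGROUND, LABEL_SCALP_SKULL, LABEL_CSF, LABEL_GRAY, LABEL_WHITE = range(5)

MEASUREMENT_COLUMNS = [
    "source", "detector", "wavelength_nm", "separation_2d_mm",
    "separation_3d_mm", "good",
]


class EmptyModelError(ValueError):
    """No voxel exceeds the sensitivity threshold."""


@dataclass
class HeadVolume:
    """Segmented head: integer tissue labels on a regular voxel grid.

    Labels: 0 background, 1 scalp/skull, 2 CSF, 3 gray matter, 4 white
    matter.  ``voxel_size_mm`` is isotropic; ``affine`` maps voxel indices
    to scanner mm.
    """

    labels: np.ndarray
    voxel_size_mm: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if not np.isin(np.unique(self.labels), np.arange(5)).all():
            raise ValueError("labels must lie in {0..4}")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, which: Sequence[int]) -> np.ndarray:
        """Boolean mask of voxels whose label is in ``which``."""
        return np.isin(self.labels, list(which))

    def cortex_mask(self, include_white: bool = False) -> np.ndarray:
        labels = [LABEL_GRAY, LABEL_WHITE] if include_white else [LABEL_GRAY]
        return self.mask(labels)


def make_measurement_list(pairs: Sequence[tuple[int, int]],
                          wavelengths_nm: Sequence[float],
                          source_pos_mm: np.ndarray | None = None,
                          detector_pos_mm: np.ndarray | None = None,
                          ) -> pd.DataFrame:
    """Build a measurement list: every pair at every wavelength, in order.

    Rows are grouped by wavelength (all pairs at the first wavelength, then
    all pairs at the second), matching the per-wavelength blocks the
    inversion consumes.  Source/detector indices are 1-based.  If optode
    positions (mm, one row per optode) are given, 2D (xy-plane) and 3D
    separations are filled in; otherwise they are NaN.
    """
    rows = []
    for wl in wavelengths_nm:
        for s, d in pairs:
            if s < 1 or d < 1:
                raise ValueError("source/detector indices are 1-based")
            sep2 = sep3 = np.nan
            if source_pos_mm is not None and detector_pos_mm is not None:
                ps, pd_ = source_pos_mm[s - 1], detector_pos_mm[d - 1]
                sep3 = float(np.linalg.norm(ps - pd_))
                sep2 = float(np.linalg.norm(ps[:2] - pd_[:2]))
            rows.append((s, d, float(wl), sep2, sep3, True))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


@dataclass
class SensitivityModel:
    """Vectorized forward model: A (measurements x retained voxels) + indexing.

    ``good_vox`` holds the strictly increasing 0-based indices of the
    retained voxels within the flattened (Fortran-order) full volume.
    Row order of ``A`` equals the row order of ``measurements``.
    """

    A: np.ndarray
    good_vox: np.ndarray
    shape: tuple[int, int, int]
    voxel_size_mm: float
    measurements: pd.DataFrame
    threshold_used: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.good_vox = np.asarray(self.good_vox, dtype=np.int64)
        if self.A.ndim != 2:
            raise ValueError("A must be 2D")
        if self.A.shape[1] != len(self.good_vox):
            raise ValueError("A column count must equal |good_vox|")
        if np.any(np.diff(self.good_vox) <= 0):
            raise ValueError("good_vox must be strictly increasing")
        if np.any(self.A < 0):
            raise ValueError("sensitivities must be non-negative")
        if len(self.measurements) != self.A.shape[0]:
            raise ValueError("measurement list length must equal A row count")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size_mm] * 3 + [1.0])

    @property
    def n_measurements(self) -> int:
        return self.A.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.A.shape[1]

    def wavelength_rows(self, wavelength_nm: float) -> np.ndarray:
        """Row indices of measurements at one wavelength."""
        return np.flatnonzero(
            np.isclose(self.measurements["wavelength_nm"].to_numpy(),
                       wavelength_nm))

    def good_vox_coords_mm(self) -> np.ndarray:
        """(n_voxels, 3) voxel-center coordinates in mm for retained voxels."""
        ijk = np.stack(np.unravel_index(self.good_vox, self.shape,
                                        order=FLAT_ORDER), axis=1)
        return ijk * self.voxel_size_mm

    def good_vox_one_based(self) -> np.ndarray:
        """good_vox as exported to text formats (1-based)."""
        return self.good_vox + 1


def vectorize_sensitivity(volumes: Sequence[np.ndarray],
                          measurements: pd.DataFrame,
                          threshold_frac: float = 0.01,
                          voxel_size_mm: float = 1.0,
                          affine: np.ndarray | None = None,
                          ) -> SensitivityModel:
    """Stack per-measurement volumes into A, dropping sub-threshold voxels.

    A voxel is retained iff any measurement's sensitivity there strictly
    exceeds ``threshold_frac`` times the global maximum over all volumes
    (default 0.01).
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    vols = [np.asarray(v, dtype=float) for v in volumes]
    if not vols:
        raise ValueError("no volumes given")
    shape = vols[0].shape
    if any(v.shape != shape for v in vols):
        raise ValueError("all sensitivity volumes must share one shape")
    if len(vols) != len(measurements):
        raise ValueError("one volume per measurement required")
    flat = np.stack([v.ravel(order=FLAT_ORDER) for v in vols])
    global_max = flat.max()
    if global_max <= 0:
        raise EmptyModelError("all sensitivity volumes are zero")
    retained = (flat > threshold_frac * global_max).any(axis=0)
    good_vox = np.flatnonzero(retained)
    if good_vox.size == 0:
        raise EmptyModelError("no voxel exceeds the sensitivity threshold")
    return SensitivityModel(
        A=flat[:, good_vox], good_vox=good_vox, shape=shape,
        voxel_size_mm=voxel_size_mm, measurements=measurements.reset_index(drop=True),
        threshold_used=threshold_frac, affine=affine,
    )


def restrict_to_good_vox(volume: np.ndarray, good_vox: np.ndarray) -> np.ndarray:
    """Extract the retained-voxel values of a full volume (Fortran flattening)."""
    return np.asarray(volume).ravel(order=FLAT_ORDER)[good_vox]


def embed_to_volume(values: np.ndarray, good_vox: np.ndarray,
                    shape: tuple[int, int, int]) -> np.ndarray:
    """Place retained-voxel values back into a full volume, zeros elsewhere.

    Inverse of :func:`restrict_to_good_vox` on the retained set.
    """
    values = np.asarray(values)
    good_vox = np.asarray(good_vox)
    if values.shape[-1] != len(good_vox):
        raise IndexError(
            f"{values.shape[-1]} values for {len(good_vox)} retained voxels")
    flat = np.zeros(int(np.prod(shape)), dtype=values.dtype)
    flat[good_vox] = values
    return flat.reshape(shape, order=FLAT_ORDER)


# ---------------------------------------------------------------------------
# NIFTI I/O


def write_nifti(volume: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None,
                voxel_size_mm: float = 1.0) -> Path:
    """Write a 3D (or 4D) array as NIFTI-1."""
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume), np.asarray(affine, dtype=float))
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIFTI file; returns (array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def read_nifti_sensitivity(paths: Sequence[str | Path],
                           ) -> tuple[list[np.ndarray], np.ndarray]:
    """Read per-measurement sensitivity NIFTIs, enforcing a common geometry."""
    vols: list[np.ndarray] = []
    affine0: np.ndarray | None = None
    shape0 = None
    for p in paths:
        vol, aff = read_nifti(p)
        if affine0 is None:
            affine0, shape0 = aff, vol.shape
        else:
            if vol.shape != shape0:
                raise ValueError(f"{p}: shape {vol.shape} != {shape0}")
            if not np.allclose(aff, affine0, atol=1e-6):
                raise ValueError(f"{p}: affine differs from first volume")
        vols.append(np.asarray(vol, dtype=float))
    if affine0 is None:
        raise ValueError("no sensitivity paths given")
    return vols, affine0


def head_volume_to_nifti(head: HeadVolume, path: str | Path) -> Path:
    return write_nifti(head.labels.astype(np.int16), path, affine=head.affine)


def head_volume_from_nifti(path: str | Path) -> HeadVolume:
    arr, aff = read_nifti(path)
    voxel = float(np.linalg.norm(aff[:3, 0]))
    return HeadVolume(np.asarray(arr, dtype=int), voxel, aff)
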