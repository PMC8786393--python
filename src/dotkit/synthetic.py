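"""Seeded synthetic phantoms: every pipeline input, generated from code.

The generators emulate the artifacts an image-reconstructed fNIRS study
consumes — a segmented head volume, per-channel sensitivity volumes, optode
digitizations, and stimulus-locked channel recordings — as pure functions of
a specification plus a seed.  The sensitivity "bananas" are a geometric
surrogate (distance-decay kernels between source and detector entry points,
masked to tissue), not photon transport: they are non-negative,
channel-localized and mutually overlapping, which is all the downstream
linear algebra requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digitization import Cap, ROLE_DETECTOR, ROLE_LANDMARK, ROLE_SOURCE
from .glm import HRFSpec, build_design, gamma_hrf
from .light_model import (
    HeadVolume,
    SensitivityModel,
    make_measurement_list,
    vectorize_sensitivity,
)
from .preprocess import ChannelRecording
from .reconstruction import DEFAULT_EXTINCTION, ExtinctionTable

__all__ = [
    "PhantomSpec",
    "ProbeSpec",
    "NoiseModel",
    "generate_phantom_head",
    "generate_probe",
    "generate_sensitivity",
    "generate_sensitivity_model",
    "make_cap_layout",
    "generate_caps",
    "default_paradigm",
    "generate_channel_data",
    "default_fixture",
]


@dataclass
class PhantomSpec:
    """Concentric-layer spherical head phantom.

    A sphere of ``head_radius_mm`` centered in the volume, layered from the
    outside in: scalp/skull shell, CSF shell, gray-matter shell, white-matter
    core.  Thicknesses are in mm.
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: float = 2.0
    head_radius_mm: float = 36.0
    scalp_skull_mm: float = 6.0
    csf_mm: float = 2.0
    gray_mm: float = 6.0

    def __post_init__(self) -> None:
        inner = (self.head_radius_mm - self.scalp_skull_mm - self.csf_mm
                 - self.gray_mm)
        if inner <= 0:
            raise ValueError("layer thicknesses exceed the head radius")

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) / 2.0 * self.voxel_size_mm

    def layer_radii_mm(self) -> dict[str, float]:
        r = self.head_radius_mm
        return {
            "scalp_skull": r,
            "csf": r - self.scalp_skull_mm,
            "gray": r - self.scalp_skull_mm - self.csf_mm,
            "white": r - self.scalp_skull_mm - self.csf_mm - self.gray_mm,
        }


@dataclass
class ProbeSpec:
    """Interleaved ring of optodes over the crown of the phantom.

    ``n_sources`` sources and ``n_detectors`` detectors alternate around a
    ring at ``polar_deg`` from the vertical axis, on the scalp surface;
    channels connect each optode to its ring neighbor.
    """

    n_sources: int = 8
    n_detectors: int = 8
    polar_deg: float = 35.0
    wavelengths_nm: tuple[float, float] = (690.0, 830.0)


def generate_phantom_head(spec: PhantomSpec) -> HeadVolume:
    """Voxelize the concentric-layer phantom into a labeled head volume."""
    radii = spec.layer_radii_mm()
    idx = np.indices(spec.shape, dtype=float)
    pos = idx * spec.voxel_size_mm
    r = np.sqrt(((pos - spec.center_mm.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[r <= radii["scalp_skull"]] = 1
    labels[r <= radii["csf"]] = 2
    labels[r <= radii["gray"]] = 3
    labels[r <= radii["white"]] = 4
    if not labels.any():
        raise ValueError("phantom volume is all background")
    return HeadVolume(labels, spec.voxel_size_mm)


def generate_probe(phantom: PhantomSpec, probe: ProbeSpec,
                   ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Optode scalp positions (mm) and the neighbor-pair channel list.

    Returns (source_pos, detector_pos, pairs) with 1-based pair indices.
    """
    n_opt = probe.n_sources + probe.n_detectors
    if n_opt < 2:
        raise ValueError("need at least one source and one detector")
    theta = np.deg2rad(probe.polar_deg)
    az = 2 * np.pi * np.arange(n_opt) / n_opt
    r = phantom.head_radius_mm - 1.0  # just inside the scalp surface
    pos = np.column_stack([
        r * np.sin(theta) * np.cos(az),
        r * np.sin(theta) * np.sin(az),
        r * np.cos(theta) * np.ones(n_opt),
    ]) + phantom.center_mm
    # alternate S, D, S, D, ... around the ring
    src_slots = np.arange(0, n_opt, 2)[:probe.n_sources]
    det_slots = np.arange(1, n_opt, 2)[:probe.n_detectors]
    sources = pos[src_slots]
    detectors = pos[det_slots]
    slot_role = {}
    for i, s in enumerate(src_slots):
        slot_role[s] = ("s", i + 1)
    for i, d in enumerate(det_slots):
        slot_role[d] = ("d", i + 1)
    pairs: list[tuple[int, int]] = []
    for a in range(n_opt):
        b = (a + 1) % n_opt
        ra, ia = slot_role[a]
        rb, ib = slot_role[b]
        if ra == "s" and rb == "d":
            pairs.append((ia, ib))
        elif ra == "d" and rb == "s":
            pairs.append((ib, ia))
    return sources, detectors, pairs


def _banana(phantom_head: HeadVolume, src_mm: np.ndarray, det_mm: np.ndarray,
            falloff_mm: float) -> np.ndarray:
    """Geometric sensitivity surrogate for one source-detector pair.

    exp(-(|p-s| + |p-d| - |s-d|) / falloff) over tissue voxels, zero in
    background, peak-normalized.  Largest on the chord between the optodes,
    decaying with detour distance — banana-shaped once masked to tissue.
    """
    idx = np.indices(phantom_head.shape, dtype=float)
    pos = idx * phantom_head.voxel_size_mm
    ds = np.sqrt(((pos - np.asarray(src_mm).reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
    dd = np.sqrt(((pos - np.asarray(det_mm).reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
    sep = np.linalg.norm(np.asarray(src_mm) - np.asarray(det_mm))
    w = np.exp(-(ds + dd - sep) / falloff_mm)
    w[phantom_head.labels == 0] = 0.0
    peak = w.max()
    return w / peak if peak > 0 else w


def generate_sensitivity(phantom_head: HeadVolume,
                         source_pos_mm: np.ndarray,
                         detector_pos_mm: np.ndarray,
                         pairs: list[tuple[int, int]],
                         falloff_mm: float = 6.0) -> list[np.ndarray]:
    """Per-pair sensitivity volumes (shared across wavelengths)."""
    return [
        _banana(phantom_head, source_pos_mm[s - 1], detector_pos_mm[d - 1],
                falloff_mm)
        for s, d in pairs
    ]


def generate_sensitivity_model(phantom: PhantomSpec, probe: ProbeSpec,
                               threshold_frac: float = 0.01,
                               falloff_mm: float = 6.0,
                               ) -> tuple[SensitivityModel, HeadVolume,
                                          list[np.ndarray]]:
    """Phantom + probe -> vectorized A-matrix with both wavelength blocks.

    The same per-pair volume serves both wavelengths (adequate for a
    geometric surrogate).  Returns (model, head volume, per-pair volumes).
    """
    head = generate_phantom_head(phantom)
    sources, detectors, pairs = generate_probe(phantom, probe)
    vols = generate_sensitivity(head, sources, detectors, pairs, falloff_mm)
    measurements = make_measurement_list(pairs, probe.wavelengths_nm,
                                         sources, detectors)
    volumes = vols * len(probe.wavelengths_nm)
    model = vectorize_sensitivity(volumes, measurements, threshold_frac,
                                  voxel_size_mm=phantom.voxel_size_mm)
    return model, head, vols


# ---------------------------------------------------------------------------
# Digitizations


def make_cap_layout(cap_size_cm: float = 48.0, n_sources: int = 8,
                    n_detectors: int = 8) -> Cap:
    """Canonical cap geometry: 5 landmarks + optode rings on a sphere.

    The head is modeled as a sphere whose circumference equals the cap
    size; landmarks sit at nasion/inion/ears/vertex and optodes on two
    upper-hemisphere rings.  Deterministic — serves as the ground-truth
    layout the cap generators perturb.
    """
    r = cap_size_cm / (2 * np.pi)
    landmarks = np.array([
        [0.0, r, 0.0],    # nz
        [0.0, -r, 0.0],   # iz
        [r, 0.0, 0.0],    # ar
        [-r, 0.0, 0.0],   # al
        [0.0, 0.0, r],    # cz
    ])

    def ring(n: int, polar_deg: float, phase: float) -> np.ndarray:
        th = np.deg2rad(polar_deg)
        az = 2 * np.pi * np.arange(n) / n + phase
        return np.column_stack([
            r * np.sin(th) * np.cos(az),
            r * np.sin(th) * np.sin(az),
            r * np.cos(th) * np.ones(n),
        ])

    sources = ring(n_sources, 40.0, 0.0)
    detectors = ring(n_detectors, 60.0, np.pi / n_detectors)
    pts = np.vstack([landmarks, sources, detectors])
    roles = ([ROLE_LANDMARK] * 5 + [ROLE_SOURCE] * n_sources
             + [ROLE_DETECTOR] * n_detectors)
    labels = (["nz", "iz", "ar", "al", "cz"]
              + [f"s{i + 1}" for i in range(n_sources)]
              + [f"d{i + 1}" for i in range(n_detectors)])
    return Cap("layout", cap_size_cm, pts, roles, labels)


def generate_caps(template_layout: Cap, n: int, noise_sd_cm: float = 0.3,
                  n_outlier_points: int = 0, outlier_shift_cm: float = 15.0,
                  misorientation_deg: float = 20.0, seed: int = 0,
                  ) -> tuple[list[Cap], dict[str, list[int]]]:
    """Simulated digitization sessions of one cap layout.

    Each cap is the layout under a random rigid misorientation plus iid
    Gaussian jitter (digitization noise); ``n_outlier_points`` randomly
    chosen points per cap are additionally displaced by
    ``outlier_shift_cm`` in a random direction, simulating stylus slips.
    Returns the caps and the ground-truth outlier indices per cap id.
    """
    rng = np.random.default_rng(seed)
    caps: list[Cap] = []
    truth: dict[str, list[int]] = {}
    for k in range(n):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = np.deg2rad(misorientation_deg) * rng.uniform(-1, 1)
        kx = np.array([[0, -axis[2], axis[1]],
                       [axis[2], 0, -axis[0]],
                       [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(ang) * kx + (1 - np.cos(ang)) * kx @ kx
        trans = rng.normal(scale=2.0, size=3)
        pts = template_layout.points @ rot.T + trans
        pts = pts + rng.normal(scale=noise_sd_cm, size=pts.shape)
        out_idx = sorted(rng.choice(len(pts), size=n_outlier_points,
                                    replace=False).tolist()) if n_outlier_points else []
        for i in out_idx:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pts[i] += outlier_shift_cm * direction
        cap_id = f"cap{k + 1:02d}"
        caps.append(Cap(cap_id, template_layout.cap_size_cm, pts,
                        list(template_layout.roles),
                        list(template_layout.labels)))
        truth[cap_id] = out_idx
    return caps, truth


# ---------------------------------------------------------------------------
# Channel recordings


@dataclass
class NoiseModel:
    """Additive channel noise in optical-density units.

    ``physio`` is a sinusoid shared identically across channels of one
    wavelength (a systemic-physiology surrogate, removable by global signal
    regression); ``white_sd`` is iid Gaussian measurement noise.
    """

    white_sd: float = 0.02
    physio_amplitude: float = 0.15
    physio_freq_hz: float = 0.33


def default_paradigm(duration_s: float = 120.0, start_s: float = 10.0,
                     isi_s: float = 15.0,
                     conditions: tuple[str, ...] = ("condA", "condB"),
                     ) -> pd.DataFrame:
    """Alternating-condition event paradigm covering the recording."""
    onsets = np.arange(start_s, duration_s - 20.0 + 1e-9, isi_s)
    rows = [(float(t), conditions[i % len(conditions)])
            for i, t in enumerate(onsets)]
    return pd.DataFrame(rows, columns=["onset_s", "condition"])


@dataclass
class GroundTruth:
    """What was injected into a synthetic recording."""

    activation_col: int
    activation_flat: int
    condition_amplitudes_um: dict[str, tuple[float, float]]
    blob_sigma_mm: float
    blob_weights: np.ndarray
    clean_od: np.ndarray
    signal_channels: list[int]
    hbo_series: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def generate_channel_data(model: SensitivityModel,
                          paradigm: pd.DataFrame,
                          activation_col: int,
                          condition_amplitudes_um: dict[str, tuple[float, float]]
                          | None = None,
                          hrf: HRFSpec | None = None,
                          noise: NoiseModel | None = None,
                          fs: float = 50.0,
                          duration_s: float = 120.0,
                          blob_sigma_mm: float = 6.0,
                          boxcar_s: float = 4.5,
                          i0: float = 1e5,
                          extinction: ExtinctionTable = DEFAULT_EXTINCTION,
                          seed: int = 0,
                          ) -> tuple[ChannelRecording, GroundTruth]:
    """Forward-simulate a stimulus-locked channel recording.

    A Gaussian blob of hemoglobin change centered on retained voxel
    ``activation_col`` follows HRF-convolved event regressors (default
    amplitudes: condA (1.0, -0.3) uM HbO2/HbR, condB half that), is mapped
    to per-wavelength absorption via the extinction table, projected to
    measurements through A, summed with shared sinusoidal physiology and
    white noise, and exponentiated to raw intensities around ``i0``
    (100 dB for the default reference).
    """
    rng = np.random.default_rng(seed)
    if condition_amplitudes_um is None:
        condition_amplitudes_um = {"condA": (1.0, -0.3),
                                   "condB": (0.5, -0.15)}
    hrf = hrf or HRFSpec()
    noise = noise or NoiseModel()
    n_frames = int(round(duration_s * fs))
    kernel = gamma_hrf(hrf, fs)
    design, names, _ = build_design(paradigm, kernel, fs, n_frames,
                                    boxcar_s=boxcar_s, intercept=False)
    missing = set(names) - set(condition_amplitudes_um)
    if missing:
        raise ValueError(f"no amplitudes for conditions {sorted(missing)}")
    coords = model.good_vox_coords_mm()
    d2 = np.sum((coords - coords[activation_col]) ** 2, axis=1)
    blob = np.exp(-d2 / (2 * blob_sigma_mm ** 2))
    hbo_t = np.zeros(n_frames)
    hbr_t = np.zeros(n_frames)
    for j, name in enumerate(names):
        a_hbo, a_hbr = condition_amplitudes_um[name]
        hbo_t += a_hbo * design[:, j]
        hbr_t += a_hbr * design[:, j]
    wavelengths = tuple(sorted(
        np.unique(model.measurements["wavelength_nm"].to_numpy())))
    e = extinction.matrix(wavelengths)  # mm^-1 per uM
    clean_od = np.zeros((n_frames, model.n_measurements))
    for i, wl in enumerate(wavelengths):
        rows = model.wavelength_rows(wl)
        # d_mua(t, vox) = e[i,0]*HbO(t)*blob + e[i,1]*HbR(t)*blob
        dmua = np.outer(e[i, 0] * hbo_t + e[i, 1] * hbr_t, blob)
        clean_od[:, rows] = dmua @ model.A[rows].T
    t = np.arange(n_frames) / fs
    od = clean_od.copy()
    for wl in wavelengths:
        rows = model.wavelength_rows(wl)
        phase = rng.uniform(0, 2 * np.pi)
        physio = noise.physio_amplitude * np.sin(
            2 * np.pi * noise.physio_freq_hz * t + phase)
        od[:, rows] += physio[:, None]
    od += rng.normal(scale=noise.white_sd, size=od.shape)
    intensity = i0 * np.exp(-od)
    rec = ChannelRecording(intensity, fs, model.measurements.copy(),
                           paradigm=paradigm.copy())
    sd = clean_od.std(axis=0)
    signal_channels = np.flatnonzero(sd > 0.25 * sd.max()).tolist()
    truth = GroundTruth(
        activation_col=activation_col,
        activation_flat=int(model.good_vox[activation_col]),
        condition_amplitudes_um=dict(condition_amplitudes_um),
        blob_sigma_mm=blob_sigma_mm,
        blob_weights=blob,
        clean_od=clean_od,
        signal_channels=signal_channels,
        hbo_series=hbo_t,
    )
    return rec, truth


def pick_cortical_activation_voxel(model: SensitivityModel,
                                   head: HeadVolume,
                                   channel_row: int = 0) -> int:
    """Column (within good_vox) of one channel's cortical sensitivity maximum.

    Injecting activation at a channel's gray-matter sensitivity peak mirrors
    how reconstructions are verified (sphere at the cortical maximum), so the
    fixture exercises that geometry directly.
    """
    from .light_model import restrict_to_good_vox

    gray = restrict_to_good_vox(head.cortex_mask(), model.good_vox)
    masked = np.where(gray, model.A[channel_row], -np.inf)
    if masked.max() <= 0:
        raise ValueError("no retained gray-matter voxel with sensitivity")
    return int(np.argmax(masked))


def default_fixture(seed: int = 0, duration_s: float = 120.0,
                    ) -> dict:
    """The standard desk-scale end-to-end fixture.

    Phantom 40x40x40 at 2 mm, 8 channels x 2 wavelengths, ``duration_s``
    of data at 50 Hz (down-sampled to 25 Hz later in the pipeline), one
    cortical activation with condition amplitudes in ratio 2:1.
    """
    phantom = PhantomSpec()
    probe = ProbeSpec()
    model, head, vols = generate_sensitivity_model(phantom, probe)
    act = pick_cortical_activation_voxel(model, head)
    paradigm = default_paradigm(duration_s)
    rec, truth = generate_channel_data(model, paradigm, act,
                                       duration_s=duration_s, seed=seed)
    return {
        "phantom": phantom, "probe": probe, "model": model, "head": head,
        "volumes": vols, "recording": rec, "truth": truth,
        "paradigm": paradigm,
    }
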