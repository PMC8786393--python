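"""Pipeline configuration and staged execution with file hand-offs.

Stages run in the order simulate -> lightmodel -> preprocess -> reconstruct
-> glm -> verify, each reading its inputs from, and writing its outputs to,
a working directory; there is no hidden state between stages, so a run can
resume at any stage whose inputs exist.  Every stage writes a sidecar JSON
stamped with the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import channel_io, glm, light_model, preprocess, reconstruction
from . import synthetic, verification

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ["simulate", "lightmodel", "preprocess", "reconstruct", "glm",
          "verify"]


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output is missing."""


@dataclass
class PipelineConfig:
    """All pipeline tunables, with the processing defaults.

    Digitization correction thresholds are in cm; regularization and
    smoothing follow the reconstruction defaults (lambda1 0.01, lambda2 0.1,
    FWHM 6 mm); channel preprocessing uses 80-130 dB pruning, 0.016-0.5 Hz
    band-pass and 25 Hz resampling; verification uses the 0.25 correlation
    criterion.
    """

    seed: int = 0
    # digitization
    threestep_thresholds_cm: tuple[float, float, float] = (12.0, 10.0, 7.0)
    template_threshold_cm: float = 10.0
    # light model
    vectorize_threshold: float = 0.01
    # preprocessing
    prune_low_db: float = 80.0
    prune_high_db: float = 130.0
    bandpass_hp_hz: float = 0.016
    bandpass_lp_hz: float = 0.5
    trigger_window_s: tuple[float, float] = (-1.0, 18.0)
    resample_fs: float = 25.0
    # reconstruction
    lambda1: float = 0.01
    lambda2: float = 0.1
    fwhm_mm: float = 6.0
    wavelengths_nm: tuple[float, float] = (690.0, 830.0)
    # GLM
    hrf: glm.HRFSpec = field(default_factory=glm.HRFSpec)
    boxcar_s: float = 4.5
    # verification
    criterion: float = 0.25
    sphere_diameter_mm: float = 20.0
    # synthetic fixture
    duration_s: float = 120.0
    raw_fs: float = 50.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "hrf" in d and isinstance(d["hrf"], dict):
            d["hrf"] = glm.HRFSpec(**d["hrf"])
        for key in ("threestep_thresholds_cm", "trigger_window_s",
                    "wavelengths_nm"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        return cls.from_dict(data or {})

    def validate(self) -> None:
        d1, d2, d3 = self.threestep_thresholds_cm
        if not d1 >= d2 >= d3 > 0:
            raise ValueError("threestep thresholds must be decreasing, > 0")
        if not 0 < self.vectorize_threshold < 1:
            raise ValueError("vectorize_threshold must be in (0, 1)")
        if not 0 < self.bandpass_hp_hz < self.bandpass_lp_hz:
            raise ValueError("band-pass cutoffs out of order")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization parameters must be >= 0")
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be positive")
        if len(self.wavelengths_nm) != 2:
            raise ValueError("exactly two wavelengths required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp(workdir: Path, stage: str, cfg: PipelineConfig,
           outputs: list[str]) -> None:
    (workdir / f"{stage}.json").write_text(json.dumps(
        {"stage": stage, "config_hash": cfg.hash(), "outputs": outputs},
        indent=2))


def _require(workdir: Path, name: str, producer: str) -> Path:
    p = workdir / name
    if not p.exists():
        raise MissingArtifactError(
            f"missing {name}; run the '{producer}' stage first")
    return p


def _stage_simulate(cfg: PipelineConfig, workdir: Path) -> None:
    phantom = synthetic.PhantomSpec()
    probe = synthetic.ProbeSpec(wavelengths_nm=cfg.wavelengths_nm)
    model, head, vols = synthetic.generate_sensitivity_model(
        phantom, probe, threshold_frac=cfg.vectorize_threshold)
    act = synthetic.pick_cortical_activation_voxel(model, head)
    paradigm = synthetic.default_paradigm(cfg.duration_s)
    rec, truth = synthetic.generate_channel_data(
        model, paradigm, act, fs=cfg.raw_fs, duration_s=cfg.duration_s,
        boxcar_s=cfg.boxcar_s, hrf=cfg.hrf, seed=cfg.seed)
    light_model.head_volume_to_nifti(head, workdir / "head.nii.gz")
    pairs = model.measurements[model.measurements.wavelength_nm
                               == cfg.wavelengths_nm[0]]
    n_pairs = len(pairs)
    sens_paths = []
    for i in range(n_pairs):
        p = workdir / f"sensitivity_{i:03d}.nii.gz"
        light_model.write_nifti(vols[i], p, affine=head.affine)
        sens_paths.append(p.name)
    channel_io.write_csv(rec, workdir / "channels")
    model.measurements.to_csv(workdir / "measurements.csv", index=False)
    truth_doc = {
        "activation_col": truth.activation_col,
        "activation_flat": truth.activation_flat,
        "condition_amplitudes_um": truth.condition_amplitudes_um,
        "blob_sigma_mm": truth.blob_sigma_mm,
        "signal_channels": truth.signal_channels,
        "voxel_size_mm": phantom.voxel_size_mm,
    }
    (workdir / "ground_truth.json").write_text(json.dumps(truth_doc, indent=2))
    _stamp(workdir, "simulate", cfg,
           ["head.nii.gz", *sens_paths, "channels.data.csv",
            "measurements.csv", "ground_truth.json"])


def _stage_lightmodel(cfg: PipelineConfig, workdir: Path) -> None:
    _require(workdir, "head.nii.gz", "simulate")
    measurements = pd.read_csv(_require(workdir, "measurements.csv",
                                        "simulate"))
    sens_paths = sorted(workdir.glob("sensitivity_*.nii.gz"))
    if not sens_paths:
        raise MissingArtifactError(
            "missing sensitivity_*.nii.gz; run the 'simulate' stage first")
    vols, affine = light_model.read_nifti_sensitivity(sens_paths)
    n_wl = measurements["wavelength_nm"].nunique()
    volumes = vols * n_wl  # per-pair volumes shared across wavelengths
    head = light_model.head_volume_from_nifti(workdir / "head.nii.gz")
    model = light_model.vectorize_sensitivity(
        volumes, measurements, cfg.vectorize_threshold,
        voxel_size_mm=head.voxel_size_mm, affine=affine)
    np.savez_compressed(
        workdir / "model.npz", A=model.A, good_vox=model.good_vox,
        shape=np.array(model.shape), voxel_size_mm=model.voxel_size_mm,
        threshold=model.threshold_used, affine=model.affine)
    _stamp(workdir, "lightmodel", cfg, ["model.npz"])


def _load_model(workdir: Path) -> light_model.SensitivityModel:
    z = np.load(_require(workdir, "model.npz", "lightmodel"))
    measurements = pd.read_csv(_require(workdir, "measurements.csv",
                                        "simulate"))
    return light_model.SensitivityModel(
        A=z["A"], good_vox=z["good_vox"], shape=tuple(z["shape"]),
        voxel_size_mm=float(z["voxel_size_mm"]), measurements=measurements,
        threshold_used=float(z["threshold"]), affine=z["affine"])


def _stage_preprocess(cfg: PipelineConfig, workdir: Path) -> None:
    _require(workdir, "channels.data.csv", "simulate")
    rec = channel_io.read_csv(workdir / "channels")
    rec = preprocess.prune_channels(rec, cfg.prune_low_db, cfg.prune_high_db)
    rec = preprocess.intensity_to_od(rec)
    rec = preprocess.reject_triggers(rec, [], window_s=cfg.trigger_window_s)
    rec = preprocess.bandpass(rec, cfg.bandpass_hp_hz, cfg.bandpass_lp_hz)
    channel_side = preprocess.resample(rec, cfg.resample_fs)
    channel_io.write_csv(channel_side, workdir / "channels_od")
    recon_side = preprocess.resample(preprocess.global_signal_regression(rec),
                                     cfg.resample_fs)
    channel_io.write_csv(recon_side, workdir / "recon_input")
    np.save(workdir / "good_meas.npy", channel_side.good_meas)
    _stamp(workdir, "preprocess", cfg,
           ["channels_od.data.csv", "recon_input.data.csv", "good_meas.npy"])


def _stage_reconstruct(cfg: PipelineConfig, workdir: Path) -> None:
    model = _load_model(workdir)
    _require(workdir, "recon_input.data.csv", "preprocess")
    rec = channel_io.read_csv(workdir / "recon_input", unit="od")
    res = reconstruction.reconstruct_hemoglobin(
        model, rec.data, cfg.wavelengths_nm, rec.fs,
        lambda1=cfg.lambda1, lambda2=cfg.lambda2, fwhm_mm=cfg.fwhm_mm)
    np.savez_compressed(workdir / "recon.npz", hbo=res.hbo, hbr=res.hbr,
                        fs=res.fs)
    _stamp(workdir, "reconstruct", cfg, ["recon.npz"])


def _stage_glm(cfg: PipelineConfig, workdir: Path) -> None:
    model = _load_model(workdir)
    z = np.load(_require(workdir, "recon.npz", "reconstruct"))
    rec = channel_io.read_csv(_require(workdir, "recon_input.data.csv",
                                       "preprocess").parent / "recon_input",
                              unit="od")
    fs = float(z["fs"])
    kernel = glm.gamma_hrf(cfg.hrf, fs)
    design, names, counts = glm.build_design(
        rec.paradigm, kernel, fs, z["hbo"].shape[0], boxcar_s=cfg.boxcar_s)
    design = glm.filter_design(design, names, fs, cfg.bandpass_hp_hz,
                               cfg.bandpass_lp_hz)
    outputs = ["betas.npz"]
    betas = {}
    for chromo in ("hbo", "hbr"):
        fit = glm.fit_glm(z[chromo], design, names, counts)
        betas[chromo] = fit.betas
        for name in counts:
            vol = light_model.embed_to_volume(
                fit.condition_betas(name), model.good_vox, model.shape)
            out = workdir / f"beta_{chromo}_{name}.nii.gz"
            light_model.write_nifti(vol, out, affine=model.affine)
            outputs.append(out.name)
    np.savez_compressed(workdir / "betas.npz", regressors=np.array(names),
                        **{f"betas_{c}": b for c, b in betas.items()})
    _stamp(workdir, "glm", cfg, outputs)


def _stage_verify(cfg: PipelineConfig, workdir: Path) -> None:
    model = _load_model(workdir)
    head = light_model.head_volume_from_nifti(
        _require(workdir, "head.nii.gz", "simulate"))
    z = np.load(_require(workdir, "recon.npz", "reconstruct"))
    chan = channel_io.read_csv(
        _require(workdir, "channels_od.data.csv", "preprocess").parent
        / "channels_od", unit="od")
    wl_a, wl_b = cfg.wavelengths_nm
    rows_a, rows_b = (model.wavelength_rows(w) for w in (wl_a, wl_b))
    cortex = head.cortex_mask()
    rows = []
    for ch in range(len(rows_a)):
        vol = light_model.embed_to_volume(model.A[rows_a[ch]], model.good_vox,
                                          model.shape)
        roi = verification.sphere_at_channel_max(
            vol, cortex, model, channel=ch,
            diameter_mm=cfg.sphere_diameter_mm)
        hbo_ch, hbr_ch, _ = reconstruction.spectroscopy(
            chan.data[:, rows_a[ch]], chan.data[:, rows_b[ch]],
            cfg.wavelengths_nm)
        for chromo, ch_series, img_series in (
                ("hbo", hbo_ch, z["hbo"]), ("hbr", hbr_ch, z["hbr"])):
            img = verification.extract_mean_timeseries(img_series, roi)
            r, _ = verification.correlate_channel_image(ch_series, img,
                                                        cfg.criterion)
            rows.append({"channel": ch, "chromophore": chromo, "r": r})
    report = verification.verification_report(rows, cfg.criterion)
    report.to_csv(workdir / "verification.tsv", sep="\t", index=False)
    (workdir / "verification_summary.json").write_text(json.dumps({
        "n_total": report.attrs["n_total"],
        "n_passed": report.attrs["n_passed"],
        "mean_r_passing": report.attrs["mean_r_passing"],
        "criterion": cfg.criterion,
    }, indent=2))
    _stamp(workdir, "verify", cfg,
           ["verification.tsv", "verification_summary.json"])


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "lightmodel": _stage_lightmodel,
    "preprocess": _stage_preprocess,
    "reconstruct": _stage_reconstruct,
    "glm": _stage_glm,
    "verify": _stage_verify,
}


def run_pipeline(cfg: PipelineConfig, workdir: str | Path,
                 stages: list[str] | None = None) -> list[str]:
    """Execute the requested stages in canonical order; returns those run.

    ``stages=None`` runs everything; an empty list is a no-op.  A stage
    whose upstream artifact is missing raises
    :class:`MissingArtifactError` naming the producing stage.
    """
    if stages is None:
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        _STAGE_FUNCS[stage](cfg, workdir)
    return ordered
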