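# dotkit

Image-reconstructed functional near-infrared spectroscopy (fNIRS) for
developmental and cognitive neuroscience labs: instead of analyzing
source–detector channel time series on the scalp, channel data are
reconstructed into a segmented volumetric head model (diffuse optical
tomography) and analyzed voxelwise, like fMRI.

The package covers the full chain:

- **Optode digitization cleaning** — Polhemus digitizations of one cap size
  are mutually aligned with the Kabsch algorithm (the closed-form proper
  rotation minimizing RMSD), averaged into a per-size template, and
  individual caps are corrected against it by three-step, iterative, or
  head-wise replacement; cleaned caps export as `digpts.txt` (mm).
- **Sensitivity vectorization** — per-measurement sensitivity volumes are
  stacked into a matrix `A` (measurements × voxels), keeping only voxels
  whose sensitivity exceeds 0.01 of the global maximum for some measurement
  (`good_vox` indexing, typically a 5–10× size reduction).
- **Channel preprocessing** — 80–130 dB signal-level pruning, optical
  density conversion OD(t) = −ln(I(t)/Ī), stimulus-trigger rejection in a
  (−1, +18) s artifact window, zero-phase 0.016–0.5 Hz band-pass, global
  signal regression per wavelength, and 25 Hz resampling.
- **Reconstruction** — per-wavelength Tikhonov inversion of the objective
  min‖y − Ax‖² + λ₁‖Lx‖² with spatially variant penalty
  diag(L) = √(diag(AᵀA) + λ₂), defaults λ₁ = 0.01, λ₂ = 0.1; Gaussian
  smoothing (3–10 mm FWHM); spectroscopic conversion of two-wavelength
  absorption changes to ΔHbO₂/ΔHbR/ΔHbT (μM) via the tabulated extinction
  coefficients.
- **GLM** — double-gamma HRF (delay 4/15 s, dispersions 1/1, ratio 6,
  16 s kernel) convolved with boxcar event trains; voxelwise OLS betas;
  event-count-weighted averaging across runs.
- **Verification** — a 2 cm sphere at each channel's cortex-constrained
  sensitivity maximum; the sphere-mean reconstructed series is correlated
  with the channel-space series and checked against the r > 0.25 criterion.
- **Synthetic phantoms** — seeded generators for every input (layered
  spherical head, geometric sensitivity "bananas", cap digitizations with
  stylus-slip outliers, stimulus-locked channel recordings with systemic
  physiology and measurement noise), so the whole pipeline runs and is
  tested with no real recordings.

## Worked example

Run the seeded end-to-end fixture — phantom head, 16-channel probe at two
wavelengths (690/830 nm), 120 s of stimulus-locked data with two event
conditions whose injected HbO₂ amplitudes are in a 2:1 ratio:

```sh
dotkit run --workdir work --seed 1
```

or from Python:

```python
from dotkit.pipeline import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(seed=1), "work")
```

`work/` then contains the head segmentation and per-channel sensitivities
(NIFTI), the simulated recording (CSV dialect), the vectorized model
(`model.npz`), reconstructed chromophore time series (`recon.npz`), beta
maps per condition and chromophore (NIFTI + `betas.npz`), and
`verification_summary.json`:

```json
{"n_total": 32, "n_passed": 27, "mean_r_passing": 0.42, "criterion": 0.25}
```

32 correlations = 16 channels × 2 chromophores; channels far from the
injected activation carry no signal, so their correlations are
noise-driven and some fall below criterion, while every signal-bearing
channel passes.

Digitization cleaning is exposed separately:

```sh
dotkit caps build-template cap1.txt cap2.txt cap3.txt \
    --sources 8 --detectors 8 --threshold 10 --out template.txt
dotkit caps correct cap1.txt --template template.txt \
    --sources 8 --detectors 8 --method threestep --thresholds 12,10,7 \
    --out-dir corrected/
```

## Layout

| Module | Role |
| --- | --- |
| `dotkit.digitization` | Polhemus/digpts I/O, Kabsch alignment, templates, corrections |
| `dotkit.light_model` | A-matrix vectorization, `good_vox` indexing, NIFTI I/O |
| `dotkit.preprocess` | channel pruning, OD, band-pass, trigger rejection, GSR, resampling |
| `dotkit.reconstruction` | Tikhonov inversion, smoothing, spectroscopy |
| `dotkit.glm` | HRF, design construction, OLS, run-weighted betas |
| `dotkit.verification` | sphere ROIs, channel-vs-image correlation reports |
| `dotkit.synthetic` | seeded phantom/probe/cap/recording generators |
| `dotkit.channel_io` | SNIRF (HDF5) and CSV recording I/O |
| `dotkit.pipeline`, `dotkit.cli` | staged file-based pipeline and `dotkit` CLI |

See `docs/methods.md` for the underlying models, parameter choices, and
what the synthetic phantom does and does not emulate.
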