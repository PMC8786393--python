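"""Voxelwise GLM on reconstructed chromophore time series.

Event trains (optionally boxcars) are convolved with a hemodynamic response
function — by default a double-gamma kernel — to form design regressors;
ordinary least squares gives per-voxel betas.  Betas from multiple runs are
combined by an event-count-weighted average per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "HRFSpec",
    "GLMResult",
    "gamma_hrf",
    "build_design",
    "filter_design",
    "fit_glm",
    "weighted_average_betas",
]


@dataclass
class HRFSpec:
    """Double-gamma HRF parameters (seconds), or a user-supplied kernel.

    The canonical kernel is a difference of gamma densities: a positive
    response lobe minus an undershoot lobe scaled down by ``ratio``.
    Defaults: delay of response 4, delay of undershoot 15, dispersions 1,
    response:undershoot ratio 6, onset 0, kernel length 16 s.  If
    ``kernel`` is given (with ``kernel_fs``), it is used verbatim.
    """

    delay_response: float = 4.0
    delay_undershoot: float = 15.0
    dispersion_response: float = 1.0
    dispersion_undershoot: float = 1.0
    ratio: float = 6.0
    onset_s: float = 0.0
    kernel_length_s: float = 16.0
    kernel: np.ndarray | None = None
    kernel_fs: float | None = None

    def __post_init__(self) -> None:
        if self.kernel_length_s <= 0:
            raise ValueError("kernel length must be positive")
        if self.kernel is not None:
            self.kernel = np.asarray(self.kernel, dtype=float)
            if not np.all(np.isfinite(self.kernel)):
                raise ValueError("sampled kernel must be finite")
            if self.kernel_fs is None or self.kernel_fs <= 0:
                raise ValueError("kernel_fs required with a sampled kernel")


def gamma_hrf(spec: HRFSpec, fs: float) -> np.ndarray:
    """Sample the HRF kernel at ``fs`` Hz, peak-normalized to 1.

    h(t) = Gpdf(t; delay_r/disp_r, disp_r)
         - Gpdf(t; delay_u/disp_u, disp_u) / ratio,
    truncated at ``kernel_length_s`` and shifted by ``onset_s``.  The
    positive lobe peaks at delay_response - dispersion_response (the gamma
    mode).  A sampled kernel in the spec is resampled by linear
    interpolation if its rate differs.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if spec.kernel is not None:
        if np.isclose(spec.kernel_fs, fs):
            k = spec.kernel.copy()
        else:
            t_src = np.arange(len(spec.kernel)) / spec.kernel_fs
            t_dst = np.arange(0, t_src[-1] + 0.5 / fs, 1.0 / fs)
            k = np.interp(t_dst, t_src, spec.kernel)
        peak = np.max(np.abs(k))
        return k / peak if peak > 0 else k
    if spec.dispersion_response <= 0 or spec.dispersion_undershoot <= 0:
        raise ValueError("dispersions must be positive")
    n = int(round(spec.kernel_length_s * fs))
    t = np.arange(n) / fs - spec.onset_s
    pos = stats.gamma.pdf(t, a=spec.delay_response / spec.dispersion_response,
                          scale=spec.dispersion_response)
    neg = stats.gamma.pdf(t, a=spec.delay_undershoot / spec.dispersion_undershoot,
                          scale=spec.dispersion_undershoot)
    h = pos - neg / spec.ratio
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF (identically zero on the grid)")
    return h / peak


def build_design(paradigm: pd.DataFrame, hrf_kernel: np.ndarray, fs: float,
                 n_frames: int, boxcar_s: float = 0.0,
                 condition_map: Mapping[str, str] | None = None,
                 intercept: bool = True,
                 ) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Convolve per-condition event trains with the HRF.

    ``paradigm`` has columns ``onset_s`` and ``condition``.  Each event is
    an impulse (``boxcar_s == 0``) or a boxcar of that duration, at frame
    resolution; each condition's train is convolved with ``hrf_kernel`` and
    truncated to ``n_frames``.  ``condition_map`` optionally collapses
    conditions onto shared regressors (condition -> regressor name).

    Returns (design matrix, regressor names, per-regressor event counts).
    Regressor names are sorted; the intercept column (all ones) is last.
    """
    if len(paradigm) == 0:
        raise ValueError("empty paradigm: no events to model")
    onsets = paradigm["onset_s"].to_numpy(dtype=float)
    if np.any(onsets * fs >= n_frames):
        raise ValueError("trigger beyond the end of the recording")
    conds = paradigm["condition"].astype(str)
    if condition_map is not None:
        conds = conds.map(lambda c: condition_map.get(c, c))
    names = sorted(conds.unique())
    box_frames = max(1, int(round(boxcar_s * fs)))
    cols = []
    counts: dict[str, int] = {}
    for name in names:
        train = np.zeros(n_frames)
        sel = onsets[(conds == name).to_numpy()]
        counts[name] = len(sel)
        for t0 in sel:
            i0 = int(round(t0 * fs))
            train[i0:i0 + box_frames] += 1.0
        reg = np.convolve(train, hrf_kernel)[:n_frames]
        cols.append(reg)
    if intercept:
        cols.append(np.ones(n_frames))
        names = names + ["intercept"]
    return np.column_stack(cols), names, counts


def filter_design(design: np.ndarray, regressors: Sequence[str], fs: float,
                  f_hp: float = 0.016, f_lp: float = 0.5, order: int = 3,
                  skip: tuple[str, ...] = ("intercept",)) -> np.ndarray:
    """Band-pass the design columns with the data's filter.

    When the time series have been temporally filtered, the regressors must
    pass through the same (zero-phase Butterworth) filter or the betas are
    biased toward whatever of the regressor survives the filtering.  Columns
    named in ``skip`` (the intercept) are left untouched.
    """
    sos = signal.butter(order, [f_hp, f_lp], btype="bandpass", fs=fs,
                        output="sos")
    out = np.asarray(design, dtype=float).copy()
    cols = [i for i, n in enumerate(regressors) if n not in skip]
    out[:, cols] = signal.sosfiltfilt(sos, out[:, cols], axis=0)
    return out


@dataclass
class GLMResult:
    """Per-voxel betas for one run.

    ``betas`` is regressor x voxel, row order matching ``regressors``;
    ``event_counts`` maps condition regressors to the number of events
    driving them in this run.
    """

    betas: np.ndarray
    design: np.ndarray
    regressors: list[str]
    event_counts: dict[str, int]
    residual_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def condition_betas(self, name: str) -> np.ndarray:
        return self.betas[self.regressors.index(name)]


def fit_glm(series: np.ndarray, design: np.ndarray,
            regressors: Sequence[str] | None = None,
            event_counts: Mapping[str, int] | None = None) -> GLMResult:
    """Ordinary least squares per voxel.

    ``series`` is time x voxel; ``design`` time x regressor.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    design = np.asarray(design, dtype=float)
    if series.shape[0] != design.shape[0]:
        raise ValueError("frame count must match design rows")
    n, p = design.shape
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        # name columns involved in the deficiency via small singular values
        _, s, vt = np.linalg.svd(design, full_matrices=False)
        bad = np.flatnonzero(np.abs(vt[rank:]).max(axis=0) > 1e-8)
        names = ([str(i) for i in bad] if regressors is None
                 else [regressors[i] for i in bad])
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear columns: {names}")
    betas, _, _, _ = np.linalg.lstsq(design, series, rcond=None)
    resid = series - design @ betas
    dof = max(n - rank, 1)
    resid_var = np.sum(resid ** 2, axis=0) / dof
    return GLMResult(
        betas=betas, design=design,
        regressors=list(regressors) if regressors is not None
        else [str(i) for i in range(p)],
        event_counts=dict(event_counts or {}),
        residual_variance=resid_var,
    )


def weighted_average_betas(results: Sequence[GLMResult],
                           ) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Combine runs: per condition, betas averaged weighted by event counts.

    beta_bar_c = sum_r n_rc * beta_rc / sum_r n_rc.  Conditions with zero
    total events are dropped (flagged by absence); all runs must share the
    condition set.  Returns (betas condition x voxel, condition names,
    total event counts).
    """
    if not results:
        raise ValueError("no runs to combine")
    cond_names = sorted(results[0].event_counts)
    for r in results[1:]:
        if sorted(r.event_counts) != cond_names:
            raise ValueError("runs must share one condition set")
    kept: list[str] = []
    rows = []
    totals: dict[str, int] = {}
    for c in cond_names:
        n_tot = sum(r.event_counts[c] for r in results)
        totals[c] = n_tot
        if n_tot == 0:
            continue
        acc = sum(r.event_counts[c] * r.condition_betas(c) for r in results)
        kept.append(c)
        rows.append(acc / n_tot)
    if not kept:
        raise ValueError("zero events for every condition across runs")
    return np.stack(rows), kept, totals
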