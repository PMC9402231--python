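"""Raw-trace preprocessing: temporal filtering, neuropil-contamination
correction, ΔF/F, and active-period detection.

The contamination model is additive: the apparent somatic signal is the true
somatic signal plus ``r`` times the mean-centred surround (neuropil) signal.
``r`` is fitted per cell by least squares on quiet frames (no obvious
spontaneous activity) and the correction is

    F_corrected(t) = F_apparent(t) - r * [F_surround(t) - mean(F_surround)]

which leaves the trace mean untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import butter, sosfiltfilt
from sklearn.base import BaseEstimator

from .config import DETECTION_DFF, FilterSettings, ProcessingConfig
from .simulate import Recording


@dataclass
class ContaminationEstimate:
    """Least-squares contamination ratio for one cell."""

    r: float
    baseline_mask: np.ndarray
    fit_residual: float


@dataclass
class DffTrace:
    """ΔF/F values and the baseline F0 they were computed against."""

    values: np.ndarray
    f0: np.ndarray | float


@dataclass
class ProcessedRecording:
    """Output of the full preprocessing chain for one recording."""

    dff: np.ndarray                # (n_cells, n_frames)
    raster: np.ndarray             # boolean (n_cells, n_frames)
    r: np.ndarray                  # per-cell contamination ratio
    baseline_mask: np.ndarray      # (n_cells, n_frames)
    f0: np.ndarray                 # (n_cells, n_frames) baseline used
    frame_rate_hz: float
    labels: np.ndarray | None = None


def _validate_series(x: np.ndarray, name: str = "trace") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains NaN or infinite frames; "
                         "drop or repair them before processing")
    return x


def butterworth_highcut(trace: np.ndarray, frame_rate_hz: float,
                        settings: FilterSettings | None = None) -> np.ndarray:
    """Zero-phase Butterworth low-pass (high-cut) along the last axis."""
    settings = settings or FilterSettings()
    settings.validate()
    trace = _validate_series(trace)
    cutoff_hz = 1.0 / settings.highcut_period_s
    nyquist = frame_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"high-cut frequency {cutoff_hz} Hz is at or above "
                         f"the Nyquist frequency {nyquist} Hz")
    if trace.shape[-1] <= 10 * settings.butterworth_order:
        raise ValueError("series too short for the requested filter order")
    sos = butter(settings.butterworth_order, cutoff_hz, btype="low",
                 fs=frame_rate_hz, output="sos")
    return sosfiltfilt(sos, trace, axis=-1)


def gaussian_lowcut(trace: np.ndarray, frame_rate_hz: float,
                    settings: FilterSettings | None = None) -> np.ndarray:
    """Remove slow baseline by subtracting a Gaussian-smoothed copy.

    sigma = lowcut_period_s / (2*pi), putting the smoother's -3 dB point
    near 1/lowcut_period_s Hz.
    """
    settings = settings or FilterSettings()
    settings.validate()
    trace = _validate_series(trace)
    sigma_frames = settings.lowcut_period_s / (2.0 * np.pi) * frame_rate_hz
    smooth = gaussian_filter1d(trace, sigma_frames, axis=-1, mode="reflect")
    return trace - smooth


def bandpass_filter(trace: np.ndarray, frame_rate_hz: float,
                    settings: FilterSettings | None = None) -> np.ndarray:
    """High-cut Butterworth followed by Gaussian low-cut; zero-mean output."""
    return gaussian_lowcut(butterworth_highcut(trace, frame_rate_hz, settings),
                           frame_rate_hz, settings)


def find_baseline_mask(cell: np.ndarray, surround: np.ndarray,
                       frame_rate_hz: float,
                       quantile: float = 0.5,
                       window_s: float = 1.0,
                       min_frames: int = 40,
                       settings: FilterSettings | None = None) -> np.ndarray:
    """Frames with no obvious spontaneous activity in cell *and* surround.

    The activity score is a ~1 s moving average of the rectified band-passed
    trace (rectification keeps the mask indifferent to the phase of residual
    slow drift); a frame enters the mask when both scores sit at or below the
    given per-trace quantile.  Works on single traces or (n_cells, n_frames)
    stacks (row-wise masks).
    """
    cell = _validate_series(cell, "cell")
    surround = _validate_series(surround, "surround")
    if cell.shape != surround.shape:
        raise ValueError("cell and surround must share shape")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")

    win = max(int(round(window_s * frame_rate_hz)), 1)
    score_c = uniform_filter1d(
        np.abs(bandpass_filter(cell, frame_rate_hz, settings)),
        win, axis=-1, mode="nearest")
    score_s = uniform_filter1d(
        np.abs(bandpass_filter(surround, frame_rate_hz, settings)),
        win, axis=-1, mode="nearest")
    qc = np.quantile(score_c, quantile, axis=-1, keepdims=True)
    qs = np.quantile(score_s, quantile, axis=-1, keepdims=True)
    # Slack breaks numerical ties on (near-)constant traces, where the score
    # is filter residue many orders below the fluorescence scale.
    slack_c = 1e-9 * np.abs(cell).max(axis=-1, keepdims=True)
    slack_s = 1e-9 * np.abs(surround).max(axis=-1, keepdims=True)
    mask = (score_c <= qc + slack_c) & (score_s <= qs + slack_s)
    if np.min(mask.sum(axis=-1)) < min_frames:
        raise ValueError(f"baseline mask smaller than {min_frames} frames; "
                         "increase the quantile")
    return mask


def estimate_contamination_ratio(cell: np.ndarray, surround: np.ndarray,
                                 baseline_mask: np.ndarray,
                                 ) -> ContaminationEstimate:
    """Least-squares contamination ratio on quiet (baseline) frames.

    Solves ``cell - mean(cell) = r * (surround - mean(surround))`` over the
    masked frames; the closed form is cov(cell, surround)/var(surround).
    """
    cell = _validate_series(cell, "cell")
    surround = _validate_series(surround, "surround")
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if cell.shape != surround.shape or cell.shape != baseline_mask.shape:
        raise ValueError("cell, surround and mask must share shape")
    if cell.ndim != 1:
        raise ValueError("estimate_contamination_ratio works on one cell; "
                         "see TraceProcessor for stacks")
    if not baseline_mask.any():
        raise ValueError("baseline mask is empty")
    x = surround[baseline_mask]
    y = cell[baseline_mask]
    x = x - x.mean()
    y = y - y.mean()
    sxx = float(x @ x)
    if sxx <= 1e-12 * len(x):
        raise ValueError("surround is constant on the baseline mask; "
                         "contamination ratio unidentifiable")
    r = float(x @ y) / sxx
    resid = y - r * x
    return ContaminationEstimate(r=r, baseline_mask=baseline_mask,
                                 fit_residual=float(resid @ resid))


def correct_neuropil(cell: np.ndarray, surround: np.ndarray,
                     r: float | np.ndarray) -> np.ndarray:
    """Subtract the scaled, mean-centred surround from the apparent trace.

    The subtracted term is zero-mean, so the corrected trace keeps the
    apparent trace's mean. ``r`` may be per-cell for stacked input.
    """
    cell = _validate_series(cell, "cell")
    surround = _validate_series(surround, "surround")
    if cell.shape != surround.shape:
        raise ValueError("cell and surround must share shape")
    r = np.asarray(r, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("r must be finite")
    centred = surround - surround.mean(axis=-1, keepdims=True)
    if cell.ndim == 2 and r.ndim == 1:
        r = r[:, None]
    return cell - r * centred


def _rolling_percentile(trace: np.ndarray, percentile: float,
                        window: int, stride: int) -> np.ndarray:
    """Strided rolling percentile with linear interpolation between centres."""
    trace2d = np.atleast_2d(trace)
    n = trace2d.shape[-1]
    half = window // 2
    centers = np.arange(0, n, max(stride, 1))
    if centers[-1] != n - 1:
        centers = np.append(centers, n - 1)
    vals = np.empty((trace2d.shape[0], len(centers)))
    for j, c in enumerate(centers):
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        vals[:, j] = np.percentile(trace2d[:, lo:hi], percentile, axis=-1)
    frames = np.arange(n)
    out = np.empty_like(trace2d)
    for i in range(trace2d.shape[0]):
        out[i] = np.interp(frames, centers, vals[i])
    return out.reshape(np.shape(trace))


def compute_dff(trace: np.ndarray, f0_method: str = "rolling_percentile",
                percentile: float = 10.0, window_s: float = 60.0,
                frame_rate_hz: float = 4.0, stride: int = 8,
                f0_smooth_s: float = 1.0) -> DffTrace:
    """ΔF/F = (F - F0)/F0 with a percentile baseline.

    ``rolling_percentile`` tracks slow drift with a per-frame F0 (the stated
    percentile over a centred window); ``global_percentile`` uses one F0 for
    the whole trace.  The percentile is taken over a lightly smoothed copy of
    the trace (sigma ``f0_smooth_s``); without this, a low percentile of the
    per-frame noise sits ~1.3 sigma below the true baseline and every ΔF/F
    value inherits a positive offset.
    """
    trace = _validate_series(trace)
    sm_sigma = max(f0_smooth_s, 0.0) * frame_rate_hz
    basis = (gaussian_filter1d(trace, sm_sigma, axis=-1, mode="reflect")
             if sm_sigma > 0 else trace)
    if f0_method == "global_percentile":
        f0 = np.percentile(basis, percentile, axis=-1, keepdims=True)
    elif f0_method == "rolling_percentile":
        window = max(int(round(window_s * frame_rate_hz)), 3)
        f0 = _rolling_percentile(basis, percentile, window, stride)
        if np.any(f0 <= 0):   # whole-trace fallback for pathological windows
            f0 = np.percentile(trace, percentile, axis=-1, keepdims=True)
            f0 = np.broadcast_to(f0, trace.shape).copy()
    else:
        raise ValueError(f"unknown f0_method {f0_method!r}")
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 is not positive; ΔF/F undefined")
    return DffTrace(values=(trace - f0) / f0, f0=np.squeeze(f0))


def detect_active_periods(dff: DffTrace | np.ndarray,
                          threshold: float = DETECTION_DFF) -> np.ndarray:
    """Active-period mask: frames whose ΔF/F meets the fixed criterion."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = dff.values if isinstance(dff, DffTrace) else np.asarray(dff,
                                                                     dtype=float)
    if values.size == 0:
        return np.zeros_like(values, dtype=bool)
    if not np.isfinite(values).all():
        raise ValueError("ΔF/F contains non-finite frames")
    return values >= threshold


class TraceProcessor(BaseEstimator):
    """Fit-and-transform preprocessing for a stack of cell/surround traces.

    ``fit`` applies the high-cut filter, finds each cell's quiet frames and
    estimates its contamination ratio; ``transform`` corrects the traces and
    returns ΔF/F.  Shapes are (n_cells, n_frames).

    Parameters mirror :class:`calsync.config.ProcessingConfig`.
    """

    def __init__(self, highcut_period_s: float = 1.0,
                 butterworth_order: int = 10,
                 lowcut_period_s: float = 120.0,
                 baseline_quantile: float = 0.5,
                 baseline_window_s: float = 1.0,
                 min_baseline_frames: int = 40,
                 f0_method: str = "rolling_percentile",
                 f0_percentile: float = 10.0,
                 f0_window_s: float = 60.0,
                 f0_stride: int = 8,
                 dff_threshold: float = DETECTION_DFF):
        self.highcut_period_s = highcut_period_s
        self.butterworth_order = butterworth_order
        self.lowcut_period_s = lowcut_period_s
        self.baseline_quantile = baseline_quantile
        self.baseline_window_s = baseline_window_s
        self.min_baseline_frames = min_baseline_frames
        self.f0_method = f0_method
        self.f0_percentile = f0_percentile
        self.f0_window_s = f0_window_s
        self.f0_stride = f0_stride
        self.dff_threshold = dff_threshold

    @classmethod
    def from_config(cls, cfg: ProcessingConfig) -> "TraceProcessor":
        return cls(highcut_period_s=cfg.filters.highcut_period_s,
                   butterworth_order=cfg.filters.butterworth_order,
                   lowcut_period_s=cfg.filters.lowcut_period_s,
                   baseline_quantile=cfg.baseline_quantile,
                   baseline_window_s=cfg.baseline_window_s,
                   min_baseline_frames=cfg.min_baseline_frames,
                   f0_method=cfg.f0_method,
                   f0_percentile=cfg.f0_percentile,
                   f0_window_s=cfg.f0_window_s,
                   f0_stride=cfg.f0_stride,
                   dff_threshold=cfg.dff_threshold)

    def _settings(self) -> FilterSettings:
        return FilterSettings(highcut_period_s=self.highcut_period_s,
                              butterworth_order=self.butterworth_order,
                              lowcut_period_s=self.lowcut_period_s)

    def fit(self, X: np.ndarray, y=None, *, surround: np.ndarray,
            frame_rate_hz: float = 4.0) -> "TraceProcessor":
        X = np.atleast_2d(_validate_series(X, "cell"))
        S = np.atleast_2d(_validate_series(surround, "surround"))
        if X.shape != S.shape:
            raise ValueError("cell and surround stacks must share shape")
        settings = self._settings()
        # High-cut only: slow shared drift is retained because it is what
        # identifies r on quiet frames.
        cell_f = butterworth_highcut(X, frame_rate_hz, settings)
        surr_f = butterworth_highcut(S, frame_rate_hz, settings)
        mask = find_baseline_mask(X, S, frame_rate_hz,
                                  quantile=self.baseline_quantile,
                                  window_s=self.baseline_window_s,
                                  min_frames=self.min_baseline_frames,
                                  settings=settings)
        r = np.empty(X.shape[0])
        resid = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            est = estimate_contamination_ratio(cell_f[i], surr_f[i], mask[i])
            r[i] = est.r
            resid[i] = est.fit_residual
        self.r_ = r
        self.fit_residual_ = resid
        self.baseline_mask_ = mask
        self.frame_rate_hz_ = float(frame_rate_hz)
        return self

    def transform(self, X: np.ndarray, *, surround: np.ndarray) -> np.ndarray:
        """Corrected ΔF/F for the fitted contamination ratios."""
        if not hasattr(self, "r_"):
            raise RuntimeError("TraceProcessor is not fitted")
        X = np.atleast_2d(_validate_series(X, "cell"))
        S = np.atleast_2d(_validate_series(surround, "surround"))
        settings = self._settings()
        cell_f = butterworth_highcut(X, self.frame_rate_hz_, settings)
        surr_f = butterworth_highcut(S, self.frame_rate_hz_, settings)
        corrected = correct_neuropil(cell_f, surr_f, self.r_)
        dff = compute_dff(corrected, f0_method=self.f0_method,
                          percentile=self.f0_percentile,
                          window_s=self.f0_window_s,
                          frame_rate_hz=self.frame_rate_hz_,
                          stride=self.f0_stride)
        self.f0_ = np.atleast_2d(dff.f0)
        return dff.values

    def fit_transform(self, X: np.ndarray, y=None, *, surround: np.ndarray,
                      frame_rate_hz: float = 4.0) -> np.ndarray:
        return self.fit(X, surround=surround,
                        frame_rate_hz=frame_rate_hz).transform(
                            X, surround=surround)

    def raster(self, dff: np.ndarray) -> np.ndarray:
        return detect_active_periods(dff, self.dff_threshold)


def process_recording(recording: Recording,
                      config: ProcessingConfig | None = None,
                      ) -> ProcessedRecording:
    """Run the full preprocessing chain on one recording."""
    cfg = config or ProcessingConfig()
    cfg.validate()
    proc = TraceProcessor.from_config(cfg)
    dff = proc.fit_transform(recording.cell_traces,
                             surround=recording.surround_traces,
                             frame_rate_hz=recording.frame_rate_hz)
    raster = proc.raster(dff)
    return ProcessedRecording(dff=dff, raster=raster, r=proc.r_,
                              baseline_mask=proc.baseline_mask_,
                              f0=proc.f0_,
                              frame_rate_hz=recording.frame_rate_hz,
                              labels=recording.labels)
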