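"""DSC perfusion processing.

Curve selection (Gaussian-dip resemblance), relaxivity conversion, linear
leakage correction against a non-enhancing reference curve, white-matter
normalized rCBV maps with the 99th-percentile hot-spot statistic, and
percentage of signal recovery.

Percentile convention: linear interpolation between order statistics
(numpy default) — rCBV-99 depends on it, so it is fixed here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import DscSeries, Volume3D
from .enhancement import EnhancementMask
from .phantom import PerfusionCurve

__all__ = [
    "PerfusionMetrics",
    "CurveFilterResult",
    "filter_curves",
    "delta_r2star",
    "boxerman_correct",
    "bolus_window",
    "rcbv_map",
    "rcbv99",
    "psr",
    "psr_max",
    "perfusion_metrics",
]


@dataclass
class PerfusionMetrics:
    rcbv99: float
    psr_max_percent: float
    n_curves_kept: int
    n_curves_rejected: int
    measurable: bool = True

    def as_dict(self) -> dict:
        return {
            "rcbv99": self.rcbv99,
            "psr_max_percent": self.psr_max_percent,
            "n_curves_kept": self.n_curves_kept,
            "n_curves_rejected": self.n_curves_rejected,
            "measurable": self.measurable,
        }


@dataclass
class CurveFilterResult:
    kept_idx: np.ndarray
    rejected_idx: np.ndarray
    fit_r: np.ndarray  # Pearson r of normalized curve vs fitted Gaussian dip


def _lowpass(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")
    return out[pad : pad + x.size] if pad else out


def normalize_minus1_0(x: np.ndarray) -> np.ndarray:
    """Min-max normalize so the bolus dip maps to -1 and the top to 0."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant curve: normalization undefined")
    return (x - hi) / (hi - lo)


def _gaussian_dip(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def _fit_gaussian_dip(y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares Gaussian dip fit; returns (fitted curve, Pearson r)."""
    t = np.arange(y.size, dtype=np.float64)
    mu0 = float(np.argmin(y))
    sigma0 = max(y.size / 10.0, 1.0)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian_dip, t, y, p0=(mu0, sigma0),
            bounds=([0.0, 0.5], [float(y.size), float(y.size)]), maxfev=2000,
        )
        fit = _gaussian_dip(t, *popt)
    except (RuntimeError, ValueError):
        fit = _gaussian_dip(t, mu0, sigma0)
    if np.std(fit) == 0 or np.std(y) == 0:
        return fit, 0.0
    r = float(np.corrcoef(y, fit)[0, 1])
    return fit, r


def filter_curves(
    curves: np.ndarray | list,
    smoothing_width: int = 3,
    gaussian_r_min: float = 0.9,
) -> CurveFilterResult:
    """Partition curves into bolus-bearing (kept) and noise (rejected).

    Each curve is low-pass filtered, normalized to [-1, 0], fitted with a
    Gaussian dip, and kept iff the Pearson correlation with the fit reaches
    ``gaussian_r_min``. Constant curves are rejected. Original signal values
    are untouched — only indices are returned.
    """
    arr = np.asarray([c.signal if isinstance(c, PerfusionCurve) else c for c in curves],
                     dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one 1D curve")
    kept, rejected, rs = [], [], np.zeros(arr.shape[0])
    for i, raw in enumerate(arr):
        smooth = _lowpass(raw, smoothing_width)
        if smooth.max() == smooth.min():
            rejected.append(i)
            rs[i] = np.nan
            continue
        norm = normalize_minus1_0(smooth)
        _, r = _fit_gaussian_dip(norm)
        rs[i] = r
        (kept if r >= gaussian_r_min else rejected).append(i)
    return CurveFilterResult(
        kept_idx=np.asarray(kept, dtype=int),
        rejected_idx=np.asarray(rejected, dtype=int),
        fit_r=rs,
    )


def delta_r2star(curve: PerfusionCurve | np.ndarray, te_ms: float | None = None,
                 n_baseline: int | None = None) -> np.ndarray:
    """Relaxivity change dR2*(t) = -(1/TE) ln(S(t)/S0), S0 = pre-bolus mean."""
    if isinstance(curve, PerfusionCurve):
        signal = curve.signal
        te_ms = te_ms if te_ms is not None else curve.te_ms
        n_baseline = n_baseline if n_baseline is not None else curve.n_baseline
    else:
        signal = np.asarray(curve, dtype=np.float64)
        if te_ms is None or n_baseline is None:
            raise ValueError("te_ms and n_baseline required for raw arrays")
    if np.any(signal <= 0):
        bad = int(np.argmax(signal <= 0))
        raise ValueError(f"nonpositive signal sample at time index {bad}")
    s0 = signal[:n_baseline].mean()
    if s0 <= 0:
        raise ValueError("nonpositive baseline mean")
    return -(1.0 / te_ms) * np.log(signal / s0)


def boxerman_correct(
    voxel_curves: np.ndarray,
    reference_curve: np.ndarray,
    dt_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leakage-correct dR2* curves against a non-enhancing reference.

    Per voxel, fits ``dR2*(t) = K1 ref(t) - K2 cumint(ref)(t)`` by linear
    least squares over all time points; the corrected curve adds the leakage
    term back: ``corrected = dR2* + K2 cumint(ref)``.

    Returns ``(corrected, K1, K2)``; ``voxel_curves`` may be (T,) or (N, T).
    """
    ref = np.asarray(reference_curve, dtype=np.float64)
    if not np.any(ref != 0):
        raise ValueError("degenerate reference curve (all zero)")
    curves = np.atleast_2d(np.asarray(voxel_curves, dtype=np.float64))
    cum = np.cumsum(ref) * dt_s
    design = np.stack([ref, -cum], axis=1)  # (T, 2)
    coef, *_ = np.linalg.lstsq(design, curves.T, rcond=None)
    k1, k2 = coef[0], coef[1]
    corrected = curves + np.outer(k2, cum)
    if np.asarray(voxel_curves).ndim == 1:
        return corrected[0], k1[0], k2[0]
    return corrected, k1, k2


def bolus_window(reference_curve: np.ndarray, n_baseline: int,
                 tail_frac: float = 0.05) -> tuple[int, int]:
    """(start, stop) indices of the bolus passage on the reference dR2* curve.

    Starts at the end of the baseline; stops at the first post-peak sample
    where the reference falls below ``tail_frac`` of its peak (else the end).
    """
    ref = np.asarray(reference_curve, dtype=np.float64)
    peak = int(np.argmax(ref))
    stop = ref.size
    if ref[peak] > 0:
        below = np.flatnonzero(ref[peak:] < tail_frac * ref[peak])
        if below.size:
            stop = peak + int(below[0]) + 1
    return int(n_baseline), int(stop)


def _integrate(curves: np.ndarray, window: tuple[int, int], dt_s: float) -> np.ndarray:
    start, stop = window
    return np.trapezoid(curves[..., start:stop], dx=dt_s, axis=-1)


def rcbv_map(
    corrected_curves: np.ndarray,
    wm_index: np.ndarray,
    window: tuple[int, int],
    dt_s: float = 1.0,
) -> np.ndarray:
    """White-matter-normalized rCBV per curve.

    Trapezoidal integral of the corrected dR2* over the bolus window, divided
    by the mean integral over the white-matter curves, so the WM mean is 1.
    """
    integrals = _integrate(np.asarray(corrected_curves, dtype=np.float64), window, dt_s)
    wm = integrals[np.asarray(wm_index)]
    if wm.size == 0:
        raise ValueError("empty white-matter ROI")
    wm_mean = wm.mean()
    if wm_mean <= 0:
        raise ValueError(f"nonpositive white-matter mean integral ({wm_mean:.3g})")
    return integrals / wm_mean


def rcbv99(values: np.ndarray | Volume3D, mask: np.ndarray | EnhancementMask | None = None):
    """99th percentile (linear-interpolation convention) over the mask."""
    arr = values.values if isinstance(values, Volume3D) else np.asarray(values, dtype=np.float64)
    if mask is not None:
        m = mask.values if isinstance(mask, EnhancementMask) else np.asarray(mask)
        arr = arr[m.astype(bool)]
    if arr.size == 0:
        return None  # non-measurable
    return float(np.percentile(arr, 99))


def psr(curve: PerfusionCurve | np.ndarray, n_baseline: int | None = None,
        tail_frac: float = 0.25) -> float:
    """Percentage of signal recovery: 100 (S_post - S_min)/(S_0 - S_min).

    S_0 is the pre-bolus baseline mean, S_min the bolus nadir, S_post the mean
    of the trailing ``tail_frac`` of samples. As a ratio of signal differences
    it is invariant under any positive affine rescaling of the signal axis.
    """
    if isinstance(curve, PerfusionCurve):
        signal, n_baseline = curve.signal, curve.n_baseline
    else:
        signal = np.asarray(curve, dtype=np.float64)
        if n_baseline is None:
            raise ValueError("n_baseline required for raw arrays")
    s0 = signal[:n_baseline].mean()
    s_min = signal[n_baseline:].min()
    if s0 <= s_min:
        raise ValueError("no bolus dip below baseline; curve should have been filtered out")
    n_tail = max(1, int(round(tail_frac * signal.size)))
    s_post = signal[-n_tail:].mean()
    return float(100.0 * (s_post - s_min) / (s0 - s_min))


def psr_max(curves, n_baseline: int | None = None, tail_frac: float = 0.25) -> float:
    """Maximum PSR over the kept curves of the enhancement mask."""
    vals = [psr(c, n_baseline=n_baseline, tail_frac=tail_frac) for c in curves]
    if not vals:
        raise ValueError("no curves")
    return float(max(vals))


def perfusion_metrics(
    dsc: DscSeries,
    mask: EnhancementMask,
    wm_roi: np.ndarray,
    gaussian_r_min: float = 0.9,
    smoothing_width: int = 3,
    tail_frac: float = 0.25,
) -> PerfusionMetrics:
    """End-to-end DSC analysis for one patient.

    Selects bolus-bearing curves inside the enhancement mask and the WM ROI,
    converts to dR2*, leakage-corrects against the mean non-enhancing (WM)
    curve, integrates to a WM-normalized rCBV and reports rCBV-99 and the
    maximum PSR within the mask.
    """
    wm = np.asarray(wm_roi).astype(bool)
    tumor = mask.values.astype(bool)
    if not wm.any():
        raise ValueError("empty white-matter ROI")
    if (wm & tumor).any():
        raise ValueError("white-matter ROI overlaps the enhancement mask")

    tumor_curves = dsc.values[tumor]
    wm_curves = dsc.values[wm]
    filt_t = filter_curves(tumor_curves, smoothing_width, gaussian_r_min)
    filt_w = filter_curves(wm_curves, smoothing_width, gaussian_r_min)
    n_rej = int(filt_t.rejected_idx.size)
    if filt_t.kept_idx.size == 0 or filt_w.kept_idx.size == 0:
        return PerfusionMetrics(float("nan"), float("nan"), 0, n_rej, measurable=False)

    kept_t = tumor_curves[filt_t.kept_idx]
    kept_w = wm_curves[filt_w.kept_idx]
    r2_t = np.stack([delta_r2star(c, dsc.te_ms, dsc.n_baseline) for c in kept_t])
    r2_w = np.stack([delta_r2star(c, dsc.te_ms, dsc.n_baseline) for c in kept_w])
    reference = r2_w.mean(axis=0)

    all_r2 = np.vstack([r2_t, r2_w])
    corrected, _, _ = boxerman_correct(all_r2, reference, dt_s=dsc.dt_s)
    window = bolus_window(reference, dsc.n_baseline)
    wm_index = np.arange(r2_t.shape[0], all_r2.shape[0])
    rcbv = rcbv_map(corrected, wm_index, window, dt_s=dsc.dt_s)
    rcbv_val = rcbv99(rcbv[: r2_t.shape[0]])
    psr_val = psr_max(kept_t, n_baseline=dsc.n_baseline, tail_frac=tail_frac)
    return PerfusionMetrics(
        rcbv99=float(rcbv_val),
        psr_max_percent=float(psr_val),
        n_curves_kept=int(filt_t.kept_idx.size),
        n_curves_rejected=n_rej,
    )
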