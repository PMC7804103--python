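"""Volume harmonization: bias correction, landmark intensity normalization,
resampling, rigid co-registration, cross-sequence intensity matching, and the
subtraction enhancement map.

All operations preserve spacing/origin metadata and accept/return
:class:`~resectquant.core.Volume3D`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import GridMismatchError, Volume3D

__all__ = [
    "IntensityMapping",
    "RigidTransform",
    "correct_bias",
    "nyul_fit",
    "nyul_apply",
    "resample",
    "register_rigid",
    "apply_rigid",
    "match_intensity",
    "intensity_gain_offset",
    "subtract",
    "DEFAULT_LANDMARK_PERCENTILES",
]

#: Min/max plus deciles — the common landmark choice for histogram matching.
DEFAULT_LANDMARK_PERCENTILES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)


@dataclass
class IntensityMapping:
    """Continuous piecewise-linear map between landmark percentiles and a
    standard intensity scale, extrapolated linearly beyond the end landmarks."""

    percentiles: np.ndarray  # which percentiles define the landmarks
    standard_scale: np.ndarray  # target landmark intensities

    def __post_init__(self) -> None:
        self.percentiles = np.asarray(self.percentiles, dtype=np.float64)
        self.standard_scale = np.asarray(self.standard_scale, dtype=np.float64)
        if self.percentiles.size != self.standard_scale.size:
            raise ValueError("landmark count mismatch")
        if self.percentiles.size < 2:
            raise ValueError("need at least 2 landmarks")
        if np.any(np.diff(self.percentiles) <= 0) or np.any(np.diff(self.standard_scale) <= 0):
            raise ValueError("landmarks must be strictly increasing")

    def map_values(self, values: np.ndarray, source_landmarks: np.ndarray) -> np.ndarray:
        src = np.asarray(source_landmarks, dtype=np.float64)
        if np.any(np.diff(src) <= 0):
            raise ValueError("degenerate histogram: source landmarks not strictly increasing")
        tgt = self.standard_scale
        out = np.interp(values, src, tgt)
        # linear extrapolation with the end-segment slopes
        lo = values < src[0]
        hi = values > src[-1]
        if np.any(lo):
            slope = (tgt[1] - tgt[0]) / (src[1] - src[0])
            out[lo] = tgt[0] + slope * (values[lo] - src[0])
        if np.any(hi):
            slope = (tgt[-1] - tgt[-2]) / (src[-1] - src[-2])
            out[hi] = tgt[-1] + slope * (values[hi] - src[-1])
        return out


@dataclass
class RigidTransform:
    """Rigid 3D transform: rotations (radians, x-y-z order) and translation (mm).

    Maps physical points of the *fixed* frame into the *moving* frame around a
    rotation center (defaults to the fixed-volume center).
    """

    rotation_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation_rad
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return mz @ my @ mx

    def apply_points(self, pts_mm: np.ndarray) -> np.ndarray:
        rot = self.matrix()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts_mm - c) @ rot.T + c + t

    def inverse(self) -> "RigidTransform":
        rot = self.matrix()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        inv = RigidTransform(center_mm=tuple(c))
        # solve for Euler angles of rot^T
        rinv = rot.T
        ry = np.arcsin(-np.clip(rinv[2, 0], -1, 1))
        if abs(np.cos(ry)) > 1e-9:
            rx = np.arctan2(rinv[2, 1], rinv[2, 2])
            rz = np.arctan2(rinv[1, 0], rinv[0, 0])
        else:  # gimbal lock
            rx = np.arctan2(-rinv[1, 2], rinv[1, 1])
            rz = 0.0
        inv.rotation_rad = (float(rx), float(ry), float(rz))
        inv.translation_mm = tuple((-rinv @ t).tolist())
        return inv

    def as_dict(self) -> dict:
        return {
            "convention": "fixed-to-moving, rotate-about-center, xyz-euler-radians",
            "rotation_rad": list(self.rotation_rad),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
        }


def correct_bias(
    vol: Volume3D,
    control_grid_spacing_mm: float = 40.0,
    max_iters: int = 3,
    foreground_mask: np.ndarray | None = None,
) -> Volume3D:
    """Remove a smooth multiplicative bias field.

    The field is estimated in the log domain by normalized Gaussian smoothing
    over the foreground (sigma = ``control_grid_spacing_mm`` / 4, so the field
    carries no appreciable energy at scales below half the control-grid
    spacing) and divided out; ``max_iters`` refinement passes are applied. The
    estimated field is normalized to unit geometric mean on the foreground, so
    overall intensity scale is preserved.
    """
    values = np.asarray(vol.values, dtype=np.float64)
    mask = foreground_mask if foreground_mask is not None else values > 0
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty foreground mask")
    if np.any(values[mask] <= 0):
        raise ValueError(
            "nonpositive intensities inside the foreground mask; "
            "shift intensities to be strictly positive before bias correction"
        )
    sigma_vox = (np.asarray(control_grid_spacing_mm) / 4.0) / np.asarray(vol.spacing_mm)
    log_img = np.zeros_like(values)
    log_img[mask] = np.log(values[mask])
    maskf = mask.astype(np.float64)

    total_field_log = np.zeros_like(values)
    residual = log_img.copy()
    for _ in range(max(1, int(max_iters))):
        num = ndimage.gaussian_filter(residual * maskf, sigma=sigma_vox, mode="nearest")
        den = ndimage.gaussian_filter(maskf, sigma=sigma_vox, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            est = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
        est = est - est[mask].mean()  # unit geometric mean on foreground
        total_field_log += est
        residual = residual - est
    field = np.exp(total_field_log)
    corrected = values.copy()
    corrected[mask] = values[mask] / field[mask]
    return vol.with_values(corrected)


def nyul_fit(
    reference_volumes,
    percentile_landmarks=DEFAULT_LANDMARK_PERCENTILES,
    standard_range: tuple[float, float] = (1.0, 100.0),
) -> IntensityMapping:
    """Learn a standard intensity scale from reference volumes.

    Each reference's landmark percentiles are linearly rescaled to
    ``standard_range`` and averaged to give the standard-scale landmarks.
    """
    pct = np.asarray(percentile_landmarks, dtype=np.float64)
    if pct.size < 2:
        raise ValueError("need at least 2 landmarks")
    rescaled = []
    for ref in reference_volumes:
        arr = ref.values if isinstance(ref, Volume3D) else np.asarray(ref)
        lm = np.percentile(arr, pct)
        if np.any(np.diff(lm) <= 0):
            raise ValueError("degenerate histogram in reference volume")
        lo, hi = standard_range
        rescaled.append(lo + (lm - lm[0]) * (hi - lo) / (lm[-1] - lm[0]))
    if not rescaled:
        raise ValueError("no reference volumes")
    standard = np.mean(rescaled, axis=0)
    return IntensityMapping(percentiles=pct, standard_scale=standard)


def nyul_apply(vol: Volume3D, mapping: IntensityMapping) -> Volume3D:
    """Map a volume onto the standard scale via its own landmark percentiles."""
    src = np.percentile(vol.values, mapping.percentiles)
    if np.any(np.diff(src) <= 0):
        raise ValueError("degenerate histogram: all voxels (nearly) equal")
    mapped = mapping.map_values(np.asarray(vol.values, dtype=np.float64), src)
    return vol.with_values(mapped)


def resample(
    vol: Volume3D,
    target_spacing_mm,
    interpolation: str = "linear",
) -> Volume3D:
    """Resample to a new voxel spacing, preserving physical extent.

    ``interpolation`` is ``"linear"`` for intensities, ``"nearest"`` for masks.
    """
    target = np.asarray(target_spacing_mm, dtype=np.float64)
    if target.size == 1:
        target = np.repeat(target, 3)
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    old = np.asarray(vol.spacing_mm)
    if np.allclose(target, old):
        return vol.with_values(np.array(vol.values, copy=True))
    new_shape = np.maximum(1, np.round(np.asarray(vol.shape) * old / target).astype(int))
    coords = np.meshgrid(
        *[np.arange(n) * t / o for n, t, o in zip(new_shape, target, old)],
        indexing="ij",
    )
    order = {"linear": 1, "nearest": 0}[interpolation]
    out = ndimage.map_coordinates(
        np.asarray(vol.values, dtype=np.float64), coords, order=order, mode="nearest"
    )
    return Volume3D(
        values=out,
        spacing_mm=tuple(target.tolist()),
        origin_mm=vol.origin_mm,
        axcodes=vol.axcodes,
    )


def _physical_grid(vol: Volume3D) -> np.ndarray:
    axes = [np.arange(n) * s + o for n, s, o in zip(vol.shape, vol.spacing_mm, vol.origin_mm)]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)


def apply_rigid(moving: Volume3D, transform: RigidTransform, reference: Volume3D,
                interpolation: str = "linear") -> Volume3D:
    """Resample ``moving`` onto the grid of ``reference`` through ``transform``."""
    pts = _physical_grid(reference)
    mapped = transform.apply_points(pts)
    idx = (mapped - np.asarray(moving.origin_mm)) / np.asarray(moving.spacing_mm)
    order = {"linear": 1, "nearest": 0}[interpolation]
    out = ndimage.map_coordinates(
        np.asarray(moving.values, dtype=np.float64),
        [idx[:, 0].reshape(reference.shape), idx[:, 1].reshape(reference.shape),
         idx[:, 2].reshape(reference.shape)],
        order=order,
        mode="nearest",
    )
    return Volume3D(out, spacing_mm=reference.spacing_mm, origin_mm=reference.origin_mm,
                    axcodes=reference.axcodes)


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    hist = ndimage.gaussian_filter(hist, sigma=0.7)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


class RegistrationError(RuntimeError):
    pass


def register_rigid(moving: Volume3D, fixed: Volume3D, bins: int = 32,
                   coarse_smooth_mm: float = 3.0) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    Maximizes mutual information with a two-level (smoothed, then full
    resolution) Powell search over 3 rotations + 3 translations.
    """
    center = tuple(
        (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing_mm) / 2.0
        + np.asarray(fixed.origin_mm)
    )

    def cost(params: np.ndarray, mov: Volume3D, fix: Volume3D) -> float:
        tr = RigidTransform(
            rotation_rad=tuple(params[:3]), translation_mm=tuple(params[3:]), center_mm=center
        )
        resampled = apply_rigid(mov, tr, fix)
        return -_mutual_information(fix.values, resampled.values, bins=bins)

    smooth = lambda v: v.with_values(
        ndimage.gaussian_filter(
            np.asarray(v.values, dtype=np.float64),
            sigma=np.asarray(coarse_smooth_mm) / np.asarray(v.spacing_mm),
        )
    )
    p0 = np.zeros(6)
    stages = [(smooth(moving), smooth(fixed)), (moving, fixed)]
    result = None
    for mov, fix in stages:
        result = optimize.minimize(
            cost,
            p0,
            args=(mov, fix),
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 50},
        )
        p0 = result.x
    if result is None or not np.all(np.isfinite(result.x)):
        raise RegistrationError(f"registration failed, final metric {result.fun if result else 'n/a'}")
    return RigidTransform(
        rotation_rad=tuple(float(x) for x in result.x[:3]),
        translation_mm=tuple(float(x) for x in result.x[3:]),
        center_mm=center,
    )


def intensity_gain_offset(
    source: Volume3D, target: Volume3D, mask: np.ndarray
) -> tuple[float, float]:
    """Gain/offset mapping ``source`` onto ``target`` by moment matching on ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty non-enhancing mask")
    s = np.asarray(source.values, dtype=np.float64)[mask]
    t = np.asarray(target.values, dtype=np.float64)[mask]
    s_sd = s.std()
    if s_sd == 0:
        raise ValueError("zero-variance mask: gain undefined")
    gain = float(t.std() / s_sd)
    offset = float(t.mean() - gain * s.mean())
    return gain, offset


def match_intensity(t1w: Volume3D, t1wc: Volume3D, nonenhancing_mask: np.ndarray) -> Volume3D:
    """Linearly rescale T1w so its mask mean and s.d. equal T1wC's."""
    t1w.require_same_grid(t1wc)
    gain, offset = intensity_gain_offset(t1w, t1wc, nonenhancing_mask)
    return t1w.with_values(np.asarray(t1w.values, dtype=np.float64) * gain + offset)


def subtract(t1wc: Volume3D, t1w_matched: Volume3D) -> Volume3D:
    """Voxelwise enhancement map ``T1wC - T1w`` (positive where contrast uptakes)."""
    t1wc.require_same_grid(t1w_matched)
    return t1wc.with_values(
        np.asarray(t1wc.values, dtype=np.float64) - np.asarray(t1w_matched.values, dtype=np.float64)
    )
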