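"""Synthetic data generators with carried ground truth.

Every generator is deterministic given its seed and returns the exact truth
needed to test downstream recovery: the voxel-exact rim mask, the injected
leakage rate, and the hazard coefficients of the simulated cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import DscSeries, Volume3D

__all__ = [
    "PhantomSpec",
    "DscCurveSpec",
    "CohortSpec",
    "PhantomTruth",
    "PerfusionCurve",
    "SCAN_DELAY_GROUPS",
    "make_phantom_pair",
    "make_dsc_curve",
    "make_dsc_series",
    "make_cohort",
]

#: Scan-delay windows: hours from surgery to the MRI scan.
SCAN_DELAY_GROUPS = ("lt24", "24to48", "48to72", "ge72")


class GeometryError(ValueError):
    """Cavity/rim geometry does not fit inside the grid."""


@dataclass
class PhantomSpec:
    """Parameters of a resection-cavity phantom with an enhancing rim."""

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 5.0)
    cavity_center_mm: tuple[float, float, float] | None = None  # default: grid center
    cavity_radius_mm: float = 12.0
    rim_thickness_mm: float = 4.0
    rim_enhancement: float = 60.0
    tissue_intensities: Mapping[str, float] = field(
        default_factory=lambda: {"background": 20.0, "white_matter": 100.0, "gray_matter": 80.0}
    )
    bias_amplitude: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 2 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 2")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.rim_thickness_mm < 0:
            raise ValueError("rim_thickness_mm must be nonnegative")
        if self.cavity_radius_mm <= 0:
            raise ValueError("cavity_radius_mm must be positive")
        extent = np.array(self.grid_shape) * np.array(self.spacing_mm)
        center = np.asarray(self.center_mm())
        outer = self.cavity_radius_mm + self.rim_thickness_mm
        if np.any(center - outer < 0) or np.any(center + outer > extent):
            raise GeometryError(
                f"cavity+rim (outer radius {outer} mm at {tuple(center)}) does not fit "
                f"inside grid extent {tuple(extent)} mm"
            )

    def center_mm(self) -> tuple[float, float, float]:
        if self.cavity_center_mm is not None:
            return tuple(float(c) for c in self.cavity_center_mm)
        extent = np.array(self.grid_shape) * np.array(self.spacing_mm)
        return tuple(extent / 2.0)


@dataclass
class DscCurveSpec:
    """Parameters of a synthetic DSC signal-time curve.

    The bolus is a gamma-variate dip; leakage (``k2_leak`` > 0) adds a term
    proportional to the running integral of the leak-free relaxivity curve —
    exactly the model the leakage correction assumes — so correction can be
    tested for exact recovery. Positive ``k2_leak`` makes the signal tail
    drift below ``recovery_level * s0``.
    """

    n_timepoints: int = 60
    n_baseline: int = 10
    s0: float = 100.0
    bolus_depth: float = 0.4
    bolus_t0: float = 12.0  # sample index of bolus onset
    bolus_width: float = 5.0  # samples from onset to nadir
    k2_leak: float = 0.0  # per second, applied to the running relaxivity integral
    recovery_level: float = 1.0
    noise_sd: float = 0.0
    te_ms: float = 40.0
    dt_s: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.n_baseline < self.n_timepoints:
            raise ValueError("need 0 < n_baseline < n_timepoints")
        if not 0 <= self.bolus_depth < 1:
            raise ValueError("bolus_depth must lie in [0, 1)")
        if self.s0 <= 0 or self.te_ms <= 0 or self.dt_s <= 0:
            raise ValueError("s0, te_ms, dt_s must be positive")
        if not 0 <= self.recovery_level <= 1.5:
            raise ValueError("recovery_level out of range")


@dataclass
class CohortSpec:
    """Parameters of a simulated survival cohort.

    Survival times are exponential with hazard
    ``baseline_hazard * exp(log_hr_per_mm * thickness)``; censoring is
    independent of the event time given covariates and hits each patient with
    probability ``censor_rate`` exactly. ``window_log_hr`` optionally
    overrides the thickness coefficient per scan-delay window.
    """

    n_patients: int = 200
    log_hr_per_mm: float = float(np.log(2.0))
    baseline_hazard: float = 1.0 / 500.0  # events per day
    censor_rate: float = 0.2
    thickness_mean_mm: float = 2.0
    thickness_sd_mm: float = 0.75
    scan_delay_probs: tuple[float, float, float, float] = (0.18, 0.35, 0.29, 0.18)
    age_mean: float = 62.0
    age_sd: float = 10.0
    kps_high_prob: float = 0.6  # P(KPS >= 90)
    window_log_hr: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not np.isclose(sum(self.scan_delay_probs), 1.0):
            raise ValueError("scan_delay_probs must sum to 1")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class PhantomTruth:
    """Ground truth carried alongside synthetic data for recovery tests."""

    rim_thickness_mm: float = 0.0
    rim_mask: np.ndarray | None = None
    wm_mask: np.ndarray | None = None
    k2_leak: float = 0.0
    log_hr_per_mm: float | None = None
    window_log_hr: dict[str, float] | None = None
    covariates: pd.DataFrame | None = None


@dataclass
class PerfusionCurve:
    """A single signal-vs-time curve with its pre-bolus baseline length."""

    signal: np.ndarray
    n_baseline: int = 10
    te_ms: float = 40.0
    dt_s: float = 1.5

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1:
            raise ValueError("curve must be 1D")
        if not 0 < self.n_baseline < self.signal.size:
            raise ValueError("need 0 < n_baseline < len(signal)")

    @property
    def baseline_mean(self) -> float:
        return float(self.signal[: self.n_baseline].mean())


def _voxel_center_radii(spec: PhantomSpec) -> np.ndarray:
    """Distance (mm) from each voxel center to the cavity center."""
    center = np.asarray(spec.center_mm())
    axes = [
        (np.arange(n) + 0.0) * s - c
        for n, s, c in zip(spec.grid_shape, spec.spacing_mm, center)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(xx**2 + yy**2 + zz**2)


def _bias_field(shape: tuple[int, int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative field with mean ~1 and relative amplitude given."""
    if amplitude == 0:
        return np.ones(shape)
    grids = np.meshgrid(*[np.linspace(0, np.pi, n) for n in shape], indexing="ij")
    field = 1.0 + amplitude * np.sin(grids[0]) * np.sin(grids[1]) * np.sin(grids[2])
    return field


def make_phantom_pair(spec: PhantomSpec) -> tuple[Volume3D, Volume3D, PhantomTruth]:
    """Generate a pre/post-contrast volume pair with an exact rim-mask truth.

    Before bias and noise, ``T1wC - T1w`` equals ``rim_enhancement`` exactly on
    the half-open spherical shell ``cavity_radius < r <= cavity_radius +
    rim_thickness`` (voxel-center membership) and zero elsewhere.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    radii = _voxel_center_radii(spec)
    tissue = spec.tissue_intensities

    extent = np.array(spec.grid_shape) * np.array(spec.spacing_mm)
    brain_radius = float(min(extent)) / 2.0 - min(spec.spacing_mm)
    brain = radii <= brain_radius

    t1w = np.full(spec.grid_shape, tissue["background"], dtype=np.float64)
    t1w[brain] = tissue["white_matter"]
    gm_shell = brain & (radii > brain_radius - 3.0 * max(spec.spacing_mm[:2]))
    t1w[gm_shell] = tissue["gray_matter"]
    cavity = radii <= spec.cavity_radius_mm
    t1w[cavity] = tissue["background"]

    rim = (radii > spec.cavity_radius_mm) & (
        radii <= spec.cavity_radius_mm + spec.rim_thickness_mm
    )
    t1wc = t1w.copy()
    t1wc[rim] += spec.rim_enhancement

    # contralateral white-matter ROI: small ball opposite the cavity center
    center_idx = np.array(spec.center_mm()) / np.array(spec.spacing_mm)
    offset = np.zeros(3)
    offset[0] = (spec.cavity_radius_mm + spec.rim_thickness_mm + brain_radius) / 2.0
    wm_center_mm = np.asarray(spec.center_mm()) + offset
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    wm_r = np.sqrt(
        (xx - wm_center_mm[0]) ** 2 + (yy - wm_center_mm[1]) ** 2 + (zz - wm_center_mm[2]) ** 2
    )
    wm_mask = (wm_r <= 6.0) & brain & ~rim & ~cavity

    bias = _bias_field(spec.grid_shape, spec.bias_amplitude)
    t1w = t1w * bias
    t1wc = t1wc * bias
    if spec.noise_sd > 0:
        t1w = t1w + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        t1wc = t1wc + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    truth = PhantomTruth(
        rim_thickness_mm=spec.rim_thickness_mm,
        rim_mask=rim.astype(np.uint8),
        wm_mask=wm_mask.astype(np.uint8),
    )
    vol_kw = dict(spacing_mm=spec.spacing_mm, origin_mm=(0.0, 0.0, 0.0))
    return Volume3D(t1w, **vol_kw), Volume3D(t1wc, **vol_kw), truth


def _gamma_variate(t_idx: np.ndarray, t0: float, width: float, alpha: float = 8.0) -> np.ndarray:
    """Gamma-variate bolus shape, unit peak at ``t0 + width`` sample indices."""
    dt = np.maximum(t_idx - t0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (dt / width) ** alpha * np.exp(alpha * (1.0 - dt / width))
    return np.nan_to_num(g, nan=0.0)


def dsc_relaxivity_true(spec: DscCurveSpec) -> np.ndarray:
    """Leak-free relaxivity-change curve implied by the spec (1/ms units)."""
    t_idx = np.arange(spec.n_timepoints, dtype=np.float64)
    g = _gamma_variate(t_idx, spec.bolus_t0, spec.bolus_width)
    # cumulative bolus passage drives the post-bolus plateau
    cum = np.cumsum(g)
    plateau = cum / cum[-1] if cum[-1] > 0 else np.zeros_like(cum)
    depth_r2 = -np.log(1.0 - spec.bolus_depth) / spec.te_ms if spec.bolus_depth > 0 else 0.0
    tail_r2 = -np.log(max(spec.recovery_level, 1e-12)) / spec.te_ms
    return depth_r2 * g + tail_r2 * plateau


def make_dsc_curve(spec: DscCurveSpec) -> PerfusionCurve:
    """Generate one synthetic DSC curve.

    Noise-free baseline samples equal ``s0`` exactly; the nadir sits at
    ``s0 * (1 - bolus_depth)``; with ``k2_leak > 0`` the observed relaxivity
    gains a ``k2_leak * integral(true relaxivity)`` term, so the signal tail
    drifts monotonically below the recovery plateau.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    r2_true = dsc_relaxivity_true(spec)
    integral = np.cumsum(r2_true) * spec.dt_s
    r2_obs = r2_true + spec.k2_leak * integral
    signal = spec.s0 * np.exp(-spec.te_ms * r2_obs)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    return PerfusionCurve(
        signal=signal, n_baseline=spec.n_baseline, te_ms=spec.te_ms, dt_s=spec.dt_s
    )


def make_dsc_series(
    phantom_spec: PhantomSpec,
    curve_spec: DscCurveSpec,
    truth: PhantomTruth,
    rim_bolus_scale: float = 3.0,
    rim_k2_leak: float | None = None,
) -> DscSeries:
    """Assemble a 4D DSC series on the phantom grid.

    White-matter and rim voxels carry bolus curves; the rim bolus is
    ``rim_bolus_scale`` times deeper in relaxivity and optionally leaky.
    All remaining voxels hold flat low-signal curves (rejected by curve
    filtering downstream).
    """
    curve_spec.validate()
    rng = np.random.default_rng(curve_spec.seed)
    shape = phantom_spec.grid_shape
    nt = curve_spec.n_timepoints
    data = np.full(shape + (nt,), curve_spec.s0 * 0.05, dtype=np.float64)

    wm_curve = make_dsc_curve(
        DscCurveSpec(**{**curve_spec.__dict__, "k2_leak": 0.0, "noise_sd": 0.0})
    ).signal

    rim_depth = 1.0 - (1.0 - curve_spec.bolus_depth) ** rim_bolus_scale
    rim_spec = DscCurveSpec(
        **{
            **curve_spec.__dict__,
            "bolus_depth": float(rim_depth),
            "k2_leak": float(rim_k2_leak if rim_k2_leak is not None else curve_spec.k2_leak),
            "noise_sd": 0.0,
        }
    )
    rim_curve = make_dsc_curve(rim_spec).signal

    if truth.wm_mask is not None:
        data[truth.wm_mask.astype(bool)] = wm_curve
    if truth.rim_mask is not None and truth.rim_mask.any():
        data[truth.rim_mask.astype(bool)] = rim_curve
    if curve_spec.noise_sd > 0:
        data = data + rng.normal(0.0, curve_spec.noise_sd, size=data.shape)
    return DscSeries(
        values=data,
        spacing_mm=phantom_spec.spacing_mm,
        te_ms=curve_spec.te_ms,
        dt_s=curve_spec.dt_s,
        n_baseline=curve_spec.n_baseline,
    )


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, PhantomTruth]:
    """Simulate a survival cohort with hazard log-linear in rim thickness.

    Censoring is exponential with a per-patient rate chosen so that the
    censoring probability equals ``censor_rate`` for every patient,
    independent of the event time given covariates.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    thickness = rng.normal(spec.thickness_mean_mm, spec.thickness_sd_mm, size=n)
    thickness = np.clip(thickness, 0.05, None)
    groups = rng.choice(SCAN_DELAY_GROUPS, size=n, p=spec.scan_delay_probs)
    if spec.window_log_hr is not None:
        betas = np.array([spec.window_log_hr.get(g, spec.log_hr_per_mm) for g in groups])
    else:
        betas = np.full(n, spec.log_hr_per_mm)

    hazard = spec.baseline_hazard * np.exp(betas * thickness)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        censor_rate_i = hazard * spec.censor_rate / (1.0 - spec.censor_rate)
        censor_time = rng.exponential(1.0 / censor_rate_i)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    kps_high = rng.random(n) < spec.kps_high_prob

    table = pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "os_days": observed,
            "os_event": event,
            "pfs_days": observed * rng.uniform(0.5, 1.0, size=n),
            "pfs_event": event,
            "age_years": age,
            "kps_ge90": kps_high.astype(int),
            "scan_delay_group": groups,
            "mean_thickness_mm": thickness,
        }
    )
    truth = PhantomTruth(
        log_hr_per_mm=spec.log_hr_per_mm,
        window_log_hr=dict(spec.window_log_hr) if spec.window_log_hr else None,
        covariates=table[["id", "mean_thickness_mm", "scan_delay_group"]].copy(),
    )
    return table, truth
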