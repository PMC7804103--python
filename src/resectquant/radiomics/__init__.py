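"""Radiomics feature extraction and robustness screening.

A 94-feature vector is computed from the masked image after resampling to an
isotropic grid and fixed-bin-width intensity discretization: first-order
(19), GLCM (24), GLRLM (16), GLSZM (16), NGTDM (5) and GLDM (14). Texture
matrices are aggregated over the 13 unique 3D directions at distance 1 by
averaging the per-direction features.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import Volume3D
from ..enhancement import EnhancementMask
from ..preprocess import resample
from . import _features

__all__ = [
    "RadiomicsConfig",
    "RobustnessReport",
    "FEATURE_FAMILIES",
    "DEFAULT_PERTURBATIONS",
    "feature_names",
    "extract_features",
    "robustness_screen",
]

#: Family sizes of the default feature bank (sums to 94).
FEATURE_FAMILIES: dict[str, int] = {
    "firstorder": 19,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
    "gldm": 14,
}

#: Default perturbation grid for the robustness screen: spacing (mm) x bin width.
DEFAULT_PERTURBATIONS: tuple[tuple[float, float], ...] = (
    (1.0, 5.0), (1.0, 10.0), (1.0, 20.0), (2.0, 5.0), (2.0, 10.0), (2.0, 20.0),
)


@dataclass
class RadiomicsConfig:
    """Extraction parameters.

    ``bin_mode="width"`` discretizes with a fixed bin width anchored at the
    mask minimum: ``level(v) = floor((v - min) / bin_width) + 1``. A
    fixed-bin-count mode is available behind ``bin_mode="count"``.
    """

    resample_spacing_mm: float = 1.0
    bin_width: float = 10.0
    bin_mode: str = "width"  # "width" | "count"
    n_bins: int = 32  # used only in count mode
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.resample_spacing_mm <= 0:
            raise ValueError("bin_width and resample_spacing_mm must be positive")
        if self.bin_mode not in ("width", "count"):
            raise ValueError("bin_mode must be 'width' or 'count'")


@dataclass
class RobustnessReport:
    """Per-feature coefficient of variation across perturbed extractions."""

    table: pd.DataFrame  # columns: feature, cov_percent, robust, zero_mean

    @property
    def robust_features(self) -> list[str]:
        return self.table.loc[self.table["robust"], "feature"].tolist()

    @property
    def n_robust(self) -> int:
        return int(self.table["robust"].sum())


def feature_names() -> list[str]:
    """The 94 feature names, family-prefixed, in canonical order."""
    names: list[str] = []
    for fam, keys in _FAMILY_KEYS.items():
        names.extend(f"{fam}_{k}" for k in keys)
    return names


def discretize(values: np.ndarray, mask: np.ndarray, cfg: RadiomicsConfig) -> np.ndarray:
    """Integer gray levels 1..Ng inside the mask, 0 outside."""
    out = np.zeros(values.shape, dtype=np.int64)
    vals = values[mask]
    vmin = vals.min()
    if cfg.bin_mode == "width":
        out[mask] = np.floor((vals - vmin) / cfg.bin_width).astype(np.int64) + 1
    else:
        vrange = vals.max() - vmin
        if vrange == 0:
            out[mask] = 1
        else:
            lv = np.floor((vals - vmin) / (vrange / cfg.n_bins)).astype(np.int64) + 1
            out[mask] = np.minimum(lv, cfg.n_bins)
    return out


def _crop_to_mask(values: np.ndarray, mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return values[sl], mask[sl]


def extract_features(
    t1wc: Volume3D,
    mask: EnhancementMask,
    cfg: RadiomicsConfig | None = None,
) -> dict[str, float] | None:
    """Extract the 94-feature vector; ``None`` if the mask is non-measurable
    (fewer than 2 voxels after resampling)."""
    cfg = cfg or RadiomicsConfig()
    img = resample(t1wc, cfg.resample_spacing_mm, "linear")
    msk = resample(
        Volume3D(mask.values.astype(np.float64), mask.spacing_mm, mask.origin_mm),
        cfg.resample_spacing_mm,
        "nearest",
    )
    m = msk.values > 0.5
    if m.sum() < 2:
        return None
    vals, m = _crop_to_mask(img.values, m)
    levels = discretize(vals, m, cfg)
    ng = int(levels.max())
    voxvol = float(np.prod(img.spacing_mm))

    out: dict[str, float] = {}
    fam_results = {
        "firstorder": _features.firstorder_features(vals[m], levels[m], voxvol),
        "glcm": _features.glcm_features(levels, ng),
        "glrlm": _features.glrlm_features(levels, ng),
        "glszm": _features.glszm_features(levels, ng),
        "ngtdm": _features.ngtdm_features(levels, ng),
        "gldm": _features.gldm_features(levels, ng, alpha=cfg.gldm_alpha),
    }
    for fam, keys in _FAMILY_KEYS.items():
        res = fam_results[fam]
        if set(res) != set(keys):  # pragma: no cover - internal consistency
            raise RuntimeError(f"{fam}: feature registry mismatch")
        for k in keys:
            out[f"{fam}_{k}"] = float(res[k])
    return out


def robustness_screen(
    t1wc: Volume3D,
    mask: EnhancementMask,
    cfg: RadiomicsConfig | None = None,
    perturbations=DEFAULT_PERTURBATIONS,
    cov_threshold_percent: float = 20.0,
) -> RobustnessReport:
    """Coefficient-of-variation screen across extraction-parameter settings.

    CoV = 100 * sd / |mean| per feature across the perturbed extractions;
    a feature is robust iff CoV < ``cov_threshold_percent``. Features with
    zero mean are flagged separately and never marked robust.
    """
    base = cfg or RadiomicsConfig()
    perturbations = list(perturbations)
    if len(perturbations) < 2:
        raise ValueError("need at least 2 perturbations")
    rows = []
    for spacing, bw in perturbations:
        pert_cfg = RadiomicsConfig(
            resample_spacing_mm=spacing,
            bin_width=bw,
            bin_mode=base.bin_mode,
            n_bins=base.n_bins,
            gldm_alpha=base.gldm_alpha,
        )
        feats = extract_features(t1wc, mask, pert_cfg)
        if feats is None:
            raise ValueError(f"mask non-measurable at spacing {spacing} mm")
        rows.append(feats)
    frame = pd.DataFrame(rows)
    means = frame.mean(axis=0)
    sds = frame.std(axis=0, ddof=1)
    zero_mean = means == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = 100.0 * sds / means.abs()
    cov[zero_mean & (sds == 0)] = 0.0
    table = pd.DataFrame(
        {
            "feature": frame.columns,
            "cov_percent": cov.values,
            "robust": ((cov < cov_threshold_percent) & ~zero_mean.values).values
            | ((sds == 0) & zero_mean).values,
            "zero_mean": zero_mean.values,
        }
    )
    return RobustnessReport(table=table)


_FAMILY_KEYS: dict[str, tuple[str, ...]] = {
    "firstorder": (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10", "Percentile90",
        "Maximum", "Mean", "Median", "InterquartileRange", "Range",
        "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
        "StandardDeviation", "Skewness", "Kurtosis", "Variance", "Uniformity",
    ),
    "glcm": (
        "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
        "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
        "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
        "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
        "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
    ),
    "glrlm": (
        "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
        "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
        "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis",
    ),
    "glszm": (
        "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
        "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
        "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LargeAreaHighGrayLevelEmphasis",
    ),
    "ngtdm": ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"),
    "gldm": (
        "SmallDependenceEmphasis", "LargeDependenceEmphasis", "GrayLevelNonUniformity",
        "DependenceNonUniformity", "DependenceNonUniformityNormalized",
        "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
        "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    ),
}

assert sum(len(v) for v in _FAMILY_KEYS.values()) == 94
assert {k: len(v) for k, v in _FAMILY_KEYS.items()} == FEATURE_FAMILIES
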