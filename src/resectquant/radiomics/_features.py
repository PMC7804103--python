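"""Feature formulas for the six radiomics families.

Degenerate-texture conventions (constant regions, single gray level) follow
the common ones: correlation-like quantities default to 1, entropies to 0,
and divisions by zero structure terms to 0.
"""
from __future__ import annotations

import numpy as np

from ._matrices import (
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)

_EPS = np.finfo(np.float64).tiny


def _log2(x: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(x, _EPS))


# ---------------------------------------------------------------- first order

def firstorder_features(values: np.ndarray, levels_in_mask: np.ndarray,
                        voxel_volume_mm3: float) -> dict[str, float]:
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    mean = v.mean()
    m2 = ((v - mean) ** 2).mean()
    m3 = ((v - mean) ** 3).mean()
    m4 = ((v - mean) ** 4).mean()
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    counts = np.bincount(levels_in_mask)[1:]
    p = counts[counts > 0] / n
    energy = float(np.sum(v**2))
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume_mm3,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(v.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "StandardDeviation": float(np.sqrt(m2)),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }


# ----------------------------------------------------------------------- GLCM

def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(px * i))
    sigma2 = float(np.sum(px * (i - mu) ** 2))

    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    psum = np.zeros(2 * ng - 1)
    pdiff = np.zeros(ng)
    np.add.at(psum, (ii + jj).ravel() - 2, p.ravel())
    np.add.at(pdiff, np.abs(ii - jj).ravel(), p.ravel())
    ksum = np.arange(2, 2 * ng + 1)
    kdiff = np.arange(ng)

    diff_avg = float(np.sum(kdiff * pdiff))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hxy = float(-np.sum(p[p > 0] * np.log2(p[p > 0])))
    pxpy = np.outer(px, px)
    hxy1 = float(-np.sum(p * _log2(pxpy)))
    hxy2 = float(-np.sum(pxpy * _log2(pxpy)))

    if sigma2 > 0:
        corr = float(np.sum(p * (ii - mu) * (jj - mu)) / sigma2)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 > 0 else 0.0

    off_diag = ii != jj
    inv_var = float(np.sum(p[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2))

    # MCC: second-largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    py = px  # symmetric
    nz = px > 0
    if nz.sum() > 1:
        psub = p[np.ix_(nz, nz)]
        pxs = px[nz]
        pys = py[nz]
        q = (psub / pxs[:, None]) @ (psub / pys[:, None]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": float(np.sum(p * ii * jj)),
        "ClusterProminence": float(np.sum(p * (ii + jj - 2 * mu) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - 2 * mu) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - 2 * mu) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(pdiff[pdiff > 0] * np.log2(pdiff[pdiff > 0]))),
        "DifferenceVariance": float(np.sum(pdiff * (kdiff - diff_avg) ** 2)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(ksum * psum)),
        "SumEntropy": float(-np.sum(psum[psum > 0] * np.log2(psum[psum > 0]))),
        "SumSquares": sigma2,
    }


def glcm_features(levels: np.ndarray, ng: int) -> dict[str, float]:
    mats = glcm_matrices(levels, ng)
    if not mats:
        raise ValueError("no valid voxel pairs for GLCM")
    per_dir = [_glcm_single(m) for m in mats]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------- GLRLM

def _glrlm_single(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = mat.sum()
    p = mat / nr
    ng, nl = mat.shape
    i = np.arange(1, ng + 1)
    l = np.arange(1, nl + 1)
    ii, ll = np.meshgrid(i, l, indexing="ij")
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = float(np.sum(pg * i))
    mu_l = float(np.sum(pl * l))
    return {
        "ShortRunEmphasis": float(np.sum(p / ll**2)),
        "LongRunEmphasis": float(np.sum(p * ll**2)),
        "GrayLevelNonUniformity": float(np.sum(mat.sum(axis=1) ** 2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2)),
        "RunLengthNonUniformity": float(np.sum(mat.sum(axis=0) ** 2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pl**2)),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(np.sum(pg * (i - mu_i) ** 2)),
        "RunVariance": float(np.sum(pl * (l - mu_l) ** 2)),
        "RunEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0]))),
        "LowGrayLevelRunEmphasis": float(np.sum(p / ii**2)),
        "HighGrayLevelRunEmphasis": float(np.sum(p * ii**2)),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(p / (ii**2 * ll**2))),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(p * ii**2 / ll**2)),
        "LongRunLowGrayLevelEmphasis": float(np.sum(p * ll**2 / ii**2)),
        "LongRunHighGrayLevelEmphasis": float(np.sum(p * ii**2 * ll**2)),
    }


def glrlm_features(levels: np.ndarray, ng: int) -> dict[str, float]:
    n_voxels = int((levels > 0).sum())
    mats = glrlm_matrices(levels, ng)
    if not mats:
        raise ValueError("no runs for GLRLM")
    per_dir = [_glrlm_single(m, n_voxels) for m in mats]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------- GLSZM

def glszm_features(levels: np.ndarray, ng: int) -> dict[str, float]:
    mat = glszm_matrix(levels, ng)
    nz = mat.sum()
    n_voxels = int((levels > 0).sum())
    p = mat / nz
    n_g, n_s = mat.shape
    i = np.arange(1, n_g + 1)
    s = np.arange(1, n_s + 1)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float(np.sum(pg * i))
    mu_s = float(np.sum(ps * s))
    return {
        "SmallAreaEmphasis": float(np.sum(p / ss**2)),
        "LargeAreaEmphasis": float(np.sum(p * ss**2)),
        "GrayLevelNonUniformity": float(np.sum(mat.sum(axis=1) ** 2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2)),
        "SizeZoneNonUniformity": float(np.sum(mat.sum(axis=0) ** 2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2)),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float(np.sum(pg * (i - mu_i) ** 2)),
        "ZoneVariance": float(np.sum(ps * (s - mu_s) ** 2)),
        "ZoneEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0]))),
        "LowGrayLevelZoneEmphasis": float(np.sum(p / ii**2)),
        "HighGrayLevelZoneEmphasis": float(np.sum(p * ii**2)),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(p / (ii**2 * ss**2))),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(p * ii**2 / ss**2)),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(p * ss**2 / ii**2)),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(p * ii**2 * ss**2)),
    }


# ---------------------------------------------------------------------- NGTDM

def ngtdm_features(levels: np.ndarray, ng: int) -> dict[str, float]:
    n_i, s_i, nvp = ngtdm_table(levels, ng)
    if nvp == 0:
        raise ValueError("no voxels with valid neighbourhood for NGTDM")
    p_i = n_i / nvp
    present = p_i > 0
    i = np.arange(1, ng + 1, dtype=np.float64)
    ngp = int(present.sum())

    coarse_den = float(np.sum(p_i * s_i))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        ip, pp, sp = i[present], p_i[present], s_i[present]
        di = ip[:, None] - ip[None, :]
        contrast = float(
            np.sum(pp[:, None] * pp[None, :] * di**2) / (ngp * (ngp - 1)) * (s_i.sum() / nvp)
        )
        busy_den = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = float(
            np.sum(
                np.abs(di)
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :])
            )
            / nvp
        )
        s_sum = float(s_i.sum())
        strength = (
            float(np.sum((pp[:, None] + pp[None, :]) * di**2)) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ----------------------------------------------------------------------- GLDM

def gldm_features(levels: np.ndarray, ng: int, alpha: int = 0) -> dict[str, float]:
    mat = gldm_matrix(levels, ng, alpha=alpha)
    nz = mat.sum()  # every in-mask voxel contributes one dependence entry
    p = mat / nz
    n_g, n_d = mat.shape
    i = np.arange(1, n_g + 1)
    d = np.arange(1, n_d + 1)
    ii, dd = np.meshgrid(i, d, indexing="ij")
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float(np.sum(pg * i))
    mu_d = float(np.sum(pd * d))
    return {
        "SmallDependenceEmphasis": float(np.sum(p / dd**2)),
        "LargeDependenceEmphasis": float(np.sum(p * dd**2)),
        "GrayLevelNonUniformity": float(np.sum(mat.sum(axis=1) ** 2) / nz),
        "DependenceNonUniformity": float(np.sum(mat.sum(axis=0) ** 2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2)),
        "GrayLevelVariance": float(np.sum(pg * (i - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(pd * (d - mu_d) ** 2)),
        "DependenceEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0]))),
        "LowGrayLevelEmphasis": float(np.sum(p / ii**2)),
        "HighGrayLevelEmphasis": float(np.sum(p * ii**2)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(p / (ii**2 * dd**2))),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(p * ii**2 / dd**2)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(p * dd**2 / ii**2)),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(p * ii**2 * dd**2)),
    }
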