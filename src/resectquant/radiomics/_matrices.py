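"""Gray-level texture matrix construction.

All matrices operate on a cropped integer level array (levels 1..Ng inside
the mask, 0 outside) and honor the 13 unique 3D offsets at Chebyshev
distance 1. Conventions:

* GLCM: symmetric per-direction co-occurrence, normalized per direction.
* GLRLM: per-direction run-length counts.
* GLSZM: 26-connected zones of constant level (direction-free).
* NGTDM: neighbourhood (26) gray-tone difference; voxels with no in-mask
  neighbour are excluded.
* GLDM: dependence size d = 1 + number of 26-neighbours within ``alpha``
  gray levels of the center (the center voxel counts itself).
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

# 13 unique 3D direction offsets (half of the 26-neighbourhood)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _shift_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Center/neighbour level pairs for one offset, both inside the mask."""
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    sl_a = tuple(slice(max(0, -d), min(n, n - d)) for d, n in zip(offset, levels.shape))
    sl_b = tuple(slice(max(0, d), min(n, n + d)) for d, n in zip(offset, levels.shape))
    a = levels[sl_a]
    b = levels[sl_b]
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


def glcm_matrices(levels: np.ndarray, ng: int) -> list[np.ndarray]:
    """Normalized symmetric co-occurrence matrix for each of 13 directions.

    Directions with no valid voxel pair are skipped.
    """
    out = []
    for off in DIRECTIONS_13:
        a, b = _shift_pairs(levels, off)
        if a.size == 0:
            continue
        mat = np.zeros((ng, ng), dtype=np.float64)
        np.add.at(mat, (a - 1, b - 1), 1.0)
        mat = mat + mat.T  # symmetric
        out.append(mat / mat.sum())
    return out


def glrlm_matrices(levels: np.ndarray, ng: int) -> list[np.ndarray]:
    """Run-length count matrix P[level-1, length-1] per direction."""
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(sum(n**2 for n in shape)))) + 1
    out = []
    for off in DIRECTIONS_13:
        mat = np.zeros((ng, max_len), dtype=np.float64)
        for start in _line_starts(shape, off):
            line = _walk_line(levels, start, off)
            _rle_into(line, mat)
        if mat.sum() > 0:
            last = np.flatnonzero(mat.sum(axis=0))[-1] + 1
            out.append(mat[:, :last])
    return out


def _line_starts(shape, off):
    """Voxels whose predecessor along ``off`` is outside the array."""
    idx = np.indices(shape).reshape(3, -1).T
    prev = idx - np.asarray(off)
    outside = np.any((prev < 0) | (prev >= np.asarray(shape)), axis=1)
    return idx[outside]


def _walk_line(levels, start, off):
    shape = levels.shape
    pos = np.asarray(start)
    vals = []
    while np.all(pos >= 0) and np.all(pos < shape):
        vals.append(levels[tuple(pos)])
        pos = pos + off
    return np.asarray(vals)


def _rle_into(line: np.ndarray, mat: np.ndarray) -> None:
    if line.size == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    for s, e in zip(starts, ends):
        lv = line[s]
        if lv > 0:
            mat[lv - 1, e - s - 1] += 1.0


def glszm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone count matrix P[level-1, size-1] (26-connected zones)."""
    max_size = int((levels > 0).sum())
    mat = np.zeros((ng, max(max_size, 1)), dtype=np.float64)
    for lv in range(1, ng + 1):
        binary = levels == lv
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            mat[lv - 1, s - 1] += 1.0
    last = np.flatnonzero(mat.sum(axis=0))
    return mat[:, : last[-1] + 1] if last.size else mat[:, :1]


def ngtdm_table(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_i, s_i, Nvp): per-level counts, gray-tone difference sums, and the
    number of valid voxels (those with >= 1 in-mask neighbour)."""
    mask = levels > 0
    lv = levels.astype(np.float64)
    neigh_sum = np.zeros_like(lv)
    neigh_cnt = np.zeros_like(lv)
    for off in DIRECTIONS_13:
        for sgn in (1, -1):
            o = tuple(sgn * d for d in off)
            sl_a = tuple(slice(max(0, -d), min(n, n - d)) for d, n in zip(o, levels.shape))
            sl_b = tuple(slice(max(0, d), min(n, n + d)) for d, n in zip(o, levels.shape))
            valid = mask[sl_b]
            neigh_sum[sl_a] += np.where(valid, lv[sl_b], 0.0)
            neigh_cnt[sl_a] += valid
    valid_center = mask & (neigh_cnt > 0)
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(neigh_cnt > 0, neigh_sum / np.maximum(neigh_cnt, 1), 0.0)
    diffs = np.abs(lv - avg)
    for i in range(1, ng + 1):
        sel = valid_center & (levels == i)
        n_i[i - 1] = sel.sum()
        s_i[i - 1] = diffs[sel].sum()
    return n_i, s_i, int(valid_center.sum())


def gldm_matrix(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P[level-1, d-1], d = 1 + #(26-neighbours with
    |level difference| <= alpha)."""
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in DIRECTIONS_13:
        for sgn in (1, -1):
            o = tuple(sgn * d for d in off)
            sl_a = tuple(slice(max(0, -d), min(n, n - d)) for d, n in zip(o, levels.shape))
            sl_b = tuple(slice(max(0, d), min(n, n + d)) for d, n in zip(o, levels.shape))
            ok = mask[sl_a] & mask[sl_b] & (
                np.abs(levels[sl_a].astype(int) - levels[sl_b].astype(int)) <= alpha
            )
            dep[sl_a] += ok
    d = dep[mask] + 1  # center voxel counts itself
    lv = levels[mask]
    mat = np.zeros((ng, int(d.max())), dtype=np.float64)
    np.add.at(mat, (lv - 1, d - 1), 1.0)
    return mat
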