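"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit loops / first-principles formulas and
stays independent of the package implementations it checks.
"""
from __future__ import annotations

import itertools

import numpy as np


def bf_distance_transform(mask: np.ndarray, spacing) -> np.ndarray:
    """Exhaustive nearest-background search (O(n_fg * n_bg))."""
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    if fg.size == 0 or bg.size == 0:
        return out
    fg_mm = fg * spacing
    bg_mm = bg * spacing
    for (i, j, k), p in zip(fg, fg_mm):
        d2 = np.sum((bg_mm - p) ** 2, axis=1)
        out[i, j, k] = np.sqrt(d2.min())
    return out


def bf_glcm(levels: np.ndarray, ng: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset, normalized."""
    mat = np.zeros((ng, ng))
    shape = levels.shape
    for idx in itertools.product(*[range(n) for n in shape]):
        a = levels[idx]
        if a == 0:
            continue
        nb = tuple(i + d for i, d in zip(idx, offset))
        if all(0 <= n < s for n, s in zip(nb, shape)):
            b = levels[nb]
            if b > 0:
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    s = mat.sum()
    return mat / s if s > 0 else mat


def bf_runs(levels: np.ndarray, offset) -> dict[tuple[int, int], int]:
    """Run-length counts {(level, length): count} along one direction,
    found by walking every maximal line voxel by voxel."""
    shape = levels.shape
    runs: dict[tuple[int, int], int] = {}
    off = np.asarray(offset)
    for idx in itertools.product(*[range(n) for n in shape]):
        prev = np.asarray(idx) - off
        if np.all(prev >= 0) and np.all(prev < shape):
            continue  # not a line start
        pos = np.asarray(idx)
        line = []
        while np.all(pos >= 0) and np.all(pos < shape):
            line.append(levels[tuple(pos)])
            pos = pos + off
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            if line[i] > 0:
                key = (int(line[i]), j - i)
                runs[key] = runs.get(key, 0) + 1
            i = j
    return runs


def bf_zones(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """26-connected constant-level zone counts {(level, size): count} via BFS."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    neigh = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for idx in itertools.product(*[range(n) for n in shape]):
        if levels[idx] == 0 or seen[idx]:
            continue
        lv = levels[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in neigh:
                nb = tuple(c + dd for c, dd in zip(cur, d))
                if all(0 <= n < s for n, s in zip(nb, shape)):
                    if not seen[nb] and levels[nb] == lv:
                        seen[nb] = True
                        stack.append(nb)
        key = (int(lv), size)
        zones[key] = zones.get(key, 0) + 1
    return zones


def bf_ngtdm(levels: np.ndarray, ng: int):
    """(n_i, s_i, Nvp) by explicit neighbourhood loops."""
    shape = levels.shape
    neigh = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    nvp = 0
    for idx in itertools.product(*[range(n) for n in shape]):
        lv = levels[idx]
        if lv == 0:
            continue
        vals = []
        for d in neigh:
            nb = tuple(c + dd for c, dd in zip(idx, d))
            if all(0 <= n < s for n, s in zip(nb, shape)) and levels[nb] > 0:
                vals.append(levels[nb])
        if not vals:
            continue
        nvp += 1
        n_i[lv - 1] += 1
        s_i[lv - 1] += abs(lv - np.mean(vals))
    return n_i, s_i, nvp


def bf_gldm(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix with d = 1 + #similar 26-neighbours."""
    shape = levels.shape
    neigh = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    entries = []
    for idx in itertools.product(*[range(n) for n in shape]):
        lv = levels[idx]
        if lv == 0:
            continue
        dep = 1
        for d in neigh:
            nb = tuple(c + dd for c, dd in zip(idx, d))
            if all(0 <= n < s for n, s in zip(nb, shape)):
                if levels[nb] > 0 and abs(int(levels[nb]) - int(lv)) <= alpha:
                    dep += 1
        entries.append((lv, dep))
    dmax = max(d for _, d in entries)
    mat = np.zeros((ng, dmax))
    for lv, d in entries:
        mat[lv - 1, d - 1] += 1
    return mat


def bf_auc(scores, labels) -> float:
    """Concordant-pair fraction (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bf_km(times, events):
    """Product-limit estimate: (event_times, survival) by hand."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    uniq = np.unique(times[events == 1])
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return uniq, np.asarray(surv)


def bf_logrank(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square statistic by hand."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_t = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        n = na + nb
        d = np.sum((ta == t) & (ea == 1)) + np.sum((tb == t) & (eb == 1))
        da = np.sum((ta == t) & (ea == 1))
        e_a = d * na / n
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def bf_bh(p_values) -> np.ndarray:
    """Step-up formula: adj p_(i) = min(1, min_{j >= i} m p_(j) / j)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [m * p[order[r - 1]] / r for r in range(rank, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def bf_percentile_linear(values, q) -> float:
    """Linear-interpolation percentile from first principles."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)
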