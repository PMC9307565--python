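"""Independent brute-force oracles, written from the definitions (plain
Python loops, no shared code with the implementation under test)."""

from __future__ import annotations

import itertools

import numpy as np

DIRS_3D = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
NEIGHBOURS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3)
                 if d != (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= pi < n for pi, n in zip(p, shape))


def glcm_oracle(levels, mask, symmetric=True):
    """Count co-occurring level pairs over the 13 unique 3D offsets."""
    ng = int(levels[mask].max())
    P = np.zeros((ng, ng))
    shape = levels.shape
    for d in DIRS_3D:
        for p in itertools.product(*(range(n) for n in shape)):
            if not mask[p]:
                continue
            q = tuple(pi + di for pi, di in zip(p, d))
            if _inside(shape, q) and mask[q]:
                P[levels[p] - 1, levels[q] - 1] += 1
    if symmetric:
        P = P + P.T
    return P


def glrlm_oracle(levels, mask):
    """Enumerate maximal same-level runs per direction, summed."""
    ng = int(levels[mask].max())
    shape = levels.shape
    runs = []
    for d in DIRS_3D:
        for p in itertools.product(*(range(n) for n in shape)):
            if not mask[p]:
                continue
            prev = tuple(pi - di for pi, di in zip(p, d))
            if (_inside(shape, prev) and mask[prev]
                    and levels[prev] == levels[p]):
                continue  # not the start of a run
            length = 1
            q = tuple(pi + di for pi, di in zip(p, d))
            while _inside(shape, q) and mask[q] and levels[q] == levels[p]:
                length += 1
                q = tuple(qi + di for qi, di in zip(q, d))
            runs.append((int(levels[p]), length))
    max_len = max(l for _, l in runs)
    P = np.zeros((ng, max_len))
    for lev, length in runs:
        P[lev - 1, length - 1] += 1
    return P


def glszm_oracle(levels, mask):
    """Flood-fill connected same-level zones with 26-connectivity."""
    ng = int(levels[mask].max())
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in itertools.product(*(range(n) for n in shape)):
        if not mask[p] or seen[p]:
            continue
        lev = levels[p]
        stack, size = [p], 0
        seen[p] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBOURS_26:
                q = tuple(ci + di for ci, di in zip(cur, d))
                if (_inside(shape, q) and mask[q] and not seen[q]
                        and levels[q] == lev):
                    seen[q] = True
                    stack.append(q)
        zones.append((int(lev), size))
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size))
    for lev, size in zones:
        P[lev - 1, size - 1] += 1
    return P


def gldm_oracle(levels, mask, alpha=0):
    """Count, per ROI voxel, dependent 26-neighbours (|level diff| <= alpha);
    dependence size = count + 1 (centre included)."""
    ng = int(levels[mask].max())
    shape = levels.shape
    entries = []
    for p in itertools.product(*(range(n) for n in shape)):
        if not mask[p]:
            continue
        count = 0
        for d in NEIGHBOURS_26:
            q = tuple(pi + di for pi, di in zip(p, d))
            if (_inside(shape, q) and mask[q]
                    and abs(int(levels[q]) - int(levels[p])) <= alpha):
                count += 1
        entries.append((int(levels[p]), count + 1))
    max_size = max(s for _, s in entries)
    P = np.zeros((ng, max_size))
    for lev, size in entries:
        P[lev - 1, size - 1] += 1
    return P


def bilinear_resample_oracle(slice2d, spacing, target):
    """Resample one slice to target (dx, dy): output pixel i (row), j (col)
    samples the input at (i * ty / dy, j * tx / dx) with bilinear weights,
    clamping to the edges."""
    dy_sp, dx_sp = spacing  # (dy, dx) of the input slice
    ty, tx = target
    nr, nc = slice2d.shape
    new_r = max(1, int(round(nr * dy_sp / ty)))
    new_c = max(1, int(round(nc * dx_sp / tx)))
    out = np.zeros((new_r, new_c))
    for i in range(new_r):
        for j in range(new_c):
            r = min(max(i * ty / dy_sp, 0.0), nr - 1)
            c = min(max(j * tx / dx_sp, 0.0), nc - 1)
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            r1, c1 = min(r0 + 1, nr - 1), min(c0 + 1, nc - 1)
            fr, fc = r - r0, c - c0
            out[i, j] = (
                slice2d[r0, c0] * (1 - fr) * (1 - fc)
                + slice2d[r1, c0] * fr * (1 - fc)
                + slice2d[r0, c1] * (1 - fr) * fc
                + slice2d[r1, c1] * fr * fc
            )
    return out


def correlation_filter_oracle(x, r2_threshold):
    """Exhaustive sequential scan: column j kept iff R² with every kept
    k < j is below threshold; zero-variance columns always dropped."""
    kept = []
    for j in range(x.shape[1]):
        if np.ptp(x[:, j]) == 0:
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(x[:, j], x[:, k])[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


def quantile_map_oracle(x, template_sorted):
    """Map each value to the template quantile at its mid-rank quantile."""
    x = np.asarray(x, float)
    t = np.asarray(template_sorted, float)
    out = np.empty_like(x)
    for i, v in enumerate(x):
        rank = (np.sum(x < v) + 0.5 * (np.sum(x == v) - 1))
        q = rank / max(x.size - 1, 1)
        pos = q * (t.size - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, t.size - 1)
        f = pos - lo
        out[i] = t[lo] * (1 - f) + t[hi] * f
    return out
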