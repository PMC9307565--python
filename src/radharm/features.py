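"""First- and second-order radiomic texture features with fixed-bin-width
discretisation.

Per ROI the panel is: 18 first-order statistics of the intensity
distribution, plus second-order features from four texture matrices —
grey-level co-occurrence (GLCM, 24 features), grey-level dependence
(GLDM, 14), grey-level run length (GLRLM, 16) and grey-level size zone
(GLSZM, 16) — 88 features in total.  Shape features are deliberately
absent: they depend only on the segmentation, not on image intensity.

Conventions (matching the common radiomics reference taxonomy):

* discretisation: ``level(x) = floor((x - min_ROI) / W) + 1`` with fixed
  bin width ``W`` anchored at the per-ROI minimum;
* GLCM and GLRLM aggregate over the 13 unique 3D directions (symmetrised /
  summed into a single matrix before feature computation);
* GLSZM zones use 26-connectivity; GLDM dependence uses the 26
  neighbourhood with tolerance ``alpha`` (default 0), and the dependence
  size ``j`` counts the centre voxel plus its dependent neighbours (so
  ``j >= 1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (FeatureTable, ImageStudy, ROI_LABELS, ROI_NAMES, feature_id)

_EPS = np.spacing(1.0)

#: 13 unique 3D direction offsets (one per +/- pair), (dz, dy, dx)
DIRECTIONS_3D = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
#: 4 unique in-plane offsets for 2D mode
DIRECTIONS_2D = ((0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1))


@dataclass
class DiscretisedROI:
    """Integer grey levels (1..Ng) over an ROI, with geometry for
    neighbourhood queries.  ``levels`` is 0 outside the ROI."""

    levels: np.ndarray  # 3D int array (cropped to the ROI bounding box)
    mask: np.ndarray  # 3D bool, same shape
    bin_width: float
    ng: int
    roi: str = ""

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretise(voxels: np.ndarray, mask: np.ndarray, bin_width: float,
               roi: str = "") -> DiscretisedROI:
    """Fixed-bin-width discretisation anchored at the ROI minimum.

    ``voxels`` is a 3D volume and ``mask`` a boolean ROI selector of the
    same shape (a 1D intensity vector with a trivially true mask also
    works).  The ROI minimum maps to level 1.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    voxels = np.asarray(voxels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if voxels.ndim == 1:
        voxels = voxels[None, None, :]
        mask = mask[None, None, :]
    if not mask.any():
        raise ValueError("empty ROI")
    # crop to bounding box to keep neighbourhood scans cheap
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    voxels, mask = voxels[sl], mask[sl]
    vals = voxels[mask]
    levels = np.zeros(voxels.shape, dtype=np.int64)
    levels[mask] = np.floor((voxels[mask] - vals.min()) / bin_width).astype(int) + 1
    ng = int(levels.max())
    if ng > 1000:
        warnings.warn(f"{ng} grey levels after discretisation; check bin width",
                      stacklevel=2)
    return DiscretisedROI(levels=levels, mask=mask, bin_width=float(bin_width),
                          ng=ng, roi=roi)


@dataclass
class TextureMatrix:
    """One grey-level texture matrix.  Rows index grey level (1..Ng);
    columns index the kind-specific second axis (co-occurring level, run
    length, zone size or dependence size, all starting at 1)."""

    kind: str  # GLCM | GLRLM | GLSZM | GLDM
    matrix: np.ndarray
    n_directions: int = 1


def _pair_slices(shape, d):
    """Views (src, dst) such that ``a[src]`` and ``a[dst]`` pair each voxel
    v with v + d."""
    src = tuple(slice(max(0, -di), n - max(0, di)) for n, di in zip(shape, d))
    dst = tuple(slice(max(0, di), n - max(0, -di)) for n, di in zip(shape, d))
    return src, dst


def _directions(d: DiscretisedROI, mode: str, override=None):
    dirs = override if override is not None else (
        DIRECTIONS_3D if mode == "3D" else DIRECTIONS_2D)
    # drop directions that cannot fit in the volume (e.g. dz on a single slice)
    return [dd for dd in dirs
            if all(abs(di) < n for di, n in zip(dd, d.levels.shape))]


def glcm(d: DiscretisedROI, mode: str = "3D", symmetric: bool = True,
         directions=None) -> TextureMatrix:
    """Grey-level co-occurrence matrix, summed over directions and (by
    default) symmetrised."""
    if d.n_voxels < 2:
        raise ValueError("GLCM requires at least two ROI voxels")
    ng = d.ng
    P = np.zeros((ng, ng), dtype=float)
    dirs = _directions(d, mode, directions)
    any_pair = False
    for dd in dirs:
        src, dst = _pair_slices(d.levels.shape, dd)
        ok = d.mask[src] & d.mask[dst]
        if not ok.any():
            continue
        any_pair = True
        i = d.levels[src][ok] - 1
        j = d.levels[dst][ok] - 1
        P += np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
    if not any_pair:
        raise ValueError("no valid voxel pairs for GLCM")
    if symmetric:
        P = P + P.T
    return TextureMatrix(kind="GLCM", matrix=P, n_directions=len(dirs))


def glrlm(d: DiscretisedROI, mode: str = "3D", directions=None) -> TextureMatrix:
    """Grey-level run length matrix: maximal same-level runs per direction,
    summed over directions."""
    if d.n_voxels == 0:
        raise ValueError("empty ROI")
    ng = d.ng
    shape = d.levels.shape
    # keep the full direction set: a direction that does not fit the volume
    # still contributes a length-1 run per voxel
    if directions is not None:
        dirs = list(directions)
    else:
        dirs = list(DIRECTIONS_3D if mode == "3D" else DIRECTIONS_2D)
    per_dir = []
    max_len = 1
    for dd in dirs:
        src, dst = _pair_slices(shape, dd)
        same = np.zeros(shape, dtype=bool)
        same[src] = d.mask[src] & d.mask[dst] & (d.levels[src] == d.levels[dst])
        start = d.mask.copy()
        start[dst] &= ~same[src]
        z, y, x = np.nonzero(start)
        lev = d.levels[z, y, x]
        n = z.size
        runlen = np.ones(n, dtype=np.int64)
        alive = np.arange(n)
        cz, cy, cx = z, y, x
        while alive.size:
            cont = same[cz, cy, cx]
            keep = np.nonzero(cont)[0]
            if keep.size == 0:
                break
            alive = alive[keep]
            cz = cz[keep] + dd[0]
            cy = cy[keep] + dd[1]
            cx = cx[keep] + dd[2]
            runlen[alive] += 1
        per_dir.append((lev, runlen))
        max_len = max(max_len, int(runlen.max()) if n else 1)
    P = np.zeros((ng, max_len), dtype=float)
    for lev, runlen in per_dir:
        np.add.at(P, (lev - 1, runlen - 1), 1.0)
    return TextureMatrix(kind="GLRLM", matrix=P, n_directions=len(dirs))


def glszm(d: DiscretisedROI, mode: str = "3D") -> TextureMatrix:
    """Grey-level size zone matrix: connected same-level zones
    (26-connectivity in 3D, 8 in 2D) counted by level and size."""
    if d.n_voxels == 0:
        raise ValueError("empty ROI")
    if mode == "3D":
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[1] = True  # in-plane 8-connectivity only
    entries = []  # (level, size)
    max_size = 1
    for lev in np.unique(d.roi_levels):
        lab, nlab = ndimage.label(d.levels == lev, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        entries.append((int(lev), sizes))
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((d.ng, max_size), dtype=float)
    for lev, sizes in entries:
        np.add.at(P, (np.full(sizes.size, lev - 1), sizes - 1), 1.0)
    return TextureMatrix(kind="GLSZM", matrix=P)


def gldm(d: DiscretisedROI, alpha: int = 0, mode: str = "3D") -> TextureMatrix:
    """Grey-level dependence matrix.  A neighbour (26-neighbourhood in 3D)
    is dependent if its level differs from the centre's by at most
    ``alpha``; the dependence size ``j`` is 1 (the centre) plus the number
    of dependent neighbours."""
    if d.n_voxels == 0:
        raise ValueError("empty ROI")
    shape = d.levels.shape
    dep = np.zeros(shape, dtype=np.int64)
    for dd in _directions(d, mode):
        src, dst = _pair_slices(shape, dd)
        ok = (d.mask[src] & d.mask[dst]
              & (np.abs(d.levels[src] - d.levels[dst]) <= alpha))
        inc = ok.astype(np.int64)
        dep[src] += inc
        dep[dst] += inc
    lev = d.roi_levels
    size = dep[d.mask] + 1  # centre voxel included
    P = np.zeros((d.ng, int(size.max())), dtype=float)
    np.add.at(P, (lev - 1, size - 1), 1.0)
    return TextureMatrix(kind="GLDM", matrix=P)


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------

def first_order_features(d: DiscretisedROI, raw: np.ndarray,
                         voxel_volume: float = 1.0) -> dict[str, float]:
    """The 18-feature first-order panel.

    Moment-type statistics are computed on the raw intensities; entropy and
    uniformity on the discretised histogram.
    """
    x = np.asarray(raw, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    mid = x[(x >= p10) & (x <= p90)]
    hist = np.bincount(d.roi_levels)[1:]
    p = hist / hist.sum()
    p_nz = p[p > 0]
    return {
        "10Percentile": p10,
        "90Percentile": p90,
        "Energy": float(np.sum(x**2)),
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz))),
        "InterquartileRange": p75 - p25,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": (
            float(np.mean(np.abs(mid - mid.mean()))) if mid.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "Uniformity": float(np.sum(p**2)),
        "Variance": float(m2),
    }


# ---------------------------------------------------------------------------
# second-order features
# ---------------------------------------------------------------------------

def _glcm_features(P: np.ndarray) -> dict[str, float]:
    if P.sum() == 0:
        raise ValueError("empty GLCM")
    ng = P.shape[0]
    p = P / P.sum()
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_x = float(np.sum(px * i))
    mu_y = float(np.sum(py * i))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    # difference distribution p_{|i-j|}(k), k = 0..ng-1
    k_diff = np.arange(ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    diff_avg = float(np.sum(p_diff * k_diff))
    # sum distribution p_{i+j}(k), k = 2..2ng
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())

    hxy = float(-np.sum(p[p > 0] * np.log2(p[p > 0])))
    pxy = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(pxy + _EPS)))
    hxy2 = float(-np.sum(pxy[pxy > 0] * np.log2(pxy[pxy > 0])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))

    if sig_x * sig_y > 0:
        correlation = float((np.sum(p * ii * jj) - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 1.0
    imc1 = float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: sqrt of the second-largest eigenvalue of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)); Q is similar to M M^T
    # with M = Dx^{-1/2} P Dy^{-1/2} restricted to occupied levels.
    nz = (px > 0) & (py > 0)
    if nz.sum() <= 1:
        mcc = 1.0
    else:
        m = (p[np.ix_(nz, nz)]
             / np.sqrt(px[nz])[:, None] / np.sqrt(py[nz])[None, :])
        eig = np.linalg.eigvalsh(m @ m.T)
        mcc = float(np.sqrt(max(0.0, eig[-2])))

    inv_var_mask = k_diff > 0
    return {
        "Autocorrelation": float(np.sum(p * ii * jj)),
        "ClusterProminence": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(
            -np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0]))
        ),
        "DifferenceVariance": float(np.sum(p_diff * (k_diff - diff_avg) ** 2)),
        "Id": float(np.sum(p_diff / (1.0 + k_diff))),
        "Idm": float(np.sum(p_diff / (1.0 + k_diff**2))),
        "Idmn": float(np.sum(p_diff / (1.0 + (k_diff / ng) ** 2))),
        "Idn": float(np.sum(p_diff / (1.0 + k_diff / ng))),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float(
            np.sum(p_diff[inv_var_mask] / k_diff[inv_var_mask] ** 2)
        ),
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(p_sum * k_sum)),
        "SumEntropy": float(-np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0]))),
        "SumSquares": float(np.sum(p * (ii - mu_x) ** 2)),
    }


def _size_family_features(P: np.ndarray, n_voxels: int, prefix: dict
                          ) -> dict[str, float]:
    """Shared formula family for GLRLM / GLSZM / GLDM: grey level on rows,
    size-like quantity (run length / zone size / dependence size) on columns.

    ``prefix`` maps generic keys to family-specific feature names.
    """
    nz = P.sum()
    if nz == 0:
        raise ValueError("empty texture matrix")
    ng, ns = P.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, ns + 1, dtype=float)
    pg = P.sum(axis=1)  # grey-level marginal
    ps = P.sum(axis=0)  # size marginal
    p = P / nz
    pg_n = pg / nz
    ps_n = ps / nz
    mu_i = float(np.sum(pg_n * i))
    mu_j = float(np.sum(ps_n * j))
    p_nz = p[p > 0]
    out = {
        "sre": float(np.sum(ps / j**2) / nz),
        "lre": float(np.sum(ps * j**2) / nz),
        "gln": float(np.sum(pg**2) / nz),
        "glnn": float(np.sum(pg**2) / nz**2),
        "sn": float(np.sum(ps**2) / nz),
        "snn": float(np.sum(ps**2) / nz**2),
        "pct": float(nz / n_voxels),
        "glv": float(np.sum(pg_n * (i - mu_i) ** 2)),
        "sv": float(np.sum(ps_n * (j - mu_j) ** 2)),
        "ent": float(-np.sum(p_nz * np.log2(p_nz))),
        "lgle": float(np.sum(pg / i**2) / nz),
        "hgle": float(np.sum(pg * i**2) / nz),
        "slgle": float(np.sum(P / (np.outer(i**2, j**2))) / nz),
        "shgle": float(np.sum(P * np.outer(i**2, 1.0 / j**2)) / nz),
        "llgle": float(np.sum(P * np.outer(1.0 / i**2, j**2)) / nz),
        "lhgle": float(np.sum(P * np.outer(i**2, j**2)) / nz),
    }
    return {name: out[key] for key, name in prefix.items()}


_GLRLM_NAMES = {
    "sre": "ShortRunEmphasis",
    "lre": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity",
    "snn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage",
    "glv": "GrayLevelVariance",
    "sv": "RunVariance",
    "ent": "RunEntropy",
    "lgle": "LowGrayLevelRunEmphasis",
    "hgle": "HighGrayLevelRunEmphasis",
    "slgle": "ShortRunLowGrayLevelEmphasis",
    "shgle": "ShortRunHighGrayLevelEmphasis",
    "llgle": "LongRunLowGrayLevelEmphasis",
    "lhgle": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "sre": "SmallAreaEmphasis",
    "lre": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity",
    "snn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage",
    "glv": "GrayLevelVariance",
    "sv": "ZoneVariance",
    "ent": "ZoneEntropy",
    "lgle": "LowGrayLevelZoneEmphasis",
    "hgle": "HighGrayLevelZoneEmphasis",
    "slgle": "SmallAreaLowGrayLevelEmphasis",
    "shgle": "SmallAreaHighGrayLevelEmphasis",
    "llgle": "LargeAreaLowGrayLevelEmphasis",
    "lhgle": "LargeAreaHighGrayLevelEmphasis",
}

_GLDM_NAMES = {
    "sre": "SmallDependenceEmphasis",
    "lre": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity",
    "sn": "DependenceNonUniformity",
    "snn": "DependenceNonUniformityNormalized",
    "glv": "GrayLevelVariance",
    "sv": "DependenceVariance",
    "ent": "DependenceEntropy",
    "lgle": "LowGrayLevelEmphasis",
    "hgle": "HighGrayLevelEmphasis",
    "slgle": "SmallDependenceLowGrayLevelEmphasis",
    "shgle": "SmallDependenceHighGrayLevelEmphasis",
    "llgle": "LargeDependenceLowGrayLevelEmphasis",
    "lhgle": "LargeDependenceHighGrayLevelEmphasis",
}


def second_order_features(matrices: dict[str, TextureMatrix],
                          n_voxels: int) -> dict[str, dict[str, float]]:
    """Feature panels for a set of texture matrices keyed by family."""
    out: dict[str, dict[str, float]] = {}
    for kind, tm in matrices.items():
        if tm.matrix.sum() == 0:
            raise ValueError(f"empty {kind} matrix")
        if kind == "GLCM":
            out[kind] = _glcm_features(tm.matrix)
        elif kind == "GLRLM":
            out[kind] = _size_family_features(
                tm.matrix, n_voxels * tm.n_directions, _GLRLM_NAMES)
        elif kind == "GLSZM":
            out[kind] = _size_family_features(tm.matrix, n_voxels, _GLSZM_NAMES)
        elif kind == "GLDM":
            out[kind] = _size_family_features(tm.matrix, n_voxels, _GLDM_NAMES)
        else:
            raise ValueError(f"unknown matrix kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# study-level extraction
# ---------------------------------------------------------------------------

#: expected per-ROI panel size: 18 first-order + 24 + 16 + 16 + 14
PANEL_SIZE = 88

_FIRSTORDER_NAMES = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "TotalEnergy", "Uniformity", "Variance",
)
_GLCM_FEATURE_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)


def extract_study(study: ImageStudy, bin_width: float, mode: str = "3D",
                  alpha: int = 0) -> dict[str, float]:
    """Extract the full per-ROI feature panel for one study.

    Returns a flat ``{feature_id: value}`` dict over the three ROIs.  An
    empty ROI yields NaN for all of its features.
    """
    dx, dy, dz = study.spacing
    voxel_volume = dx * dy * dz
    out: dict[str, float] = {}
    for label, roi in ROI_LABELS.items():
        sel = study.mask == label
        if not sel.any():
            d = None
        else:
            d = discretise(study.voxels, sel, bin_width, roi=roi)
        if d is None:
            fo = {k: np.nan for k in _FIRSTORDER_NAMES}
            so = {fam: {name: np.nan for name in names.values()}
                  for fam, names in (("GLRLM", _GLRLM_NAMES),
                                     ("GLSZM", _GLSZM_NAMES),
                                     ("GLDM", _GLDM_NAMES))}
            so["GLCM"] = {k: np.nan for k in _GLCM_FEATURE_NAMES}
        else:
            raw = study.voxels[sel]
            fo = first_order_features(d, raw, voxel_volume)
            matrices = {
                "GLCM": glcm(d, mode=mode),
                "GLRLM": glrlm(d, mode=mode),
                "GLSZM": glszm(d, mode=mode),
                "GLDM": gldm(d, alpha=alpha, mode=mode),
            }
            so = second_order_features(matrices, d.n_voxels)
        for name, value in fo.items():
            out[feature_id(roi, "firstorder", name)] = value
        for fam, feats in so.items():
            for name, value in feats.items():
                out[feature_id(roi, fam, name)] = value
    return out


def extract_features(studies: list[ImageStudy], bin_width: float,
                     mode: str = "3D", alpha: int = 0) -> FeatureTable:
    """Extract features for a cohort into a :class:`FeatureTable`.

    Rows are studies (subject x phase); metadata comes from each study.
    """
    rows = {}
    meta = {}
    for s in studies:
        rows[s.study_id] = extract_study(s, bin_width, mode=mode, alpha=alpha)
        meta[s.study_id] = {
            "subject_id": s.subject_id,
            "centre": s.centre_id,
            "pathology": s.class_label,
            "phase": s.phase,
        }
    data = pd.DataFrame.from_dict(rows, orient="index")
    row_meta = pd.DataFrame.from_dict(meta, orient="index")
    return FeatureTable.from_matrix(data, row_meta)
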