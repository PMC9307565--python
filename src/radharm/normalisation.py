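"""Image intensity normalisation: rescaling, z-scoring, histogram matching
and piecewise linear histogram matching (Nyúl–Udupa), at whole-image or
per-ROI scope.

All four transforms are monotone (rank-preserving) within their fitting
scope.  Methods:

``O``
    pass-through (no normalisation).
``R``
    min–max rescaling to [0, 1].
``N``
    z-normalisation (subtract mean, divide by population SD).
``HM``
    histogram matching: empirical quantile mapping onto a single template
    subject's intensity distribution.
``PLHM``
    piecewise linear histogram matching: the input's percentile values on a
    landmark grid (p1, deciles 10..90, p99) are mapped onto standard-scale
    landmarks learned by averaging over a reference population.

ROI scope fits and applies each transform independently per ROI label,
leaving background voxels untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ImageStudy, ROI_LABELS

METHODS = ("O", "R", "N", "HM", "PLHM")
SCOPES = ("whole", "roi")

#: landmark percentile grid: tail anchors plus deciles
DEFAULT_GRID = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)


class DegenerateInputWarning(UserWarning):
    """Constant-valued input to a normalisation transform."""


# ---------------------------------------------------------------------------
# element transforms on 1D value arrays
# ---------------------------------------------------------------------------

def rescale(values: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 1]; constant input maps to zeros (warned)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("rescale requires at least one finite value")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant input to rescale; returning zeros",
                      DegenerateInputWarning, stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def znorm(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-SD standardisation (population SD).

    Zero-variance input maps to zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("znorm requires at least two values")
    sd = x.std()
    if sd == 0:
        warnings.warn("zero-variance input to znorm; returning zeros",
                      DegenerateInputWarning, stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class HistogramTemplate:
    """Sorted intensities of one reference subject (whole image or one ROI)."""

    values: np.ndarray
    scope: str = "whole"

    def __post_init__(self):
        v = np.sort(np.asarray(self.values, dtype=float).ravel())
        if v.size == 0:
            raise ValueError("empty histogram template")
        self.values = v


def histogram_match(values: np.ndarray, template: HistogramTemplate) -> np.ndarray:
    """Monotone quantile mapping of ``values`` onto the template distribution.

    Each value is sent to the template quantile at its own (mid-rank)
    empirical quantile, with linear interpolation between template order
    statistics.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input to histogram_match")
    from scipy.stats import rankdata

    t = template.values
    # mid-rank empirical quantiles; ties share a rank so equal inputs map
    # to equal outputs
    ranks = rankdata(x, method="average") - 1.0
    q = ranks / max(x.size - 1, 1)
    tq = np.linspace(0.0, 1.0, t.size)
    return np.interp(q, tq, t)


@dataclass
class LandmarkSet:
    """Trained standard-scale landmarks for piecewise linear histogram
    matching."""

    percentile_grid: tuple = DEFAULT_GRID
    standard_landmarks: np.ndarray = None
    standard_range: tuple[float, float] = (0.0, 1.0)
    training_centre: str = ""

    def __post_init__(self):
        if self.standard_landmarks is not None:
            lm = np.asarray(self.standard_landmarks, dtype=float)
            if np.any(np.diff(lm) < 0):
                raise ValueError("standard landmarks must be non-decreasing")
            s_min, s_max = self.standard_range
            if lm.min() < s_min - 1e-9 or lm.max() > s_max + 1e-9:
                raise ValueError("landmarks outside standard range")
            self.standard_landmarks = lm


def _mapped_percentiles(x: np.ndarray, grid, standard_range) -> np.ndarray:
    """Image percentiles affinely mapped so the two anchor percentiles hit
    (s_min, s_max)."""
    p = np.percentile(x, grid)
    s_min, s_max = standard_range
    lo, hi = p[0], p[-1]
    if hi == lo:
        return np.full(len(grid), 0.5 * (s_min + s_max))
    return s_min + (p - lo) * (s_max - s_min) / (hi - lo)


def fit_plhm(
    training: list[np.ndarray],
    grid=DEFAULT_GRID,
    standard_range: tuple[float, float] = (0.0, 1.0),
    training_centre: str = "",
) -> LandmarkSet:
    """Learn standard-scale landmarks from a reference population.

    Per training image: percentiles on ``grid`` are linearly mapped so the
    extreme anchors hit the standard range, then averaged across images.
    """
    if not training:
        raise ValueError("fit_plhm needs at least one training array")
    grid = tuple(float(g) for g in grid)
    if list(grid) != sorted(grid):
        raise ValueError("percentile grid must be sorted")
    mapped = []
    for arr in training:
        x = np.asarray(arr, dtype=float).ravel()
        if x.size == 0 or not np.all(np.isfinite(x)):
            raise ValueError("training arrays must be non-empty and finite")
        mapped.append(_mapped_percentiles(x, grid, standard_range))
    lm = np.mean(mapped, axis=0)
    lm = np.maximum.accumulate(lm)  # guard against tiny non-monotone jitter
    return LandmarkSet(percentile_grid=grid, standard_landmarks=lm,
                       standard_range=tuple(standard_range),
                       training_centre=training_centre)


def apply_plhm(values: np.ndarray, landmarks: LandmarkSet) -> np.ndarray:
    """Piecewise-linear map sending the input's own grid percentiles onto the
    standard landmarks; linear extrapolation beyond the anchors."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input to apply_plhm")
    src = np.percentile(x, landmarks.percentile_grid)
    dst = landmarks.standard_landmarks
    if src[-1] == src[0]:
        warnings.warn("constant input to apply_plhm; mapping to range midpoint",
                      DegenerateInputWarning, stacklevel=2)
        return np.full_like(x, 0.5 * sum(landmarks.standard_range))
    # collapse duplicate source knots to keep the map a function
    keep = np.concatenate([[True], np.diff(src) > 0])
    src, dst = src[keep], dst[keep]
    out = np.interp(x, src, dst)
    # linear extrapolation from the end segments
    lo_slope = (dst[1] - dst[0]) / (src[1] - src[0])
    hi_slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
    below = x < src[0]
    above = x > src[-1]
    out[below] = dst[0] + (x[below] - src[0]) * lo_slope
    out[above] = dst[-1] + (x[above] - src[-1]) * hi_slope
    return out


# ---------------------------------------------------------------------------
# fitting on a reference centre and applying to studies
# ---------------------------------------------------------------------------

@dataclass
class NormalisationModel:
    """Fitted state for the methods that need a reference: HM templates and
    PLHM landmark sets, at both scopes.

    ``hm_whole`` is one template; ``hm_roi`` maps ROI name -> template (all
    from the same reference subject).  ``plhm_whole`` is one landmark set;
    ``plhm_roi`` maps ROI name -> landmark set.
    """

    reference_centre: str = ""
    hm_whole: HistogramTemplate | None = None
    hm_roi: dict = field(default_factory=dict)
    plhm_whole: LandmarkSet | None = None
    plhm_roi: dict = field(default_factory=dict)


def fit_normalisation(
    studies: list[ImageStudy],
    reference_centre: str | None = None,
    grid=DEFAULT_GRID,
    standard_range=(0.0, 1.0),
) -> NormalisationModel:
    """Fit HM templates and PLHM landmarks from one reference centre.

    The reference defaults to the centre with the most studies.  The HM
    template subject is the reference centre's first study in subject order
    (a deterministic stand-in for the study's visually selected template).
    """
    if not studies:
        raise ValueError("no studies to fit on")
    if reference_centre is None:
        centres = [s.centre_id for s in studies]
        reference_centre = max(sorted(set(centres)), key=centres.count)
    ref = sorted(
        (s for s in studies if s.centre_id == reference_centre),
        key=lambda s: s.study_id,
    )
    if not ref:
        raise ValueError(f"no studies from reference centre {reference_centre!r}")

    template_study = ref[0]
    model = NormalisationModel(reference_centre=reference_centre)
    model.hm_whole = HistogramTemplate(template_study.voxels.ravel(), scope="whole")
    model.plhm_whole = fit_plhm([s.voxels.ravel() for s in ref], grid=grid,
                                standard_range=standard_range,
                                training_centre=reference_centre)
    for label, roi in ROI_LABELS.items():
        tvals = template_study.roi_values(label)
        if tvals.size:
            model.hm_roi[roi] = HistogramTemplate(tvals, scope="roi")
        train = [s.roi_values(label) for s in ref if s.roi_values(label).size]
        if train:
            model.plhm_roi[roi] = fit_plhm(train, grid=grid,
                                           standard_range=standard_range,
                                           training_centre=reference_centre)
    return model


def _transform(values, method, roi, model: NormalisationModel | None, scope):
    if method == "R":
        return rescale(values)
    if method == "N":
        return znorm(values)
    if method == "HM":
        if model is None:
            raise ValueError("HM requires a fitted NormalisationModel")
        tpl = model.hm_whole if scope == "whole" else model.hm_roi.get(roi)
        if tpl is None:
            raise ValueError(f"no HM template for roi {roi!r}")
        return histogram_match(values, tpl)
    if method == "PLHM":
        if model is None:
            raise ValueError("PLHM requires a fitted NormalisationModel")
        lms = model.plhm_whole if scope == "whole" else model.plhm_roi.get(roi)
        if lms is None:
            raise ValueError(f"no PLHM landmarks for roi {roi!r}")
        return apply_plhm(values, lms)
    raise ValueError(f"unknown method {method!r}")


def apply_normalisation(
    study: ImageStudy,
    method: str,
    scope: str = "whole",
    model: NormalisationModel | None = None,
) -> ImageStudy:
    """Normalise one study.

    ``scope='whole'`` fits on and transforms every voxel; ``scope='roi'``
    transforms each ROI's voxels from that ROI's own statistics, leaving
    background untouched.  Method ``O`` is the identity at either scope.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    if method == "O":
        return replace(study, voxels=study.voxels.copy(), flags=list(study.flags))

    vox = study.voxels.copy()
    if scope == "whole":
        vox = _transform(vox.ravel(), method, None, model, scope).reshape(vox.shape)
    else:
        for label, roi in ROI_LABELS.items():
            sel = study.mask == label
            if not sel.any():
                continue
            vox[sel] = _transform(study.voxels[sel], method, roi, model, scope)
    return replace(study, voxels=vox, flags=list(study.flags))
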