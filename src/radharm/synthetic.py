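"""Synthetic multi-centre, two-class cardiac-like phantom cohorts.

The generator emulates the statistical structure of a multi-centre
short-axis cardiac MR cohort without any anatomical realism:

* each subject is a stack of slices containing a left-ventricular (LV)
  cavity disc, a myocardial ring and a right-ventricular (RV) crescent on a
  darker background, rendered on a canonical intensity scale in [0, 1];
* disease (HCM, hypertrophic cardiomyopathy) thickens the myocardial ring
  and alters myocardial texture (larger correlation length and variance of
  a smoothed Gaussian random field) — the class signal therefore lives in
  myocardial geometry and second-order texture, and survives intensity
  normalisation;
* each centre applies a monotone intensity transform (gain, offset, gamma)
  to a centre-specific raw dynamic range, plus additive Gaussian noise —
  mimicking the order-of-magnitude differences in raw intensity ranges
  between MR scanners from different vendors.

Default cohort: 5 centres, 112 healthy + 106 HCM subjects (218 total), two
cardiac phases (ED, ES) per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import ImageStudy

HEALTHY = "healthy"
HCM = "HCM"

#: per-centre (healthy, HCM) subject counts for the default 5-centre cohort
DEFAULT_COUNTS = {
    "C1": (14, 15),
    "C2": (11, 5),
    "C3": (33, 37),  # largest centre; default reference for normalisation
    "C4": (32, 24),
    "C5": (22, 25),
}


@dataclass(frozen=True)
class CentreProfile:
    """Monotone intensity transform characterising one centre's scanner.

    output = max_intensity * (gain * canonical**gamma + offset) + N(0, noise_sd),
    clipped at zero.
    """

    centre_id: str
    gain: float = 1.0
    offset: float = 0.0
    gamma: float = 1.0
    noise_sd: float = 0.0
    max_intensity: float = 1.0

    def __post_init__(self):
        if self.gain <= 0 or self.gamma <= 0:
            raise ValueError("gain and gamma must be positive")
        if self.offset < 0 or self.noise_sd < 0:
            raise ValueError("offset and noise_sd must be non-negative")


#: default profiles: raw dynamic ranges spread from hundreds to ten-thousands
DEFAULT_PROFILES = {
    "C1": CentreProfile("C1", gain=1.00, offset=0.00, gamma=1.00,
                        noise_sd=3.0, max_intensity=360.0),
    "C2": CentreProfile("C2", gain=0.90, offset=0.03, gamma=0.85,
                        noise_sd=8.0, max_intensity=1200.0),
    "C3": CentreProfile("C3", gain=1.10, offset=0.01, gamma=1.15,
                        noise_sd=20.0, max_intensity=3000.0),
    "C4": CentreProfile("C4", gain=0.95, offset=0.05, gamma=0.90,
                        noise_sd=25.0, max_intensity=3700.0),
    "C5": CentreProfile("C5", gain=1.05, offset=0.02, gamma=1.10,
                        noise_sd=90.0, max_intensity=14400.0),
}


def null_profiles(centres=None) -> dict[str, CentreProfile]:
    """Identical (identity-scale) profiles for every centre: no centre effect
    beyond independent noise realisations.  Used to validate that downstream
    centre identification finds nothing when nothing was injected."""
    centres = list(centres or DEFAULT_COUNTS)
    return {
        c: CentreProfile(c, gain=1.0, offset=0.0, gamma=1.0,
                         noise_sd=10.0, max_intensity=1000.0)
        for c in centres
    }


@dataclass(frozen=True)
class PhantomGeometry:
    """Concentric-ring phantom parameters (pixel units).

    ``wall_mean``/``wall_sd`` are per-class myocardial wall thickness
    distributions; texture parameters control the smoothed Gaussian random
    field added to the myocardium.
    """

    image_size: tuple[int, int, int] = (3, 64, 64)  # (slices, rows, cols)
    lv_radius_mean: float = 9.0
    lv_radius_sd: float = 1.0
    wall_mean: dict = field(default_factory=lambda: {HEALTHY: 4.0, HCM: 8.0})
    wall_sd: dict = field(default_factory=lambda: {HEALTHY: 0.6, HCM: 1.0})
    rv_radius_mean: float = 7.0
    rv_radius_sd: float = 1.0
    # tissue base intensities on the canonical [0, 1] scale
    base_intensity: dict = field(
        default_factory=lambda: {"bg": 0.12, "LV": 0.80, "MYO": 0.42, "RV": 0.72}
    )
    # myocardial texture: (smoothing sigma in px, field sd) per class
    myo_texture: dict = field(
        default_factory=lambda: {HEALTHY: (0.8, 0.05), HCM: (1.6, 0.10)}
    )
    other_texture_sd: float = 0.02  # unstructured texture in non-MYO tissue
    noise_sd: float = 0.015  # canonical-scale acquisition-independent noise


@dataclass
class CohortSpec:
    """Cohort composition: per-centre (healthy, HCM) counts, phases, seed."""

    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    phases: tuple[str, ...] = ("ED", "ES")
    seed: int = 0
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)

    def __post_init__(self):
        for c, (nh, nd) in self.counts.items():
            if nh < 0 or nd < 0:
                raise ValueError(f"negative count for centre {c}")

    @property
    def n_subjects(self) -> int:
        return sum(nh + nd for nh, nd in self.counts.values())


def _textured(shape, sigma, sd, rng) -> np.ndarray:
    """Stationary Gaussian random field: white noise smoothed in-plane with a
    Gaussian kernel of scale ``sigma`` and rescaled to standard deviation
    ``sd``."""
    w = rng.standard_normal(shape)
    if sigma > 0:
        w = ndimage.gaussian_filter(w, sigma=(0, sigma, sigma))
        s = w.std()
        if s > 0:
            w = w / s
    return sd * w


def make_phantom(
    class_label: str,
    geometry: PhantomGeometry,
    rng: np.random.Generator,
    subject_id: str = "S0",
    phase: str = "ED",
) -> ImageStudy:
    """Generate one centre-free phantom study on the canonical [0, 1] scale.

    ES phases get a ~20% smaller LV cavity with correspondingly thicker wall,
    a crude systolic contraction.
    """
    if class_label not in (HEALTHY, HCM):
        raise ValueError(f"unknown class label {class_label!r}")
    ns, nr, nc = geometry.image_size

    lv_r = max(3.0, rng.normal(geometry.lv_radius_mean, geometry.lv_radius_sd))
    wall = max(1.5, rng.normal(geometry.wall_mean[class_label],
                               geometry.wall_sd[class_label]))
    rv_r = max(2.5, rng.normal(geometry.rv_radius_mean, geometry.rv_radius_sd))
    if phase == "ES":
        lv_r *= 0.8
        wall *= 1.15

    outer = lv_r + wall
    # LV centre right of mid-line, RV centre to its left
    cy = nr / 2 + rng.normal(0, 1.0)
    cx = nc / 2 + 6 + rng.normal(0, 1.0)
    rv_cx = cx - outer - rv_r + 2.0  # crescent hugging the myocardium

    yy, xx = np.mgrid[0:nr, 0:nc]
    d_lv = np.hypot(yy - cy, xx - cx)
    d_rv = np.hypot(yy - cy, xx - rv_cx)
    lv = d_lv < lv_r
    myo = (d_lv >= lv_r) & (d_lv < outer)
    rv = (d_rv < rv_r) & (d_lv >= outer)
    if not (lv.any() and myo.any() and rv.any()):
        raise ValueError("geometry yields an empty ROI")

    mask2d = np.zeros((nr, nc), dtype=int)
    mask2d[lv] = 1
    mask2d[myo] = 2
    mask2d[rv] = 3
    mask = np.repeat(mask2d[None], ns, axis=0)

    base = geometry.base_intensity
    vox = np.full((ns, nr, nc), base["bg"], dtype=float)
    vox[mask == 1] = base["LV"]
    vox[mask == 2] = base["MYO"]
    vox[mask == 3] = base["RV"]

    sigma, sd = geometry.myo_texture[class_label]
    myo_field = _textured((ns, nr, nc), sigma, sd, rng)
    vox = np.where(mask == 2, vox + myo_field, vox)
    if geometry.other_texture_sd > 0:
        other = _textured((ns, nr, nc), 0.5, geometry.other_texture_sd, rng)
        vox = np.where(mask != 2, vox + other, vox)
    if geometry.noise_sd > 0:
        vox = vox + rng.normal(0, geometry.noise_sd, vox.shape)
    vox = np.clip(vox, 0.0, 1.0)

    return ImageStudy(
        voxels=vox,
        spacing=(1.0, 1.0, 10.0),
        mask=mask,
        centre_id="",
        class_label=class_label,
        phase=phase,
        subject_id=subject_id,
    )


def apply_centre_effect(
    study: ImageStudy, profile: CentreProfile, rng: np.random.Generator
) -> ImageStudy:
    """Map a canonical-scale study through one centre's intensity transform."""
    x = study.voxels
    if x.min() < 0 or x.max() > 1 + 1e-9:
        raise ValueError("apply_centre_effect expects canonical-scale input in [0, 1]")
    out = profile.max_intensity * (profile.gain * x**profile.gamma + profile.offset)
    if profile.noise_sd > 0:
        out = out + rng.normal(0, profile.noise_sd, out.shape)
    out = np.clip(out, 0.0, None)
    return replace(study, voxels=out, centre_id=profile.centre_id,
                   flags=list(study.flags))


def generate_cohort(
    spec: CohortSpec, profiles: dict[str, CentreProfile] | None = None
) -> list[ImageStudy]:
    """Generate the full multi-centre cohort, deterministic under ``spec.seed``.

    Each subject contributes one study per phase, all drawn from a single
    per-subject random stream (ES additionally applies a crude systolic
    contraction to the drawn geometry).
    """
    profiles = profiles if profiles is not None else DEFAULT_PROFILES
    missing = [c for c in spec.counts if c not in profiles]
    if missing:
        raise ValueError(f"no centre profile for: {missing}")
    rng = np.random.default_rng(spec.seed)
    studies: list[ImageStudy] = []
    i = 0
    for centre in sorted(spec.counts):
        nh, nd = spec.counts[centre]
        for class_label, n in ((HEALTHY, nh), (HCM, nd)):
            for _ in range(n):
                sid = f"{centre}_{class_label}_{i:03d}"
                # per-subject child generator: phase loop shares the stream
                sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
                for phase in spec.phases:
                    study = make_phantom(class_label, spec.geometry, sub_rng,
                                         subject_id=sid, phase=phase)
                    studies.append(
                        apply_centre_effect(study, profiles[centre], sub_rng)
                    )
                i += 1
    return studies
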