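"""Stereo-rig simulation with ground-truth pincushion distortion.

Emulates a non-convergence mobile stereo acquisition: one pinhole camera
translated laterally by the baseline between the two exposures, imaging
a planar line target (optionally with per-line depth steps) at working
distances of a few centimetres.  The lens applies *positive-displacement
pincushion* distortion in the division-model form

    (xu, yu) = (xd, yd) / (1 + lam1*rd**2 + lam2*rd**4),

where (xd, yd) is the observed (distorted) point relative to the image
center, rd its radius, and (xu, yu) the ideal point.  With lam1, lam2
negative the observed points are pulled inward toward the center, which
is the regime seen in zoomed close-up phone images.  The left and right
halves of the image may carry different coefficient pairs, reproducing
the left/right asymmetry of real lenses.

The division model above maps distorted -> ideal in closed form; the
renderer needs the opposite direction, which is obtained by a bisection
on the distorted radius (the radial map is strictly monotone).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .patterns import (
    DEFAULT_LINE_SIGMA_PX,
    GrayImage,
    LinePattern,
    ScalarBar,
    line_profile,
    make_vertical_line_pattern,
)

__all__ = [
    "StereoConfig",
    "DistortionSpec",
    "StereoPair",
    "default_distortion_spec",
    "scale_distortion_spec",
    "undistort_points",
    "distort_points",
    "project_pattern",
    "render_distorted_stereo",
    "angle_of_view",
    "pattern_for_config",
]

#: working-distance grid of the standard acquisition protocol (mm)
WORKING_DISTANCES_MM = (60.0, 65.0, 70.0, 75.0, 80.0)


@dataclass(frozen=True)
class StereoConfig:
    """Geometry of one stereo acquisition.

    The focal model is a pinhole with focal length ``focal_mm`` and a
    square pixel pitch ``pixel_pitch_mm``; the default pair (5.6 mm,
    3.5 um) makes a 2.0x-zoomed 800-px-wide view span 30 mm of object
    plane at a 60 mm working distance.
    """

    working_distance_mm: float = 60.0
    baseline_mm: float = 10.0
    focal_mm: float = 5.6
    pixel_pitch_mm: float = 0.0035
    width_px: int = 800
    height_px: int = 600

    def __post_init__(self) -> None:
        if self.working_distance_mm <= 0 or self.focal_mm <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("working distance, focal length and pixel pitch must be positive")
        if self.baseline_mm < 0:
            raise ValueError("baseline must be non-negative")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def focal_px(self) -> float:
        """Focal length expressed in pixels."""
        return self.focal_mm / self.pixel_pitch_mm

    @property
    def px_per_mm_at_object(self) -> float:
        """Object-plane sampling density at the working distance (decreases with z)."""
        return self.focal_px / self.working_distance_mm

    @property
    def center(self) -> tuple[float, float]:
        return self.width_px / 2.0, self.height_px / 2.0

    @property
    def fov_mm(self) -> float:
        """Object-plane width of the field of view."""
        return self.width_px / self.px_per_mm_at_object


@dataclass(frozen=True)
class DistortionSpec:
    """Division-model coefficients, one pair per image half.

    Coefficients must be non-positive so that displacement points toward
    the center (positive-displacement pincushion); zero everywhere is
    the identity.  A point exactly on the vertical midline belongs to
    the left half.
    """

    lambda1_left: float = 0.0
    lambda2_left: float = 0.0
    lambda1_right: float = 0.0
    lambda2_right: float = 0.0
    center: tuple[float, float] = (400.0, 300.0)

    def __post_init__(self) -> None:
        for v in (self.lambda1_left, self.lambda2_left, self.lambda1_right, self.lambda2_right):
            if v > 0:
                raise ValueError(
                    "positive division-model coefficients would displace outward "
                    "(barrel); this simulator models inward pincushion displacement"
                )

    @property
    def is_identity(self) -> bool:
        return (
            self.lambda1_left == self.lambda2_left
            == self.lambda1_right == self.lambda2_right == 0.0
        )

    def coeffs(self, side: str) -> tuple[float, float]:
        if side == "left":
            return self.lambda1_left, self.lambda2_left
        if side == "right":
            return self.lambda1_right, self.lambda2_right
        raise ValueError(f"unknown side {side!r}")


def default_distortion_spec(center: tuple[float, float] = (400.0, 300.0)) -> DistortionSpec:
    """Reference lens of the simulator.

    The coefficients are fixed so that, on the standard five-distance
    stereo protocol (60-80 mm, 10 mm baseline, 30 mm field of view at
    60 mm), the maximum corresponding-line distance before correction is
    0.240 mm at 60 mm rising monotonically to ~0.32 mm at 80 mm — the
    magnitude range reported for real zoomed phone optics.  The right
    half is 35% stronger than the left.
    """
    l1, l2 = -1.14531820788431e-07, -1.07373581989154e-13
    return DistortionSpec(
        lambda1_left=l1,
        lambda2_left=l2,
        lambda1_right=1.35 * l1,
        lambda2_right=1.35 * l2,
        center=center,
    )


def scale_distortion_spec(spec: DistortionSpec, factor: float) -> DistortionSpec:
    """Scale all four coefficients by ``factor`` (distortion strength dial)."""
    return replace(
        spec,
        lambda1_left=spec.lambda1_left * factor,
        lambda2_left=spec.lambda2_left * factor,
        lambda1_right=spec.lambda1_right * factor,
        lambda2_right=spec.lambda2_right * factor,
    )


def _division_factor(rd2: np.ndarray, l1: float, l2: float) -> np.ndarray:
    return 1.0 + l1 * rd2 + l2 * rd2 * rd2


def _side_mask(x_rel: np.ndarray) -> np.ndarray:
    """True where a center-relative point belongs to the left half (x <= 0)."""
    return np.asarray(x_rel) <= 0.0


def undistort_points(points: np.ndarray, spec: DistortionSpec) -> np.ndarray:
    """Closed-form division model: distorted -> ideal, center-relative px."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rd2 = np.sum(pts**2, axis=1)
    fac = np.empty_like(rd2)
    left = _side_mask(pts[:, 0])
    for sl, side in ((left, "left"), (~left, "right")):
        l1, l2 = spec.coeffs(side)
        fac[sl] = _division_factor(rd2[sl], l1, l2)
    if np.any(fac <= 0):
        raise ValueError("distortion too strong: division factor non-positive")
    return pts / fac[:, None]


def _distort_radius(ru: np.ndarray, l1: float, l2: float, tol: float = 1e-10) -> np.ndarray:
    """Invert the radial division map: find rd with rd/(1+l1*rd^2+l2*rd^4) = ru.

    For pincushion coefficients (<= 0) the distorted radius lies in
    (0, ru] and the map is strictly increasing there, so a bisection is
    robust; ~90 halvings drive the bracket far below ``tol``.
    """
    ru = np.asarray(ru, dtype=float)
    lo = np.zeros_like(ru)
    hi = ru.copy()
    f_hi = hi / _division_factor(hi * hi, l1, l2) - ru
    if np.any(f_hi < -tol):
        raise ValueError("radial inversion bracket failed: distortion outside model range")
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        f = mid / _division_factor(mid * mid, l1, l2) - ru
        hi = np.where(f >= 0.0, mid, hi)
        lo = np.where(f < 0.0, mid, lo)
    rd = 0.5 * (lo + hi)
    resid = np.abs(rd / _division_factor(rd * rd, l1, l2) - ru)
    if np.any(resid > tol * np.maximum(1.0, ru)):
        raise ValueError("radial inversion did not converge to tolerance")
    return rd


def distort_points(points: np.ndarray, spec: DistortionSpec) -> np.ndarray:
    """Numeric inverse of the division model: ideal -> distorted, center-relative px.

    The center maps to itself; displacement magnitude grows with radius;
    the half-image membership of a point is decided by the sign of its
    x-coordinate (ties to the left half).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    ru = np.sqrt(np.sum(pts**2, axis=1))
    rd = np.empty_like(ru)
    left = _side_mask(pts[:, 0])
    for sl, side in ((left, "left"), (~left, "right")):
        l1, l2 = spec.coeffs(side)
        rd[sl] = _distort_radius(ru[sl], l1, l2)
    scale = np.ones_like(ru)
    nz = ru > 0
    scale[nz] = rd[nz] / ru[nz]
    return pts * scale[:, None]


@dataclass
class StereoPair:
    """A simulated stereo acquisition with full ground truth.

    ``reference`` is taken with the camera at lateral offset 0 and
    ``shift`` with the camera moved by the baseline; before distortion
    the shift image equals the reference translated by
    ``baseline * px_per_mm_at_object`` pixels.  The true ideal and
    distorted line x-positions (absolute px, on the central row) are
    stored for both images, as are the per-line depths.
    """

    reference: GrayImage
    shift: GrayImage
    ideal_lines_reference: np.ndarray
    ideal_lines_shift: np.ndarray
    distorted_lines_reference: np.ndarray
    distorted_lines_shift: np.ndarray
    line_depths_mm: np.ndarray
    config: StereoConfig
    spec: DistortionSpec
    line_indices_reference: np.ndarray = field(default=None)  # type: ignore[assignment]
    line_indices_shift: np.ndarray = field(default=None)  # type: ignore[assignment]


def _visible(centers_px: np.ndarray, width_px: int, margin_px: float) -> np.ndarray:
    return (centers_px >= margin_px) & (centers_px <= width_px - 1 - margin_px)


def project_pattern(
    pattern: LinePattern | ScalarBar,
    config: StereoConfig,
    lateral_offset_mm: float = 0.0,
    margin_px: float = 8.0,
) -> tuple[GrayImage, np.ndarray, np.ndarray, np.ndarray]:
    """Pinhole projection of a (possibly depth-stepped) line target.

    The camera sits at lateral object-plane offset ``lateral_offset_mm``
    looking straight down; a line at object x-position ``p`` and depth
    ``dz`` toward the camera projects to absolute pixel

        x = width/2 + (p - offset) * f_px / (z - dz).

    Returns the ideal rendered image, the visible projected line centers
    (absolute px, increasing), their depths, and their indices into the
    pattern's line list.

    Raises
    ------
    ValueError
        if the pattern sheet is narrower than the field of view.
    """
    bar = pattern if isinstance(pattern, ScalarBar) else None
    pat = bar.pattern if bar is not None else pattern
    depths = bar.line_depths_mm if bar is not None else np.zeros(pat.n_lines)
    if bar is None and pat.extent_mm < config.fov_mm:
        raise ValueError(
            f"pattern ({pat.extent_mm:.1f} mm) narrower than the field of view "
            f"({config.fov_mm:.1f} mm)"
        )
    z_eff = config.working_distance_mm - depths
    if np.any(z_eff <= 0):
        raise ValueError("line depth exceeds the working distance")
    centers = (
        config.width_px / 2.0
        + (pat.line_positions_mm - lateral_offset_mm) * config.focal_px / z_eff
    )
    vis = _visible(centers, config.width_px, margin_px)
    centers, depths = centers[vis], depths[vis]
    indices = np.where(vis)[0]
    row = line_profile(np.arange(config.width_px, dtype=float), centers, pat.line_sigma_px)
    image = GrayImage(np.tile(row, (config.height_px, 1)), config.px_per_mm_at_object)
    return image, centers, depths, indices


def _render_distorted(
    ideal_centers_px: np.ndarray,
    config: StereoConfig,
    spec: DistortionSpec,
    line_sigma_px: float,
) -> GrayImage:
    """Render the distorted view by evaluating the analytic ideal profile
    at the closed-form undistorted coordinate of every pixel (exact
    forward rendering, no resampling blur)."""
    xc, yc = spec.center
    xs = np.arange(config.width_px, dtype=float) - xc
    ys = np.arange(config.height_px, dtype=float) - yc
    xx, yy = np.meshgrid(xs, ys)
    rd2 = xx * xx + yy * yy
    fac = np.empty_like(rd2)
    left = xx <= 0.0
    for sl, side in ((left, "left"), (~left, "right")):
        l1, l2 = spec.coeffs(side)
        fac[sl] = _division_factor(rd2[sl], l1, l2)
    xu = xx / fac + xc
    pixels = line_profile(xu.ravel(), ideal_centers_px, line_sigma_px).reshape(xu.shape)
    return GrayImage(pixels, config.px_per_mm_at_object)


def _distort_centers(centers_px: np.ndarray, spec: DistortionSpec) -> np.ndarray:
    """True distorted x-positions of vertical lines on the central row (y = yc)."""
    xc, _ = spec.center
    rel = np.column_stack([centers_px - xc, np.zeros_like(centers_px)])
    return distort_points(rel, spec)[:, 0] + xc


def render_distorted_stereo(
    pattern: LinePattern | ScalarBar,
    config: StereoConfig,
    spec: DistortionSpec,
    pattern_offset_mm: float = 0.0,
    noise_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    margin_px: float = 8.0,
) -> StereoPair:
    """Render a full stereo pair under ground-truth distortion.

    The reference camera sits at lateral offset ``pattern_offset_mm``
    (i.e. the pattern center is displaced by minus that amount from the
    optical axis) and the shift camera a further baseline to the right.
    Optional additive Gaussian intensity noise (off by default) uses the
    supplied generator.
    """
    if tuple(spec.center) != config.center:
        raise ValueError(
            f"distortion center {spec.center} does not match image center {config.center}"
        )
    pat = pattern.pattern if isinstance(pattern, ScalarBar) else pattern
    images, ideal, distorted, idx = [], [], [], []
    depths = None
    for cam_offset in (pattern_offset_mm, pattern_offset_mm + config.baseline_mm):
        img_ideal, centers, dep, ind = project_pattern(pattern, config, cam_offset, margin_px)
        img = _render_distorted(centers, config, spec, pat.line_sigma_px)
        if noise_sigma > 0:
            gen = rng if rng is not None else np.random.default_rng(0)
            img = GrayImage(
                np.clip(img.pixels + gen.normal(0.0, noise_sigma, img.pixels.shape), 0, 1),
                img.px_per_mm,
            )
        images.append(img)
        ideal.append(centers)
        distorted.append(_distort_centers(centers, spec))
        idx.append(ind)
        depths = dep if depths is None else depths
    return StereoPair(
        reference=images[0],
        shift=images[1],
        ideal_lines_reference=ideal[0],
        ideal_lines_shift=ideal[1],
        distorted_lines_reference=distorted[0],
        distorted_lines_shift=distorted[1],
        line_depths_mm=depths,
        config=config,
        spec=spec,
        line_indices_reference=idx[0],
        line_indices_shift=idx[1],
    )


def angle_of_view(config: StereoConfig) -> float:
    """Horizontal angle of view in degrees: 2*atan(object half-width / z)."""
    half_width_mm = config.fov_mm / 2.0
    return float(np.degrees(2.0 * np.arctan(half_width_mm / config.working_distance_mm)))


def pattern_for_config(
    config: StereoConfig,
    spacing_mm: float = 1.0,
    pattern_offset_mm: float = 0.0,
    px_per_mm: float = 20.0,
    line_sigma_px: float = DEFAULT_LINE_SIGMA_PX,
) -> LinePattern:
    """A line pattern wide enough to fill both views of ``config``."""
    width_mm = config.fov_mm + config.baseline_mm + 2 * abs(pattern_offset_mm) + 6 * spacing_mm
    width_px = int(np.ceil(width_mm * px_per_mm))
    return make_vertical_line_pattern(
        width_px, 64, spacing_mm=spacing_mm, px_per_mm=px_per_mm, line_sigma_px=line_sigma_px
    )
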