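"""Ideal calibration targets: vertical line patterns and the depth scalar bar.

Close-up stereo rigs are calibrated here against a printed grid of dark
vertical lines on a light background, spaced at regular millimetre
intervals in the object plane.  Because the correction has to resolve
sub-0.1 mm displacements, lines are rendered with a Gaussian
cross-section of a few pixels so that subpixel centroid detection on the
rendered image is meaningful; a binary one-pixel column would quantise
every measurement to the pixel grid.

The scalar bar is the same line grid with a per-line depth offset: each
successive line is raised toward the camera by a fixed step, producing a
disparity staircase in a stereo pair that validates depth recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "LinePattern",
    "ScalarBar",
    "make_vertical_line_pattern",
    "make_scalar_bar",
    "line_profile",
    "save_pattern",
    "load_pattern",
]

#: default Gaussian cross-section scale of a rendered line, in pixels
DEFAULT_LINE_SIGMA_PX = 1.2


@dataclass
class GrayImage:
    """A 2-D grayscale raster with object-plane sampling metadata.

    Parameters
    ----------
    pixels
        2-D float array of intensities in [0, 1]; row index is y
        (downward), column index is x (rightward), 0-based.
    px_per_mm
        Object-plane sampling density: how many pixel widths one
        millimetre in the imaged plane occupies.
    """

    pixels: np.ndarray
    px_per_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not (self.pixels.size and np.all(np.isfinite(self.pixels))):
            raise ValueError("pixels must be a non-empty finite array")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        if not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be positive")

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def center(self) -> tuple[float, float]:
        """Image center (xc, yc) = (width/2, height/2), the assumed principal point."""
        return self.width_px / 2.0, self.height_px / 2.0


@dataclass
class LinePattern:
    """A rendered vertical-line target plus the true line geometry.

    ``line_positions_mm`` are object-plane x-coordinates of the line
    centers relative to the pattern center, strictly increasing and
    equally spaced by ``spacing_mm``.
    """

    image: GrayImage
    line_positions_mm: np.ndarray
    spacing_mm: float
    line_sigma_px: float = DEFAULT_LINE_SIGMA_PX

    def __post_init__(self) -> None:
        self.line_positions_mm = np.asarray(self.line_positions_mm, dtype=float)
        d = np.diff(self.line_positions_mm)
        if self.line_positions_mm.size < 2 or np.any(d <= 0):
            raise ValueError("need >= 2 strictly increasing line positions")
        if np.any(np.abs(d - self.spacing_mm) > 1e-9):
            raise ValueError("line positions are not uniformly spaced by spacing_mm")

    @property
    def n_lines(self) -> int:
        return int(self.line_positions_mm.size)

    @property
    def extent_mm(self) -> float:
        """Physical width of the printed pattern sheet."""
        return self.image.width_px / self.image.px_per_mm

    def positions_px(self) -> np.ndarray:
        """Line centers in absolute pixel x on the pattern's own raster."""
        return self.image.width_px / 2.0 + self.line_positions_mm * self.image.px_per_mm


@dataclass
class ScalarBar:
    """A line pattern whose lines step toward the camera in depth.

    Line ``i`` (1-based) is raised by ``i * depth_step_mm`` above the
    reference plane, so the bar spans ``n_lines * depth_step_mm`` of
    depth in total: 20 lines at a 50 um step give the standard 1 mm bar.
    """

    pattern: LinePattern
    line_depths_mm: np.ndarray = field(init=False)
    depth_step_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.depth_step_mm < 0:
            raise ValueError("depth step must be non-negative")
        n = self.pattern.n_lines
        self.line_depths_mm = (np.arange(1, n + 1)) * float(self.depth_step_mm)
        span = self.n_lines * self.depth_step_mm
        if abs(self.line_depths_mm[-1] - span) > 1e-9:
            raise AssertionError("depth span does not equal n_lines * depth_step_mm")

    @property
    def n_lines(self) -> int:
        return self.pattern.n_lines

    @property
    def total_span_mm(self) -> float:
        """Depth of the last line above the reference plane."""
        return float(self.n_lines * self.depth_step_mm)


def line_profile(
    x_px: np.ndarray,
    centers_px: np.ndarray,
    line_sigma_px: float = DEFAULT_LINE_SIGMA_PX,
) -> np.ndarray:
    """Analytic intensity of the line target sampled at arbitrary x.

    Background is 1, each line subtracts a unit-depth Gaussian of scale
    ``line_sigma_px``.  Only the two nearest lines can contribute at any
    x when lines are separated by >= 4 sigma (the generator's
    precondition), so the sum is truncated accordingly; this keeps the
    profile exact to double precision while staying O(1) per sample.
    """
    x = np.atleast_1d(np.asarray(x_px, dtype=float))
    c = np.asarray(centers_px, dtype=float)
    out = np.ones_like(x)
    if c.size == 0:
        return out
    idx = np.searchsorted(c, x)
    for off in (-1, 0):
        j = idx + off
        ok = (j >= 0) & (j < c.size)
        out[ok] -= np.exp(-0.5 * ((x[ok] - c[j[ok]]) / line_sigma_px) ** 2)
    return np.clip(out, 0.0, 1.0)


def _symmetric_positions(width_mm: float, spacing_mm: float) -> np.ndarray:
    # largest odd line count that keeps every line strictly inside the sheet
    # with at least half a spacing of margin; symmetric about the center
    n = int(np.floor(width_mm / spacing_mm - 1.0))
    if n % 2 == 0:
        n -= 1
    if n < 2:
        raise ValueError(
            f"sheet of {width_mm} mm holds fewer than 2 lines at {spacing_mm} mm spacing"
        )
    return (np.arange(n) - (n - 1) / 2.0) * spacing_mm


def make_vertical_line_pattern(
    width_px: int,
    height_px: int,
    spacing_mm: float = 1.0,
    px_per_mm: float = 20.0,
    line_sigma_px: float = DEFAULT_LINE_SIGMA_PX,
) -> LinePattern:
    """Render the ideal vertical-line calibration target.

    Dark lines at ``spacing_mm`` object-plane intervals, symmetric about
    the sheet center, anti-aliased with a Gaussian cross-section.

    Raises
    ------
    ValueError
        on non-positive dimensions/spacing, when fewer than two lines
        fit, or when lines would be too close to separate
        (``spacing_mm * px_per_mm < 4 * line_sigma_px``).
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError("image dimensions must be positive")
    if spacing_mm <= 0 or px_per_mm <= 0 or line_sigma_px <= 0:
        raise ValueError("spacing_mm, px_per_mm and line_sigma_px must be positive")
    if spacing_mm * px_per_mm < 4.0 * line_sigma_px:
        raise ValueError("lines are not separable: spacing*px_per_mm < 4*line_sigma_px")
    positions_mm = _symmetric_positions(width_px / px_per_mm, spacing_mm)
    centers_px = width_px / 2.0 + positions_mm * px_per_mm
    row = line_profile(np.arange(width_px, dtype=float), centers_px, line_sigma_px)
    pixels = np.tile(row, (height_px, 1))
    image = GrayImage(pixels, px_per_mm)
    return LinePattern(image, positions_mm, spacing_mm, line_sigma_px)


def make_scalar_bar(
    n_lines: int = 20,
    spacing_mm: float = 1.0,
    depth_step_mm: float = 0.05,
    width_px: int = 800,
    height_px: int = 600,
    px_per_mm: float = 20.0,
    line_sigma_px: float = DEFAULT_LINE_SIGMA_PX,
) -> ScalarBar:
    """Build the standard scalar bar: ``n_lines`` lines stepping in depth.

    The rendered raster shows the bar face-on (depth does not alter the
    printed geometry); the depth offsets take effect when the bar is
    projected by a stereo camera.
    """
    if n_lines < 2:
        raise ValueError("a scalar bar needs at least 2 lines")
    if depth_step_mm < 0:
        raise ValueError("depth step must be non-negative")
    width_needed = (n_lines + 1) * spacing_mm * px_per_mm
    if width_px < width_needed:
        raise ValueError(f"width_px={width_px} cannot hold {n_lines} lines; need >= {width_needed:.0f}")
    positions_mm = (np.arange(n_lines) - (n_lines - 1) / 2.0) * spacing_mm
    centers_px = width_px / 2.0 + positions_mm * px_per_mm
    row = line_profile(np.arange(width_px, dtype=float), centers_px, line_sigma_px)
    image = GrayImage(np.tile(row, (height_px, 1)), px_per_mm)
    pattern = LinePattern(image, positions_mm, spacing_mm, line_sigma_px)
    return ScalarBar(pattern, depth_step_mm=depth_step_mm)


# ---------------------------------------------------------------------------
# disk I/O: 16-bit PNG plus a JSON sidecar carrying the true geometry
# ---------------------------------------------------------------------------

def save_gray_image(image: GrayImage, path: str | Path) -> None:
    path = Path(path)
    data = np.round(image.pixels * 65535.0).astype(np.uint16)
    iio.imwrite(path, data)


def load_gray_image(path: str | Path, px_per_mm: float) -> GrayImage:
    raw = np.asarray(iio.imread(Path(path)), dtype=float)
    if raw.ndim == 3:  # luma conversion for any color input (ITU-R BT.601 weights)
        raw = raw[..., 0] * 0.299 + raw[..., 1] * 0.587 + raw[..., 2] * 0.114
    scale = 65535.0 if raw.max() > 255 else (255.0 if raw.max() > 1 else 1.0)
    return GrayImage(raw / scale, px_per_mm)


def save_pattern(pattern: LinePattern | ScalarBar, path: str | Path) -> None:
    """Write the raster as 16-bit PNG and the geometry as a JSON sidecar."""
    path = Path(path)
    bar = pattern if isinstance(pattern, ScalarBar) else None
    pat = bar.pattern if bar is not None else pattern
    save_gray_image(pat.image, path)
    meta = {
        "px_per_mm": pat.image.px_per_mm,
        "spacing_mm": pat.spacing_mm,
        "line_sigma_px": pat.line_sigma_px,
        "line_positions_mm": pat.line_positions_mm.tolist(),
    }
    if bar is not None:
        meta["depth_step_mm"] = bar.depth_step_mm
        meta["line_depths_mm"] = bar.line_depths_mm.tolist()
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_pattern(path: str | Path) -> LinePattern | ScalarBar:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    image = load_gray_image(path, meta["px_per_mm"])
    pattern = LinePattern(
        image,
        np.asarray(meta["line_positions_mm"]),
        meta["spacing_mm"],
        meta.get("line_sigma_px", DEFAULT_LINE_SIGMA_PX),
    )
    if "depth_step_mm" in meta:
        return ScalarBar(pattern, depth_step_mm=meta["depth_step_mm"])
    return pattern
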