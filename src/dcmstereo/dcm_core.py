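"""The Distortion Correction Matrix: per-pixel pincushion correction.

Given point correspondences between an ideal calibration target and its
distorted photograph, each pair yields a *distortion ratio*

    R = ru / rd,

the quotient of the ideal and distorted radial distances from the image
center (assumed to be the principal point, at (width/2, height/2)).
For positive-displacement pincushion distortion the observed points are
pulled inward, so R >= 1, R(0) = 1, and R grows with radius.  A reduced
single-coefficient division model absorbs the ratio into a distortion
coefficient

    k = (1 - R) / rd**2        (k <= 0 for pincushion),

and the per-pixel correction coefficient solves the quadratic
``k*ru**2 * lam**2 + lam - 1 = 0``:

    lam = (-1 + sqrt(1 + 4*k*ru**2)) / (2*k*ru**2),    lam -> 1 as k*ru**2 -> 0.

The corrected position of a distorted pixel is the radial relocation

    (xn, yn) = lam * (xd - xc, yd - yc) + (xc, yc)  ~  (xu, yu).

Correspondences are only measured at calibration points, so R is
interpolated over radius by an even polynomial (R - 1 has no constant
term), fitted separately for the left and right image halves because
real lenses distort the two halves unequally.  At correction time the
ideal radius is unknown and is taken as ru = R(rd)*rd from the fitted
field; the product k*ru**2 then collapses to (1 - R)*R**2, which is
evaluated directly to avoid cancellation.

``lam`` equals the exact ratio R only to second order: the relocation
overshoots by about ``4*(R-1)**2 * rd`` pixels.  For fine distortion
(R - 1 of a few 1e-3) this is far below a tenth of a pixel; at stronger
magnitudes it is the method's intrinsic residual (see docs/methods.md).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Correspondences",
    "RatioField",
    "DCM",
    "distortion_ratio",
    "fit_ratio_field",
    "coefficient_k",
    "lambda_coefficient",
    "build_dcm",
    "map_point",
    "DistortionCorrector",
    "correspondences_from_lines",
]

#: below this |k*ru^2| the quadratic degenerates and lam takes its limit value 1
_QUAD_EPS = 1e-12


@dataclass
class Correspondences:
    """Paired ideal/distorted calibration points, center-relative px.

    ``center`` is the absolute principal point (width/2, height/2).
    Pairs with zero distorted radius carry no ratio information and are
    rejected at construction.
    """

    xu: np.ndarray
    yu: np.ndarray
    xd: np.ndarray
    yd: np.ndarray
    center: tuple[float, float]

    def __post_init__(self) -> None:
        self.xu, self.yu, self.xd, self.yd = (
            np.asarray(a, dtype=float).ravel() for a in (self.xu, self.yu, self.xd, self.yd)
        )
        n = {a.size for a in (self.xu, self.yu, self.xd, self.yd)}
        if len(n) != 1 or self.xu.size == 0:
            raise ValueError("coordinate arrays must be non-empty and equally sized")
        if np.any(self.rd == 0):
            raise ValueError("pairs at the exact center (rd = 0) carry no ratio information")

    @property
    def rd(self) -> np.ndarray:
        return np.hypot(self.xd, self.yd)

    @property
    def ru(self) -> np.ndarray:
        return np.hypot(self.xu, self.yu)

    @property
    def n_pairs(self) -> int:
        return int(self.xu.size)

    def left_mask(self) -> np.ndarray:
        """Left-half membership by the sign of the distorted x (ties left)."""
        return self.xd <= 0.0

    @classmethod
    def from_absolute(
        cls, ideal_xy: np.ndarray, distorted_xy: np.ndarray, center: tuple[float, float]
    ) -> "Correspondences":
        iu = np.atleast_2d(np.asarray(ideal_xy, float))
        dd = np.atleast_2d(np.asarray(distorted_xy, float))
        if iu.shape != dd.shape:
            raise ValueError("ideal and distorted point arrays must have the same shape")
        xc, yc = center
        return cls(iu[:, 0] - xc, iu[:, 1] - yc, dd[:, 0] - xc, dd[:, 1] - yc, center)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"xu": self.xu, "yu": self.yu, "xd": self.xd, "yd": self.yd}).to_csv(
            Path(path), index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, center: tuple[float, float]) -> "Correspondences":
        import pandas as pd

        df = pd.read_csv(Path(path))
        return cls(df["xu"], df["yu"], df["xd"], df["yd"], center)


def correspondences_from_lines(
    ideal_x_abs: np.ndarray,
    distorted_x_abs: np.ndarray,
    y_abs: np.ndarray,
    center: tuple[float, float],
    min_abs_x_px: float = 5.0,
) -> Correspondences:
    """Build correspondences from matched vertical-line observations.

    A vertical ideal line fixes only the ideal x-coordinate ``Xu``; the
    point on it corresponding to a distorted observation (xd, yd) is
    recovered from the radial model (ideal and distorted points are
    collinear with the center):

        yu = Xu * yd / xd,        so        R = ru/rd = Xu / xd.

    Observations too close to the vertical midline (``|xd| <
    min_abs_x_px``) make the reconstruction ill-conditioned and are
    dropped.

    Parameters
    ----------
    ideal_x_abs, distorted_x_abs, y_abs
        Flat arrays of equal length: for each observation, the ideal
        line's absolute x, the measured distorted absolute x, and the
        absolute y (row) at which it was measured.
    """
    xc, yc = center
    Xu = np.asarray(ideal_x_abs, float).ravel() - xc
    xd = np.asarray(distorted_x_abs, float).ravel() - xc
    yd = np.asarray(y_abs, float).ravel() - yc
    if not (Xu.size == xd.size == yd.size):
        raise ValueError("mismatched observation arrays")
    keep = np.abs(xd) >= min_abs_x_px
    if not np.any(keep):
        raise ValueError("no usable observations away from the vertical midline")
    Xu, xd, yd = Xu[keep], xd[keep], yd[keep]
    yu = Xu * yd / xd
    return Correspondences(Xu, yu, xd, yd, center)


def distortion_ratio(corr: Correspondences) -> np.ndarray:
    """Per-pair distortion ratio R = ru / rd (>= 1 for pincushion input)."""
    rd = corr.rd
    if np.any(rd == 0):
        raise ValueError("rd = 0 pair encountered")
    return corr.ru / rd


@dataclass
class RatioField:
    """Smooth per-half model of the distortion ratio R(rd).

    R - 1 is an even polynomial in the distorted radius with no constant
    term (R(0) = 1 by construction); separate coefficient vectors for
    the left and right halves.  Evaluation clamps the radius to the
    fitted range, warning when asked to extrapolate.
    """

    powers: np.ndarray
    coef_left: np.ndarray
    coef_right: np.ndarray
    rd_max_left: float
    rd_max_right: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.powers = np.asarray(self.powers, dtype=int)
        self.coef_left = np.asarray(self.coef_left, dtype=float)
        self.coef_right = np.asarray(self.coef_right, dtype=float)
        for side in ("left", "right"):
            rr = np.linspace(0, getattr(self, f"rd_max_{side}"), 256)
            if np.any(self._eval_side(rr, side) <= 0):
                raise ValueError(f"fitted ratio field non-positive on the {side} half")

    def _eval_side(self, rd: np.ndarray, side: str) -> np.ndarray:
        coef = self.coef_left if side == "left" else self.coef_right
        rd_max = self.rd_max_left if side == "left" else self.rd_max_right
        rd = np.asarray(rd, dtype=float)
        if np.any(rd > rd_max * (1 + 1e-9)):
            warnings.warn(
                f"evaluating ratio field beyond the fitted radius range "
                f"({side}: max {rd_max:.1f} px); clamping",
                stacklevel=3,
            )
        rr = np.minimum(rd, rd_max)
        return 1.0 + (rr[:, None] ** self.powers[None, :]) @ coef

    def __call__(self, rd: np.ndarray, left: np.ndarray) -> np.ndarray:
        """Evaluate R at distorted radii ``rd`` with left-half mask ``left``."""
        rd = np.asarray(rd, dtype=float)
        left = np.broadcast_to(np.asarray(left, bool), rd.shape)
        out = np.empty_like(rd, dtype=float)
        out[left] = self._eval_side(rd[left], "left")
        out[~left] = self._eval_side(rd[~left], "right")
        return out

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.coef_left == 0) and np.all(self.coef_right == 0))


def fit_ratio_field(corr: Correspondences, degree: int = 2) -> RatioField:
    """Least-squares fit of R - 1 as an even polynomial in rd, per half.

    Requires at least ``degree + 1`` pairs on each half so the per-half
    fit is comfortably overdetermined.
    """
    if degree < 2 or degree % 2:
        raise ValueError("degree must be an even integer >= 2")
    powers = np.arange(2, degree + 1, 2)
    R = distortion_ratio(corr)
    rd = corr.rd
    left = corr.left_mask()
    coefs, rd_maxes, resid = {}, {}, []
    for side, sl in (("left", left), ("right", ~left)):
        if sl.sum() < degree + 1:
            raise ValueError(
                f"underdetermined fit: {int(sl.sum())} pairs on the {side} half, "
                f"need >= {degree + 1}"
            )
        A = rd[sl, None] ** powers[None, :]
        c, *_ = np.linalg.lstsq(A, R[sl] - 1.0, rcond=None)
        coefs[side] = c
        rd_maxes[side] = float(rd[sl].max())
        resid.append(A @ c - (R[sl] - 1.0))
    rms = float(np.sqrt(np.mean(np.concatenate(resid) ** 2)))
    return RatioField(
        powers, coefs["left"], coefs["right"], rd_maxes["left"], rd_maxes["right"], rms
    )


def coefficient_k(R: np.ndarray, rd: np.ndarray) -> np.ndarray:
    """Distortion coefficient k = (1 - R) / rd**2 (negative for pincushion)."""
    R = np.asarray(R, dtype=float)
    rd = np.asarray(rd, dtype=float)
    if np.any(rd <= 0):
        raise ValueError("rd must be positive")
    return (1.0 - R) / rd**2


def _lambda_from_product(q: np.ndarray) -> np.ndarray:
    """Solve q*lam^2 + lam - 1 = 0 for the root continuous at q = 0."""
    q = np.asarray(q, dtype=float)
    shape = q.shape
    q = np.atleast_1d(q)
    disc = 1.0 + 4.0 * q
    if np.any(disc < 0):
        raise ValueError("1 + 4*k*ru^2 < 0: distortion too strong for the model")
    lam = np.ones_like(q)
    nz = np.abs(q) > _QUAD_EPS
    lam[nz] = (-1.0 + np.sqrt(disc[nz])) / (2.0 * q[nz])
    return lam.reshape(shape)


def lambda_coefficient(k: np.ndarray, ru: np.ndarray) -> np.ndarray:
    """Correction coefficient lam = (-1 + sqrt(1 + 4*k*ru^2)) / (2*k*ru^2).

    Returns the limit value 1 where ``k*ru**2`` vanishes; raises when
    ``1 + 4*k*ru**2 < 0`` (distortion too strong for the reduced model).
    """
    k = np.asarray(k, dtype=float)
    ru = np.asarray(ru, dtype=float)
    out = _lambda_from_product(k * ru**2)
    return float(out) if out.ndim == 0 else out


@dataclass
class DCM:
    """The Distortion Correction Matrix: per-pixel R, k and lam arrays.

    ``lam`` multiplies the center-relative coordinates of each pixel to
    relocate it to its corrected position.  lam = 1 wherever R = 1 (in
    particular at the center), and the left and right halves may differ.
    The fitted ratio field is retained so subpixel points can be mapped
    without re-gridding.
    """

    R: np.ndarray
    k: np.ndarray
    lam: np.ndarray
    center: tuple[float, float]
    field: RatioField

    @property
    def height_px(self) -> int:
        return self.R.shape[0]

    @property
    def width_px(self) -> int:
        return self.R.shape[1]

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.lam == 1.0))

    def save(self, path: str | Path) -> None:
        """Serialize as a compressed array container plus a JSON header."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), R=self.R, k=self.k, lam=self.lam)
        header = {
            "center": list(self.center),
            "width_px": self.width_px,
            "height_px": self.height_px,
            "field": {
                "powers": self.field.powers.tolist(),
                "coef_left": self.field.coef_left.tolist(),
                "coef_right": self.field.coef_right.tolist(),
                "rd_max_left": self.field.rd_max_left,
                "rd_max_right": self.field.rd_max_right,
                "rms_residual": self.field.rms_residual,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DCM":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        f = header["field"]
        field = RatioField(
            np.asarray(f["powers"]),
            np.asarray(f["coef_left"]),
            np.asarray(f["coef_right"]),
            f["rd_max_left"],
            f["rd_max_right"],
            f.get("rms_residual", 0.0),
        )
        return cls(arrays["R"], arrays["k"], arrays["lam"], tuple(header["center"]), field)


def build_dcm(field: RatioField, width_px: int, height_px: int) -> DCM:
    """Evaluate the correction coefficient at every pixel of the grid.

    For each pixel: rd is its distance to the center, R comes from the
    fitted field of its half, ru = R*rd, k = (1-R)/rd^2, and lam solves
    the defining quadratic via the cancellation-free product
    k*ru^2 = (1-R)*R^2.  The center pixel (rd = 0) takes the limit
    values R = 1, k = 0, lam = 1.
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError("image dimensions must be positive")
    xc, yc = width_px / 2.0, height_px / 2.0
    xs = np.arange(width_px, dtype=float) - xc
    ys = np.arange(height_px, dtype=float) - yc
    xx, yy = np.meshgrid(xs, ys)
    rd = np.hypot(xx, yy)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # corner radii may clamp; expected on full grids
        R = field(rd, left=xx <= 0.0)
    q = (1.0 - R) * R * R
    try:
        lam = _lambda_from_product(q)
    except ValueError as exc:
        bad = np.unravel_index(int(np.argmin(1.0 + 4.0 * q)), q.shape)
        raise ValueError(f"lambda undefined at pixel (row={bad[0]}, col={bad[1]}): {exc}") from exc
    k = np.zeros_like(rd)
    off = rd > 0
    k[off] = (1.0 - R[off]) / rd[off] ** 2
    R = np.where(off, R, 1.0)
    lam = np.where(off, lam, 1.0)
    return DCM(R=R, k=k, lam=lam, center=(xc, yc), field=field)


def map_point(dcm: DCM, point: np.ndarray) -> np.ndarray:
    """Relocate distorted point(s) (absolute px) to corrected positions.

    lam is evaluated from the fitted ratio field at the exact (subpixel)
    radius of each point, then (xn, yn) = lam*(x - xc, y - yc) + (xc, yc).
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    xc, yc = dcm.center
    rel = pts - [xc, yc]
    if np.any(pts[:, 0] < -0.5) or np.any(pts[:, 0] > dcm.width_px - 0.5) or np.any(
        pts[:, 1] < -0.5
    ) or np.any(pts[:, 1] > dcm.height_px - 0.5):
        raise ValueError("point outside the image")
    rd = np.hypot(rel[:, 0], rel[:, 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R = dcm.field(rd, left=rel[:, 0] <= 0.0)
    lam = _lambda_from_product((1.0 - R) * R * R)
    out = rel * lam[:, None] + [xc, yc]
    return out[0] if np.asarray(point).ndim == 1 else out


class DistortionCorrector(BaseEstimator, TransformerMixin):
    """Scikit-learn style estimator for per-pixel pincushion correction.

    ``fit`` takes distorted calibration points ``X`` (n, 2 absolute px)
    and their ideal positions ``y`` (n, 2), fits the per-half ratio
    field, and builds the per-pixel correction matrix.  ``transform``
    relocates distorted points to their corrected positions.

    Parameters
    ----------
    image_width, image_height
        Pixel dimensions of the images the corrector applies to; the
        principal point is fixed at (width/2, height/2).
    degree
        Even degree of the radial polynomial for R - 1 (2 = single
        quadratic coefficient per half).

    Attributes
    ----------
    correspondences_ : Correspondences
    field_ : RatioField
    dcm_ : DCM
    center_ : tuple of float
    """

    def __init__(self, image_width: int = 800, image_height: int = 600, degree: int = 2):
        self.image_width = image_width
        self.image_height = image_height
        self.degree = degree

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DistortionCorrector":
        self.center_ = (self.image_width / 2.0, self.image_height / 2.0)
        self.correspondences_ = Correspondences.from_absolute(y, X, self.center_)
        self.field_ = fit_ratio_field(self.correspondences_, degree=self.degree)
        self.dcm_ = build_dcm(self.field_, self.image_width, self.image_height)
        return self

    def fit_lines(
        self,
        ideal_x_abs: np.ndarray,
        distorted_x_abs: np.ndarray,
        y_abs: np.ndarray,
        min_abs_x_px: float = 5.0,
    ) -> "DistortionCorrector":
        """Fit from matched vertical-line observations (see
        :func:`correspondences_from_lines` for the radial reconstruction
        of the ideal y-coordinate)."""
        self.center_ = (self.image_width / 2.0, self.image_height / 2.0)
        self.correspondences_ = correspondences_from_lines(
            ideal_x_abs, distorted_x_abs, y_abs, self.center_, min_abs_x_px
        )
        self.field_ = fit_ratio_field(self.correspondences_, degree=self.degree)
        self.dcm_ = build_dcm(self.field_, self.image_width, self.image_height)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return map_point(self.dcm_, np.atleast_2d(np.asarray(X, float)))

    def correct_image(self, image):
        """Forward-map a full image through the matrix; see dcmstereo.warp."""
        self._check_fitted()
        from .warp import correct_image

        return correct_image(image, self.dcm_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "dcm_"):
            raise RuntimeError("DistortionCorrector is not fitted")
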