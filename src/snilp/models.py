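"""Vignetting estimators.

Five models of the vignetting surface of a lens-camera system, fitted to a
reference flat-field image ``I_V`` (a picture of a uniformly lit uniform
surface, so its only spatial structure is vignetting plus noise):

``LocalPolynomial`` (LP)
    Pixelwise mean of two independent families of 1D least-squares
    polynomial fits: one degree-``s`` polynomial per image row and one per
    image column.  (With ``degree=2`` this is the classical *Local
    Parabolic* model.)
``SmoothLocalPolynomial`` (SLP)
    The LP operator composed with itself ``n_iter`` times; iterating
    smooths out the ragged surface a single LP pass leaves behind.
``SNILP`` (Smooth Non-Iterative Local Polynomial)
    Sequential line fits: fit every line along one axis, then fit every
    line of *that result* along the other axis.  Because both passes are
    linear projections, the axis order is irrelevant up to float rounding,
    the operator is idempotent, and it is the ``k -> inf`` limit of SLP —
    at the cost of a single LP-like pass.
``Polynomial2D`` (P2D)
    One global bivariate polynomial of total degree ``s`` fitted to the
    whole image by ordinary least squares.
``RadialPolynomial`` (RP)
    A 1D polynomial in the distance ``r`` to the optical center, fitted
    over all pixels; the center is located as the stationary point of a
    degree-2 bivariate fit unless supplied.

All estimators are scikit-learn compatible transformers: ``fit(X)`` takes
the flat-field image (a 2D array or :class:`~snilp.raster.FlatImage`) and
stores the normalized estimate in ``vignetting_``; ``transform(X)``
divides an image by the estimate (flat-field correction).

Every polynomial fit uses line/pixel coordinates affinely mapped to
``[-1, 1]`` to keep design matrices well conditioned up to degree ~10 on
lines of thousands of pixels; exported parameters record this convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import NamedTuple

import numpy as np
from numpy.polynomial import polynomial as npoly
from sklearn.base import BaseEstimator, TransformerMixin

from .raster import FlatImage

__all__ = [
    "ModelKind",
    "AxisOrder",
    "VignettingEstimate",
    "ModelParams",
    "OpticalCenter",
    "BaseVignettingModel",
    "LocalPolynomial",
    "SmoothLocalPolynomial",
    "SNILP",
    "Polynomial2D",
    "RadialPolynomial",
    "MODEL_REGISTRY",
    "fit_lines_1d",
    "fit_lp",
    "fit_slp",
    "fit_snilp",
    "fit_p2d",
    "fit_rp",
    "find_optical_center",
    "export_params",
    "evaluate_params",
    "parameter_count",
]

COORDS_CONVENTION = "line and pixel coordinates affinely mapped to [-1, 1] per axis"


class ModelKind(str, Enum):
    LOCAL_PARABOLIC = "local_parabolic"
    LP = "lp"
    SLP = "slp"
    SNILP = "snilp"
    P2D = "p2d"
    RP = "rp"


class AxisOrder(str, Enum):
    """Axis sequence for the two sequential SNILP passes."""

    X_THEN_Y = "x_then_y"  # fit rows (along columns) first, then columns
    Y_THEN_X = "y_then_x"


# ---------------------------------------------------------------------------
# basic containers
# ---------------------------------------------------------------------------


@dataclass
class VignettingEstimate:
    """A fitted vignetting surface plus its provenance.

    ``values`` has the source image's shape; when ``normalized`` the global
    maximum is exactly 1 and values are expected in ``(0, 1]``.  ``flags``
    collects estimator warnings (e.g. non-positive pixels after
    normalization, a degenerate optical-center fit).
    """

    values: np.ndarray
    model: ModelKind
    degree: int
    iterations: int = 1
    normalized: bool = True
    norm_constant: float = 1.0
    coefficients: dict | None = None
    center: tuple[float, float] | None = None
    flags: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class OpticalCenter(NamedTuple):
    """Subpixel optical-center location in (row, col) order."""

    row: float
    col: float
    flagged: bool = False
    method: str = "quadratic_argmax"


# ---------------------------------------------------------------------------
# low-level least-squares helpers
# ---------------------------------------------------------------------------


def _scaled_coords(n: int) -> np.ndarray:
    """Affine map of 0..n-1 onto [-1, 1] (a single point maps to 0)."""
    if n == 1:
        return np.zeros(1)
    return np.linspace(-1.0, 1.0, n)


def _as_array(img) -> np.ndarray:
    if isinstance(img, VignettingEstimate):
        arr = img.values
    elif isinstance(img, FlatImage):
        arr = img.pixels
    else:
        arr = np.asarray(img)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {arr.shape}")
    return arr


def fit_lines_1d(img, axis: str, degree: int, return_coeffs: bool = False):
    """Independently fit a degree-``s`` polynomial along every image line.

    ``axis='horizontal'`` fits each row against its column coordinate;
    ``axis='vertical'`` fits each column against its row coordinate.  Returns
    the fitted values on the full grid (same shape as the input), and
    optionally the per-line coefficient matrix ``(n_lines, degree+1)`` in the
    scaled-coordinate basis.
    """
    data = _as_array(img)
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    n = data.shape[1] if axis == "horizontal" else data.shape[0]
    if n <= degree:
        raise ValueError(
            f"line length {n} must exceed polynomial degree {degree} "
            f"for a determined fit along axis '{axis}'"
        )
    basis = npoly.polyvander(_scaled_coords(n), degree)  # (n, s+1)
    if axis == "horizontal":
        coef, *_ = np.linalg.lstsq(basis, data.T, rcond=None)  # (s+1, M)
        fitted = (basis @ coef).T
        coeffs = coef.T  # one row of coefficients per image row
    else:
        coef, *_ = np.linalg.lstsq(basis, data, rcond=None)  # (s+1, N)
        fitted = basis @ coef
        coeffs = coef.T  # one row of coefficients per image column
    if return_coeffs:
        return fitted, coeffs
    return fitted


def _p2d_exponents(degree: int) -> np.ndarray:
    """(T, 2) array of (p, q) with p + q <= degree; T = (s+1)(s+2)/2."""
    return np.array(
        [(p, q) for total in range(degree + 1) for p in range(total + 1) for q in (total - p,)]
    )


def _p2d_design(shape: tuple[int, int], degree: int) -> np.ndarray:
    m, n = shape
    y = _scaled_coords(m)  # rows
    x = _scaled_coords(n)  # cols
    xx, yy = np.meshgrid(x, y)
    exps = _p2d_exponents(degree)
    cols = [(xx.ravel() ** p) * (yy.ravel() ** q) for p, q in exps]
    return np.column_stack(cols)


def _fit_p2d_surface(data: np.ndarray, degree: int):
    m, n = data.shape
    nterms = (degree + 1) * (degree + 2) // 2
    if m * n <= nterms:
        raise ValueError(
            f"image with {m * n} pixels cannot determine the {nterms}-term "
            f"bivariate polynomial of degree {degree}"
        )
    design = _p2d_design(data.shape, degree)
    coef, _, rank, sv = np.linalg.lstsq(design, data.ravel(), rcond=None)
    if rank < nterms:
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        raise np.linalg.LinAlgError(
            f"rank-deficient bivariate design (rank {rank} < {nterms}, "
            f"condition estimate {cond:.3g})"
        )
    fitted = (design @ coef).reshape(m, n)
    return fitted, coef


def find_optical_center(img) -> OpticalCenter:
    """Locate the optical center as the maximum of a quadratic surface fit.

    Fits the 6-term degree-2 bivariate polynomial by OLS and returns its
    analytic stationary point when the quadratic form is negative definite
    (an interior maximum).  Degenerate flats (tilted planes, saddles) fall
    back to the argmax of a Gaussian-smoothed copy of the image (sigma=0.5,
    10x10 kernel) and come back ``flagged``.  Coordinates are subpixel
    ``(row, col)``, clamped to the image bounds.
    """
    data = _as_array(img)
    m, n = data.shape
    if m * n < 6:
        raise ValueError("need at least 6 pixels for a quadratic surface fit")
    _, coef = _fit_p2d_surface(data, 2)
    # term order from _p2d_exponents(2): 1, y, x, y^2, xy, x^2 as (p,q) pairs
    exps = [tuple(e) for e in _p2d_exponents(2)]
    c = dict(zip(exps, coef))
    cx, cy = c[(1, 0)], c[(0, 1)]
    cxx, cxy, cyy = c[(2, 0)], c[(1, 1)], c[(0, 2)]
    hess = np.array([[2 * cxx, cxy], [cxy, 2 * cyy]])
    eigvals = np.linalg.eigvalsh(hess)
    if np.all(eigvals < 0):
        sx, sy = np.linalg.solve(hess, [-cx, -cy])
        # map scaled coords back to pixel indices
        col = (sx + 1.0) * (n - 1) / 2.0
        row = (sy + 1.0) * (m - 1) / 2.0
        flagged = False
        method = "quadratic_argmax"
    else:
        from .correction import _gaussian_smooth_10x10

        smoothed = _gaussian_smooth_10x10(data)
        row, col = np.unravel_index(int(np.argmax(smoothed)), data.shape)
        flagged = True
        method = "smoothed_argmax_fallback"
    row = float(np.clip(row, 0, m - 1))
    col = float(np.clip(col, 0, n - 1))
    return OpticalCenter(row, col, flagged, method)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class BaseVignettingModel(BaseEstimator, TransformerMixin):
    """Common fit/normalize/correct machinery for all vignetting models.

    Subclasses implement ``_estimate(data)`` returning the raw (not yet
    normalized) surface and a coefficient payload (or ``None``).  ``fit``
    normalizes the surface to a global maximum of 1, the range every model's
    output is compared on.

    Parameters shared by all models
    -------------------------------
    degree : int
        Degree ``s`` of the approximation polynomials.
    keep_coefficients : bool
        Retain the fitted coefficients so :func:`export_params` can build a
        compact parameter file.  Off by default: the estimate matrix itself
        is the primary artifact.
    eps : float
        Guard for near-zero estimate pixels when building correction gains.
    clip_range : (lo, hi) or None
        Truncation range applied by ``transform``; ``None`` disables
        truncation.
    """

    model_kind: ModelKind  # set by subclasses

    def __init__(self, degree=2, keep_coefficients=False, eps=1e-3, clip_range=None):
        self.degree = degree
        self.keep_coefficients = keep_coefficients
        self.eps = eps
        self.clip_range = clip_range

    # subclass hook ------------------------------------------------------
    def _estimate(self, data: np.ndarray):  # pragma: no cover - abstract
        raise NotImplementedError

    def _iterations(self) -> int:
        return 1

    def fit(self, X, y=None):
        data = _as_array(X)
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        raw, coeffs = self._estimate(data)
        norm = float(np.max(raw))
        if norm <= 0:
            raise ValueError("estimate has a non-positive maximum; cannot normalize")
        values = raw / norm
        flags = []
        if np.any(values <= 0):
            flags.append("non_positive_values")
        if getattr(self, "_center_flagged", False):
            flags.append("optical_center_fallback")
        self.estimate_ = VignettingEstimate(
            values=values,
            model=self.model_kind,
            degree=self.degree,
            iterations=self._iterations(),
            normalized=True,
            norm_constant=norm,
            coefficients=coeffs if self.keep_coefficients else None,
            center=getattr(self, "center_", None),
            flags=flags,
        )
        self.vignetting_ = values
        self.norm_constant_ = norm
        self.n_features_in_ = data.shape[1]
        return self

    def transform(self, X):
        """Flat-field correct ``X``: multiply by the per-pixel inverse gain."""
        from .correction import build_lut, correct

        if not hasattr(self, "vignetting_"):
            raise AttributeError("model is not fitted yet; call fit() first")
        lut = build_lut(self.estimate_, clip_range=self.clip_range, eps=self.eps)
        return correct(X, lut).pixels

    def export_params(self) -> "ModelParams":
        return export_params(self.estimate_)


class LocalPolynomial(BaseVignettingModel):
    """LP model: mean of independent per-row and per-column polynomial fits.

    ``degree=2`` reproduces the Local Parabolic model exactly.
    """

    model_kind = ModelKind.LP

    def _estimate(self, data):
        return _lp_pass(data, self.degree, want_coeffs=self.keep_coefficients)


def _lp_pass(data: np.ndarray, degree: int, want_coeffs: bool = False):
    if want_coeffs:
        h, hc = fit_lines_1d(data, "horizontal", degree, return_coeffs=True)
        v, vc = fit_lines_1d(data, "vertical", degree, return_coeffs=True)
        return 0.5 * (h + v), {"horizontal": hc, "vertical": vc}
    h = fit_lines_1d(data, "horizontal", degree)
    v = fit_lines_1d(data, "vertical", degree)
    return 0.5 * (h + v), None


class SmoothLocalPolynomial(BaseVignettingModel):
    """SLP model: the LP operator iterated ``n_iter`` times on its own output.

    ``n_iter=1`` is identical to :class:`LocalPolynomial` (same code path).
    The iteration count is fixed by the caller; there is no stopping rule.
    """

    model_kind = ModelKind.SLP

    def __init__(self, degree=2, n_iter=25, keep_coefficients=False, eps=1e-3,
                 clip_range=None):
        super().__init__(degree, keep_coefficients, eps, clip_range)
        self.n_iter = n_iter

    def _iterations(self):
        return self.n_iter

    def _estimate(self, data):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        current = data
        coeffs = None
        for _ in range(self.n_iter):
            current, coeffs = _lp_pass(current, self.degree,
                                       want_coeffs=self.keep_coefficients)
        return current, coeffs


class SNILP(BaseVignettingModel):
    """SNILP model: sequential line fits, one pass per axis, then normalize.

    The second family of line fits is applied to the *output* of the first,
    so the result lies in the tensor-product polynomial space: every row of
    the estimate is a degree-``s`` polynomial in the column coordinate and
    every column one in the row coordinate.  Both passes are orthogonal
    projections, hence the axis order only matters at float rounding level
    and re-applying the model reproduces its own output (idempotence).
    """

    model_kind = ModelKind.SNILP

    def __init__(self, degree=2, order=AxisOrder.X_THEN_Y, keep_coefficients=False,
                 eps=1e-3, clip_range=None):
        super().__init__(degree, keep_coefficients, eps, clip_range)
        self.order = order

    def _estimate(self, data):
        order = AxisOrder(self.order)
        if order is AxisOrder.X_THEN_Y:
            first, second = "horizontal", "vertical"
        else:
            first, second = "vertical", "horizontal"
        mid = fit_lines_1d(data, first, self.degree)
        surface = fit_lines_1d(mid, second, self.degree)
        coeffs = None
        if self.keep_coefficients:
            coeffs = _snilp_line_coeffs(surface, self.degree)
        return surface, coeffs


def _snilp_line_coeffs(surface: np.ndarray, degree: int) -> dict:
    """Compact SNILP payload: per-line coefficients along the larger side.

    The fitted surface is polynomial along both axes, so refitting the lines
    of the smaller-count side (each line running along the larger dimension)
    represents it exactly with ``min(M, N) * (degree + 1)`` numbers.
    """
    m, n = surface.shape
    if m <= n:
        _, coeffs = fit_lines_1d(surface, "horizontal", degree, return_coeffs=True)
        axis = "horizontal"
    else:
        _, coeffs = fit_lines_1d(surface, "vertical", degree, return_coeffs=True)
        axis = "vertical"
    return {"axis": axis, "lines": coeffs}


class Polynomial2D(BaseVignettingModel):
    """P2D model: one global bivariate OLS polynomial of total degree ``s``."""

    model_kind = ModelKind.P2D

    def _estimate(self, data):
        fitted, coef = _fit_p2d_surface(data, self.degree)
        coeffs = {"beta": coef, "exponents": _p2d_exponents(self.degree)}
        return fitted, coeffs


class RadialPolynomial(BaseVignettingModel):
    """RP model: a 1D polynomial in the radius from the optical center.

    The radius of every pixel is computed from ``center`` (``(row, col)``,
    found via :func:`find_optical_center` when omitted), scaled by the
    largest radius in the image, and a single degree-``s`` polynomial in the
    scaled radius is fitted over all pixels by OLS.  ``even_only=True``
    restricts the basis to even powers (r^0, r^2, ...), the form radially
    symmetric lens laws actually take.
    """

    model_kind = ModelKind.RP

    def __init__(self, degree=2, center=None, even_only=False,
                 keep_coefficients=False, eps=1e-3, clip_range=None):
        super().__init__(degree, keep_coefficients, eps, clip_range)
        self.center = center
        self.even_only = even_only

    def _estimate(self, data):
        m, n = data.shape
        if self.center is None:
            oc = find_optical_center(data)
            center = (oc.row, oc.col)
            if oc.flagged:
                # recorded on the estimate via flags below
                self._center_flagged = True
        else:
            center = (float(self.center[0]), float(self.center[1]))
            if not (0 <= center[0] <= m - 1 and 0 <= center[1] <= n - 1):
                center = (min(max(center[0], 0.0), m - 1.0),
                          min(max(center[1], 0.0), n - 1.0))
        self.center_ = center
        rows = np.arange(m)[:, None] - center[0]
        cols = np.arange(n)[None, :] - center[1]
        r = np.hypot(rows, cols)
        rmax = float(r.max())
        if rmax == 0:
            rmax = 1.0
        u = (r / rmax).ravel()
        if self.even_only:
            powers = np.arange(0, self.degree + 1, 2)
        else:
            powers = np.arange(0, self.degree + 1)
        design = u[:, None] ** powers[None, :]
        coef, _, rank, sv = np.linalg.lstsq(design, data.ravel(), rcond=None)
        if rank < len(powers):
            cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
            raise np.linalg.LinAlgError(
                f"rank-deficient radial design (condition estimate {cond:.3g})"
            )
        fitted = (design @ coef).reshape(m, n)
        coeffs = {
            "beta": coef,
            "powers": powers,
            "center": center,
            "rmax": rmax,
        }
        return fitted, coeffs


MODEL_REGISTRY = {
    "local_parabolic": LocalPolynomial,
    "lp": LocalPolynomial,
    "slp": SmoothLocalPolynomial,
    "snilp": SNILP,
    "p2d": Polynomial2D,
    "rp": RadialPolynomial,
}


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_lp(img, degree: int, keep_coefficients: bool = False) -> VignettingEstimate:
    """Fit the Local Polynomial model (Local Parabolic when ``degree=2``)."""
    est = LocalPolynomial(degree, keep_coefficients=keep_coefficients).fit(img)
    out = est.estimate_
    if degree == 2:
        out.model = ModelKind.LP  # LP subsumes the parabolic special case
    return out


def fit_slp(img, degree: int, k: int, keep_coefficients: bool = False) -> VignettingEstimate:
    """Fit the Smooth Local Polynomial model with ``k`` iterations."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return SmoothLocalPolynomial(
        degree, n_iter=k, keep_coefficients=keep_coefficients
    ).fit(img).estimate_


def fit_snilp(img, degree: int, order: AxisOrder = AxisOrder.X_THEN_Y,
              keep_coefficients: bool = False) -> VignettingEstimate:
    """Fit the SNILP model (sequential per-axis line fits + normalization)."""
    return SNILP(
        degree, order=order, keep_coefficients=keep_coefficients
    ).fit(img).estimate_


def fit_p2d(img, degree: int, keep_coefficients: bool = False) -> VignettingEstimate:
    """Fit the global bivariate polynomial (P2D) model."""
    return Polynomial2D(degree, keep_coefficients=keep_coefficients).fit(img).estimate_


def fit_rp(img, degree: int, center=None, even_only: bool = False,
           keep_coefficients: bool = False) -> VignettingEstimate:
    """Fit the radial polynomial (RP) model."""
    return RadialPolynomial(
        degree, center=center, even_only=even_only,
        keep_coefficients=keep_coefficients,
    ).fit(img).estimate_


# ---------------------------------------------------------------------------
# parameter export / reconstruction
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Compact, self-describing parameter form of a fitted estimate.

    ``payload_count`` (number of model coefficients, excluding the separate
    normalization constant) follows the per-model formulas:
    P2D ``(s^2+3s+2)/2``; RP ``s+3`` (coefficients + center); SLP
    ``(M+N)(s+1)``; SNILP ``min(M,N)(s+1)``.
    """

    model: ModelKind
    degree: int
    shape: tuple[int, int]
    coords_convention: str
    payload: dict
    norm_constant: float = 1.0
    iterations: int = 1

    @property
    def payload_count(self) -> int:
        return _count_payload(self)

    # -- text (JSON) serialization --------------------------------------
    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, ModelKind):
                return o.value
            raise TypeError(type(o))

        return json.dumps(
            {
                "model": self.model.value,
                "degree": self.degree,
                "shape": list(self.shape),
                "coords_convention": self.coords_convention,
                "norm_constant": self.norm_constant,
                "iterations": self.iterations,
                "payload": self.payload,
            },
            default=enc,
            indent=1,
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        d = json.loads(text)
        payload = {
            k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in d["payload"].items()
        }
        return cls(
            model=ModelKind(d["model"]),
            degree=int(d["degree"]),
            shape=tuple(d["shape"]),
            coords_convention=d["coords_convention"],
            payload=payload,
            norm_constant=float(d["norm_constant"]),
            iterations=int(d.get("iterations", 1)),
        )

    @classmethod
    def load(cls, path) -> "ModelParams":
        return cls.from_json(Path(path).read_text())


def parameter_count(model, degree: int, shape: tuple[int, int]) -> int:
    """Closed-form coefficient count for saving a model of degree ``s``.

    P2D: ``(s^2 + 3s + 2) / 2``; RP: ``s + 3``; SLP: ``(M+N)(s+1)``;
    SNILP: ``min(M, N) * (s + 1)``.
    """
    model = ModelKind(model)
    m, n = shape
    s = degree
    if model is ModelKind.P2D:
        return (s * s + 3 * s + 2) // 2
    if model is ModelKind.RP:
        return s + 3
    if model in (ModelKind.SLP, ModelKind.LP, ModelKind.LOCAL_PARABOLIC):
        return (m + n) * (s + 1)
    if model is ModelKind.SNILP:
        return min(m, n) * (s + 1)
    raise ValueError(f"unknown model {model}")


def _count_payload(p: ModelParams) -> int:
    if p.model is ModelKind.P2D:
        return int(np.asarray(p.payload["beta"]).size)
    if p.model is ModelKind.RP:
        return int(np.asarray(p.payload["beta"]).size) + 2
    if p.model in (ModelKind.SLP, ModelKind.LP, ModelKind.LOCAL_PARABOLIC):
        return int(
            np.asarray(p.payload["horizontal"]).size
            + np.asarray(p.payload["vertical"]).size
        )
    if p.model is ModelKind.SNILP:
        return int(np.asarray(p.payload["lines"]).size)
    raise ValueError(f"unknown model {p.model}")


def export_params(v: VignettingEstimate) -> ModelParams:
    """Convert a fitted estimate to its minimal coefficient set.

    Requires the fit to have been run with ``keep_coefficients=True``
    (coefficient retention is opt-in: the matrix form is the primary,
    real-time-friendly artifact).
    """
    if v.coefficients is None:
        raise ValueError(
            "estimate carries no coefficients; refit with keep_coefficients=True"
        )
    model = v.model
    payload: dict
    if model is ModelKind.P2D:
        payload = {
            "beta": np.asarray(v.coefficients["beta"]),
            "exponents": np.asarray(v.coefficients["exponents"]),
        }
    elif model is ModelKind.RP:
        payload = {
            "beta": np.asarray(v.coefficients["beta"]),
            "powers": np.asarray(v.coefficients["powers"]),
            "center": list(v.coefficients["center"]),
            "rmax": float(v.coefficients["rmax"]),
        }
    elif model in (ModelKind.SLP, ModelKind.LP, ModelKind.LOCAL_PARABOLIC):
        payload = {
            "horizontal": np.asarray(v.coefficients["horizontal"]),
            "vertical": np.asarray(v.coefficients["vertical"]),
        }
    elif model is ModelKind.SNILP:
        payload = {
            "axis": v.coefficients["axis"],
            "lines": np.asarray(v.coefficients["lines"]),
        }
    else:
        raise ValueError(f"unknown model {model}")
    p = ModelParams(
        model=model,
        degree=v.degree,
        shape=v.shape,
        coords_convention=COORDS_CONVENTION,
        payload=payload,
        norm_constant=v.norm_constant,
        iterations=v.iterations,
    )
    expected = parameter_count(model, v.degree, v.shape)
    if p.payload_count != expected:
        raise AssertionError(
            f"payload count {p.payload_count} != expected {expected} for {model}"
        )
    return p


def evaluate_params(p: ModelParams) -> VignettingEstimate:
    """Reconstruct the estimate matrix from its parameter form."""
    m, n = p.shape
    model = p.model
    if model is ModelKind.P2D:
        beta = np.asarray(p.payload["beta"], dtype=float)
        exps = np.asarray(p.payload["exponents"], dtype=int)
        nterms = (p.degree + 1) * (p.degree + 2) // 2
        if beta.size != nterms or exps.shape != (nterms, 2):
            raise ValueError("P2D payload does not match degree/shape")
        design = _p2d_design((m, n), p.degree)
        values = (design @ beta).reshape(m, n)
    elif model is ModelKind.RP:
        beta = np.asarray(p.payload["beta"], dtype=float)
        powers = np.asarray(p.payload["powers"], dtype=int)
        if beta.size != powers.size:
            raise ValueError("RP payload does not match its power list")
        crow, ccol = p.payload["center"]
        rmax = float(p.payload["rmax"])
        rows = np.arange(m)[:, None] - crow
        cols = np.arange(n)[None, :] - ccol
        u = (np.hypot(rows, cols) / rmax).ravel()
        values = (u[:, None] ** powers[None, :] @ beta).reshape(m, n)
    elif model in (ModelKind.SLP, ModelKind.LP, ModelKind.LOCAL_PARABOLIC):
        hc = np.asarray(p.payload["horizontal"], dtype=float)
        vc = np.asarray(p.payload["vertical"], dtype=float)
        if hc.shape != (m, p.degree + 1) or vc.shape != (n, p.degree + 1):
            raise ValueError("SLP payload does not match degree/shape")
        bx = npoly.polyvander(_scaled_coords(n), p.degree)
        by = npoly.polyvander(_scaled_coords(m), p.degree)
        h = hc @ bx.T  # (m, n): per-row polynomials
        v = (vc @ by.T).T  # (m, n): per-column polynomials
        values = 0.5 * (h + v)
    elif model is ModelKind.SNILP:
        lines = np.asarray(p.payload["lines"], dtype=float)
        axis = p.payload["axis"]
        if axis == "horizontal":
            if lines.shape != (m, p.degree + 1):
                raise ValueError("SNILP payload does not match degree/shape")
            basis = npoly.polyvander(_scaled_coords(n), p.degree)
            values = lines @ basis.T
        else:
            if lines.shape != (n, p.degree + 1):
                raise ValueError("SNILP payload does not match degree/shape")
            basis = npoly.polyvander(_scaled_coords(m), p.degree)
            values = (lines @ basis.T).T
    else:
        raise ValueError(f"unknown model {model}")
    # parameter files store coefficients of the *raw* surface; re-apply the
    # stored normalization so the round trip reproduces the normalized matrix
    if p.norm_constant == 0:
        raise ValueError("norm_constant must be non-zero")
    values = values / p.norm_constant
    return VignettingEstimate(
        values=values,
        model=model,
        degree=p.degree,
        iterations=p.iterations,
        normalized=True,
        norm_constant=p.norm_constant,
        coefficients=None,
    )
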