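"""Synthetic flat-field simulator.

Generates ground-truth vignetting surfaces and noisy flat-field frames so
every estimator and metric in the package can be exercised and compared
against a known truth, with no camera in the loop.

The ground-truth law is natural (cos^4) vignetting: a pixel at metric
distance ``r`` from the optical center on the sensor plane, seen through a
lens of focal length ``f``, is attenuated by ``cos^4(theta)`` with
``tan(theta) = r / f``.  The sensor defaults to the 135 ("full-frame")
format, 36 x 24 mm.  Shorter focal lengths give a stronger fall-off:
f = 24 mm drops to ~0.24 in the corner, f = 300 mm only to ~0.99, which is
why short lenses need higher polynomial degrees (24 mm -> 10, 50 mm -> 6,
300 mm -> 2 is the pairing used throughout the package's studies).

Optional knobs create the asymmetric cases radial models cannot represent:
``center_offset_px`` shifts the optical center off the image center and
``anisotropy > 1`` compresses the fall-off vertically (an anamorphic-like
squeeze).

A noisy frame is ``I_V = clip(V * (1 + eta_m) + eta_a, 0, 1)`` with
independent per-pixel Gaussians: multiplicative ``eta_m ~ N(0, sigma_multi^2)``
(fraction of signal, default 10%) and additive ``eta_a ~ N(0, sigma_add^2)``
(fraction of full scale, default 5%).  The ideal reference surface is
constant full-scale 1, so the noiseless frame equals V itself.  One root
seed drives everything; per-repeat substreams are spawned deterministically
so any single repeat is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .raster import FlatImage

__all__ = [
    "SimulationSpec",
    "DEGREE_FOR_FOCAL",
    "natural_vignetting",
    "make_vignetting",
    "make_flat_image",
    "make_flat_stack",
    "run_model_comparison",
    "summarize_comparison",
]

#: Polynomial degree paired with each simulated focal length (mm): the
#: degree at which each lens's fall-off is captured best by the line fits.
DEGREE_FOR_FOCAL = {24.0: 10, 50.0: 6, 300.0: 2}


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one reproducible synthetic flat-field setup.

    resolution : (M, N) = (rows, cols)
    center_offset_px : (d_row, d_col) shift of the optical center, pixels
    anisotropy : >= 1; scales vertical metric distances (1 = radial)
    sigma_add : additive noise sigma as a fraction of full scale
    sigma_multi : multiplicative noise sigma as a fraction of signal
    """

    focal_length_mm: float
    resolution: tuple[int, int] = (480, 640)
    sensor_width_mm: float = 36.0
    sensor_height_mm: float = 24.0
    center_offset_px: tuple[float, float] = (0.0, 0.0)
    anisotropy: float = 1.0
    sigma_add: float = 0.05
    sigma_multi: float = 0.10
    n_repeats: int = 1
    seed: int = 0
    clip: bool = True

    def __post_init__(self) -> None:
        if self.focal_length_mm <= 0:
            raise ValueError("focal_length_mm must be positive")
        if self.anisotropy < 1:
            raise ValueError("anisotropy must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        m, n = self.resolution
        if m < 2 or n < 2:
            raise ValueError("resolution must be at least 2x2")

    def to_dict(self) -> dict:
        return asdict(self)


def natural_vignetting(r_mm, focal_length_mm: float):
    """cos^4 fall-off at metric radius ``r_mm`` for a lens of focal length f.

    ``cos^4(atan(r/f)) = (1 + (r/f)^2)^-2``.
    """
    ratio2 = (np.asarray(r_mm, dtype=float) / focal_length_mm) ** 2
    return 1.0 / (1.0 + ratio2) ** 2


def _sensor_radii(spec: SimulationSpec) -> np.ndarray:
    """Metric distance of each pixel center from the (offset) optical center."""
    m, n = spec.resolution
    pitch_x = spec.sensor_width_mm / n
    pitch_y = spec.sensor_height_mm / m
    d_row, d_col = spec.center_offset_px
    cols = (np.arange(n) - (n - 1) / 2.0 - d_col) * pitch_x
    rows = (np.arange(m) - (m - 1) / 2.0 - d_row) * pitch_y * spec.anisotropy
    return np.hypot(cols[None, :], rows[:, None])


def make_vignetting(spec: SimulationSpec) -> FlatImage:
    """Deterministic ground-truth vignetting surface, normalized to max 1."""
    v = natural_vignetting(_sensor_radii(spec), spec.focal_length_mm)
    v = v / v.max()
    return FlatImage(v, "float", (0.0, 1.0))


def _repeat_rngs(spec: SimulationSpec) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(spec.seed)
    return [np.random.default_rng(child) for child in seq.spawn(spec.n_repeats)]


def _noisy_frame(v: np.ndarray, spec: SimulationSpec,
                 rng: np.random.Generator) -> np.ndarray:
    eta_m = rng.normal(0.0, spec.sigma_multi, size=v.shape)
    eta_a = rng.normal(0.0, spec.sigma_add, size=v.shape)
    frame = v * (1.0 + eta_m) + eta_a
    if spec.clip:
        frame = np.clip(frame, 0.0, 1.0)
    return frame


def make_flat_image(spec: SimulationSpec, repeat: int = 0) -> FlatImage:
    """One noisy flat-field frame ``I_V`` (repeat ``repeat`` of the stack)."""
    if not 0 <= repeat < spec.n_repeats:
        raise ValueError(f"repeat {repeat} outside 0..{spec.n_repeats - 1}")
    v = make_vignetting(spec).pixels
    rng = _repeat_rngs(spec)[repeat]
    return FlatImage(_noisy_frame(v, spec, rng), "float", (0.0, 1.0))


def make_flat_stack(spec: SimulationSpec) -> np.ndarray:
    """All ``n_repeats`` noisy frames as an ``(n_repeats, M, N)`` array."""
    v = make_vignetting(spec).pixels
    return np.stack([_noisy_frame(v, spec, rng) for rng in _repeat_rngs(spec)])


# ---------------------------------------------------------------------------
# comparison protocol
# ---------------------------------------------------------------------------


def run_model_comparison(spec: SimulationSpec, degrees, models=None,
                         k_values=(25,), n_reps: int | None = None,
                         window_spec=None) -> pd.DataFrame:
    """Fit each model/degree to repeated noisy frames and score them all.

    For every repetition a fresh noisy frame is drawn, each requested model
    is fitted at each degree (SLP once per entry of ``k_values``), and the
    metrics recorded: MAE and RMSE against the known truth, MLSD and MLSCD
    of the estimate surface, and STD/IQR of the corrected flat (corrected on
    the simulator's [0, 1] scale).  Returns a long-format table with columns
    ``model, degree, k, rep, metric, value``.
    """
    from .correction import build_lut, correct
    from .metrics import SmoothnessWindowSpec, flat_quality, mae, mlscd, mlsd, rmse
    from .models import MODEL_REGISTRY, SmoothLocalPolynomial

    if models is None:
        models = ["lp", "slp", "snilp", "p2d", "rp"]
    if n_reps is None:
        n_reps = spec.n_repeats
    if window_spec is None:
        window_spec = SmoothnessWindowSpec()

    truth = make_vignetting(spec).pixels
    run_spec = SimulationSpec(**{**spec.to_dict(), "n_repeats": n_reps})
    rngs = _repeat_rngs(run_spec)

    rows = []

    def score(name, degree, k, rep, estimate, frame):
        lut = build_lut(estimate, clip_range=(0.0, 1.0))
        flat = correct(frame, lut)
        quality = flat_quality(flat)
        values = {
            "mae": mae(estimate.values, truth),
            "rmse": rmse(estimate.values, truth),
            "mlsd": mlsd(estimate.values, window_spec),
            "mlscd": mlscd(estimate.values, window_spec),
            "std": quality.std,
            "iqr": quality.iqr,
        }
        for metric, value in values.items():
            rows.append(
                {"model": name, "degree": degree, "k": k, "rep": rep,
                 "metric": metric, "value": value}
            )

    for rep, rng in enumerate(rngs):
        frame = _noisy_frame(truth, run_spec, rng)
        for degree in degrees:
            for name in models:
                cls = MODEL_REGISTRY[name]
                if cls is SmoothLocalPolynomial and name == "slp":
                    for k in k_values:
                        est = cls(degree, n_iter=k).fit(frame).estimate_
                        score(name, degree, k, rep, est, frame)
                else:
                    est = cls(degree).fit(frame).estimate_
                    score(name, degree, 1, rep, est, frame)
    return pd.DataFrame(rows)


def summarize_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics (min/q1/median/q3/max) per model/degree/k/metric."""
    grouped = table.groupby(["model", "degree", "k", "metric"])["value"]
    summary = grouped.agg(
        min="min",
        q1=lambda s: s.quantile(0.25),
        median="median",
        q3=lambda s: s.quantile(0.75),
        max="max",
    )
    return summary.reset_index()
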