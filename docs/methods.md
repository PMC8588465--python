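# Methods

## Image formation and correction model

A reference flat-field image is modeled as `I_V(i, j) = V(i, j) · I_flat(i, j)`,
where `V ∈ (0, 1]` is the vignetting surface of the lens-camera system and
`I_flat` is the ideal image of the uniformly lit reference surface.  An
estimate `V~` of `V` is fitted to `I_V`, normalized so `max V~ = 1`, and
images are corrected by `I~ = I · V~⁻¹`, realized as a per-pixel gain
lookup table.  Corrected values are truncated to the sensor range
(`[0, 255]` for 8-bit, `[0, 65535]` for 16-bit, `[0, 1]` for normalized
float data).

Axis convention: arrays are row-major, axis 0 = rows = vertical, axis 1 =
columns = horizontal; all coordinates are `(row, col)`.

## Estimators

All least-squares fits map their regressor coordinates affinely onto
`[-1, 1]`.  Raw pixel indices raised to the 10th power on lines of
thousands of pixels make the Vandermonde design catastrophically
ill-conditioned; on `[-1, 1]` plain `lstsq` is accurate for every degree
the package is used at (`s ≤ 10`), and exported parameter files record the
convention so they are self-describing.

- **LP** — per-row and per-column 1D OLS fits of degree `s`, averaged.
  Each family of fits is computed as a single `lstsq` with one
  right-hand-side column per line.
- **SLP** — the LP operator applied `k` times; `k` is fixed by the caller
  (no stopping rule), with `k = 25` the conventional choice in
  comparisons and `k = 1` identical to LP by construction (same code
  path).
- **SNILP** — the row-fit projection followed by the column-fit projection
  (or vice versa; the `order` parameter exists only to demonstrate the
  invariance), then normalization by the global maximum.  Writing the row
  and column projectors as `P_x` (acting on the right) and `P_y` (acting
  on the left), the estimate is `P_y · I_V · P_x`.  Decomposing
  `I_V = A + B + C + D` with `A = P_y I_V P_x`, `B = (I−P_y) I_V P_x`,
  `C = P_y I_V (I−P_x)`, `D = (I−P_y) I_V (I−P_x)` shows
  `LP(A) = A`, `LP(B) = B/2`, `LP(C) = C/2`, `LP(D) = 0`, hence
  `SLP_k = A + (B + C)/2^k + D·[k=0]`: the SLP iteration converges
  geometrically to the SNILP estimate, which is itself an idempotent
  projection.  These identities are what the order-invariance (≤ 2·10⁻¹²),
  idempotence (≤ 10⁻¹³ mean change per extra application, ≤ 10⁻¹¹ after
  25, RMSE spread ≤ 5·10⁻¹³) and convergence checks in the test suite and
  acceptance script verify numerically.
- **P2D** — all monomials `x^p y^q` with `p + q ≤ s`
  (`(s+1)(s+2)/2` terms) fitted over all pixels in one `lstsq`; a
  rank-deficient design raises with the condition estimate.
- **RP** — radii are computed from the optical center, scaled by the
  largest radius, and a single degree-`s` polynomial in the scaled radius
  is fitted over all pixels.  The default basis uses all powers
  `r⁰..r^s`; `even_only=True` restricts to even powers, the form
  rotationally symmetric lens laws take (on a symmetric surface the two
  agree, because odd powers contribute nothing to the fit).
- **Optical center** — the 6-term degree-2 bivariate OLS fit; when its
  Hessian is negative definite the analytic stationary point is returned
  with subpixel precision, clamped to the image bounds.  Degenerate flats
  (planes, saddles) fall back to the argmax of a Gaussian-smoothed copy
  (σ = 0.5, 10×10 kernel) and the result is flagged.

Normalization to `max V~ = 1` is applied uniformly to every model's output
so STD/IQR comparisons of corrected flats are on a common footing; the
pre-normalization scale is kept in `norm_constant`.  When several pixels
attain the maximum the scalar maximum is used; no pixel identity is needed.

### Parameter form

Estimates are primarily stored as matrices (the right choice for real-time
gain tables); coefficient retention is opt-in (`keep_coefficients=True`).
Payload sizes are: P2D `(s²+3s+2)/2`; RP `s+1` coefficients plus the
2-coordinate center; SLP `(M+N)(s+1)` (last-iteration line fits in both
directions); SNILP `min(M, N)·(s+1)` — the fitted surface is polynomial
along both axes, so refitting the lines of the smaller-count side
represents it exactly.  The normalization constant is stored separately.
Reconstruction from parameters matches the matrix to ≤ 10⁻¹².

## Metrics

- MAE and RMSE are plain per-pixel means against the known truth.
- MLSD: mean over interior window positions of the in-window *population*
  standard deviation (divisor `w_x·w_y`, exactly as the defining sums are
  written; not the `n−1` sample form).  Window centers keep the full
  window inside the image, so a border of half the window width is
  excluded.
- MLSCD: the same with the window first detrended by an in-window
  bivariate OLS polynomial of total degree `s` (default 2, window 7×7).
  One orthonormalized design is shared by every window position (the
  geometry is identical everywhere); residuals are formed explicitly
  rather than via the Gram identity to avoid cancellation on very smooth
  surfaces.  `detrend_degree = 0` reduces to MLSD through the same code
  path.  MLSD carries an irreducible slope-sensitivity floor on sloped
  surfaces; once an SLP sequence reaches that floor, consecutive iterates
  fluctuate around it at rounding level (~10⁻⁹ relative), which is why
  monotonicity checks use a looser tolerance for MLSD than for MLSCD.
- Flat quality: population STD and IQR over all pixels (no border
  exclusion).  IQR uses linearly interpolated percentiles (q75 − q25);
  any consistent convention preserves model rankings.

## Synthetic flat-field simulator

The simulator provides ground truth where a real camera cannot: the true
`V` is known exactly, so accuracy metrics are meaningful.

- **Vignetting law**: natural (cos⁴) vignetting.  A pixel at metric
  distance `r` from the optical center on the sensor plane has
  `V = cos⁴(atan(r/f)) = (1 + (r/f)²)⁻²`.  The sensor defaults to the 135
  format (36 × 24 mm); pixel centers are mapped to millimetres by the
  pixel pitch per axis.  `center_offset_px` shifts the optical center and
  `anisotropy ≥ 1` scales vertical metric distances, producing the
  off-center/anamorphic surfaces that radial models cannot represent.
  Focal lengths 24/50/300 mm span strong to nearly flat fall-off (corner
  values ≈ 0.30 / 0.71 / 0.99), and are conventionally paired with fit
  degrees 10/6/2 — the degree each profile needs for a good polynomial
  approximation.
- **Noise**: `I_V = clip(V·(1 + η_m) + η_a, 0, 1)` with independent
  per-pixel Gaussians, multiplicative `η_m ~ N(0, σ_multi²)` (default 10%
  of signal) and additive `η_a ~ N(0, σ_add²)` (default 5% of full
  scale).  The two named sigmas force exactly this two-component
  structure.  `I_flat` is constant full-scale 1.  Clipping mirrors sensor
  saturation and can be disabled for pure-noise statistical tests.  Note
  that with `max V = 1`, clipping biases the *mean* of repeated frames
  slightly below `V` near the peak — a realistic saturation artifact that
  dominates the RMSE of fits to heavily averaged stacks.
- **Seeding**: one root seed; per-repeat substreams are spawned from a
  `SeedSequence`, so repeat `r` of a stack is bit-reproducible in
  isolation and identical spec + seed gives bit-identical output.

What the simulator does *not* emulate: optical/pixel/mechanical
vignetting physics, lens distortion, camera response curves, spatially
correlated (fixed-pattern) noise, dead pixels, or non-uniform reference
illumination.  Passing tests therefore demonstrate the estimators'
numerical behavior under the stated noise model, not robustness to every
real-camera artifact.

## Study problem sizes

The package's own verification studies are sized to run quickly on one
CPU: order-invariance and idempotence are checked at SXGA (1024 × 1280,
the resolution the printed precision bounds refer to) over a handful of
seeded repetitions per lens; the SLP-convergence study uses 20 repetitions
at 640 × 480; the model-ordering study fits the mean of a 100-frame
simulated stack at 640 × 480 — averaging first mirrors the real
calibration protocol (the flat used for fitting is the average of 100
captured frames) and is what lets fit quality, rather than per-frame noise
amplification, determine the STD/IQR ordering SNILP ≈ SLP(25) ≤ P2D ≤ RP.

## Numerical choices and edge cases

- Population (not sample) standard deviations throughout the smoothness
  metrics; `np.linalg.lstsq` (SVD) rather than explicit normal equations
  for all fits — the explicit `(XᵀX)⁻¹Xᵀy` solve appears only as the
  independent oracle in tests.
- A line fit requires line length > degree; shorter lines raise before
  any computation.
- Correction gains are guarded by `eps` (default 10⁻³ of the normalized
  range): estimate pixels below `eps` get their gain capped at `1/eps`
  and are flagged, since a blind division would blow up on dead pixels.
- The display normalization (divide by the max of a Gaussian-smoothed
  copy, σ = 0.5, 10 × 10) uses an even-sized kernel centered between
  pixels with zero (constant) padding at the borders; it is a
  visualization aid only and never enters estimation.
- The degree-2 quadratic for the optical center is accepted only if its
  Hessian is strictly negative definite; anything else takes the flagged
  smoothed-argmax fallback.

## Known limitations

- The cos⁴ law is the only built-in ground-truth family; estimators are
  of course applicable to arbitrary flats, but simulated accuracy numbers
  are specific to that law plus the stated noise.
- RP's optical-center search inherits the quadratic-fit bias on strongly
  non-quadratic surfaces; the package intentionally mirrors the standard
  procedure rather than improving it, since RP is a comparator here.
- Per-channel color correction is out of scope: RGB flats are collapsed
  to luma (`0.2989 R + 0.5870 G + 0.1140 B`, the printed 4-decimal
  weights) before estimation.
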