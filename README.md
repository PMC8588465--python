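# snilp — flat-field (vignetting) estimation and correction

Vignetting is the fall-off of image brightness from the optical center of a
lens-camera system toward its edges. Quantitative imaging pipelines —
microscopy, micro-CT, remote sensing, image stitching — remove it by
*flat-field correction*: acquire a reference image `I_V` of a uniformly lit
uniform surface, estimate the normalized vignetting surface `V~ ∈ (0, 1]`
from it, and divide every acquired image by it, `I~ = I · V~⁻¹`.

This package implements the **Smooth Non-Iterative Local Polynomial
(SNILP)** vignetting model together with the comparator models it is
usually judged against, the accuracy/smoothness/flatness metrics used to
compare them, and a seedable synthetic flat-field simulator, so the whole
methodology runs end-to-end with no camera attached.

## Models

For an `M × N` flat-field and polynomial degree `s`:

- **LP** (Local Polynomial): fit a 1D degree-`s` polynomial by OLS
  independently along every row and every column; the estimate is the
  pixelwise mean of the two fitted families, `V~ = ½(V~x + V~y)`.
  (`s = 2` is the classical Local Parabolic model.)
- **SLP** (Smooth LP): iterate the LP operator `k` times on its own output;
  smooths the ragged surface LP leaves, at `k`-fold cost.
- **SNILP**: fit all lines along one axis, then fit all lines of *that
  result* along the other axis, then normalize to max 1:
  `V~ = PolyApp_y^s(PolyApp_x^s(I_V)) / max(·)`. Both passes are orthogonal
  projections onto per-line polynomial spaces, which yields three provable
  properties checked by this package's test suite:
  - *order invariance*: x-then-y and y-then-x agree to ≤ 2·10⁻¹²,
  - *idempotence*: re-applying SNILP to its own output changes the mean
    pixel by ≤ 10⁻¹³,
  - *SLP limit*: SLP's iterates converge geometrically (factor ½ per
    iteration) to the SNILP estimate — one SNILP pass buys the `k → ∞`
    SLP result at `1/k` of the cost.
- **P2D**: one global bivariate polynomial of total degree `s` fitted to
  all pixels by OLS.
- **RP**: a 1D polynomial in the radius `r` from the optical center
  (located as the argmax of a degree-2 bivariate fit), fitted over all
  pixels — the classical radial model, which cannot represent off-center
  or anisotropic vignetting.

All estimators are scikit-learn compatible transformers (`fit` on the
flat-field, `transform` corrects images) with functional wrappers
(`fit_snilp`, `fit_lp`, ...).

## Metrics

- `mae` / `rmse` against a known ground-truth surface.
- `mlsd` — Mean Local Standard Deviation: mean in-window population
  standard deviation over a moving window (default 7×7), slope-sensitive.
- `mlscd` — Mean Local Slope-Corrected Deviation: the same statistic on
  residuals from an in-window bivariate polynomial (default degree 2);
  with degree 0 it reduces to MLSD exactly.
- `flat_quality` — population STD and IQR of a corrected flat (lower =
  flatter).

## Worked example

```python
import numpy as np
from snilp import (SimulationSpec, make_flat_stack, make_vignetting,
                   fit_snilp, build_lut, correct, flat_quality,
                   mae, rmse, mlscd)

# a simulated 50 mm lens on a 135-format sensor; calibration stack of 100
# noisy frames (5% additive, 10% multiplicative Gaussian noise), averaged
spec = SimulationSpec(focal_length_mm=50.0, resolution=(480, 640),
                      n_repeats=100, seed=0)
flat = make_flat_stack(spec).mean(axis=0)
truth = make_vignetting(spec).pixels

est = fit_snilp(flat, degree=6)
print(f"RMSE vs truth:  {rmse(est.values, truth):.6f}")
print(f"MLSCD (7x7, s=2): {mlscd(est.values):.3e}")

lut = build_lut(est, clip_range=(0.0, 1.0))
q = flat_quality(correct(flat, lut))
q0 = flat_quality(np.clip(flat, 0, 1))
print(f"corrected flat: STD={q.std:.6f}  IQR={q.iqr:.6f}")
print(f"uncorrected:    STD={q0.std:.6f}  IQR={q0.iqr:.6f}")
```

prints

```
RMSE vs truth:  0.029928
MLSCD (7x7, s=2): 3.818e-08
corrected flat: STD=0.009484  IQR=0.012442
uncorrected:    STD=0.058299  IQR=0.091236
```

The estimate tracks the true surface to ~3% RMS (dominated by the
saturation bias of the averaged input near the peak, not by fit noise), its
surface is smooth to 4·10⁻⁸, and correction flattens the flat-field's
dispersion by a factor of ~6 in STD and ~7 in IQR.

The same workflows are available from the shell:

```sh
snilp simulate flats.tif -f 50 --rows 480 --cols 640 -n 100 --seed 0
snilp estimate flats.tif estimate.tif -m snilp -s 6
snilp correct estimate.tif flats.tif corrected.tif --clip-hi 1.0
snilp compare table.tsv --degrees 2,4,6,8,10 -n 5
```

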