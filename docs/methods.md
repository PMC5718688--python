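# Methods

This note documents the models implemented in `mosdose`, the defaults they
ship with, and what the synthetic experiments do and do not demonstrate.

## Dose model

The pencil-beam algorithm (PBA) treats a broad proton beam as a square
lattice of parallel pencils. A pencil entering at (x₀, y₀) deposits

F(x, y, z) = φ(x₀, y₀) · DD(z + WET(x₀, y₀)) · exp(−[(x−x₀)² + (y−y₀)²] / 2σ²) / (2πσ²),

where

- **z** is slab depth downstream of the bolus in polyethylene-equivalent
  (PE) mm, 0 at the phantom entrance;
- **DD** is the broad-beam depth-dose curve, evaluated at the pencil's
  *effective depth* — slab depth plus the bolus water/PE-equivalent
  thickness (WET) traversed by that pencil. The raytrace is a straight
  parallel ray: the bolus acts as a pure range offset, with no beam
  divergence;
- **σ(z, WET)** is the lateral spread from multiple Coulomb scattering.

The lateral term is a normalised bivariate Gaussian, so integrating a
pencil over the lateral plane returns exactly φ·DD; summed dose is linear
in the fluences. Pencil fluence is φ · spacing², which makes the summed
dose independent of lattice spacing in the converged limit; the default
spacing is 1 mm over a 100 mm field radius (≈ 31 400 pencils), and profiles
computed at 1 mm versus finer spacing agree to well below the reading
noise.

### Lateral spread model

No measured σ values are available for the modelled beam line, so σ is a
quadrature sum of three terms with transparent knobs:

σ(z, WET) = √(σ₀² + (a·z^p)² + (b·WET)²)

| parameter | default | meaning |
|---|---|---|
| σ₀ | 3 mm | beam-line spread at the phantom surface |
| a, p | 5.6 × 10⁻⁴, 1.8 | depth growth; gives σ ≈ 6 mm at z = 160 mm |
| b | 0.04 mm/mm | extra spread per mm of upstream bolus |

The defaults are chosen to be representative of a scattered ~190 MeV
proton beam and, importantly, to reproduce the characteristic *bump and
dip* at a bolus thickness step: because pencils behind the thick branch
spread more than those behind the thin branch, net lateral flux crosses
the edge and the profile overshoots on the thin side and undershoots on
the thick side, localised within ~15 mm of the step. This emergent
structure is asserted by the tests; its exact amplitude depends on σ and
is not a calibrated quantity.

## Depth-dose curves

### Analytic pristine Bragg curve

Measured Bragg curves are loadable from CSV, but the reference curve is an
analytic stand-in so the pipeline is self-contained: a slowly rising
entrance plateau 1 + 0.4·(z/z_peak)², cut off by a sigmoidal distal edge,
plus a Gaussian peak at z_peak whose amplitude is solved (Brent's method)
so the peak-to-entrance ratio is exactly the requested value (default 3.5).
The distal Gaussian width is tied to the fall-off parameter so output drops
below 1 % of entrance within five fall-off lengths (default fall-off 3 mm).
Curves are entrance-normalised (output 1 at depth 0) and evaluated by
linear interpolation on a 0.5 mm grid; depths beyond the grid are past
distal extinction and evaluate to 0.

The default peak depth is 160 mm PE, consistent with peaks at 110/150 mm
behind the 50/10 mm bolus branches of the reference L-bolus experiment.
The first breakpoint structure of the mono-energetic correction table is
in slight tension with a bare-beam peak at exactly 160 mm (its steep
segment would place the peak response ratio near 164 mm); the peak depth
is therefore configurable and no invariant pins the peak-response ratio.

### SOBP synthesis and weight fitting

An SOBP is composed stepwise, exactly as a ridge filter does physically:
out(z) = Σₖ wₖ · pristine(z + sₖ) with range pullbacks sₖ equally spaced
over [0, modulation]. Weights are fitted by non-negative least squares
(`scipy.optimize.nnls`) to flatten the plateau [peak − modulation, peak];
the default 21 components over an 80 mm modulation give a plateau flat to
within ± 1 % with ≥ 78 mm contiguously inside ± 2 %. SOBP curves are
normalised to plateau mean 1 (an SOBP has no meaningful entrance
normalisation; its entrance value, ≈ 0.73 of plateau here, is a
prediction of the synthesis, not a convention).

## Correction mathematics

- **Piecewise tables.** cf(d_PE) is stored as lower-closed/upper-open
  segments with ascending-power polynomial coefficients; the first segment
  is pinned to the constant 1. The shipped mono-energetic table is unity
  below 100.421 mm with two linear segments beyond; the shipped SOBP table
  is unity below 40 mm with a linear and a quadratic segment. Both are
  continuous at their interior breakpoints to better than 10⁻⁴ (the printed
  coefficients' own rounding leaves ~10⁻⁵ gaps). Beyond a fitted table's
  characterised domain the last segment is continued linearly (tangent at
  the domain edge) with a logged warning.
- **Dose-weighted correction field.** CF at a point is the dose-weighted
  mean of per-pencil cf values, each evaluated at that pencil's effective
  PE depth. CF is therefore bounded by the extreme per-pencil cf values,
  equals plain cf wherever all pencils share one effective depth, and is
  exactly 1 at slab depth 0 behind the L-bolus (both branches sit below the
  first breakpoint). Points with zero total dose are outside the field and
  raise rather than returning a value.
- **Ordering.** The angular correction multiplies the reading before
  calibration (R → R · CV(θ) → ×F_calib → ×CF); the order is mathematically
  immaterial but fixed for reporting.

### Fitting tables from ratio data

`fit_piecewise_correction` does plain per-segment least squares at *fixed*
breakpoints (they are an empirical input, not searched), pins the first
segment to 1 and reports — but does not enforce — continuity residuals.
Noise-free synthetic ratio data reproduce the generating coefficients to
10⁻⁶.

`derive_cf_sobp` is deliberately different: when deriving an SOBP table
from a *simulated* ratio curve there are no empirical breakpoints, and the
steep distal rise punishes fixed-breakpoint least squares. The tabulated
IC/MOSFET ratio (on depths with IC dose > 1 % of plateau) is fitted by a
continuity-constrained minimax (Chebyshev) model — unity segment, linear
segment, cubic distal segment, all anchored at their breakpoints — solved
as a linear program (`scipy.optimize.linprog`, HiGHS) with non-decreasing
shape constraints, scanning the two breakpoints coarsely (4 mm) and then
refining (1 mm). Under the default conditions the fitted table tracks the
simulated ratio to ≈ 1.3 % maximum relative error, which bounds the error
of the full simulate–derive–correct round trip. Degenerate inputs reduce
exactly: a unity mono table yields the unity correction, and a
single-zero-shift "SOBP" returns the mono table itself.

## Synthetic experiments

The generators emulate:

- **Calibration**: n exposures of a fixed dose, readings
  dose · sensitivity · (1 + ε), ε ~ N(0, 0.014), sensitivity 0.72 mV/cGy.
  With five 200 cGy exposures the estimated sensitivity has a standard
  error of ≈ 0.0045 mV/cGy, so it lands within ± 0.01 of truth in ~97 % of
  seeds.
- **Depth scans**: IC(d) = DD(d)(1+ε), raw MOSFET = [DD(d)/cf(d)](1+ε′);
  the noise-free ratio reproduces cf by construction, which is what makes
  the round-trip tests regression guards rather than physics claims.
- **Lateral scans**: IC = engine dose, raw MOSFET = engine dose divided by
  the dose-weighted CF computed *with the same engine* (a stress mode can
  generate the truth at finer pencil spacing to emulate model mismatch).
  Correcting therefore cancels the model exactly, and residuals against
  the noisy IC column have spread √2 · 1.4 % ≈ 2 %, which is what the
  pooled accuracy figures measure.

Noise is multiplicative Gaussian, independent per exposure, seeded through
`numpy.random.default_rng`; all generators are bit-reproducible under a
fixed seed.

**What passing does and does not show.** Because generation and correction
share the dose engine by default, the end-to-end accuracy figures
demonstrate that the correction machinery is unbiased and noise-limited —
they do not validate the PBA against real beam data, detector fading,
temperature drift, or tissue heterogeneity beyond a lateral step bolus.
The measured detector characterisations (0.72 mV/cGy sensitivity, 1.4 %
reproducibility, the printed correction tables, the peak relative response)
enter as configuration, never as computed outputs.

## Problem sizes and numerical choices

The reference experiments use a 100 mm field radius at 1 mm pencil spacing,
a 5 mm lateral grid over [−60, 60] mm, and 1 mm depth grids over
[0, 170] mm — the full suite and the acceptance script each complete in
well under a minute on one CPU. Point-by-pencil work matrices are chunked
at 4 × 10⁶ elements. Ties at segment breakpoints resolve to the deeper
segment (lower-closed intervals, as the tables are printed). Depths are PE
mm throughout; the 1.02 PE→water factor is exposed (`pe_to_water`) for
water-equivalent reporting but correction-table arguments stay in PE mm,
matching how the tables are defined.

## Known limitations

- Parallel-beam geometry: no source divergence, no oblique raytracing
  through the bolus.
- The σ model is phenomenological; it is not derived from
  Molière/Highland theory and its bolus term is a single linear
  coefficient.
- Heterogeneity is limited to a lateral step-thickness map; no CT-based
  geometry.
- The angular correction is an independent multiplicative step; it is not
  mixed into the dose-weighted field for oblique-incidence geometries.
- IC measurements are modelled as exact dose plus noise; no chamber
  perturbation corrections.
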