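# Methods

## The transform and the association measure

A measurement of spectral irradiance is a curve `X = {X_λ}` on a strictly
increasing wavelength grid over an analysis window, by default
[300, 800] nm. For a pen thickness τ > 0 the pen boundaries at grid point λ
are the minimum and maximum of X over all grid points `l` with
`λ ≤ l ≤ λ + τ`; the window is a wavelength interval, inclusive at both
ends, never an index count, so non-equispaced grids are handled without
interpolation. The thick pen transform is the family of boundary pairs
over a strictly increasing thickness set, by default
{15, 20, 25, 30, 40, 50, 60, 70, 80} nm — a cross-section of scales from
rough (several nm) to smooth (tens of nm). Bands nest: a thicker pen never
has a higher lower boundary or a lower upper boundary.

Association is computed on *normalized* curves: X is restricted to the
analysis window and mapped affinely so its minimum is 0 and its maximum 1.
Normalization uses the window restriction only, and it makes the measure
invariant to positive affine rescaling of the raw signal — shapes are
compared, not amplitudes. For K ≥ 2 normalized curves on one common grid,

    ρ_λ^τ = (min_k U_k − max_k L_k) / (max_k U_k − min_k L_k),

which is intersection-over-union when the K pen intervals overlap and
minus gap-over-span when they do not. ρ is symmetric in the curves,
bounded above by 1 (attained exactly for identical curves) and below
by −1. The wavelength mean ρ̄^τ is by default the unweighted arithmetic
mean over grid points, exactly as the measure is defined, even though the
grid is not equispaced; a trapezoid-weighted mean is available
(`mean_tpma(..., mode="trapezoid")`) for users who prefer quadrature
weighting, and on the study grid (gap jitter under 10 %) the two differ
negligibly.

### Numerical choices and degenerate cases

- **Right edge.** The window `[λ, λ + τ]` overruns the grid for
  `λ > λ_max − τ`. The default (`edge="truncate"`) cuts the window at the
  last grid point, so every output stays on the input grid and association
  curves for all thicknesses are directly comparable; `edge="restrict"`
  instead drops the affected points. Truncation has one side effect worth
  knowing: at the very last grid point the pen interval degenerates to the
  single value X_λmax, and if two curves differ there the association
  attains exactly −1 at that point. The strict lower bound ρ > −1 is
  guaranteed only where at least one pen interval has positive length —
  always the case for full windows over non-constant data. The invariant
  tests therefore check the open bound on full windows and the closed
  bound in general.
- **Zero denominator.** If all K pen intervals are identical single
  points, ρ is 0/0; it is defined as 1, the limit of identical curves,
  preserving the upper bound.
- **Thickness below the smallest grid gap.** The band collapses onto the
  curve (L = U = X). This is legal but defeats the purpose, so it warns
  rather than errors; the study set starts at 15 nm, far above the
  0.44 nm minimum gap.
- **Implementation.** Running extrema over variable-width windows are
  answered from a sparse table (range-min/max query) built once per curve:
  O(n log n) build, O(n) vectorised queries per thickness, and — because
  queries return input floats without arithmetic — results identical bit
  for bit to a brute-force double loop, which the tests enforce on random
  non-equispaced instances.
- **Tolerances.** Grid equality across curves is exact (no interpolation
  is ever performed; curves to be associated must share a grid by
  construction). Normalized bound attainment is checked to 1e−12 absolute;
  invariant comparisons in tests use 1e−9 relative.

## The synthetic spectra

The generator emulates instantaneous spectroradiometer recordings from a
spring survey of five forest stands (two Betula stands of different age,
a mixed Betula stand, Quercus, Picea) on three dates (25 April, 22 May,
5 June), at three understorey positions plus open-area full-sun
references. Each spectrum is

    continuum × canopy attenuation × O₂ A-band dip × roughness,

rescaled to a position-dependent maximum.

- **Grid.** 1,091 points over [300, 800] nm with consecutive gaps jittered
  inside [0.44, 0.48] nm; jitter is drawn with zero sum so the gaps total
  the window length exactly. Deterministic given the seed.
- **Continuum.** A smooth quasi-blackbody curve at 5,800 K, peaking near
  500 nm. The functional form is irrelevant to the correctness of the
  transform; it only needs to be solar-like and smooth.
- **Canopy attenuation.** A logistic-edged absorption band over roughly
  400–690 nm whose depth depends on position: 0.75 in shade, 0.45 in
  semi-shade, 0.04 in sunflecks, 0 in full sun. This is what differentiates
  the *normalized shapes*: shade spectra are relatively enriched in
  far-red, the classic understorey signature. Stand identity perturbs the
  depth (±25 % relative, default `stand_effect=0.25`) and the band edges
  (±10 nm); date perturbs the same parameters about three times more
  weakly (`date_effect=0.08`). Perturbations are reproducible draws
  attached to the factor level, so every replicate survey shares the same
  "true" factor effects. The defaults are chosen to produce the effect
  ordering position > stand > date in mean-association terms; they are
  exposed in the scenario and the run configuration.
- **Oxygen A-band.** A Gaussian dip at 762 nm (σ = 2.3 nm, depth 0.55),
  the concurrent feature that produces a hump of agreement in association
  curves around 700–760 nm in all groups.
- **Roughness and noise.** Multiplicative log-normal roughness with a
  ~3 nm correlation length (default scale 0.03) gives each curve
  independent fine-scale content for small pens to detect. Contiguous
  replicate sets add independent 1 % multiplicative measurement noise per
  replicate, and can mark a configurable fraction of replicates as
  saturated (a value pushed above the detector ceiling) or UV-deficient
  (300–400 nm signal crushed below the accuracy floor) for the screening
  stage to remove.
- **Amplitudes.** Spectrum maxima are drawn uniformly per position:
  shade 0.12–0.25, semi-shade 0.30–0.50, sunfleck 0.65–1.00, full-sun
  1.00–1.50 W m⁻² nm⁻¹, preserving the observed ordering of position
  maxima. Amplitude is invisible after normalization; it matters only for
  the raw-curve summaries.
- **Design missingness.** Semi-shade does not exist before leaf-out: it is
  absent in all stands on the April date and in Quercus on the May date.
  Comparison groups touching those cells are skipped with a logged notice,
  never an error.
- **Seeding.** One integer seed per scenario; named sub-streams (grid,
  amplitude, roughness, replicates) are derived through `SeedSequence`
  with CRC-32 tags, so outputs are bit-reproducible across processes.

What the generator does *not* emulate: radiative transfer, absolute
calibration, Fraunhofer line positions, stray light, or any quantitative
per-stand canopy optics — the stand and date effects are placeholders with
a realistic ordering, not estimates. Passing tests on synthetic surveys
therefore demonstrates that the machinery recovers a known factor
structure of the stated effect sizes; it does not validate ecological
conclusions about real canopies.

## The comparison pipeline

Raw contiguous sets are screened (drop a spectrum if any value exceeds the
detector ceiling, or if its 300–400 nm signal stays below the UV accuracy
floor — the floor has no canonical value and is configurable), averaged
per measurement point and then across points (two-stage unweighted mean,
equal to the grand mean when replicate counts are equal), and collapsed to
one curve per date × stand × position cell. Averaging happens on raw
irradiance *before* normalization. Comparisons then vary one factor while
fixing the rest:

- vary **date**: group per (stand, position), K up to 3;
- vary **stand**: group per (date, position), K up to 5;
- vary **position**: group per (stand, date), K up to 3;
- **position vs full-sun**: each canopy cell against its date's open-area
  reference (the three open recordings of a date are collapsed to their
  mean by default; a single labelled recording can be selected instead);
- **bivariate position pairs**: shade~semi-shade, semi-shade~sunfleck,
  shade~sunfleck per (stand, date).

Groups with fewer than two available levels are skipped with a notice.
Pen transforms are computed once per cell and thickness and shared across
layouts (`factor_hierarchy`), which keeps the full-design analysis at a
fraction of a second per replicate survey; the behavioural tests use 20
replicate surveys for the factor hierarchy and 50 curve pairs for the
thickness trend, sizes at which both effects are unambiguous.

Summary optics use trapezoid quadrature on the native grid with the band
edges included exactly by linear interpolation: PAR integrates 400–700 nm,
R:FR divides the integral over [655, 665] nm by the one over
[725, 735] nm (an all-zero far-red band makes the ratio undefined and
raises), and the curve maximum is taken over the analysis window.

## Design notes

- The association subset property holds in one direction only: when the
  K-variate intersection is non-empty, adding curves can only lower ρ.
  A useful corollary checked in the tests: three pairwise comparisons can
  be positive-looking while the trivariate measure is negative — but note
  that three intervals on a line cannot *all* overlap pairwise without a
  common point (Helly's theorem in one dimension), so a negative
  trivariate ρ always implies at least one negative pair.
- scikit-learn estimator wrappers exist for the two genuinely
  transform-shaped operations (row-wise normalization, row-wise pen
  transform); the association statistic and the grouped survey procedure
  are not fit/predict-shaped and remain functions over curve containers.
- File formats are plain CSV (UTF-8, "." decimals, header required), long
  format with one row per wavelength; round-trips are lossless because
  floats are written at full repr precision and parsed with the
  round-trip parser. There is no reader for raw instrument files; a
  converter to the documented CSV layout is the adapter point.

## Known limitations

- No statistical inference is attached to association values; the measure
  is descriptive.
- No smoothing, interpolation or wavelet machinery: curves to be compared
  must already share a grid.
- The truncate edge rule biases the last ~τ nm of an association curve
  toward degenerate short-window behaviour; use `edge="restrict"` when
  that margin matters more than a common grid.
- The unweighted wavelength mean treats grid points, not wavelengths,
  equally; on strongly irregular grids prefer the trapezoid mode.
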