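# thickpen

Multi-scale comparison of curves with a thick pen, applied to solar
spectral irradiance in forest understoreys.

A spectrum measured under a canopy is a curve with rough, fine-scale
content (Fraunhofer lines, sensor noise) superimposed on smooth, trend-like
structure (the solar continuum filtered by foliage). Classical summaries —
PAR, the R:FR ratio — integrate that structure away. This package instead
compares whole curves scale by scale:

- **Thick pen transform (TPT).** Drawing a curve X with a square pen of
  thickness τ traces a band whose boundaries at wavelength λ are the
  running extrema over the window `[λ, λ + τ]`:

      L_λ^τ(X) = min{ X_l : λ ≤ l ≤ λ + τ },
      U_λ^τ(X) = max{ X_l : λ ≤ l ≤ λ + τ }.

  Window membership is decided by wavelength value, so non-equispaced
  grids need no interpolation. Small τ outlines rough features, large τ
  only the trend. The TPT is the collection of (L, U) pairs over a
  thickness set T = {τ₁, …, τₙ}.

- **Thick pen measure of association (TPMA).** For K ≥ 2 curves,
  normalized to `[0, 1]` so shapes rather than amplitudes are compared,
  the pens mark K vertical intervals at each wavelength, and

      ρ_λ^τ = ( min_k U_λ^τ(k) − max_k L_λ^τ(k) )
              / ( max_k U_λ^τ(k) − min_k L_λ^τ(k) ) ∈ (−1, 1].

  Positive ρ is the intersection-over-union of the K intervals; negative
  ρ is minus the gap over the spanning interval. Its wavelength average
  ρ̄^τ is a one-number similarity per scale.

The package also provides a synthetic generator of understorey solar
spectra (five stands × three spring dates × shade / semi-shade / sunfleck
positions, plus open-area full-sun references, on a 1,091-point
non-equispaced grid over 300–800 nm) and the survey pipeline built on it:
screening of saturated or UV-inaccurate recordings, hierarchical
averaging, grouped comparisons varying one factor at a time, and the
summary optics PAR, R:FR and per-curve maxima. It is intended for
ecologists and statisticians analysing spectroradiometer surveys, and for
anyone needing an interpretable multi-scale similarity measure for curves
on irregular grids.

## Worked example

Three positions in one stand on one date, compared at three scales:

```python
import dataclasses
import thickpen as tp

scenario = tp.SpectrumScenario(stand="BetulaOld", date="2015-05-22", seed=1)
grid = tp.make_grid(scenario)
curves = [
    tp.simulate_spectrum(
        dataclasses.replace(
            scenario, position=p,
            seed=tp.simulate.cell_seed(1, "BetulaOld", scenario.date, p),
        ),
        grid=grid,
    )
    for p in ("shade", "semi-shade", "sunfleck")
]
rho, mean = tp.associate(curves, window=(300, 800))
for tau in (15.0, 40.0, 80.0):
    print(f"tau = {tau:4.0f} nm   mean TPMA = {mean[tau]: .3f}")
```

```
tau =   15 nm   mean TPMA = -0.573
tau =   40 nm   mean TPMA = -0.333
tau =   80 nm   mean TPMA = -0.120
```

The trivariate mean TPMA is negative at every scale: the normalized shade,
semi-shade and sunfleck spectra are dissimilar, because canopy shade
depletes the 400–690 nm region relative to the far-red. The association
rises with τ — at coarse scales the shapes share more structure than their
fine-scale roughness suggests.

The same analysis from the shell, over the full synthetic design:

```sh
thickpen simulate --seed 1 --out design.csv
thickpen compare --in design.csv --vary position --out rho.csv --summary summary.csv
```

`summary.csv` holds one `mean_rho` per (date, stand, τ) group; the
BetulaOld / 22 May row at τ = 80 nm reads `-0.120091`, matching the
library call above. Varying position gives the lowest association (grand
mean −0.376 over all groups and thicknesses), varying stand an
intermediate one, and varying date within sunflecks the highest — position
shapes the understorey spectrum most, stand identity less, date least.

Other subcommands: `thickpen transform` (pen-boundary tables),
`thickpen associate` (one K-variate association), `thickpen plot`
(ribbon / overlap / mean-TPMA figures). Library users can also compose the
scikit-learn transformers `CurveNormalizer` and `ThickPenTransform` in a
`Pipeline` over arrays of curves sharing one grid.

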