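# fiberbloom

Quantitative analysis of additive **blooming** from cylindrical polymer
fibers: the migration of a dissolved additive to the fiber surface by
Fickian diffusion, followed by surface crystallization. The reference
system is ROY (5-methyl-2-[(2-nitrophenyl)amino]thiophene-3-carbonitrile)
in polyethylene — a famously polymorphic compound whose red/orange/yellow
crystals make surface crystallization directly visible, serving as a proxy
for insecticide blooming on long-lasting insecticidal bed nets.

The package is aimed at materials chemists characterizing controlled- or
delayed-release fibers. It covers both halves of that workflow:

**Release kinetics.** Transport in an infinite cylinder of radius *R* is
modeled by

```
∂C/∂t = D (∂²C/∂r² + (1/r) ∂C/∂r),     C(r, 0) = C₀,
```

with a surface-evaporation (Robin) boundary condition
`−D ∂C/∂r = α (C_s − C_s,eq)` at *r = R*; surface crystals act as a
perfect sink so `C_s,eq ≈ 0`. In dimensionless time `τ = Dt/R²` and with
`η = αR/D`, the released fraction is the eigenfunction series

```
w(τ) = 1 − Σₙ 4η² exp(−βₙ²τ) / (βₙ²(βₙ² + η²)),    βₙ J₁(βₙ) = η J₀(βₙ),
```

collapsing for `η → ∞` (diffusion-limited transport) to
`w(τ) = 1 − Σₙ (4/βₙ²) exp(−βₙ²τ)` with βₙ the zeros of J₀, and to
`w ≈ (4/√π)√τ − τ` at short times. The package fits measured release
curves for the log–log power-law exponent (≈0.5 early, drifting to
≈0.44–0.45 over the practically fitted range *w* < 0.85) and for the
diffusion coefficient *D*, converting raw UV–vis absorbances to released
fractions via the Beer–Lambert law on the way.

**Polymorph identification.** Surface crystals are classified from the
Raman nitrile-stretch position ν_CN (with color and habit as
disambiguating attributes, since several yellow forms share ν_CN values)
and, independently, from 3D-electron-diffraction unit cells matched
against a reference library after Niggli reduction.

## Worked example

```python
import numpy as np
from fiberbloom import (FiberGeometry, TransportParameters, predict_curve,
                        fit_power_law, fit_diffusion_coefficient)

geometry = FiberGeometry(radius_cm=0.03)            # 0.6 mm diameter fiber
params = TransportParameters(diffusion_coeff_cm2_s=3.5e-11,
                             initial_conc_frac=0.01)  # 1 wt% loading
times = np.array([1, 2, 4, 8, 16, 32, 64, 125], float) * 86400.0  # days -> s

curve = predict_curve(params, geometry, times)
print(curve.fractions.round(3))
# [0.127 0.178 0.248 0.342 0.467 0.624 0.8   0.939]

print(fit_power_law(curve).exponent)                  # 0.4458
print(fit_diffusion_coefficient(curve, geometry).diffusion_coeff_cm2_s)  # 3.5e-11
```

At these conditions roughly 80% of the additive has bloomed after ~64–125
days; the power-law exponent over the fitted range (the last point at
w = 0.939 is excluded by the w < 0.85 rule) is 0.446 — below the ideal 0.5
because the eigenseries bends once release is substantial — and the
diffusion fit recovers the generating D exactly on noiseless data.

The numbered drivers under `analysis/` run the full narrative on synthetic
data and write their tables to `results/`:

```
python analysis/01_simulate_release.py     # noisy release observations
python analysis/02_fit_release.py          # exponent 0.440, D = 3.33e-11 cm²/s (seed 42)
python analysis/03_classify_crystals.py    # 33 crystals -> 29 ON, 2 Y, 2 R
python analysis/04_match_cells.py          # needle cell -> ON (QAXMEH54), 100/100 recovery
```

A `fiberbloom` console script exposes the same stages
(`simulate`, `bloom-fit`, `classify`, `cell-match`) for file-based use.

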