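# celltex

Cellulose crystal **texture** in plant primary cell walls from
grazing-incidence wide-angle X-ray scattering (GIWAXS).

Primary cell walls of onion epidermis, Arabidopsis hypocotyls and moss
phyllids scatter anisotropically in grazing incidence: out-of-plane arcs
from cellulose Iβ crystallites whose (110)/(1̄10) and (200) planes stack
preferentially parallel to the wall plane, and sharp in-plane rings from
epicuticular wax (d = 4.13 / 3.73 Å). Quantifying that preferred
orientation requires assembling a complete χ-pole figure — the intensity
of a reflection versus the polar angle χ from the substrate normal — from
two measurements, because a flat detector cannot sample crystallites lying
nearly parallel to the substrate (the *missing wedge*): a GIWAXS frame
covers |χ| ≥ 7.5°, and a specular rocking scan fills |χ| < 30°.

`celltex` implements that analysis end to end, for real detector frames or
for synthetic ones rendered by its own forward model:

- **X-ray optics** — λ = hc/E, electron density ρₑ = ρN_A Σwᵢ Zᵢ/Aᵢ,
  critical angle θ_c = √(2δ) with δ = rₑλ²ρₑ/2π, penetration depth
  Λ = λ / (4π Im√(α² − θ_c² + 2iβ)), and the exact detector → (q, χ)
  map with Ewald-sphere curvature and missing-wedge masking
  (χ_min = arcsin(q/2k) − α_i).
- **Cellulose Iβ crystallography** — d-spacings from the triclinic
  reciprocal metric tensor (monoclinic cell a = 7.784, b = 8.201,
  c = 10.38 Å, γ = 96.5°), geometric peak lists, Scherrer broadening
  Δq = 2πK/L, and simulated 1D powder patterns.
- **Synthetic scattering** — scenes composed of textured phases
  (Gaussian out-of-plane, in-plane, isotropic orientation densities
  normalized on the sin χ hemisphere measure), an amorphous halo and flat
  background, rendered as GIWAXS frames, rocking series and transmission
  frames with Poisson noise.
- **Reduction** — sector and azimuthal (cake) integration, GISAXS line
  cuts, χ-resolved local background subtraction.
- **Pole figures & metrics** — branch stitching with a scale factor
  matched at χ = ±7.5°, the oriented fraction
  ∫₀^χ₀ I(χ) sin χ dχ / ∫₀^90 I(χ) sin χ dχ, distribution FWHM, and the
  Segal crystallinity index CI = 100·(I₂₀₀ − I_am)/I₂₀₀.

## Worked example

Optics of the model cell wall (anhydroglucose at 1.5 g/cm³):

```sh
$ celltex optics --energy 10 --energy 12.7
electron density: 0.4791 e/A^3
E = 10 keV: lambda = 1.23984 A, theta_c = 0.1473 deg, depth(0.15 deg) = 0.826 um
E = 12.7 keV: lambda = 0.97625 A, theta_c = 0.1160 deg, depth(0.15 deg) = 5.4 um
```

The critical angles are the working points of grazing-incidence
experiments on cell walls: the beam is kept just above θ_c so that a
micrometer-scale depth of the wall scatters.

Full synthetic pipeline (render → reduce → stitch → metrics):

```python
from celltex.pipeline import RunConfig, run_pipeline

record = run_pipeline(RunConfig.from_dict({"seed": 1, "outdir": "demo"}))
print(record.metrics)
```

```
{'oriented_fraction_sin': 0.6447, 'oriented_fraction_flat': 0.8544,
 'chi0_deg': 34.0, 'texture_fwhm_deg': 48.32,
 'segal_ci_percent': 88.66, 'stitch_scale_factor': 10.96}
```

This simulates the "unextracted" specimen (Gaussian out-of-plane cellulose
texture with σ = 20°, in-plane wax, amorphous halo), builds the stitched
χ-pole figure of the 110 band (q = 1.15 ± 0.16 Å⁻¹) from one GIWAXS frame
plus an 11-frame rocking series, and reports: the fraction of (110)/(1̄10)
plane normals within ±34° of the wall normal under both hemisphere
(sin χ) and flat weightings, the FWHM of the orientation distribution
(48.3° ≈ 2.355·σ for the injected σ = 20°), the Segal crystallinity of the
out-of-plane 1D profile, and the GIWAXS→rocking stitch scale. All frames,
1D profiles, the pole-figure CSV and a machine-readable run record land in
`demo/`.

The same run is available from the shell:
`celltex run --config config.yaml --seed 1 --outdir demo`.

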