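# Methods

This note documents the models, conventions and numerical choices behind
`celltex`, and what the synthetic-data tests do and do not demonstrate
about real measurements.

## Geometry and reciprocal-space mapping

The laboratory frame puts the incident beam along +y and the detector
plane perpendicular to it at distance D; pixel centers sit at integer
indices with row 0 at the image top, and an orientation flag declares
which image axis points away from the substrate. The sample surface is
tilted by the incidence angle α_i against the beam, normal
n = (0, −sin α_i, cos α_i), so the specular exit direction has χ = 0.
For every pixel the scattered unit vector is formed exactly — no
small-angle approximation anywhere — and q = k(k̂_f − k̂_i) is decomposed
into q·n (out of plane) and the in-plane remainder; χ = atan2(|q_ip|, q·n)
in degrees, signed by the horizontal pixel offset, χ = 0 along the
substrate normal and ±90° in plane.

This exact construction contains the Ewald-sphere curvature that 2D
grazing-incidence images must be corrected for: a pixel on the vertical
axis at scattering angle 2θ probes plane normals tilted by θ − α_i, not 0.
Consequently the *missing wedge* χ_min(q) = arcsin(q/2k) − α_i (floored at
0) emerges from the map itself; the map's mask additionally rejects the
direct beam and pixels below the sample horizon. Refraction shifts near
the critical angle are ignored — at q ≥ 0.9 Å⁻¹ they are far below a bin
width.

Per-pixel solid-angle weights (cos³ of the pixel's off-axis angle) are
carried in the map and used as weights in per-bin means, which preserves
constants (a flat frame reduces to a flat profile).

## X-ray optics

Wavelength λ = 12.3984 keV·Å / E. Electron density
ρₑ = ρ N_A Σ wᵢZᵢ/Aᵢ; the model cell-wall material is anhydroglucose
(C₆H₁₀O₅) at 1.5 g/cm³ — cellulose, pectin and hemicellulose have
near-identical stoichiometry and density, so one average composition
suffices for optics. Critical angle θ_c = √(2δ), δ = rₑλ²ρₑ/2π. At 10 and
12.7 keV this gives 0.147° and 0.116°.

Penetration depth uses Λ = λ / (4π Im√(α² − θ_c² + 2iβ)) with
β = µλ/4π. Two 1/e conventions exist in the literature; both are
implemented behind a flag, and the **intensity**-1/e definition is the
default (its absorption-dominated limit is sin α/µ; the amplitude
convention is exactly twice it). Published depth figures for cell walls
are sensitive to both the convention and the attenuation data, so the
package treats them as order-of-magnitude quantities. Mass attenuation
coefficients for H, C, N, O are embedded as a small static table on an
8–15 keV grid (NIST-style values) and interpolated log-log; per-element
µ/ρ values can be supplied explicitly to override the table.

## Cellulose Iβ and wax crystallography

d-spacings come from the general triclinic reciprocal metric tensor,
1/d² = hᵀG*h, with the monoclinic cellulose Iβ preset
(a = 7.784, b = 8.201, c = 10.38 Å, γ = 96.5°). The equatorial
reflections land at q = 1.0549, 1.1817 and 1.6248 Å⁻¹. Which member of
the 110 pair carries the bar depends on the sign convention of γ, which
varies across the literature; the package therefore labels the pair with
q_low/q_high roles and never asserts the assignment. Peak lists are
geometric (symmetry-reduced index enumeration, Friedel pairs collapsed,
coincident spacings merged within 1 µÅ); no structure factors are
computed — relative peak weights are user inputs, and Rietveld refinement
is out of scope.

Size broadening is the q-space Scherrer form Δq(FWHM) = 2πK/L with
K = 0.9 by default. Peak profiles are Gaussian by default (pseudo-Voigt
optional); no profile function is canonical for cell-wall cellulose, and
the Gaussian keeps areas exactly additive. At the primary-wall coherence
length L = 30 Å (the ~3 nm microfibril), Δq ≈ 0.19 Å⁻¹ exceeds the
0.13 Å⁻¹ splitting of the 110 pair, merging it into the familiar single
broad peak near 1.15 Å⁻¹; at L = 300 Å the pair resolves. The wax phase
is a two-reflection set at d = 4.13 and 3.73 Å with a 150 Å default
coherence length, much sharper than cellulose.

## Synthetic scenes

A scene is a sum of crystalline phases (peak set × orientation texture ×
scale), an isotropic amorphous halo, and a flat background; expected
counts at a pixel are
`exposure · Σ scale·R(q)·f(χ) + halo(q) + background`, with R the
unit-area radial profile and f the orientation density, and Poisson noise
drawn per pixel from one explicit integer seed. Orientation densities are
normalized on the hemisphere with the sin χ measure, so an injected
"fraction within ±χ₀" has an unambiguous analytic value — the quantity the
round-trip tests recover. The nominally delta-like in-plane wax texture is
rendered as a 4°-wide Gaussian at χ = 90°.

Rocking frames are rendered with the same exact map evaluated at the
rocked incidence θ_s (rather than the first-order mapping
χ ≈ (θ_s − θ_B) + detector polar offset, which the exact map reproduces
in the small-tilt limit): a vertical pixel at the Bragg ring then probes
crystallite tilt |θ_B − θ_s| exactly, and summing a series spanning
θ_B ± 0.75° samples the orientation density near χ = 0 and closes the
missing wedge.

Specimen presets mirror the chemical treatments used on onion epidermis:
`unextracted` (textured cellulose + in-plane wax + halo), `driselase`
(wax + halo — polysaccharides digested), `chloroform` (cellulose + halo —
wax dissolved), `ground` and `stem_segment4` (isotropic cellulose + halo).
The halo parameterization (center 1.4 Å⁻¹, FWHM 0.7 Å⁻¹) is a synthetic
stand-in — no experimental parameterization of the amorphous background
of digested walls exists to copy — and the default texture width σ = 20°
is a configurable choice, not a fitted value.

The default detector is 512×512 pixels of 0.172 mm at 120 mm distance
with the beam center near the bottom edge. The short distance is chosen
so that, at 10 keV, the in-plane wax reflections (q ≈ 1.52/1.68 Å⁻¹)
fall on the detector horizontally while the vertical reach extends to
q ≈ 3.1 Å⁻¹ for the rocking background band; a longer camera would push
the wax rings off the chip at this pixel count.

What the synthetic model deliberately omits: detector point-spread,
polarization, air scattering, refraction distortion, coherent speckle,
paracrystalline disorder, and any structure-factor intensities. Passing
round trips therefore validate the *geometry, reduction and stitching
arithmetic*, not the photometric realism of real beamline frames.

## Reduction conventions

Pixels are assigned to the nearest bin center (no pyFAI-style pixel
splitting); the per-bin statistic is a (solid-angle-weighted) mean rather
than a sum, so sectors of different areas are directly comparable. Bins
receiving no pixels are flagged (NaN, n_pixels = 0), never zero-filled.
Count conservation holds exactly for the unweighted 2D cake: the sum of
cell mean × cell count reproduces the total masked counts.

Azimuthal band profiles support q sub-slicing: the band is split into
(default 8) q slices averaged per (slice, χ) cell and then combined with
equal slice weight. On a flat detector the pixel density in (q, χ) piles
up against the missing-wedge rim, which otherwise skews band averages in
the bins just outside the wedge — precisely where the pole-figure branches
are scaled to each other.

Background correction subtracts a χ-resolved local background band
(onion GIWAXS 0.5–0.6 Å⁻¹, rocking 2.0–2.2 Å⁻¹; Arabidopsis and moss
bands are registered too) from the signal band at each χ. Negative
differences are retained — clipping would bias the estimator — and
counted in the output metadata. Because the background band sits at a
different scattering angle, its own missing wedge can blank a few bins
near χ = 0 that the signal band does cover; those background bins are
filled by linear interpolation in χ (the background is smooth there), and
the number of filled bins is recorded.

## Pole-figure assembly and metrics

The GIWAXS branch is the background-corrected azimuthal profile of the
110 band (1.15 ± 0.16 Å⁻¹) restricted to |χ| ≥ 7.5°; the rocking branch
is the same reduction of the summed rocking series restricted to
|χ| < 30°, using the map at the central rocking angle. The stitch scale
s = mean(rocking at ±7.5°)/mean(GIWAXS at ±7.5°) — interpolated at the
match points, both signed lobes averaged, a plain ratio rather than a
fit — multiplies the GIWAXS branch. In the 7.5°–30° overlap the GIWAXS
branch is kept (better off-specular statistics) and the rocking branch is
used only inside |χ| < 7.5°; where the preferred branch is missing the
other fills in, labeled `overlap`.

The oriented fraction integrates the folded |χ| trace with sin χ
(hemisphere) weighting by default; flat weighting is exposed because
height-based conventions also appear in practice, and the choice is
recorded in output metadata. Folding averages the two signed lobes after
linear interpolation onto a 0.01° grid (trapezoidal quadrature error
≈ 10⁻⁹ relative, so the uniform-distribution closed forms 1 − cos χ₀ and
χ₀/90 are met to 10⁻⁶); a left/right asymmetry above 20% raises a
warning. The distribution FWHM is read off the folded trace by linear
interpolation; an isotropic input returns NaN (a flagged result) rather
than raising.

The Segal crystallinity index is computed in q-space,
CI = 100·(I₂₀₀ − I_am)/I₂₀₀ with I₂₀₀ the maximum in 1.40–1.70 Å⁻¹ and
I_am the minimum in 1.10–1.40 Å⁻¹ — a wavelength-independent
transcription of the classical Cu-Kα 2θ windows. Height-based CI is a
comparative proxy, not an absolute crystallinity.

## Validation strategy and problem sizes

The vectorized (q, χ) map is checked against an independent per-pixel
scalar-trigonometry oracle on a 32×32 detector to 10⁻¹⁰. Texture round
trips inject Gaussian densities (σ = 10°, 20°, 35°) with the signal band
scaled to ≈ 1.3×10⁶ counts, run the full render → reduce → stitch →
integrate chain over six noise replicates, and require agreement with the
analytic injected fraction within three Monte-Carlo standard errors of
the replicate mean. Segal monotonicity is checked over five crystalline
scales (noiseless). Specimen-contrast checks use single noisy 512×512
frames. These sizes keep the whole suite under ~1 minute on one CPU while
leaving per-bin Poisson errors at the percent level, large enough that
the round trips are statistically meaningful.

## Known limitations

- The analysis assumes fiber texture (in-plane isotropy); no full
  orientation-distribution-function inversion is attempted.
- The missing-wedge rule ignores refraction near θ_c; below
  q ≈ 0.3 Å⁻¹ in grazing geometry the map should not be trusted to the
  bin level.
- Penetration depths inherit the uncertainty of the embedded attenuation
  table (~ a few percent) and the 1/e convention ambiguity (factor 2).
- The renderer's rocking model sums incoherently over sample angles; it
  does not model the finite rocking speed or shutter effects of a real
  scan.
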