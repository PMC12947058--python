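# Methods

## The compound-Poisson specific-energy model

The engine models the specific energy of a micron-scale voxel at
absorbed dose D as a compound Poisson sum

    Z = Σ_{i=1}^{N} z1_i,    N ~ Poisson(λ),    z1_i iid ≥ 0,

where `z1` is the single-event specific energy (one charged-particle
traversal or cluster of depositions) with mean `μ₁` and raw second
moment `m₂`, and the event frequency is tied to dose by the identity
`E[Z] = D`, i.e. `λ = D/μ₁`.  This structure yields exact expressions
used throughout:

| quantity | expression |
|---|---|
| zero fraction `f_{z=0}` | `exp(−λ)` |
| spread `σ_z/z̄` | `sqrt(m₂/(D·μ₁))` |
| Laplace functional `E[e^{−αZ}]` | `exp(−λ(1 − M₁(α)))` |

with `M₁(α) = E[e^{−α z1}]`.  The spread obeys an exact `D^{−1/2}` law
for a fixed event spectrum, and the `>10×` spread ratio between
0.003 and 0.5 Gy follows as `sqrt(0.5/0.003) ≈ 12.9` independent of any
model detail.

**Assumptions.** Event counts are Poisson (independent traversals — no
beam time structure or dead time), event sizes are iid and independent
of N, and the event spectrum does not change with dose (valid for a
fixed beam quality; dose is varied only through fluence).  Voxels are
treated as exchangeable: spatial correlation between neighbouring
voxels sharing an electron track is not modelled, so maps reproduce
marginal statistics, not two-point correlations.

**Calibration.** A single anchor row `(D₀, f_{z=0}, σ_z/z̄)` at a low
dose identifies both moments: `λ = −ln f_{z=0}`, `μ₁ = D₀/λ`,
`m₂ = (σ_z/z̄)²·λ·μ₁²`.  The two built-in anchors are the published
0.003 Gy rows for the two voxel presets: vx-sm (0.8862×0.8862×6 μm³,
the confocal Raman sampling volume; 0.65 / 343 %) and vx-lg
(1.436×1.436×9.4 μm³, the mean LiPCDA monomer crystal size;
0.35 / 205 %).  Calibration requires `f_{z=0} > 0`; at doses where the
printed zero fraction is 0 the rate is unidentifiable and the anchor
must come from a lower dose.

**Event-spectrum family.** The default family is gamma: two parameters
match `(μ₁, m₂)` exactly, the Laplace transform is closed form
`(1+αθ)^{−k}`, and Poisson sums of gammas stay gamma, so a field of n
voxels needs a single vectorized gamma draw.  The vx-sm anchor gives
`k ≈ 0.25` — a heavily right-skewed spectrum, qualitatively consistent
with chord-length-dominated single events.  Delta, exponential,
lognormal (Laplace transform by adaptive quadrature, relative tolerance
1e-8) and empirical families are provided; note a gamma spectrum has
mass arbitrarily close to z = 0, so `α → ∞` limits are approached as a
power law rather than exponentially.

**Geometry.** Mean chord length uses Cauchy's `4V/S` for convex bodies
(0.8253 μm and 1.3341 μm for the presets).  Active-layer density
defaults to 1.2 g/cm³ and is configurable.

**Sampling.** Counter-based Philox streams keyed by the user seed; one
Poisson draw and one event-sum draw per voxel (exact marginals, no
approximation).  Fields are reproducible for a fixed seed and shape.

## The one-hit response model

A sensitive volume (a LiPCDA monomer crystal) is activated by a single
effective hit; with saturation parameter α (hit probability per unit
specific energy), the affected fraction is
`R_theory(D) = 1 − ∫ e^{−αz} f(z;D) dz`, and the measured response is
`R(D) = m·R_theory(D) + C` with a modality-specific scaling m and
radiation-independent offset C (intrinsic polymerization).  At D = 0
the distribution is a unit point mass at z = 0 and R = C exactly.

The integral is evaluated either against an explicit f(z;D) histogram
(zero spike separated from a 200-bin log-spaced density, midpoint rule;
mass conservation enforced to 1e-6 for inputs, achieved to 1e-12 by the
histogram builder) or via the closed-form Laplace functional for
compound-Poisson fields; the two routes agree within histogram
resolution (≤0.5 % at α ≤ 10 Gy⁻¹, 400 bins).

**Calibration.** Unweighted least squares by default (optional 1/σ²
weights), Levenberg–Marquardt, positivity of m and α enforced by
fitting (ln m, ln α, C).  Default start: C₀ = response at the lowest
dose, m₀ = response range, α₀ = 1 Gy⁻¹.  Per-dose percentage
differences use the measured value as denominator.  Calibration
histograms default to vx-lg geometry (crystal-sized sensitive volumes).

**Identifiability note.** On the 15-dose design with α ≈ 1 Gy⁻¹ the
three parameters are strongly collinear (the response is near-linear up
to 0.5 Gy).  With additive noise of σ = 2 % of the maximum response,
the Cramér–Rao bound for α is a relative SD of ≈0.31 (OD parameters),
i.e. a best-possible median |α̂−α|/α of ≈21 %; the implemented
estimator attains this bound (efficiency is what the test suite
asserts).  Noise-free curves are recovered to well beyond 4 significant
figures.

## Measurement-side chains

**OD.** `OD = log₁₀(I₀/I)` on 16-bit transmission readings (red channel
by convention); 3×3 block averaging takes 300 dpi to 100 dpi ("groups
of three adjacent pixels" read two-dimensionally — a 1-D reading would
not reproduce the dpi reduction).  Block averaging precedes the log by
default (averaging transmissions); the opposite order is available and
differs only at second order in the OD variation.  Offset correction
subtracts the 0 Gy map pixel-by-pixel, nulling the corrected control
exactly.

**Raman.** Chain order: despike → repeat-average → SNIP baseline →
vector normalize → band ratio.  Despiking replaces entries deviating
from the pixel-wise median spectrum by more than 8 robust SDs, where
the scale is pooled per pixel (1.4826 × median over channels of the
per-channel MAD across repeats) — stable with 5 repeats, ~0 false
positives on clean spectra, ≥99 % recall on 10σ spikes.  This is a
documented stand-in for an unspecified "modified cosmic-ray algorithm".
SNIP uses the decreasing-window variant (default 40 iterations ≈
160 cm⁻¹ half-window at 4 cm⁻¹ sampling) and clips in intensity space:
the classic log-log-sqrt compression is available (`lls=True`) but off
by default because its concavity makes straight or gently curved
baselines self-clip at wide windows (measured ~35 % bias on a linear
baseline), whereas intensity-space clipping leaves linear and convex
backgrounds exactly untouched and recovers the baseline under a
20 cm⁻¹-FWHM peak to <5 %.  Edges are left unclipped; film bands
(~10 cm⁻¹ FWHM) are far narrower than the window, so the near-edge
2260 cm⁻¹ band is still baselined correctly.  The dose response is the
1445 cm⁻¹ band area over the 2260 cm⁻¹ internal-standard band area
(both 14 cm⁻¹ wide, trapezoidal with interpolated band edges); the
ratio is invariant to laser-power drift and to vector normalization.
The instrument sensitivity correction is supported only as a
user-supplied per-channel multiplicative curve.

## The synthetic-data generator

The generator defines the study conditions: the 15-dose series 0.003,
0.005, 0.007, 0.01, 0.02, 0.03, 0.04, 0.05, 0.07, 0.09, 0.1, 0.2, 0.3,
0.4, 0.5 Gy plus a 0 Gy control (a second published dose list —
0.006/0.009/0.011 in place of 0.005/0.007/0.01 — is exposed as a
constant; any list is accepted).  Per-pixel response is
`s_px·m·(1−e^{−α·z_px}) + C + ε` with defaults matching the reported
fits (OD: m=0.19, α=1.2 Gy⁻¹, C=0.026; RS: m=8.6, α=1.02 Gy⁻¹,
C=1.96).  Pixel sensitivities `s_px` are lognormal with mean 1,
multiplicative on m only (crystal density varies spatially; the offset
is chemistry-wide), cv defaults 0.05 (OD) and 0.12 (RS).  Raman pixels
are single vx-sm sampling volumes; scanner pixels aggregate
`(85 μm)²·28 μm / V_voxel ≈ 10⁴` vx-lg voxels via the compound-Poisson
aggregation identity (rate ×n, event size /n).  Noise defaults: OD
0.003 OD units additive; RS channel noise 1 % of the 1445 cm⁻¹ peak
height at 0.5 Gy — free parameters chosen to resemble the reported
measurement scatter.  RS spectra carry four dose-scaled bands
(696/1086/1445/2060 cm⁻¹), the fixed 2260 cm⁻¹ reference band
(unit band area, so the noise-free 1445/2260 ratio equals the pixel
response identically), a smooth exponential baseline and
Poisson-rate cosmic spikes.  OD scans are rendered as
`I = round(I₀·10^{−R})` at 16 bits, which reproduces the generating
response within quantization (~1e-5 OD).

**What passing tests do and do not show.**  The generator reproduces
marginal Poisson statistics, the exact `D^{−1/2}` spread law, the
one-hit response surface and the internal-standard structure; it does
not emulate track-structure spatial correlation, scanner lateral
artifacts, spectrometer wavelength drift, or dose-rate effects — so
agreement here validates the analysis chain, not those physical
effects.  Its per-pixel Raman variability is dose-dependent (from ~5 %
at 0.003 Gy up to ~17 % near 0.1–0.3 Gy, inside the reported 8.9–17 %
band at 0.4–0.5 Gy), whereas the reported variability appears
dose-independent; reproducing that would require a larger
dose-independent inhomogeneity and a smaller Poisson term than the
vx-sm single-voxel model implies.  Offset-corrected relative-SD trends
fitted with a power law give exactly −1/2 for the pure engine and
flatten monotonically toward 0 as the configured film inhomogeneity
grows — the mechanism proposed for measured trends sitting above the
microdosimetric expectation at high dose.

## Numerical choices and degenerate inputs

* Population (not sample) SD in summaries — microdosimetric convention;
  negligible difference at the 10⁴–10⁶ voxel counts used.
* All-zero fields: spread is reported as NaN with a `spread_defined`
  flag; histograms degenerate to a unit zero spike.
* Log-binned histograms span [min positive z, max z]; a single distinct
  positive value gets one ±0.1 % bin.
* 10×10 grid sampling uses rounded `linspace` indices over the ROI
  (0, 11, ..., 99 across 100 voxels).
* Moment-matching degenerates to a delta spectrum when `m₂ ≤ μ₁²`.
* Problem sizes: property tests sample 10⁶-voxel fields; fit round
  trips use 2×10⁴–10⁵ voxels per dose, which keeps the full suite under
  a minute while leaving sampling error far below the asserted
  tolerances.

## Known limitations

* No radiation transport: the engine matches the statistical structure
  of scored output only; anchor moments inherit any bias of the
  published summaries.  (The published large-voxel zero fractions at
  0.006 Gy deviate from pure Poisson scaling of the 0.003 Gy anchor —
  0.099 vs 0.35² = 0.1225; the engine follows the Poisson identity and
  the anchor.)
* One anchor per geometry: dose-dependence of the event spectrum (beam
  hardening with depth, spectral changes) is outside the model.
* The despiking and SNIP parameter defaults target film spectra on the
  614–2313 cm⁻¹ axis at 4 cm⁻¹ sampling; other instruments may need
  different windows.
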