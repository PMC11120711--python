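# Methods

## Forward model

The phantom is a laterally and axially extended two-layer medium: a silicone
slab of pre-calibrated Young's modulus `E_ref` (default 100 kPa, default
thickness 300 um) resting on tissue with an arbitrary modulus field
`E(x, z)` (scalar, two-block, or any vectorized callable). Mechanics follow
a uniform-stress column approximation: at surface pressure `P`, every layer
carries uniaxial strain `ε = P / E`, and axial displacement is the integral
of strain from the fixed bottom boundary. This is exactly the assumption
under which the silicone-calibrated modulus ratio is valid (equal stress in
silicone and tissue), so the forward model and the estimator share their
idealization deliberately; lateral expansion, friction, and viscoelasticity
are not modeled. An optional stress-stiffening toggle
(`nonlinear_beta_per_kpa`, tangent modulus `E0 (1 + βP)`) exists solely to
demonstrate what pressure standardization buys.

Speckle is rendered by depositing point scatterers — positions i.i.d.
uniform, complex amplitudes circular Gaussian with unit-mean intensity
(fully developed speckle; pixel amplitudes are then exactly Rayleigh) — under
a separable Gaussian PSF with FWHM equal to the stated resolutions
(axial divided by the group index n = 1.4, since the stated value is in
air). Default density is 10 scatterers per resolution cell. Optical phase
is carried per scatterer as `exp(i · 4πn/λ0 · u)`, with the envelope drawn
at the scatterer's optical depth in the probe frame; the interframe phase at
depth z therefore unwraps to `(4πn/λ0)·Δu(z)` up to a global per-frame
constant. n cancels in the stiffness ratio; only phase realism depends on
it. Additive complex white Gaussian noise is scaled to a configurable SNR
(default 25 dB). The default sweep is 21 pressure steps to 8 kPa: the
silicone phase-gradient per step (≈0.27 rad/px) is comfortably below the
aliasing limit while the sweep crosses the 4 ± 1 kPa standardization window
mid-range; the frame count and sweep depth are conventions, not claims.

Pixel pitch defaults to half the resolution (5 x 7.5 um); the axial pitch is
validated against Nyquist sampling of the resolution cell.

## Strain estimation

The interframe map is the pixelwise conjugate product `b · conj(a)`; its
argument is the wrapped phase difference. The axial phase-difference
gradient is estimated inside a sliding window by complex-vector averaging of
axial-lag products `pdm[z + L] · conj(pdm[z])`, with the argument divided by
the lag `L`. Two numerical choices matter:

- **Axial lag L = 2.** At lag 1, adjacent pixels share scatterers (the
  axial speckle correlation at one Nyquist pixel is ≈0.5), and
  same-scatterer terms carry zero phase difference, biasing the gradient
  toward zero by tens of percent. Lag 2 is the first essentially
  decorrelated lag at this sampling; the residual bias term is < 1%.
- **Bulk-displacement compensation.** Compression moves deep speckle toward
  the probe by the integrated compaction of everything above it (micrometres
  per step), decorrelating the pair even at small local strain. A first
  gradient pass is integrated axially into an apparent shift profile,
  frame B is resampled along depth (cubic interpolation, shift clipped to
  ±3 px, lateral smoothing over the window width), and the gradient is
  re-estimated. This halves the per-pixel strain noise; it is skipped when
  the estimated shift is below 0.1 px.

Strain converts from the gradient as `ε = −g · λ0 / (4πn · Δz)`; the sign
convention makes compression positive (under compression the interframe
phase decreases with depth in the probe frame). The gradient between rows
`z` and `z + L` is attributed to the centre of the span. Validity is the
normalized vector magnitude of the windowed lag products (coherence) against
a floor of 0.3. The default 8 x 8 px window brings the output resolution to
~40-60 um, about four times coarser than the frames; per-pixel relative
accuracy at the 5% level requires roughly a 20 x 20 px window (or
equivalent ROI averaging), which the tests make explicit.

Cumulative strain is the running sum of consecutive-pair estimates, keeping
every pair inside the unambiguous phase range regardless of total
compression. A pair whose windowed gradient (95th percentile over valid
pixels, robust to isolated noise spikes) implies more than π/2 of phase per
axial resolution cell is reported in an `AliasingError`; the remedy is a
finer pressure sweep, not unwrapping heuristics.

Measured systematic: at a soft-to-stiff interface the magnitude-weighted
window slightly favours the more coherent (stiffer, less-displaced) side,
pulling the apparent boundary ~1-2 px shallow. This is below one axial
resolution cell and does not affect block- or ROI-level statistics.

## Stiffness mapping

The reference layer is segmented from a cumulative strain map as the
laterally homogeneous high-strain top band: per column, the boundary is the
midpoint crossing between the silicone and tissue strain levels (for a
box-blurred step the midpoint crossing sits at the interface), constrained
to ±30% of the thickness hint, with a lateral coefficient-of-variation guard
and a documented flat-band fallback (with warning) when the contrast is too
low to segment.

Local pressure at sweep step k is `E_ref ×` the median cumulative silicone
strain; the standardized state is the first step entering the target window
(default 4 ± 1 kPa). Stiffness is `E = E_ref · ε_sil / ε_tissue`, with
`ε_sil` the global median over the reference mask by default (a per-column
mode exists for tilted contact; the global median is the more robust default
and the choice is recorded in the map metadata). Values are capped (default
2000 kPa) and pixels with non-positive measured tissue strain are set to the
cap and flagged: a non-positive strain means "stiffer than resolvable", and
mapping it to the cap keeps E a monotone function of strain so that ROI
medians of modulus and of strain agree under noise. The tumor-cell mask is
`E > 520 kPa`; ROI quantification is the mean over `ROI ∩ mask`, excluding
the reference layer, with the masked-pixel fraction reported and NaN when
the mask is empty.

## Synthetic cohort

The cohort fixes every categorical margin of the observed series by
construction — 54 ROIs over 46 cases (34 complex tubular / 6 mucinous / 14
solid; 8 dual-pattern cases), driver genes per pattern (KRAS 8/3/9, NRAS
1/0/0, BRAF 2/0/1), grades (33 low-grade with 10 mutant cases, 13 high-grade
with 10), case-level KRAS in 16/46, MSI in 3 high-grade cases (4 ROIs), and
one designated heterogeneous case (#21: tubular KRAS-mutant, mucinous
wild-type). Only mean ROI stiffness is sampled: normal by mutation group
(mutant 967 ± 145, wild-type 751 ± 92 kPa) — or per pattern (770 ± 164 /
968 ± 234 / 1039 ± 270 kPa) when stratified sampling is requested —
truncated by rejection at the 520 kPa floor, which is where the quantified
values live by construction of the tumor-cell mask.

What this emulates: the group means/SDs and label frequencies of the real
series. What it does not: within-ROI stiffness texture, correlation between
stiffness and grade beyond what the mutation labels induce, inter-case
variance components, or any MSI-stiffness relationship (deliberately out of
scope). Passing cohort-level tests therefore validates the statistical
machinery and the threshold logic under the published group parameters —
not the biology of any new sample.

## Statistics and classification

Group comparisons use the Mann-Whitney U test (midrank ties), exact by full
permutation when `n_a + n_b ≤ 12` without ties, otherwise the normal
approximation with continuity and tie corrections; Bonferroni adjustment
uses the number of pairwise comparisons in the family (3 for the pattern
family). The intrinsic error of the normal approximation at 5-6 per group
is about 0.02, which is exactly why the exact mode is auto-selected there.
Fisher's exact test is two-sided by the probability-mass rule (sum of
same-margin tables no more probable than the observed one); a zero margin
returns p = 1 with a warning. Both engines are validated in the test suite
against exhaustive-enumeration oracles written independently of the
implementation.

ROC curves sweep all distinct observed values plus infinite endpoints with
the strict positive rule "stiffness above threshold"; boundary equality is a
negative call. AUC is the trapezoidal area and equals the Mann-Whitney
identity `U / (n₊ n₋)` exactly, ties included. The Youden threshold
maximizes `J = sensitivity + specificity − 1`, breaking ties toward the
smallest cut and reporting the midpoint of the empirical gap; degenerate
sweeps return `J = 0` with a warning. KRAS-specific evaluation counts
NRAS/BRAF-mutant ROIs as KRAS-wild-type negatives. All reported confusion
metrics are in-sample and labelled as such. Multi-ROI cases get per-ROI
threshold calls against both fixed cut-offs and a discordance flag — the
in-silico analogue of spotting intratumoral molecular heterogeneity from the
stiffness map alone.

## Problem sizes and determinism

Image-level validations run on 0.9 x 1.2 mm phantoms (120 x 240 px, ~72k
scatterers, 21 frames) and smaller; cohort-level aggregates use 100-500
sampled cohorts. Every stochastic step takes an explicit integer seed
(numpy `default_rng`); identical (configuration, seed) pairs give
bit-identical phantoms, frames, cohorts, and reports, and each written
artifact embeds its seed and a configuration hash.

## Known limitations

- The mechanical model is 1-D per column; no lateral coupling, contact
  mechanics, or viscoelasticity, so recovery tests cannot detect errors
  that only such physics would produce.
- The estimator's interface bias (~1-2 px shallow) and the ±10% accuracy of
  block medians at the default window set the scale of what image-level
  claims the package can support.
- Published operating points (803/850/857 kPa and the 91/80/85, 90/88/89
  percentages) are in-sample quantities of the original patient series; on
  synthetic cohorts the package reproduces their distributional
  counterparts (AUC near the binormal value, Youden cut between the group
  means, fixed-cut accuracy beating morphology baselines), not the exact
  printed numbers, whose per-ROI inputs were never published.
- MSI labels are generated but no MSI-stiffness inference is implemented.
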