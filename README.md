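# coce

Compression optical coherence elastography (C-OCE) for label-free screening
of driver mutations in colorectal cancer tissue.

## The problem

Molecular testing of colorectal cancer (KRAS/NRAS/BRAF driver mutations,
microsatellite status) steers first-line therapy but is slow, expensive, and
in practice ordered only for a minority of patients. C-OCE measures tissue
stiffness at ~40-50 um resolution within minutes of excision, and mutant
tumor regions are systematically stiffer than wild-type regions
(967 ± 145 kPa vs 751 ± 92 kPa, mean ± SD). A single stiffness threshold
therefore works as a fast pre-screen: above ~800 kPa, flag the region for
targeted molecular analysis.

This package implements the full quantitative chain as reusable,
scikit-learn-style components, with a synthetic phantom and cohort generator
standing in for patient data:

1. **Forward model** (`coce.phantom`) — two-layer scatterer phantom
   (pre-calibrated 100 kPa silicone on tissue) imaged by a simulated 1310 nm
   OCT system (10 um axial / 15 um lateral resolution); uniaxial compression
   with per-layer strain ε = P/E; complex speckle frames with known ground
   truth.
2. **Strain estimation** (`coce.strain`) — the phase-gradient ("vector")
   method: axial strain from the argument of complex-vector-averaged
   axial-lag products of the interframe conjugate product, wrap-tolerant,
   with bulk-displacement compensation. `VectorStrainEstimator` is a
   sklearn transformer.
3. **Stiffness mapping** (`coce.stiffness`) — tangent Young's modulus
   `E_tissue = E_silicone · ε_silicone / ε_tissue`, formed at a standardized
   local pressure (4 ± 1 kPa, sensed by the silicone layer) so tissue
   nonlinearity does not bias comparisons; ROI statistics restricted to the
   > 520 kPa tumor-cell mask. `StiffnessMapper.fit` learns the reference
   mask and the standardized compression state.
4. **Cohort + statistics** (`coce.cohort`, `coce.stats`) — a 46-case /
   54-ROI synthetic cohort reproducing the observed morphological and
   molecular margins exactly; Mann-Whitney U with Bonferroni correction and
   two-sided Fisher's exact tests.
5. **Classification** (`coce.classify`) — ROC curves, Youden-optimal
   thresholds, confusion metrics at the fixed clinical cut-offs (803 kPa for
   any driver mutation, 850 kPa for KRAS), morphology-as-marker baselines,
   and per-case discordance reports for heterogeneous tumors.
   `StiffnessThresholdClassifier` composes with sklearn model selection.

## Worked example

```python
import coce

report = coce.run_pipeline(coce.RunConfig(seed=1))

roc = report["roc_results"]["any_driver"]
at803 = report["confusion_metrics"]["any_driver_at_fixed_803_kpa"]
print(roc["auc"], roc["youden_threshold_kpa"])
print(at803["sensitivity"], at803["specificity"], at803["accuracy"])
print(report["fisher_tests"]["grade_high_vs_low"]["p_two_sided"])
```

prints (seed 1):

```
0.9666666666666667 843.3053163761161
0.9583333333333334 0.7333333333333333 0.8333333333333334
0.007289843931931281
```

Reading: on this draw of the cohort, mean ROI stiffness separates mutant
from wild-type ROIs with AUC 0.967; the in-sample Youden-optimal threshold
is 843 kPa; the fixed 803 kPa cut detects a driver mutation with 96%
sensitivity, 73% specificity, 83% accuracy — far above the best
morphology-as-marker baseline (67%). The Fisher p-value for the association
of mutations with high-grade tumors is 0.0073; it is exact because the
label structure of the cohort is assigned, not sampled. The report also
contains group summaries (here mutant 984 ± 91 kPa vs wild-type
747 ± 84 kPa, Mann-Whitney p = 5.2e-9), the KRAS-specific task, and the
per-case heterogeneity flags — case #21's complex-tubular ROI calls
KRAS-positive while its mucinous ROI does not, mirroring true intratumoral
molecular heterogeneity.

The image-level chain is exercised the same way:

```python
chain = coce.run_image_chain(coce.RunConfig(seed=1), snr_db=None)
print(chain["block_median_kpa"], chain["achieved_pressure_kpa"])
# {'left': 611.8, 'right': 1038.9} 3.23
```

— a 600/1000 kPa two-block phantom under a 100 kPa silicone reference is
recovered within a few percent, at a silicone-sensed standardization
pressure inside the 4 ± 1 kPa window.

A thin CLI wraps the same functions:

```
coce simulate-phantom --out frames.npz
coce estimate-strain frames.npz --out strain.tiff
coce map-stiffness frames.npz --out stiffness.tiff
coce sample-cohort --out cohort.csv
coce analyze --out-dir results/
coce run-all --out-dir results/
```

## Documentation

`docs/methods.md` describes the forward model and its assumptions, the
estimator design choices (axial lag, displacement compensation, pressure
standardization), what the synthetic data does and does not emulate, and
known limitations.
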