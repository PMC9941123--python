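# wormquant

Quantitative imaging and lifespan analysis for *C. elegans* nuclear-reporter
studies under dietary restriction (DR).

## The problem

Endogenously tagged transcription-factor reporters such as DAF-16::GFP are
extremely dim — nuclear signal is comparable to the autofluorescence of lipid
droplets and gut granules.  To quantify nuclear localisation across the whole
animal, each worm is imaged as four z-stacks of 30 slices (3 µm spacing) in
two channels: green (reporter + autofluorescence) and red (autofluorescence
only).  Subtracting the red channel from the green removes the shared
autofluorescent signal, leaving nuclei as dim elliptical objects.

`wormquant` implements the full analysis chain on that design:

1. **Nuclei segmentation** (`wormquant.segmentation`) — per slice: channel
   subtraction (negatives clipped), automatic histogram thresholding (Otsu by
   default, logged per slice), morphological opening with a disc, 8-connected
   labelling, and object filtering: extent ≥ 0.50, eccentricity < 0.85,
   solidity > 0.75, area within `[A_min, A_max]` (defaults 4–120 µm²,
   "smaller than neurons / larger than intestinal cells").  Nuclei appearing
   in several slices are deduplicated: centroids within ±4 px in both row and
   col (a Chebyshev box) across slices are grouped transitively and only the
   largest-area member is kept.  The per-animal readout is the **total
   nuclear intensity** `I = Σ_nuclei Σ_pixels (green − red)`.
2. **Tissue classification** (`wormquant.classify`) — a CART-style "fine"
   decision tree (Gini impurity, ≤ 100 splits, deterministic tie-breaks) over
   three features: area, eccentricity, equivalent diameter
   `√(4·area/π)`, assigning intestine / neuron / hypodermis / muscle,
   plus per-tissue intensity aggregation.
3. **Nucleolus scoring** (`wormquant.nucleolus`) — intestinal nuclei are
   called nucleolus-*filled* or *empty* from the ratio of the mean intensity
   in a central disc (0.3 × equivalent diameter) to the mean over the
   surrounding ring; filled fractions carry binomial confidence intervals.
4. **Survival analysis** (`wormquant.survival`) — Kaplan–Meier product-limit
   curves from alive/dead/censored scoring; mean lifespan as the restricted
   mean survival time `∫₀^{t_last} S(t) dt` (equal to the arithmetic mean of
   death times when nothing is censored); mortality quantiles (earliest time
   with 50/75/90 % dead).
5. **Association analysis** (`wormquant.association`) — cumulative lifelong
   intensity `Σ_{d∈{1,4,7,10}} Ī_d`, total food availability (the integral of
   the piecewise-constant food profile from adult Day 1 to Day 11, in
   cells·day/ml, with ad libitum = 10¹⁰ OP50 cells/ml outside the DR
   exposure windows), and regime-level OLS regressions (linear and
   quadratic) of lifespan metrics on these predictors.

Because the raw microscopy and cohort data live in an external repository,
the package ships a first-class **synthetic generator**
(`wormquant.synthetic`, `wormquant.cohort`) that reproduces the statistical
structure the pipeline must handle — dim green-only ellipsoidal nuclei,
irregular dual-channel blobs, a non-monotonic DAF-16-like response surface
over (food concentration, exposure time) peaking at 10⁸ cells/ml × 12 h with
age-declining responsiveness, and lifespans linear in cumulative intensity —
with every planted object recorded as ground truth.  Every stage is therefore
testable end to end without external data.

## Worked example

```bash
python analysis/05_survival_association.py
```

simulates the full 9-regime + control study (200 animals per regime) and
prints:

```
mean lifespan ~ cumulative intensity: R^2 = 0.996, slope 0.00304 d/a.u. (generative 0.003)
  day  1 intensity alone: R^2 = 0.996
  day  4 intensity alone: R^2 = 0.996
  day  7 intensity alone: R^2 = 0.996
  day 10 intensity alone: R^2 = 0.663
  50% mortality quantile: R^2 = 0.996
  75% mortality quantile: R^2 = 0.999
  90% mortality quantile: R^2 = 0.995
mean lifespan ~ food availability (quadratic): R^2 = 0.370, vertex at 7.92e+10 cells.day/ml
```

Reading this: regime-level mean lifespan is recovered as an almost perfect
linear function of cumulative nuclear intensity (the generative slope
0.003 days per intensity unit is re-estimated as 0.00304), Day-10 intensity
alone is a much weaker predictor because responsiveness has decayed by then,
and food availability — a quadratic with an interior optimum near
7.9×10¹⁰ cells·day/ml — captures lifespan only partially in this generative
model.  The other drivers (`analysis/01…04`) cover scene simulation,
segmentation recovery (sensitivity ≈ 0.99, zero blob-derived false
positives), classifier validation (100 % on separable priors; tracks the
Monte-Carlo Bayes rate under calibrated overlap) and nucleolar calls; each
writes its tables under `results/`.

There is also a CLI for the individual stages:

```bash
wormquant pipeline --out runs/demo --seed 1
wormquant simulate --out runs/sim --seed 1 --worms 1
wormquant segment --manifest runs/sim/worm-000_manifest.json --out runs/seg
```

## Layout

```
src/wormquant/      library: synthetic, stacks, segmentation, classify,
                    nucleolus, survival, cohort, association, pipeline, cli
analysis/           numbered narrative drivers writing results/
tests/              pytest suite incl. brute-force reference implementations
scripts/            acceptance script
docs/methods.md     model, assumptions, parameter choices, limitations
```
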