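# Methods

## Model

A hyperspectral image of one plant line contains two treatments of the
same genotype: control and salt-stressed plants. After segmentation the
vegetation pixels form a matrix **X** (d bands × n pixels) with a
treatment label per column. The central modeling assumption is the
two-endmember linear mixing model: every vegetation spectrum is
approximately a convex combination of a "fully healthy" spectrum **w₁**
and a "fully stressed" spectrum **w₂**,

    x ≈ (1 − s)·w₁ + s·w₂,   0 ≤ s ≤ 1,

and the mixing coefficient *s* — the similarity to the salt endmember —
carries the stress signal. The endmembers are taken from the data
itself as the two pixels at maximum Euclidean distance in feature space
(the vertices of the maximum-volume 1-simplex). Similarity is computed
by orthogonal projection onto the endmember axis with the coordinate
clipped to [0, 1]:

    s = clip(⟨x − w₁, w₂ − w₁⟩ / ‖w₂ − w₁‖², 0, 1).

The clip is not cosmetic: it makes the projection exactly equal to the
salt coefficient of the box- and sum-constrained least-squares unmixing
problem (for two endmembers the QP's KKT conditions reduce to the
clamped 1-D projection), so the cheap vectorized formula inherits the
constrained QP's semantics. `qp_unmix` retains the iterative SQP
solution per pixel purely as a cross-check; the equivalence is asserted
to 10⁻⁶ in the tests and typically holds to ~10⁻¹³.

Complementarity (similarity-to-control = 1 − s) holds by construction,
so one channel per pixel carries all the information the model can
express — a d-fold storage and time reduction that is the point of the
method.

### Ranking statistics

Per line, three statistics summarize how far the salt class moved away
from the control class; all increase with susceptibility and the line
ranking is ascending (most tolerant first):

* **NRD-AUC.** NRDᵢ = (C̄ᵢ − S̄ᵢ)/C̄ᵢ per band i (class means of raw
  reflectance; bands with zero control mean are flagged undefined and
  excluded). The area under the curve is computed with trapezoids on a
  photon-energy axis Eᵢ = hc/λᵢ (h = 6.62607015×10⁻³⁴ J·s,
  c = 2.99792458×10⁸ m/s), taking |ΔE| as the measure while the
  integrand keeps its sign — negative NRD regions (bands where stress
  *raises* reflectance) subtract from the area. Units: joules.
* **MDPA.** Control and salt similarity values are histogrammed into
  b = 100 bins tiling [0, 1]; bins are half-open [k/b, (k+1)/b) with
  the last bin closed so s = 1 (the salt endmember itself) is in-range.
  The minimum difference of pair assignments,
  D = Σᵢ |Σⱼ≤ᵢ (Hⱼ(C) − Hⱼ(S))|, is the minimal number of one-bin
  sample moves equalizing the histograms — the 1-D earth-mover
  distance, appropriate for ordinal histograms because (unlike
  Euclidean or Bhattacharyya distances) it is *not* invariant to bin
  shuffling. It requires equal totals, so the larger class is first
  subsampled bin-by-bin (stratified, proportional quotas with a
  deterministic largest-remainder correction; uniform within-bin
  selection under the run seed), which preserves the distribution
  shape. The raw distance is divided by the per-class pixel count
  (post-subsampling count, the only size both histograms share) to be
  comparable across lines.
* **Bayesian posterior.** With balanced classes the priors are exactly
  equal, so Bayes' rule at the split point s = 0.5 reduces to
  P(salt | s > 0.5) = cc_s / (cc_s + cc_c) with cc_s = P(s > 0.5 |
  salt), cc_c = P(s > 0.5 | control); the split rule is the strict
  inequality. The evidence P(s > 0.5) = (cc_s + cc_c)/2 is reported
  alongside, and the table can also be built from (cc_s, evidence)
  via cc_c = 2·evidence − cc_s, which is how published component
  tables are reproduced. When no pixel exceeds the split the posterior
  is flagged NaN rather than defaulted. A 10-bin posterior curve
  P(salt | s ∈ bin) is provided for threshold selection; empty bins are
  NaN. Reported percentages are rounded to two decimals only at the
  reporting layer.

## Segmentation parameters

Index bands are the nearest kept bands to blue 470, green 550, red 670,
NIR 800 nm (nearest-neighbor, no interpolation). Default thresholds
NDVI > 0.5 and EGI > 0.05 (both strict); the acceptance tests verify
mask behavior over the grid NDVI ∈ {0.35, 0.45, 0.55} ×
EGI ∈ {0.03, 0.05, 0.07} to show the conclusions do not hinge on the
default. Erosion uses a single pass of a 3×3 ones element with
out-of-bounds neighbors counting as absent, so image-border pixels are
always removed; a second pass would be a 5×5 erosion and is
deliberately not applied. Rectangles are half-open [r0, r1) × [c0, c1),
coordinates 0-based (row, col), flattening in row-major scan order.

## Synthetic scenes

The generator renders the data regime the pipeline expects: two
vegetation plots (control top, salt bottom) on a dark flat background
(reflectance 0.02), 120×120 pixels, 50 bands over 400–900 nm. Each
vegetation pixel is

    illum · [(1 − a)·w_control + a·w_salt] + noise,

with the salt abundance a ~ Beta(mean μ, concentration 16), μ = 0.35
for control pixels and 0.35 + shift for salt pixels. The Beta keeps the
similarity histograms unimodal; `shift` is the single severity knob and
every downstream statistic must increase with it. The healthy spectrum
has the canonical leaf shape (green bump at 550 nm, red edge at
~712 nm, NIR plateau 0.47); the stressed spectrum loses 25–35 % of the
NIR plateau, shifts the red edge 4–10 nm toward longer wavelengths,
weakens the green bump 10–25 %, and gains 0.01–0.02 reflectance on the
red shoulder (chlorosis) — drawn once per scene seed, so the stress
direction is reproducible and, importantly, far from collinear with a
brightness change. The multiplicative illumination factor is log-normal
with unit median and log-sd 0.03, modeling moderate leaf-angle/
illumination variability of an indoor line-scan acquisition; additive
Gaussian sensor noise has sd 0.005 reflectance. One pure control pixel
(a = 0) and one pure salt pixel (a = 1) are planted at the plot centers
with unit illumination, so noise-free scenes contain the exact
endmembers; a 1-pixel plot border of 50/50 vegetation/background
mixtures exercises the mixed-pixel filter. All draws flow from a single
generator in a documented order (control abundances row-major, salt
abundances, illumination field, noise cube), making cubes bit-identical
under identical scene specs.

What the generator does **not** emulate: radiative-transfer realism
(no PROSPECT/SAIL), sensor PSF/smile, spatially correlated illumination
(real leaf angle varies smoothly), within-plot biological structure,
or specular highlights. Passing the synthetic recovery tests therefore
shows the statistics respond correctly to a controlled class shift
under mixed pixels, illumination jitter, and sensor noise — not that
they are robust to every field condition.

## Design choices where the design was open

* **Endmember search.** For two endmembers the simplex-volume principle
  reduces to the farthest pixel pair. The exact O(n²) scan is used up
  to n = 5,000; above that a certified search runs an alternating
  farthest-point pass for a lower bound and then sweeps pixels in
  decreasing centroid radius with the bound d(i,j) ≤ rᵢ + rⱼ, pruning
  partners that cannot beat the incumbent. It returns the exact pair
  (asserted against brute force in tests) without materializing the
  n² distance matrix. Ties are broken lexicographically on indices.
* **Orientation.** Which extreme is "control" is decided by projecting
  the class centroids onto the endmember axis — the orientation under
  which the control class mean sits nearer w₁. Using every labeled
  pixel is robust when classes overlap, where the label of a single
  extreme pixel is nearly uninformative; it coincides with that label
  whenever classes are separated.
* **Zero-denominator conventions.** NDVI with NIR+R = 0 maps to 0;
  NRD bands with zero control mean are excluded from the AUC rather
  than zero-filled (zero-filling would silently shrink the area);
  similarity pixels equal to the background value 0 are distinguished
  from background by the coordinate list, not the grid.
* **Noisy-band windows** are closed intervals on band centers — the
  reproducible reading of nm ranges when the instrument's exact band
  table is unknown. The published count of kept bands for the original
  240-band camera is therefore descriptive, not a contract.
* **Subsampling rounding.** Largest-remainder correction makes the
  balanced classes exactly equal, which both the pair-assignment
  distance and the equal-prior simplification require. Whether the
  per-line MDPA normalization uses the pre- or post-subsampling count
  is ambiguous in the source material; the post-subsampling (equal)
  count is used.
* **Validation scale.** The ordering-recovery test uses four synthetic
  lines with shifts 0.00/0.08/0.10/0.20 over 20 seed replicates at the
  default 120×120 scene size (~5,800 masked pixels per class), where
  the binomial standard error of the exceedance fractions is well below
  the smallest between-line contrast. The acceptance suite runs in
  about a minute on one CPU.

## Known limitations

* The two-endmember model collapses all spectral variation onto one
  axis; senescence, water status, and nutrient effects that move pixels
  off the control–salt axis are projected onto it indistinguishably.
* Endmembers are single pixels, so they inherit that pixel's noise; on
  very noisy images a robust (e.g., local-average) endmember would be
  preferable but is not implemented.
* The similarity scale is per-image (normalized to that image's own
  extremes), so absolute similarity values are not comparable across
  images — only the within-image class contrast is.
* The Bayesian posterior uses a single split at s = 0.5; lines whose
  class separation happens elsewhere on the axis are better read from
  the 10-bin posterior curve.
* DN→radiance conversion is a per-band linear gain/offset supplied by
  configuration; vendor calibration file formats are not parsed.
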