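# Methods

This note documents the models, estimators and design choices behind
`ecmprofiler`, and what the synthetic study does and does not establish.

## Force-curve model and Hertz inversion

A force volume is a rectangular grid of approach curves (default 16 × 16
over a 70 µm × 70 µm area, 4096 points over a 10 µm ramp at 1.1 Hz),
acquired with a colloidal probe: a glass microsphere (radius R, default
9 µm, the midpoint of the 8–10 µm fabrication range) on a soft cantilever
(spring constant k, default 0.25 N/m from the 0.2–0.3 N/m range).  The
probe radius is deliberately comparable to the micro-structural domains of
decellularized ECM, so each curve reads a mesoscale elastic response
rather than single-fibril mechanics.

For tip–sample contact the spherical-indenter Hertz law is used,

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2},

with Poisson ratio ν = 0.5 (incompressible soft tissue; the true value is
unknown and only rescales E by a condition-independent factor, leaving all
folds unchanged).  Indentation is δ = (z − z_c) − (d − d_c) on the
approach branch; retract data are ignored.

**Contact point.**  z_c is found by piecewise model selection: a linear
baseline left of the split plus a `δ^{3/2}` branch right of it, scored by
total squared error over a hierarchical grid of candidate splits and
refined continuously between samples.  The method is deterministic and
threshold-free.  Curves are rejected when (i) fewer than ~1% of samples
precede contact or contact is never reached, (ii) the post-contact signal
does not exceed 10× the baseline noise, or (iii) the fitted "baseline"
slope exceeds 1% deflection per unit travel — real optical-interference
tilt is orders of magnitude smaller, so such a slope means the curve has
no true pre-contact region.

**Fit.**  After subtracting a linear baseline (fitted over the leading
50% of pre-contact points), the force F = k·d is regressed on δ^{3/2}
over δ ∈ [0.35·δ_max, δ_max].  The exclusion of the first 35% of
indentation separates the contribution of loosely bound superficial
layers from the bulk response; on curves synthesized with an explicit
soft surface layer the exclusion demonstrably reduces the bias of the
recovered bulk modulus.  The modulus enters linearly, so the fit is
closed-form and positive whenever the window's force is.  Fits are
rejected with fewer than 20 points in the window or a residual RMS above
10% of the peak force.  On noiseless synthetic curves the full chain
(contact estimation included) recovers E to better than 1 part in 10⁴;
with 1 nm RMS deflection noise the bias is ≲0.3%.

## Stiffness statistics

Measured modulus distributions of ECM are envelopes of several nearly
lognormal modes.  `decompose_modes` fits Gaussian mixtures to log₁₀ E
(scikit-learn, 10 seeded restarts per order) and selects the component
count by BIC (ties toward fewer modes, maximum 5).  Mode membership is by
maximum posterior; the hard-assigned count N and fraction f = N/N_tot are
the mode's weight.  A degenerate sample (all values equal) yields a single
flagged mode with the spread floored at 10⁻³ dex.

Each mode is summarized by the median of its lognormal, `E_med = 10^µ`,
with the asymptotic standard deviation of a sample median transferred to
the linear scale by the delta method:

    σ_med = E_med · ln10 · √(π/2) · s / √N.

A Monte-Carlo check (SD of the sample median over simulated mode
populations) agrees with this closed form within 10%, which is also the
tolerance asserted in the test suite.  The per-sample effective rigidity
is the weight-averaged mode median `E = Σ fᵢ·E_med,i` with total error

    σ_E = √( Σ (fᵢ·σ_med,i)² + (ε_rel·E)² ),

where ε_rel (default 0.05, configurable) is an effective instrumental
relative error that keeps σ_E honest when mode statistics are large.
Folds vs healthy are ratios of effective rigidities; per-patient folds are
aggregated by the median across patients.  Within-sample pooling weights
volumes by curve count (each curve contributes equally).

## Micrograph morphometrics

**Anisotropy.**  Intensity gradients (centred differences after Gaussian
smoothing, σ = 1 px) build the summed nematic tensor over the *entire*
image — no sub-region selection, which would bias toward chosen fibres.
The score is the normalized eigenvalue difference
`√((Jxx−Jyy)² + 4Jxy²)/(Jxx+Jyy)` ∈ [0, 1]; the mean fibril orientation is
perpendicular to the dominant gradient axis.  A constant image scores 0 by
convention and is flagged.  The score is exactly invariant under 90°/180°
rotation and reflection, invariant to intensity rescaling, and stable to
±0.02 under arbitrary rotation with resampling.

**Fibril width.**  The paper's manual calliper measurements are replaced
by an automated, reproducible estimator: bright ridge points are detected
on a lightly smoothed image, the local orientation is taken from the
structure tensor in a 15 px window, and an intensity profile is sampled
perpendicular to it (0.25 px steps).  The width is the full width at half
prominence of the central peak — equal to the FWHM for an isolated
Gaussian ridge and insensitive to constant background.  Prominence is
evaluated within a 300 nm window (`max_width_nm`): structures wider than
that are not fibrils, and the window keeps valleys of distant neighbours
from deepening the base and inflating widths.  Profiles with a displaced,
clipped or strongly asymmetric peak (width-halves differing by more than
2×, i.e. crossings) are discarded.  On an isolated 90 nm ridge the
estimator is accurate to ~1%; on dense synthetic fields the mean is
within ~5% for 90 nm fibrils, with a mild upward bias (~15%) for the
thin-fibril (40 nm) carcinoma regime where crossings are proportionally
wider — rankings and condition separation are preserved.

**Capillaries.**  On binary lumen masks, density is the connected-
component count over the field area and lumen width is the minor axis of
each component's fitted ellipse (scikit-image regionprops).  Components
touching the field border are counted but excluded from widths (their
shape is truncated).

## Crosslink biochemistry

Collagen content is hydroxyproline / 0.135 (hydroxyproline is 13.5% of
the collagen amino-acid composition).  Panels carry HP
(hydroxylysyl-pyridinoline) and LP (lysyl-pyridinoline), the mature
crosslinks formed downstream of lysyl oxidase; summaries report
HP + LP totals, HP/LP ratios, and per-patient folds vs matched healthy
samples aggregated by the median (pooled condition medians are reported
separately).  Units are kit-relative; every downstream quantity is a
ratio, so the unit choice is inert.  LP = 0 renders the ratio undefined
and flags the sample.

## Matrisome proteomics

Protein tables mirror post-search MaxQuant output (rows = proteins,
columns = `LFQ intensity <condition>_p<patient>_r<replicate>`).
Annotation joins gene symbols (case-insensitive) against a matrisome
category table; unmatched proteins are non-matrisome, and conflicting
duplicate entries in the table are an error.  Differential composition is
per-protein one-way ANOVA across conditions on replicate-averaged log₁₀
intensities (patients are the unit; zeros floored at the table's minimum
positive value), significant at raw p < 0.01 with **no** multiplicity
correction — this mirrors the original analysis; a Benjamini–Hochberg
option exists but is off by default.  Zero within-group variance trips a
variance floor and a flag (identical copied samples are never
significant).  Whether to test raw or log intensities was open; log is the
default because LFQ noise is multiplicative, with `use_log=False`
available.

The hydroxylysine statistic treats the lysine-oxidation token in the
"Modified sequence" column as OH-Lys.  Globally per sample it is the
summed intensity of OH-Lys-bearing peptides over the summed matrisome
protein intensity; per protein it is the same numerator restricted to the
protein over that protein's intensity.  The global value is exactly the
intensity-share-weighted average of the per-protein fractions.  The
collagen XII : VI balance is COL12A1 over the summed COL6A3 forms (the
two forms are configurable protein ids), with folds vs matched healthy.
Heatmap clustering uses average linkage on Euclidean distance over log₁₀
median-centred intensities, rows sorted by protein id before linkage so
the tree is invariant to input row order; all-equal rows are excluded
with notice.

## Synthetic study design

The generator realizes the study conditions as ground truth:

* **Stiffness** — three lognormal modes per condition; healthy at
  µ = (2.8, 3.4, 4.0) log₁₀ Pa, s = 0.15, weights (0.5, 0.3, 0.2).  The
  modes sit 4σ apart (clearly resolvable, as in the observed
  distributions) and give a ~3 kPa healthy weighted median, consistent
  with 60–70 nN producing 2–3 µm indentations under the default probe.
  Perilesional and carcinoma mixtures are the healthy modes rigidly
  shifted by log₁₀ 2.5 and log₁₀ 9.4, so the true weighted-median folds
  are exact.  Forward curves invert the Hertz relation by dense
  parametric sampling (quadratically spaced in δ to resolve the unbounded
  curvature at contact); the contact point is placed so the ramp ends at
  the target peak force (uniform in 60–70 nN) while preserving ≥15% of
  the ramp as baseline.  Noise: 1 nm RMS Gaussian deflection noise and a
  small random linear baseline tilt.
* **Fibril textures** — sums of Gaussian ridges with FWHM drawn from the
  condition's width law (90 ± 26 nm healthy/perilesional, 40 ± 8 nm
  carcinoma, truncated at 1 px) at 10 nm/px on 512 px fields, 25 fibrils
  per field.  Orientations follow an axial von Mises model (doubled-angle
  construction) whose concentration is solved from the target nematic
  order (0.1 / 0.2 / 0.4) via I₁(κ)/I₀(κ).  Two variance-control choices
  make a 25-fibril field carry its configured order faithfully: angles
  are drawn by randomized stratified inverse-CDF sampling, and fibrils
  span the field with amplitude ∝ √width so each contributes equal
  gradient power.  Without them the weak healthy order (0.1) would be
  inflated by O(1/√n) sampling noise and the anisotropy gradient would
  not be recoverable at realistic fibril counts.
* **Capillary masks** — Poisson lumen counts at the condition density
  (146 vs 262 mm⁻²) over 0.5 × 0.5 mm fields at 0.25 µm/px; elliptical
  lumens with truncated-normal minor axes (2.9 ± 0.4 µm vs 5.3 ± 0.8 µm —
  the published ±0.05/±0.1 are standard errors of donor means, so a
  realistic ~15% per-lumen CV is used) and jittered elongation, placed by
  rejection sampling with a 2 px minimum gap so components never merge
  and the count is exact.  Tumor vessels are ectatic and not modelled as
  lumens; the report marks carcinoma vascularization unavailable.
* **Proteomics** — 1139 proteins of which 128 matrisome (76 core = 12
  proteoglycans + 18 collagens + 46 glycoproteins; 52 associated = 16
  affiliated + 24 regulators + 12 secreted), matching the published
  detection counts by construction.  Base intensities are log-uniform
  over 10^6.5–10^8.5 with collagen I pinned to the top decade (it
  dominates ECM mass, which is what lets a COL1A1-specific hydroxylation
  shift move the global OH-Lys statistic) and COL11A1 near the floor
  outside carcinoma.  Biological noise is 0.1 dex per (protein, patient,
  condition); technical noise 0.02 dex per replicate, giving replicate
  correlations > 0.98.  Carcinoma-only effects: 0.2× on basal-membrane
  and interstitial proteins (LAMB2, NID1, MATN2, both COL6A3 forms, OGN,
  DCN, DPT), 5× on invasion-associated proteins (FN1, FBLN1, MFAP2, TNC,
  LGALS3), 20× on COL12A1 (with COL6A3 at 0.2× this yields a ~100-fold
  XII : VI shift, inside the reported 50–200 range) and 30× on COL11A1.
  OH-Lys fractions: 5% on collagens everywhere, 20% on COL1A1 in
  carcinoma, 30% on COL11A1.  Missing values are off: the emulated tables
  are post-filter.  The matrisome table is synthetic (1065 genes in the
  published category proportions) carrying the real symbols the analysis
  keys on, padded with clearly synthetic identifiers.
* **Crosslink panels** — healthy HP = LP = 0.5, perilesional 0.75/0.75,
  carcinoma 4/3 and 2/3: total folds exactly 1.5× and 2×, HP/LP ratio
  doubled only in carcinoma, constant hydroxyproline (collagen content
  does not change across the gradient).  Multiplicative lognormal noise
  (unit mean, default 5% CV).

All randomness derives from the single configuration seed through fixed
per-artifact streams: identical configurations produce byte-identical
serialized outputs, and each artifact records its ground truth.

**What the synthetic data do not emulate:** instrument drift and
hydrodynamic drag on force curves, finite-thickness (bottom-effect)
corrections, SEM imaging physics (charging, depth of field, secondary-
electron contrast), curved or branching fibrils, peptide-level missing
values and interference, and batch effects.  Passing recovery tests
therefore demonstrates the correctness and calibration of the estimation
chains under the stated noise models, not robustness to every artifact of
real instruments.

## Problem sizes and numerical choices

The study-level recovery runs use 5 force volumes × 256 curves per
condition (≈1280 moduli, matching the typical per-mode occupancies of
1000–2000 curves), 10 micrographs per condition for anisotropy folds,
≥52 width profiles and ≥146 lumens — the published sample sizes for the
corresponding measurements.  Unit tests use smaller grids with a
proportionally shortened ramp so contact regions stay well sampled.
Tolerances asserted end to end: 15% on stiffness folds, 25% on the
anisotropy fold, 10% on mean fibril width, 5% on mean capillary width,
exactness (10⁻¹²) for the noiseless crosslink folds and the
hydroxyproline conversion.  Degenerate inputs are flagged rather than
fatal wherever a study could plausibly produce them (constant images,
all-identical moduli, LP = 0, zero-variance proteins).

## Known limitations

* The contact-point algorithm is validated against synthetic truth only;
  real curves with adhesion hysteresis or long-range interactions may
  need the rejection thresholds revisited.
* The width estimator's upward bias on thin, densely crossing fibrils
  (~15% at 40 nm) is documented above; between-condition orderings are
  unaffected.
* The ANOVA mirrors the original no-correction procedure; with thousands
  of proteins the raw p < 0.01 rule implies ~1% false positives by
  design (the BH option exists for stricter use).
* Serialized force volumes are plain text and large (~40 MB per 16 × 16
  volume); in-memory pipelines avoid the round trip.
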