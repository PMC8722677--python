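# Methods

This note documents the models each stage implements, the estimators and
numerical choices behind them, the synthetic-data generators used to
validate them, and the known limitations.

## Optical-mapping action potentials

**Model.** A voltage-dye fluorescence train is a sequence of action
potentials riding on a slow baseline (photobleaching, focus drift), with
an arbitrary sign convention: many potentiometric dyes report
depolarisation as a fluorescence *decrease*.  Features per beat: APD30 and
APD80 (time from activation until the trace first repolarises below
`peak − 0.30·amplitude` and `peak − 0.80·amplitude`), cycle length
(spacing of successive activations) and amplitude.

**Pipeline.**

1. *Polarity*: the orientation whose lightly smoothed derivative has the
   larger positive extreme is taken as upward (the upstroke is always the
   steepest transition).
2. *Baseline*: a rolling 20th-percentile of the trace (decimated for
   speed), low-passed with two odd-reflection moving-average passes, is
   subtracted.  A rolling *median* — the textbook choice — fails here:
   spontaneous cardiomyocyte trains spend ≈ 50% of the cycle depolarised,
   so the median straddles the two levels and oscillates with beat phase.
   The low quantile sits on the diastole at any duty cycle below ~75%, and
   the extra smoothing removes the beat-periodic ripple the sliding
   quantile otherwise leaks.  Odd reflection at the edges preserves linear
   drift; default window 2,000 ms (≈ 2 × the longest expected cycle).
3. *Beat detection*: prominent peaks of the smoothed trace
   (height ≥ 0.5 and prominence ≥ 0.4 of the robust amplitude, minimum
   spacing = the 100 ms refractory default).
4. *Activation*: the first instant the smoothed derivative reaches half
   its beat maximum — for a linear upstroke under symmetric smoothing this
   is exactly the upstroke onset, the optical analogue of the dV/dt-max
   convention.  When the raw step is much steeper than the smoothed
   derivative (near-instantaneous upstroke), the onset is the sample after
   the largest raw step instead.
5. *Amplitude and levels*: estimated once per site from the per-sample
   **median ensemble beat** (beats aligned at activation).  The apex value
   is the intersection of a line fit to the upstroke with a line fit to
   the early-repolarisation shoulder — a noisy sample maximum is biased
   upward by extreme-value statistics, and because early repolarisation is
   shallow, even a 1% amplitude error moves the APD30 crossing by several
   milliseconds.  The diastolic level is the pre-activation mean of the
   ensemble beat.
6. *Crossings*: located on the smoothed trace (two consecutive samples
   below the level, rejecting single-sample dips), then refined by an
   ordinary least-squares line over the raw samples just *before* the
   crossing, which is unbiased wherever repolarisation is locally linear;
   a second pass re-anchors the window at the refined estimate.  When the
   local slope at the crossing is ≥ 5× steeper than the pre-crossing
   trend (abrupt repolarisation), plain linear interpolation between the
   bracketing samples is already sub-frame accurate and is used directly.

On noise-free input every step reduces to the exact geometric
construction.  Two outputs are exposed: `extract_ap_features` (one row per
beat, site-level levels + per-beat crossing times) and
`extract_site_features` (APDs measured on the ensemble beat itself, the
recommended low-noise estimate — signal averaging suppresses frame noise
by √n_beats).  At 500 frames/s and 5% amplitude noise the *per-beat* APD30
has an irreducible spread of ~10–15 ms because the 30% level sits on a
ramp of only ~1.6 × 10⁻³ amplitude/ms; accuracy claims therefore attach to
the site-level (ensemble) estimates and to per-beat means, which land
within about one frame (2 ms) of truth.

**Group statistics.** `compare_groups` reports per-group n/mean/SEM,
`percent_increase = 100·(mean_A − mean_B)/mean_B`, and the classic
pooled-variance unpaired two-tailed Student's t.

## AFM Hertz nanoindentation

**Model.** For a spherical tip of radius R on an incompressible soft
sample (ν = 0.5), force and indentation obey
`F = (4√R/3)·E/(1−ν²)·δ^{3/2}`.  The instrument records piezo position z
and cantilever deflection d; geometry gives `z = z_contact + d + δ` and
`F = k·(d − d_baseline)`.  Units: z, d, δ, R in µm, k in nN/nm, F in nN,
E in Pa (the prefactor carries a 10⁻³ collecting the unit conversions).

**Estimators.**

- `fit_hertz`: origin-constrained least squares of F on δ^{3/2} — the
  closed form `slope = ΣFδ^{3/2}/Σδ³`, no iterative optimisation, fit
  range contact-to-maximum-force by default.
- `find_contact_and_fit`: under the model, `F^{2/3}` is *exactly linear*
  in the tip-sample position `y = z − bend`, crossing zero at the contact
  point.  The contact is the zero-crossing of a regression of `F^{2/3}`
  (noisy response) on y (nearly noise-free predictor, deflection noise
  enters y divided by the ~286 nN/µm stiffness) over the high-force region
  (F ≥ 25% of max), iterated twice with the deflection baseline
  re-estimated from the pre-contact samples each pass.  Points are
  selected by the previous iteration's *fitted line*, not by the noisy
  force — thresholding on noise preferentially admits upward-fluctuating
  points at the cutoff and biases the intercept.  An alternative we
  rejected — choosing the contact by minimising the Hertz-fit residual —
  is exact on clean curves but acquires a systematic few-percent modulus
  bias under noise from the contact/modulus trade-off; the regression
  form is exact noise-free *and* unbiased under noise.
- `cell_stiffness`: the cell's stiffness is the arithmetic mean of its
  per-site moduli; the protocol expects 5 sites per cell (warned
  otherwise).

Retract curves are parsed but not fitted (adhesion hysteresis out of
scope), and no bottom-effect or viscoelastic corrections are applied.

## Quantitative-phase dry mass and motion

**Model.** The phase camera yields optical path difference (OPD) per
pixel; dry mass is `OPD·pixel_area/α` with the specific refractive
increment α = 0.18 µm³/pg (a standard literature value, exposed as a
parameter).  Cells are compact mass distributions that translate, grow,
or internally redistribute mass.

**Pipeline.** Tiled local-Otsu segmentation (64 px tiles, per-tile
thresholds bilinearly interpolated to a threshold surface; low-contrast
tiles fall back to the global Otsu; components < 50 px dropped) → greedy
nearest-neighbour linking on centroid distance gated at 20 µm, ties
broken by smallest relative mass difference, no merge/split →
per-interval metrics:

- net displacement = Euclidean step of the mass-weighted centroid (µm);
- percent mass fluctuation = `100·Σ|m_{t+1}(x−s) − m_t(x)|/M_t` over the
  union of the two aligned supports, with s the *integer-pixel* shift of
  the centroids.  Integer alignment means a rigid integer-pixel
  translation cancels exactly and no interpolation can manufacture
  phantom fluctuation; a bilinear sub-pixel mode exists behind
  `QPMConfig.subpixel_align` for data with genuine sub-pixel drift.
  Normalisation uses the earlier frame's mass.
- mass accumulation rate = straight-line slope of total mass vs time
  (pg/h).

## scRNA QC, markers, TPM

QC removes cells with < 200 detected genes **or** < 3,000 UMIs first,
then genes detected in < 3 surviving cells; boundaries are strict
("fewer than"), and the operation is idempotent.  Normalization is
`ln(1 + 10⁴·count/cell_total)`.  Marker detection tests genes detected in
≥ 30% of either group with a two-sided Wilcoxon rank-sum test:

- full permutation enumeration (midranks, two-sided = doubled smaller
  tail) whenever all label assignments are enumerable (≤ 20,000
  combinations) — this handles ties exactly;
- the exact rank-sum distribution for tie-free groups of ≤ 25 cells;
- the normal approximation with tie correction otherwise (enumerating
  C(50,25) ≈ 10¹⁴ assignments is not an option);
- genes identical across all cells get p = 1 by convention.

`avg_log2FC = log2((mean₁+ε)/(mean₂+ε))` of de-logged (expm1) normalized
expression, ε = 10⁻⁹; BH correction across the tested genes; positive
fold change defines group-1 markers.  Bulk counts are length-normalized
to TPM (summing to 10⁶ per sample before the log) and returned as
log2(TPM + 1).

## Promoter-occupancy enrichment

Promoters are TSS ± 2 kb windows (strand-aware, clipped at chromosome
bounds; the window is a parameter since no standard exists).  A gene is
*bound* when its promoter shares ≥ 1 bp with any peak, under 0-based
half-open semantics ([0,10) and [10,20) do not overlap), computed by a
sorted sweep per chromosome.  The universe is the set of genes with
promoter coordinates — the hypergeometric population must be the set in
which "bound" is defined.  Per TF, 12 upper-tail hypergeometric tests are
run — the two marker-derived sets (positive / negative fold change) plus
10 seeded random sets of 150 genes drawn without replacement from the
universe minus both marker sets — and BH-corrected *within that TF's 12
tests*.  An ortholog map, when marker and TSS namespaces differ, is an
input table, not a computation.  Real external peak/TSS/ortholog files
(BED / TSV) run through the same entry points.

## Mitochondrial stress test

Phase summaries follow the conventional reductions: last pre-oligomycin
measurement (basal raw), post-oligomycin minimum, post-FCCP maximum,
post-antimycin minimum (phase means available via `reduce="mean"`).  With
levels L1..L4: non-mito = L4, basal = L1−L4, ATP-linked = L1−L2, proton
leak = L2−L4, maximal = L3−L4, spare = maximal − basal.  The identity
`basal ≡ atp_linked + proton_leak` holds exactly for any input — which
also means no pair of groups can differ in ATP-linked respiration alone:
a shift in the post-oligomycin plateau necessarily moves proton leak the
opposite way.  Normalization divides by cell_count/1,000 (per-1,000-cells
units keep magnitudes readable); ECAR is carried through untransformed.

## Synthetic data: what it emulates, and what it does not

All generators draw from one `numpy.random.Generator` seeded by the
`SimSpec`, so identical specs give byte-identical output.

- **AP trains**: piecewise-linear template (linear upstroke, shoulder to
  70% at APD30, segment to 20% at APD80, short tail), repeated at the
  cycle length, plus Gaussian noise, optional linear drift and inverted
  polarity.  True APDs are exact by construction.  *Not emulated*: ionic
  -current dynamics, beat-to-beat APD variability, conduction, motion
  artefacts.
- **Force curves**: exact Hertz force with the z = contact + d + δ
  geometry inverted by bisection per sample; protocol defaults k = 0.286
  nN/nm, R = 5 µm (10 µm sphere), ν = 0.5, 3 nN force cap.  *Not
  emulated*: adhesion, viscoelastic relaxation, substrate effects, tilt.
- **Phase stacks**: cells are truncated-Gaussian blobs with σ (25 px)
  deliberately wide relative to the truncation radius (14 px), so every
  in-support pixel sits well above background and the Otsu histogram has
  a clean gap — Otsu under heavy class imbalance otherwise cuts into the
  object.  Pulsating cells alternate between two two-lobe states
  exchanging a mass fraction; their ground-truth fluctuation is computed
  by direct pixel-sum of the two rendered states, and the default lobe
  offset (2 px) keeps the states' centroid shift below half a pixel so
  the analyzer's aligned difference equals that oracle.  Overlapping
  cells are rejected (segmentation ambiguity is out of scope for
  fixtures).  *Not emulated*: optical transfer functions, halo artefacts,
  cell-shape irregularity, division/fusion.
- **Count matrices**: gamma-Poisson baseline with lognormal gene means,
  markers as multiplicative fold changes (optional Bernoulli detection
  gates), engineered QC casualties (low-gene cells, low-UMI cells, rare
  genes) occupying known columns/rows.  *Not emulated*: ambient RNA,
  doublets, batch effects.
- **Genome fixtures**: genes on a uniform grid spaced so a promoter peak
  can only hit its own gene; enriched-set promoters receive a peak with
  probability p_in, others p_out.  An explicit `require_enrichment` flag
  guards the p_in ≤ p_out error, because null calibration legitimately
  generates with p_in = p_out.
- **OCR traces**: four-phase step profiles with per-phase measurement
  counts and Gaussian noise; physiologically odd profiles (post-antimycin
  above basal) warn but generate.

Passing tests therefore demonstrate correctness of the *estimators* under
these idealised conditions, not robustness to every artefact of real
instruments.

## Problem sizes and calibration checks

The test suite and `scripts/acceptance.py` run at desk scale: 100-beat
trains at 3–4 sites; 100 force curves per noise condition; 50-frame
stacks; 1,000–2,000-gene matrices with 50–160 cells; 2,000-gene genome
fixtures with 150-gene sets, 100–200 seeded replicates for calibration;
12-well respirometry groups over 60–100 seeded replicates.  Null
calibrations compare observed rejection rates against binomial error
around the *exact discrete* null expectation where the test statistic is
discrete (hypergeometric p-values cannot attain every level, so the raw
p < 0.05 rate sits slightly below 0.05 by construction), and additionally
assert the tests are never anticonservative.

## Known limitations

- Per-beat APD30 at ≥ 5% noise is noisy by physics (shallow ramp); use
  the ensemble estimates for quantitative work.
- The greedy tracker neither merges nor splits; tracks end at cell
  contact events.
- The Wilcoxon normal approximation is used for large tied groups, as in
  standard toolkits.
- The enrichment stage treats peaks as given; peak calling, motif
  analysis and assembly liftover are out of scope.
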