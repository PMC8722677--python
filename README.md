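# cardiofield

Quantitative phenotyping of first- versus second-heart-field (FHF/SHF)
hESC-derived cardiomyocytes.  The package re-implements, as a tested
multi-stage pipeline, the bespoke quantifications such comparisons rest on:

- **Optical-mapping action potentials** — per-beat APD30, APD80 and cycle
  length from voltage-dye fluorescence trains, with unpaired two-tailed
  Student's t group comparisons.
- **AFM nanoindentation** — Young's modulus *E* from approach curves via the
  spherical-tip Hertz model
  `F = (4√R/3) · E/(1−ν²) · δ^{3/2}`, with automatic contact-point
  estimation and per-cell averaging over indentation sites.
- **Quantitative-phase dry-mass motion** — local-Otsu segmentation,
  phase-to-mass conversion through the specific refractive increment
  (α ≈ 0.18 µm³/pg), nearest-neighbour tracking, and per-interval net
  displacement and percent mass fluctuation (internal mass redistribution).
- **scRNA-seq QC and markers** — the standard droplet filters (≥ 200 genes
  and ≥ 3,000 UMIs per cell; genes in ≥ 3 cells), log-normalization, and
  two-group Wilcoxon rank-sum marker detection with Benjamini-Hochberg FDR;
  bulk counts as log2(TPM + 1).
- **Promoter-occupancy enrichment** — for a TF ChIP-seq peak set, an
  upper-tail hypergeometric test `P(X ≥ k)` for marker-gene promoters bound
  versus the gene universe, scored against 10 random 150-gene control sets
  (12 BH-corrected tests per TF).
- **Mitochondrial stress test** — basal, ATP-linked, proton-leak, maximal,
  spare and non-mitochondrial respiration from OCR traces with sequential
  oligomycin / FCCP / antimycin-A injections, normalized per 1,000 cells.

Every stage is paired with a seeded synthetic-data generator
(`cardiofield.synthio`) that emits the stage's native input format together
with programmed ground truth (true APDs, true moduli, true marker sets,
true bound promoters, true stress-test parameters), so the whole pipeline
is testable end-to-end with known answers.

## Worked example

Two optical-mapping groups generated with a programmed 45% APD30
difference, analysed per site on the ensemble-averaged beat:

```python
from cardiofield import synthio
from cardiofield.optical_ap import extract_site_features, compare_groups

fhf, _ = synthio.gen_ap_traces(synthio.SimSpec("ap", 11, {
    "noise_sd": 0.05, "n_beats": 60, "n_sites": 4, "apd30_ms": 232.0,
    "apd80_ms": 406.0, "cycle_length_ms": 900.0, "group_label": "FHF"}))
shf, _ = synthio.gen_ap_traces(synthio.SimSpec("ap", 12, {
    "noise_sd": 0.05, "n_beats": 60, "n_sites": 4, "apd30_ms": 160.0,
    "apd80_ms": 280.0, "cycle_length_ms": 900.0, "group_label": "SHF"}))

a, b = extract_site_features(fhf), extract_site_features(shf)
print(a.round(2).to_string(index=False))
cmp = compare_groups(a, b, metric="apd30_ms", label_a="FHF", label_b="SHF")
print(f"APD30: FHF {cmp.mean_a:.1f} ms vs SHF {cmp.mean_b:.1f} ms "
      f"(+{cmp.percent_increase:.1f}%), t = {cmp.t_statistic:.1f}, "
      f"p = {cmp.p_value:.2e}")
```

prints

```
   site  n_beats  apd30_ms  apd80_ms  cycle_length_ms  amplitude
site000       60    227.80    405.48           900.03       1.00
site001       60    233.19    406.31           900.00       1.00
site002       60    230.57    404.89           900.03       1.00
site003       60    235.72    407.39           900.00       0.99
APD30: FHF 231.8 ms vs SHF 160.9 ms (+44.1%), t = 37.1, p = 2.55e-08
```

i.e. the per-site APD30 estimates recover the programmed 232 ms / 160 ms
within a frame or two at 5% amplitude noise, and the group contrast
recovers the programmed 45% increase.

The same pattern — simulate with known truth, analyse, compare — works for
every modality; the `cfp` command line exposes each stage
(`cfp simulate`, `cfp ap`, `cfp afm`, `cfp qpm`, `cfp markers`,
`cfp occupancy`, `cfp mito`) plus `cfp run --config run.yaml`, which
executes a whole configured pipeline and writes a manifest with content
hashes so a run is reproducible byte-for-byte from its seed.

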