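# Methods

## Scope

`plasmaqc` implements a contamination-aware quality-control pipeline for
MS-based plasma proteomics: derivation of blood-cell contamination marker
panels, per-sample contamination statistics, dose–response modelling of
contamination signal versus cell count, a three-step QC strategy for
biomarker studies, and workflow enrichment-bias profiling. Because the
quantities of interest are *properties of a procedure* (does the marker
filter recover the right proteins? does the QC strategy catch
contamination-driven artifacts without sacrificing genuine biomarkers?),
everything is exercised against a synthetic spike-in simulator that carries
full ground truth. The simulator is first-class, tested code, not a test
fixture.

## The simulator

### Plasma proteome

Per-protein relative mass is log-normal in log10 space (sd 1.5 decades),
sorted descending, with the top-20 block rescaled to carry a configurable
mass fraction (default 0.99: roughly twenty proteins dominate the plasma
proteome, which spans many orders of magnitude). The rescaling includes a
monotone repair that keeps the whole vector descending; for low targets at
small n this is provably impossible (the top-20 mean would fall below the
tail mean), in which case the exact blockwise mass split is kept with
per-block ordering and a warning is emitted. Ids are assigned by rank
(`P00000` is the most abundant).

### Contaminant cell proteomes

Platelet, erythrocyte and PBMC proteomes use a flatter log-normal (sd 0.8
decades, the ~4–5 orders typical of cellular proteomes). Erythrocytes
concentrate 80% of mass in the top five proteins (hemoglobin dominance).
Per-cell protein mass defaults scale with cell volume (10 / 90 / 250 fL ×
2000 intensity units/fL), which is why PBMCs perturb a sample at counts an
order of magnitude lower than platelets. The top `n_markers` abundance
ranks are *cell-exclusive* (namespaced ids such as `PLT-M000`); all other
cell proteins are shared with plasma, their ids drawn from the plasma
namespace. This encodes the fact that usable contamination markers are
precisely the proteins a cell does not share with plasma.

### Mixing, capture, measurement

True per-protein mass of a sample is plasma mass (1 µL ≡ 1e10 intensity
units, an MS-like scale at fixed column loading) plus, per cell type,
count × per-cell mass × cell abundance — exact linear mixing, so mass
conservation holds to 1e-9 and doubling a count exactly doubles that cell's
contribution. Pure-contaminant reference runs are normalised to the same
total (equal protein loading), which makes the absolute log10-intensity
marker thresholds meaningful on simulated data.

Workflow capture is `captured_i = affinity_i · true_i^e`, with compression
exponent e ≤ 1, followed by a global proportional rescale whenever the
column total exceeds the bead binding capacity. Two consequences worth
stating:

* the contamination index is a within-sample ratio of sums and is therefore
  **invariant to the capacity rescale**; the concave ("power law")
  dose–response of bead workflows is carried by the compression exponent,
  while capacity shapes the total captured signal. Bead presets combine
  both (exponent 0.62–0.78, finite capacity); neat is the identity.
* on a noiseless neat series with a *fully cell-exclusive* contaminant the
  index is exactly linear in cell count (R² = 1 to machine precision);
  shared cell proteins inflate the denominator and make the response very
  slightly sublinear, as they would in reality. Exactness tests therefore
  use `markers_only=True`.

Measurement corruption: multiplicative log-normal noise with mean 1 whose
scale is calibrated so that the *observed* replicate CV (population sd /
mean over quadruplicates) matches the workflow's `cv` parameter — the naive
draw would read ~20% low at n = 4. Noise is mildly abundance-dependent
(×10^(0.15/decade below the median detectable intensity), clipped to
[0.5, 2]×), reflecting the general loss of precision for low-abundance
proteins in DIA data. Missingness is deterministic below the detection
limit and Bernoulli above it with probability sigmoidal in log10 intensity
(midpoint at the lod, steepness 2/decade), truncated to zero three decades
above the limit — abundant proteins are never missed. Simulated precursor
counts are `max(1, round(2·(log10 I − log10 floor)))`, a monotone proxy
that gives high-abundance proteins the "two or more precursors" the marker
filter expects.

All randomness flows through one explicit integer seed per call; identical
inputs and seed give bit-identical outputs.

### Scenario presets and their conditions

* **Dilution series** — single-cell-type spike-ins at the experimental
  ranges (single cells to 2×10⁶/µL for platelets/erythrocytes, to
  1.4×10⁴/µL for PBMCs), quadruplicates. `baseline_count` adds a constant
  residual contamination: ultra-pure spike-in plasma has ~0, routinely
  processed study plasma retains residual platelets (2×10⁴/µL is
  conservative relative to clinical counts after 3000 g × 7 min).
* **Model-regime experiments** — the linear regime is the neat workflow on
  study-like plasma with the 2×10⁴/µL residual baseline (the intercept is
  what makes "linear" identifiable: a zero-intercept line *is* a b = 1
  power law); the power regime is a bead workflow on ultra-pure plasma.
* **Two-group study** — n = 20/20; cases carry 5× the control platelet
  contamination with 0.3 decades of log-normal between-sample spread in
  both groups. The designated *false biomarker* is a platelet-exclusive
  protein outside the 50-marker panel; the *genuine biomarker* is a
  non-shared mid-abundance plasma protein elevated 1.4× in cases with 0.5
  biological CV (a realistic effect size, d ≈ 0.8–1).
* **Outlier study** — n = 60 samples whose baseline platelet counts are
  log-uniform over 0.3 decades (a standardized single-site collection
  protocol: bounded spread), with 5% of samples carrying 10× their baseline
  contamination.
* **Rescue** — contaminant mass scaled by (1 − removal fraction) before
  capture and noise are re-applied with the same seed, so a 90% removal
  reduces marker summed intensity exactly tenfold in the noiseless linear
  case.

### What the simulator does not emulate

Protein-group intensities only: no peptide-level signals, retention time or
spectra; no per-protein bead competition kinetics (capacity acts as a
global proportional rescale — a deliberate simplest-mechanism choice); no
platelet-activation biochemistry (activation markers are ordinary marker
proteins); no batch effects, interferences or shared-peptide quantification
artifacts. Passing tests show the *statistics* behave as designed under
controlled contamination; they do not certify performance on real data with
heavy-tailed baselines or correlated biology. In particular, the
zero-false-flag behaviour of the outlier screen depends on the bounded
baseline spread of the scenario; a heavy-tailed real cohort will produce
occasional flags beyond the spiked samples, as any fixed robust threshold
must.

## Statistics

* **Fold changes** are ratios of linear-scale means over detected
  replicates; proteins never detected in plasma are flagged exclusive and
  aligned to 1.1× the largest finite fold change, so exclusives outrank all
  shared proteins. CV is population sd / mean from the contaminant
  replicates. The abundance threshold applies to the contaminant-side mean
  (the only side where markers are reliably detected).
* **Marker selection** is a pure conjunction of the four filters
  (enrichment, precursors, abundance, CV), ranked by fold change with a
  deterministic protein-id tie-break, truncated to the panel size; short
  panels are emitted with a warning, never padded. Default thresholds are
  the published ones per cell type.
* **Contamination index** CI = Σ marker intensity / Σ all other detected
  intensity, per sample, on linear intensities (a summed MS intensity is a
  linear-scale quantity); missing contributes zero to both sums; an empty
  denominator yields an explicit undefined flag, never infinity.
  **Enrichment score** ES = Σ top-30 marker intensity / Σ top-30 plasma
  protein intensity in the same sample, the plasma top-30 ranked on a
  designated reference set with markers excluded. The **enrichment factor**
  is the CI ratio against a matched pure-plasma reference (an ES-ratio
  alternative is available) — the factor is a documented interpretation, as
  no closed definition exists for it in common use.
* **Dose–response**: OLS on the raw scale (zero counts included) versus
  least squares on log10–log10 (positive pairs only; dropped pairs are
  counted). Model comparison evaluates both on the shared positive subset
  on the raw CI scale and prefers the lower residual sum of squares with an
  AICc margin reported; raw-scale and log-scale R² are never compared.
* **Outlier screen**: baseline = study median of log10(CI + 1e-6); flag
  when a sample exceeds median + k·MAD with k = 3 and the
  consistency-scaled MAD (×1.4826, the standard three-sigma-equivalent
  robust rule; `scale_mad=False` gives the raw MAD). One-sided: only high
  contamination flags. Fewer than 5 defined indices → all flags undefined.
* **Group bias**: Mann–Whitney U (two groups) or Kruskal–Wallis (more, with
  pairwise follow-up when the omnibus flags); rank tests because CI
  distributions are heavy-tailed by construction. Degenerate all-equal
  input returns p = 1.
* **Candidate validation**: Spearman correlation (monotone association
  suffices; Pearson available) of each candidate against every panel
  protein and against the per-sample CI, pairwise-complete, undefined below
  6 paired detections; artifact flag at max |ρ| ≥ 0.7. A screening rule,
  deliberately uncorrected for multiplicity.
* **Z-scored panels**: per protein across samples, population sd on
  detected values; sd = 0 ⇒ z = 0; proteins detected in < 2 samples are
  excluded from the per-sample mean. Population-sd convention is used
  everywhere a CV or z is computed.
* **Physicochemical properties**: recomputed from sequence (no annotation
  lookups): average-mass MW, Kyte–Doolittle GRAVY, (F+W+Y)/length
  aromaticity, Guruprasad instability (hydropathy and dipeptide-weight
  tables from Biopython's ProtParam data), and pI by bisection of the
  Henderson–Hasselbalch net charge with the EMBOSS pKa set (N-term 8.6,
  C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1) to
  |charge| < 1e-4 on pH ∈ [0, 14]. Ambiguous letters (B, Z, X, U, O) count
  toward length and the aromaticity denominator but are excluded from mass,
  hydropathy, charge and dipeptide sums. Enriched-vs-depleted property
  comparisons use Welch two-sided t-tests (the robust default when the
  sidedness and variance assumption are open); "differs by ≥ 80% from neat"
  is read literally as ratio ≥ 1.8 / ≤ 0.2, with a |log2 FC| alternative.
* **PCA/KNN**: sample-space KNN imputation (scikit-learn, k = 3 default,
  NaN-aware Euclidean distance = shared detected proteins), proteins with
  < 2 detections dropped first, then column-centred SVD; variance fractions
  are reported per component.

## Problem sizes

Simulated studies use 150–400 plasma proteins and 50–300 contaminant
proteins, chosen so that repeated-seed experiments (100-seed regime
selection, 100-seed two-group QC, 100-seed outlier screens) each complete
in seconds while every structural feature the statistics depend on — the
dominant top-20 block, the marker/shared split, dropout near the detection
limit — is present. The matrix dimensions affect only estimator variance,
not the identities being tested.

## Known limitations

* The bead capture model has no mechanistic basis (no Langmuir isotherm);
  exponent and capacity are empirical descriptors chosen to reproduce the
  qualitative workflow ranking.
* The exclusive-marker fold-change alignment produces ties; panel ordering
  among exclusives is then decided by the protein-id tie-break, so panel
  *membership* (via the CV filter), not order, is the meaningful output for
  fully exclusive panels.
* Erythrocyte panels derived at the published 8.2 abundance threshold come
  out short under hemoglobin dominance — consistent with the
  hemoglobin-heavy character of real erythrocyte panels, but worth knowing
  when requesting 30 markers.
* Spearman screening flags any candidate monotonically associated with
  contamination, including genuine biomarkers that happen to correlate with
  contamination through the group structure when contamination is strongly
  confounded with the outcome; the strategy reduces, not eliminates, that
  ambiguity (hence step 2, group-bias detection, which fires precisely in
  that situation).
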