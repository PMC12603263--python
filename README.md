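# plasmaqc

Contamination-aware quality control for MS-based plasma proteomics.

Blood plasma is the most widely used biofluid for protein biomarker
discovery, but residual blood cells — platelets, erythrocytes and
peripheral blood mononuclear cells (PBMCs) — contaminate routinely
collected samples and can inflate a plasma proteome by thousands of
cellular proteins. Bead-based enrichment workflows, which compress the
enormous plasma dynamic range to reach low-abundance proteins, are
especially susceptible: a small difference in platelet contamination
between case and control groups can manufacture spurious biomarker
candidates. `plasmaqc` is for proteomics researchers and QC engineers who
need to *measure* that contamination, *model* how it scales, and *screen*
biomarker candidates against it.

## What it computes

**Marker panels.** Cell-type contamination markers are mined from
pure-contaminant vs pure-plasma replicate runs through a four-filter
cascade: fold enrichment over plasma (> 1000× for platelets/erythrocytes,
> 100× for PBMCs), ≥ 2 precursors, mean log10 intensity above a per-cell
threshold (7.5 / 8.2 / 7.1), and replicate CV below 20% / 20% / 35%.
Proteins never seen in plasma are cell-exclusive and ranked above all
shared proteins. Published top-5 panels (ACTB, PFN1, THBS1, TPM4, TLN1 for
platelets; HBB, HBA1, HBD, HBG2, CA1 for erythrocytes; H4C1, H2AZ1, H2BC3,
H2BC14, RAP1B for PBMCs) ship for gene-symbol matching.

**Contamination statistics.** Per sample, the contamination index

    CI = Σ marker intensity / Σ intensity of all other quantified proteins

and the cellular enrichment score ES = Σ top-30 marker intensity / Σ
top-30 plasma protein intensity, both on linear intensities. CI versus
spiked cell count is fitted as CI = m·c + b (ordinary least squares) and
CI = a·c^b (log–log least squares); a concave response (b < 1) is the
signature of bead binding-capacity saturation, and the two models are
compared by raw-scale residuals with an AICc margin.

**Three-step QC for biomarker studies.** (1) flag high-contamination
outliers against the study baseline (median + 3·MAD on log10 CI,
one-sided); (2) test for contamination bias between study groups
(Mann–Whitney U / Kruskal–Wallis); (3) correlate candidate biomarkers with
every marker protein and with the CI (Spearman, pairwise-complete) and
flag candidates with max |ρ| ≥ 0.7 as likely contamination artifacts.

**Workflow profiling.** Rank-abundance shift profiles against the neat
baseline, enrichment/depletion classification (≥ 80% change), Welch
t-tests of six sequence-derived physicochemical properties (MW, length,
pI, GRAVY, aromaticity, instability) between enriched and depleted
proteins, replicate-CV distributions, and PCA with K-nearest-neighbour
imputation.

**Simulator.** A fully ground-truthed generator of plasma + cellular
spike-in experiments (plasma whose top-20 proteins carry ~99% of total
mass; cell proteomes with count-proportional contribution; workflow
compression and bead capacity; calibrated multiplicative noise;
abundance-dependent missingness) so every statistic above is testable
without external data. See `docs/methods.md` for the model.

## Worked example

```python
import warnings
warnings.simplefilter("ignore")
from plasmaqc import simulate as sim, markers as mk, metrics, dose_response as dr
from plasmaqc.markers import MarkerPanel

# 1. derive a platelet marker panel from a simulated pure-contaminant experiment
cont, plasma, truth = sim.scenario_marker_derivation(cell_type="platelet", seed=7)
fc = mk.compute_fold_changes(cont, plasma)
panel = mk.select_markers(fc, cell_type="platelet")
designed = set(truth["marker_ids"])
print(f"derived {len(panel)} markers; all designed markers: "
      f"{set(panel.protein_ids) <= designed}")

# 2. score a bead-workflow dilution series with the panel
matrix, samples, series = sim.scenario_dilution_series(
    cell_type="platelet", workflow="sax", seed=7)
ci = metrics.contamination_index(matrix, panel)
counts = samples.set_index("sample_id")["cell_count"]
for c in (0.0, 1e4, 1e6):
    sel = counts[counts == c].index
    print(f"  {c:>9.0f} platelets/uL -> mean CI {ci.loc[sel, 'ci'].mean():.4f}")

# 3. dose-response regime: residual-baseline neat series vs ultra-pure bead series
for label, wf, baseline in [("neat, study plasma", "neat", 2e4),
                            ("sax, ultra-pure", "sax", 0.0)]:
    m, s, t = sim.scenario_dilution_series(
        workflow=wf, cv=0.15, lod=0.0, markers_only=True,
        n_replicates=4, seed=7, baseline_count=baseline)
    p = MarkerPanel.from_protein_ids("platelet", t.true_markers["platelet"])
    cc = s.set_index("sample_id")["cell_count"].to_numpy()
    civ = metrics.contamination_index(m, p)["ci"].to_numpy()
    out = dr.compare_models(cc, civ)
    print(f"  {label:>20}: preferred {out['preferred']} "
          f"(power exponent b = {out['power'].params['b']:.2f})")
```

prints

```
derived 30 markers; all designed markers: True
          0 platelets/uL -> mean CI 0.0000
      10000 platelets/uL -> mean CI 0.0495
    1000000 platelets/uL -> mean CI 0.7176
    neat, study plasma: preferred linear (power exponent b = 0.31)
       sax, ultra-pure: preferred power (power exponent b = 0.72)
```

The derived panel contains only the designed cell-exclusive markers; the
contamination index rises monotonically with spiked platelet count (0.05
at a moderate 10⁴ cells/µL on the bead workflow); and the model comparison
recognises the unsaturated neat series as linear while identifying the
dynamic-range-compressing bead series as a power law whose fitted exponent
(0.72) recovers the workflow's compression exponent.

A command-line interface mirrors the library:

```sh
plasmaqc simulate --scenario dilution-series --workflow sax --seed 7 --out sim/
plasmaqc derive-markers --matrix pure_runs.tsv --contaminant-samples c1,c2,c3,c4 \
    --plasma-samples p1,p2,p3,p4 --cell-type platelet --out panel.tsv
plasmaqc score --matrix sim/matrix.tsv --panels panel.tsv --out scores.tsv
plasmaqc fit-dose-response --scores scores.tsv --metadata sim/samples.tsv --out fits.tsv
plasmaqc qc --matrix study.tsv --metadata meta.tsv --panels panel.tsv \
    --candidates ids.txt --out report/
```

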