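# cartt2 — layer-specific femorotibial cartilage T2 relaxometry

Articular cartilage T2 relaxation time, mapped from multi-echo spin-echo
(MESE) knee MRI, tracks cartilage matrix composition (hydration, collagen
content and orientation) and varies strongly with tissue depth.  `cartt2`
implements, as a tested pipeline, a laminar (depth-wise) femorotibial T2
analysis for studying early radiographic knee osteoarthritis (ROA):

1. **Voxelwise T2 fitting** — the mono-exponential model
   `S(TE) = S0 · exp(−TE/T2)` is fitted per voxel by nonlinear least squares
   over echoes 2–7 (TE 20–70 ms of a 7-echo TR 2700 ms protocol).  The first
   echo (10 ms) is excluded because stimulated echoes inflate it, and voxels
   with fit R² < 0.66 are eliminated as low image quality.
2. **Laminar partition** — cartilage voxels receive a normalized depth
   `d_bone / (d_bone + d_surface)` from Euclidean distance transforms
   between the segmented bone interface and articular surface, and are split
   into deep (depth ≤ 0.5) and superficial (depth > 0.5) 50% layers.  The
   femoral plates (cMF/cLF) are restricted to their central, weight-bearing
   region of interest; tibial plates (MT/LT) are analyzed whole.
3. **Cohort statistics** — crude between-group contrasts with the pooled-
   variance two-sample t (Welch behind a flag), Cohen's D on the pooled SD,
   ANCOVA adjustment for age/sex/BMI via OLS, Bonferroni significance at
   0.05/6 for the six primary comparisons (3 group pairs × 2 layers), paired
   within-knee one-year change tests, and the superficial-vs-deep change
   contrast.

The original cohort's images (Osteoarthritis Initiative, access-controlled)
cannot be redistributed, so the package ships a first-class synthetic-data
module: MESE phantoms with slab and curved-shell cartilage plates carrying a
known through-thickness T2 profile, optional stimulated-echo contamination
and noise; and subject cohorts with the published three-group structure
(riskROA n=28, earlyROA n=32, healthy n=89) drawn from the published group
summary statistics.  Every downstream stage is validated against this known
ground truth.

## Worked example

Reproduce the knee-level baseline contrast between healthy reference knees
and knees at risk of ROA from the published group summaries (superficial
layer: 45.4 ± 2.3 ms at n=89 vs 48.1 ± 3.1 ms at n=28):

```python
>>> from cartt2 import comparison_from_summary
>>> r = comparison_from_summary(45.4, 2.3, 89, 48.1, 3.1, 28)
>>> round(r.mean_diff_ms, 1), tuple(round(c, 1) for c in r.ci95)
(-2.7, (-3.8, -1.6))
>>> round(abs(r.cohens_d), 2), r.significant_bonferroni
(1.08, True)
```

Healthy knees show 2.7 ms shorter superficial T2 (95% CI [−3.8, −1.6] ms), a
large effect surviving the 0.05/6 multiplicity threshold.  End-to-end on
synthetic data:

```sh
cartt2 run --config configs/demo.yaml --out scratch/demo
```

generates a four-plate phantom at the healthy reference T2 levels and a
three-group cohort, fits the T2 map, writes plate × layer summaries
(`laminar_summaries.csv`), the six primary comparisons crude + adjusted
(`group_comparisons.csv`), longitudinal change tests
(`longitudinal_changes.csv`) and a report with full config provenance.  The
same stages are available stepwise as `cartt2 synth-phantom | synth-cohort |
fit | laminar | stats | validate`.

The `analysis/` directory holds the same study as numbered narrative
scripts (`01_simulate.py` … `05_longitudinal_change.py`), each a thin driver
over the library that prints what it finds and writes its tables under
`results/`.

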