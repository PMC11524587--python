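# reladyn

Analysis pipeline for single-cell NF-κB/RELA nuclear-translocation dynamics
in pancreatic ductal adenocarcinoma (PDAC) cells, with planted-truth
synthetic data so every stage is verifiable end to end.

In PDAC cell lines, the transcription factor RELA (p65) translocates to the
nucleus upon TNFα stimulation, rapidly and without the oscillations seen in
many other cell types; the response is heterogeneous across single cells,
sustained in some lines (MIA PaCa2-like) and damped in others (PANC1-like).
`reladyn` implements the quantitative analyses such an experiment needs:

- **Trajectory analytics** (`reladyn.tracks`) — linear imputation of
  interior gaps, Savitzky–Golay smoothing (order *P*=1, window *n*=7 for
  display/knockdown tracks; *P*=3, *n*=11 before peak calling), per-timepoint
  normalisation to the solvent control (cancels photobleaching),
  first-peak calling as the first post-stimulus timepoint with smoothed
  slope ≤ 0, within-track Pearson correlations between timepoints,
  area-under-the-curve on a 1000-interval refinement, AUC normalisation
  to the non-targeting-siRNA mean and TNFα/control fold-changes, and
  Wilcoxon/t tests with Benjamini–Hochberg correction.
- **Morphometrics** (`reladyn.features`) — derived per-cell features
  (elongatedness = (2·length)²/area, region mean intensities, actin-filament
  area fraction, grouped neighbour contact), per-replicate mean
  normalisation, z-scoring to untreated controls, reduction of the feature
  panel to *k*=10 representatives by complete-linkage clustering on the
  1 − Pearson *r* distance, and PCA.
- **Network inference** (`reladyn.network`) — hybrid Gaussian
  Bayesian-network structure learning (Fisher-z partial-correlation
  restriction, then BIC hill climbing with add/delete/reverse moves),
  per-arc strengths as per-observation BIC deltas on removal, signed
  log₂ dependency matrices for arcs touching the nuclear-RELA node
  (entry = log₂|strength|, ×−1 when the feature depends on RELA), and
  CPDAG-based recovery scoring (SHD, skeleton and orientation
  precision/recall) against a planted truth.
- **Expression profiles** (`reladyn.expression`) — gene filters (<10 total
  counts removed; any-zero genes excluded from results), median-of-ratios
  size-factor normalisation, log₂ transform relative to the matched
  no-TNFα/no-IκB-super-repressor control, per-gene z-scoring, and
  hierarchical clustering into *k*=7 response profiles with mean ± 95% CI
  summaries.
- **Synthetic data** (`reladyn.simulate`) — generators with planted truth
  for all three input kinds: Hill-dose-scaled saturating-rise/decay
  trajectories with lognormal per-cell heterogeneity and interior dropouts,
  linear-Gaussian structural-equation feature tables over the 11-node
  panel, and negative-binomial count matrices with seven planted response
  archetypes over the dose × time × IκB-SR grid.

## Worked example

Simulate damped tracks at three TNFα doses, run the trajectory pipeline,
then learn a dependency network from a planted feature table:

```python
from reladyn import simulate, tracks, network

cfg = simulate.SimulationConfig(doses=(0.0, 0.1, 10.0), n_cells_per_condition=20,
                                sustain_mode="damped", seed=7)
frame, truth = simulate.simulate_tracks(cfg)
res = tracks.analyze_tracks(frame)
peaks = res["peaks"]
print(peaks[peaks.dose_ng_ml > 0]
      .groupby("dose_ng_ml")[["peak_time", "peak_amplitude"]].median())

table, planted = simulate.simulate_feature_table(simulate.SemSpec(seed=7))
sub = network.balanced_subsample(table, strata=("cell_line", "bio_rep"),
                                 n=1000, seed=7)
model = network.arc_strengths(network.learn_network(sub), sub)
rep = network.compare_to_truth(model, planted)
print(f"arcs={len(model.arcs)}  SHD={rep.shd}  "
      f"skeleton P/R={rep.skeleton_precision:.2f}/{rep.skeleton_recall:.2f}")
```

prints

```
            peak_time  peak_amplitude
dose_ng_ml
0.1              60.0            2.17
10.0             60.0            2.68
arcs=10  SHD=0  skeleton P/R=1.00/1.00
```

Peaks fall at 60 min post-stimulus (the damped generator's noise-free
maximum), peak amplitude — the smoothed value at the peak relative to each
cell's pre-stimulus baseline — grows with dose along the Hill curve, and
the learner recovers the planted 10-arc graph exactly (structural Hamming
distance 0 on the equivalence class).

The same stages are scriptable from the shell:

```sh
reladyn simulate tracks --seed 5 --out sim/
reladyn tracks analyze --tracks sim/tracks.csv --out results/
reladyn network learn --table features.csv --strata cell_line,bio_rep \
    --n-per-stratum 1000 --seed 7 --out net/
reladyn expression cluster --counts counts.tsv --meta samples.tsv --k 7 --out expr/
```

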