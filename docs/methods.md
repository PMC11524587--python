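# Methods

## Trajectory model and processing

Tracks are nuclear-intensity time series on a uniform 10-minute grid from
−120 to +600 min around TNFα addition (t = 0). The synthetic generator uses
a minimal phenomenological response

    I(t) = B · (1 + A_cell · E_max · H(d) · g(t)),   t > 0;   I(t) = B,  t ≤ 0

with baseline `B` (a.u.), maximal fold-amplitude `E_max` (default 3),
Hill activation `H(d) = d^h / (d^h + EC50^h)` of the TNFα dose `d` (ng/ml;
EC50 = 0.05, h = 1, placing the half-maximal response between the
physiological 0.01 and the inflamed-tissue 0.1 ng/ml), and shape
`g(t) = (1 − e^{−t/τ_r})` (sustained) or `g(t) = (1 − e^{−t/τ_r}) e^{−t/τ_d}`
(damped). τ_r = 30 min and τ_d = 190 min put the damped noise-free peak
near 60 min post-stimulus, where PDAC cells peak. No mechanistic
NF-κB/IκB feedback is modelled: the form is the simplest one reproducing
the sustained-vs-damped phenomenology, which is all the downstream
statistics consume.

Per-cell heterogeneity is lognormal in the amplitude (`cell_cv`, default
0.3) and, in damped mode, in the decay time (`decay_cv`, default 0.2). The
decay-time spread is what makes late timepoints decorrelate from early ones
within tracks, the behaviour the within-track correlation statistic is
designed to detect; a fixed decay constant would leave r(60, 600) ≈
r(60, 180). No distributional family is reported for the real cells, so
lognormal (positive, right-skewed) is an assumption. Gaussian measurement
noise (sd 2 a.u. against baseline 100) is added and intensities are clipped
at 0; dropouts hit interior grid points only (rate 0.02), matching the
imputation rule's domain. One global seed fans out to per-condition child
seeds by condition index, so adding a dose never changes existing draws.

Processing decisions:

- **Imputation** is linear interpolation of interior gaps; leading/trailing
  gaps are left missing and flagged, and the pipeline trims them before
  smoothing. Linear is an assumption (only a package default is reported
  upstream).
- **Savitzky–Golay edges** are handled by fitting the full window
  polynomial and evaluating it at edge positions (`scipy.signal.savgol_filter`,
  `mode="interp"`).
- **Peak calling** smooths with order 3 / window 11, takes the slope at
  t_i as the forward difference `(s_{i+1} − s_i)/dt` — the simplest
  estimator consistent with a "first timepoint with slope ≤ 0" rule — and
  returns the first t_i > 0 satisfying it. If none exists before the final
  difference, the call is censored at the last timepoint (the fallback is
  otherwise unspecified). Peak amplitude divides the smoothed value at the
  peak by the mean smoothed pre-stimulus (t < 0) signal; whether amplitudes
  should instead be scaled to t = 0 or to the solvent control is an open
  question upstream, and this choice is configurable in effect by
  normalising first.
- **Solvent-control normalisation** divides each value by the mean of the
  dose-0 measurements for the same cell line (and, when present, siRNA
  stratum) and timepoint. Any multiplicative drift shared by treated and
  control wells cancels exactly; control strata have per-timepoint mean
  exactly 1.
- **AUC** integrates the linear interpolant over `[0, t_last]` by default
  (the pre-stimulus 2 h are excluded; the window is configurable). The
  trapezoid runs on the union of a 1000-interval uniform refinement and
  the track's own knots, so the quadrature is exact for the piecewise-linear
  interpolant and AUCs are additive over adjacent windows to machine
  precision.
- **Group testing** uses the Mann–Whitney U (Wilcoxon rank-sum) statistic —
  exact for small tie-free samples, normal approximation with tie
  correction otherwise, as implemented in scipy — or Welch-free pooled
  t-tests, with Benjamini–Hochberg step-up adjustment across each
  comparison family and α = 0.05.

## Morphometric features

Feature reduction computes Pearson correlations between features across
single cells pooled over all conditions (a seeded subsample cap of 20,000
cells bounds memory), clusters on 1 − r with complete linkage, and cuts at
k = 10. The representative of each cluster is its **medoid** — the member
with the greatest mean |r| to the others, ties broken lexicographically —
because the original selection rule for one feature per cluster is not
recorded; the medoid is the reproducible default. Control z-scores use the
sample (n−1) standard deviation of the pooled control cells per feature and
biological replicate. PCA runs on the z-scored matrix via a full SVD;
loadings are orthonormal and components ordered by explained variance.

The feature-table generator draws from a linear-Gaussian structural
equation model over the 11-node panel (nuclear RELA mean plus ten reduced
morphometric features): each node is the coefficient-weighted sum of its
parents plus unit-variance Gaussian noise, evaluated in topological order.
The default planted DAG has 10 arcs with coefficients |β| ≥ 0.5 — e.g.
cytoplasm actin and tubulin means feeding nuclear RELA, RELA feeding the
membrane/cytoplasm actin ratio and nucleus roundness — a regime in which
every dependency is identifiable at the default n = 15,000 (1000 cells per
stratum over 5 cell lines × 3 replicates; stratum labels are annotations
only, the SEM is shared, matching the pooled analysis). Per-node noise is
seeded by a CRC of the node name, so permuting declarations leaves the
sample unchanged.

## Network inference

Structure learning is a hybrid restrict/maximise procedure over Gaussian
variables:

1. **Restrict.** A PC-style skeleton: starting from the complete graph,
   the edge i–j is deleted as soon as some conditioning set S (drawn from
   the current neighbourhoods of i or j, |S| growing from 0 to
   `max_sepset_size` = 3) yields a Fisher-z partial-correlation test with
   p > α (`restrict_alpha` = 0.05). Traversal is lexicographic, so the
   phase is deterministic and the surviving adjacencies symmetric.
2. **Maximise.** Greedy hill climbing from the empty graph over arc
   additions, deletions and reversals confined to the restricted skeleton,
   maximising the Gaussian BIC
   `Σ_v [loglik(v | parents) − (|parents|+2)/2 · log n]`, with acyclicity
   checked at every move and candidate moves ordered lexicographically by
   (from, to) so ties resolve deterministically. No random restarts by
   default.

The score choice (BIC) and the arc-strength semantics are design
decisions: **arc strength** is the per-observation score delta on removing
the arc, `(score_without − score_with)/n`, negative when removal worsens
the fit, chosen over test-p-value semantics because downstream summaries
log-transform strength magnitudes. The **dependency matrix** collects, per
data context (all data, per cell line, per dose), `log₂|strength|` for
every arc touching the nuclear-RELA node, multiplied by −1 when the arc
points from RELA to the feature; zero-magnitude strengths are left
undefined. Dose enters only through data pooling, not as a network node.

Because covariance-equivalent DAGs can reverse arcs without changing fit,
**recovery scoring is on the CPDAG**: v-structures are identified and
Meek's rules R1–R3 close the compelled orientations (starting from a DAG's
pattern, R4 never fires); SHD counts per-pair disagreements between
CPDAGs, and orientation precision/recall is computed on compelled arcs
only. On three-node problems the learner provably reaches the global BIC
optimum found by exhaustively scoring all 25 DAGs (checked in tests).

## Expression profiles

Differential-expression inference itself (DESeq2 dispersion estimation and
Wald tests) is out of scope; the pipeline consumes a gene set — in
practice the synthetic planted panel — and implements the descriptive
stages: the two-stage filter (<10 total counts removed before statistics;
genes with any zero count retained for statistics but excluded from
results), **median-of-ratios size factors** (per sample, the median over
all-positive genes of the count over its geometric mean across samples),
log₂ values relative to the matched control — the mean of the normalised
counts of the no-TNFα/no-IκB-SR technical replicates for the same cell
line and timepoint, taken before the log (log-of-mean; the alternative
mean-of-log is a one-line change) — per-gene z-scores with the population
(n) standard deviation (the convention under which the two-point profile
{−1, +1} standardises to itself; zero-variance genes are set to 0 and
flagged rather than dropped), and complete-linkage clustering of
z-profiles on 1 − Pearson r cut at k = 7, mirroring the feature-reduction
settings because the distance used upstream for the gene heatmap is not
recorded. Cluster summaries report mean z per condition with a
mean ± 1.96·se ribbon across member genes.

The count generator plants seven response archetypes over the dose × time
× IκB-SR grid — two down-regulated clusters (one further suppressed by the
super-repressor, one RELA-independent), a strongly dose-dependent
RELA-dependent cluster growing with duration, a late RELA-dependent
cluster, a dose- and duration-independent cluster, a dose-dependent
duration-independent cluster, and an early-response cluster. Archetypes
were designed to be genuinely distinct under the clustering metric
(pairwise profile correlations ≤ 0.72, response magnitudes ≥ 1.5 log₂),
the defining property of well-separated response classes. Defaults: 254
genes (the size of a TNFα-regulated panel) assigned round-robin,
negative-binomial dispersion 0.02 — the technical-replicate regime
appropriate to repeated libraries from one clone; samples here are
technical replicates, not biological donors — lognormal relative
abundances, and uniform library sizes in [5×10⁵, 1.5×10⁶]. At
biological-cohort dispersions recovery degrades monotonically (a seeded
sanity test tracks this), so recovery results should not be read as claims
about noisy cross-donor designs. Dispersion 0 switches sampling to
Poisson.

## What the synthetic data do and do not show

The generators reproduce the statistical structure each stage assumes —
Hill dose dependence, sustained/damped kinetics with heterogeneity and
interior dropouts, linear-Gaussian feature dependencies, archetypal
expression responses with NB noise. They do not emulate: image
segmentation error, cell division/death and track fragmentation,
cell-cycle effects, non-linear or non-Gaussian feature dependencies,
cell-line-specific expression asymmetries (archetypes are shared across
lines), or transcriptome-scale abundance tails. Passing tests therefore
demonstrate correctness of the computations and recoverability under the
stated models, not robustness to every failure mode of real microscopy or
sequencing data.

## Numerical and reproducibility notes

- Problem sizes in the validation harness: 500 cells for peak recovery;
  2000 null replicates for the test-level check; 20 planted-SEM seeds at
  n = 15,000 and 50 null-model runs at n = 2000 for the network benchmark;
  254 genes × 64 samples for profile recovery.
- All generators are pure functions of (spec, seed); child seeds derive
  from `numpy.random.SeedSequence` spawn keys. The learner, clusterings
  and CLI stages are deterministic given their inputs, so reruns are
  byte-identical.
- Hill climbing accepts a move only if it improves BIC by >1e−10;
  degenerate inputs (constant nodes, collinear features, zero control sd,
  zero-variance correlation strata) raise or flag rather than silently
  producing numbers.
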