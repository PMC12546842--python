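# cyclequant

Quantitative analysis of multi-plex TMT time-course proteomics for the
predatory life cycle of *Bdellovibrio bacteriovorus*.

*B. bacteriovorus* invades the periplasm of a prey bacterium (here
*Escherichia coli*), consumes it from within, divides, and lyses the
prey remnants to escape — a cyclic lifestyle whose stages can be read
from the relative abundance of predator proteins over time.  Measuring
this requires isobaric (TMT) labeling across several multiplexed MS
runs, and that in turn requires careful cross-run normalization before
any biology can be inferred.  `cyclequant` implements that analysis as
a reusable, tested library for proteomics analysts:

* **Baseline pooling** — an in-silico `AP_Ec` channel combining the
  attack-phase (AP) and prey-only (Ec) controls, the baseline for all
  comparisons with the mixed predator+prey timepoints.
* **Normalization** — sample-loading (SL) equalization of channel
  totals within each plex; internal reference scaling (IRS) anchoring
  all plexes on golden-standard (GS) channels that contain an equal
  mixture of every sample; trimmed-mean-of-M-values (TMM) correction of
  residual compositional shifts; then a >1 filter, log2 transform and
  per-channel median-centering.
* **Differential expression** — per-protein linear model
  `y = Condition + Plex`, empirical-Bayes moderated t-tests of every
  timepoint against `AP_Ec` (variance shrinkage
  `s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g)` with trigamma
  moment-matched prior), Benjamini–Hochberg FDR per contrast, and
  regulation calls at |log2FC| ≥ 1, FDR < 0.05.
* **Profile clustering** — baseline-relative log2 trajectories,
  hierarchical clustering (Euclidean) cut at 18, automated merging of
  correlated centroids (r ≥ 0.9) to ~9 temporal clusters plus one
  "unchanged" cluster, and COG category composition per cluster.
* **QC & reports** — PCA of normalized samples (reference channels at
  the center, timepoints tracing the life-cycle loop), proteome
  coverage, protein-length/membrane bias diagnostics, volcano tables,
  heatmap ordering.
* **Synthetic studies** — a simulator of the full five-plex design with
  known ground truth (archetype trajectories, batch and loading
  factors, reporter noise, abundance/length-biased missingness), so the
  whole chain is testable end to end.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Simulate a default five-plex study and run the full chain:

```sh
cyclequant run --out demo --seed 7
```

prints (abridged):

```json
{
  "counts": {
    "input": 2800,
    "after_complete_case_filter": 1471,
    "predator_split": 1051,
    "predator_significant": 608
  },
  "log2fc_rmse_vs_truth": 0.0947
}
```

2800 simulated proteins (2000 predator + 800 prey) enter; 1471 are
observed in every channel of all five plexes; 1051 predator proteins are
analyzed, of which 608 pass the clustering prefilter (omnibus moderated
F, p < 0.001, q < 0.01).  The estimated per-timepoint log2 fold changes
agree with the simulator's ground truth to an RMSE of 0.095 log2 units.

`demo/de.tsv` holds one row per protein × contrast:

```
protein_id  condition  contrast       log2fc   t      p         q          fold  call
Bd0727      T4h        T4h_vs_AP_Ec   2.03     ...    ...       1.0e-75    4.1   up
Bd0619      T4h        T4h_vs_AP_Ec   1.98     ...    ...       1.6e-73    3.9   up
```

— proteins called `up` at the exit phase (T4h) are 4-fold above the
pooled baseline with vanishing FDR, the simulated analogue of
exit-phase proteases.  `demo/clusters.tsv` assigns each profiled
protein to a merged temporal cluster (A…I by peak time) or `unchanged`;
on this run the 9 simulated archetypes are recovered (~60–77 proteins
each) with 443 proteins in the unchanged cluster.

The same stages are available as a library:

```python
from cyclequant import SimConfig, simulate_experiment, pipeline

study = simulate_experiment(SimConfig(seed=7))
result = pipeline.run_on_study(study)
result.predator.de          # DataFrame: log2fc, t, p, q, fold, call
result.predator.clusters    # fine + merged cluster assignment
```

Useful analytic one-liners:

```python
from cyclequant.report import coverage_fraction
from cyclequant.diffexp import fold_change_linear

coverage_fraction(2195, 3583)   # -> 61   (percent of the proteome quantified)
fold_change_linear(3.20)        # -> 9.2  (linear fold for a log2FC of 3.20)
```

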