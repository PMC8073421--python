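# grtime

Time-course analysis of glucocorticoid-receptor (GR/NR3C1) enhancer binding,
enhancer remodeling, and gene-expression dynamics after dexamethasone.

## The problem

Dexamethasone activates GR, which binds distal enhancer sites and recruits
coactivators (EP300) while enhancer chromatin marks (H3K27ac, H3K4me1) are
remodeled; transcription of target genes changes over the following hours.
Given RNA-seq counts and ChIP-seq peak calls / coverage tracks sampled on a
time grid (0–12 h), the question is *when* each signal is concentrated in
time relative to the others: does enhancer remodeling lead or follow
expression change?

`grtime` implements the analysis as a reusable, tested pipeline:

1. **Expression**: quantile normalization → per-gene one-way ANOVA across
   time points → Benjamini–Hochberg FDR → z-scored profiles leveled to 0 at
   baseline, classified up/down → a random control gene set matched on
   expression level and transcript length.
2. **Peak-to-gene mapping**: ChIP peaks are assigned to every gene whose TSS
   lies within ±100 kb of the peak midpoint; the ±2 kb core around the TSS
   is the promoter class, the rest of the window the enhancer class.  Per
   gene, the enhancer peak with the strongest NR3C1 amplitude at the 1 h
   reference time is selected.
3. **Kinetics**: within each selected peak, coverage of NR3C1, EP300,
   H3K27ac and H3K4me1 is summarized (maximum by default) at every time
   point, and each series is reduced to its **weighted maximum time (MWT)**.
4. **EP300 dynamic ranking**: all enhancer NR3C1 peaks are ranked by the
   largest difference in mean EP300 coverage between any two time points
   from 30 min on; the top-100 peaks are mapped to their nearest genes (one
   peak per gene, keeping the stronger NR3C1 amplitude).
5. **Statistics**: two-way (time × cluster) interaction ANOVA on peak
   amplitudes, post hoc ratio *t*-tests against baseline, one-/two-way ANOVA
   across MWT groups with Bonferroni pairwise tests, cubic trend fits.

## The MWT statistic

For a ChIP amplitude series $a_i$ on the grid $t_0 = 0 < t_1 < \dots < t_n$:

$$\mathrm{MWT} = \frac{\sum_i a_i\, t_i}{\sum_i a_i}$$

i.e. the amplitude-weighted mean of time — an MWT of 1.5 h means binding is
concentrated equally around 1 h and 2 h.  For expression, the weights are
forward differences of the replicate-averaged profile,
$d_i = x(t_i) - x(t_{i-1})$, attributed to the later time point and clamped
to the regulated direction ($w_i = \max(d_i, 0)$ for upregulated genes),
so the statistic locates the time of maximal expression *change*:

$$\mathrm{MWT}_\mathrm{expr} = \frac{\sum_{i\ge1} w_i\, t_i}{\sum_{i\ge1} w_i}$$

MWT is invariant under positive scaling of the weights and equivariant under
time shifts.

Because re-deriving every input from public archives is a heavy download,
the package ships a synthetic-data generator (`grtime.simulate`) that emits
the complete input set — counts, annotation, narrowPeak calls, bedGraph
tracks — from logistic expression responses and factor-specific binding
pulses with *known* amplitude-weighted centroids, so every stage is testable
against ground truth.

## Worked example

```python
from grtime.simulate import SimulationConfig, simulate_dataset
from grtime.pipeline import PipelineConfig, run_pipeline

cfg = SimulationConfig(seed=42, n_up=50, n_down=50, n_null=500)
ann, counts, expr_truth, peaks, tracks, chip_truth = simulate_dataset(cfg)
res = run_pipeline(counts, ann, peaks[("NR3C1", 1.0)], tracks,
                   PipelineConfig(seed=42, ep300_k=50))

print(res.counts_log)
up = res.regulated.index[res.regulated.cluster == "up"]
print(res.mwt.loc[res.mwt.index.intersection(up)].median().round(2))
print("F =", round(res.stats.F, 1))
```

prints

```
{'genes_total': 600, 'genes_up': 50, 'genes_down': 68, 'genes_random': 118,
 'peaks_assigned': 184, 'genes_with_enhancer_peak': 77, 'genes_with_mwt': 77,
 'ep300_top_genes': 50}
NR3C1         4.60
EP300         5.51
H3K27ac       4.98
H3K4me1       4.79
expression    5.53
F = 203.6
```

Reading the medians: GR binding is concentrated earliest (4.6 h), the
histone marks follow (4.8–5.0 h), and EP300 recruitment (5.5 h) nearly
coincides with the time of maximal expression change (5.5 h) — the one-way
ANOVA across the five MWT groups is overwhelming (F = 203.6), and the post
hoc table shows expression vs EP300 as the single non-significant pair
(p ≈ 0.99 before correction) while every other pairwise difference survives
Bonferroni at p < 1e-9.

The same stages are available from a shell:

```sh
grtime simulate --seed 42 --out-dir data/
grtime de --counts data/counts.tsv --meta data/meta.tsv -o de.tsv
grtime map-peaks --peaks data/NR3C1_t1.narrowPeak --annotation data/genes.tsv -o asg.tsv
grtime signal --peaks selected.tsv --tracks data/tracks.yaml -o series.tsv
grtime mwt --series series.tsv -o mwt.tsv
grtime ep300-top --peaks data/NR3C1_t1.narrowPeak --tracks data/tracks.yaml \
       --annotation data/genes.tsv --k 100 -o top.tsv
grtime stats --mwt mwt.tsv -o stats.tsv
```

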