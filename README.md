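# sescape

Super-enhancer landscape analysis for two-condition ChIP-seq experiments.

`sescape` implements the regulatory-genomics pipeline used to ask whether a
hyper-activated transcriptional co-activator (such as nuclear YAP after loss
of the Hippo kinases Mst1/2) remodels the super-enhancer landscape of a cell:
which binding sites gain signal, which factors co-occupy them, where new
super-enhancers arise, and whether nearby genes respond transcriptionally.
It consumes standard files — narrowPeak/broadPeak peak calls, fragment BED,
bedGraph signal, a BED6 gene table, a chromatin-state segmentation and an
FPKM expression table — and is exercised end-to-end on a built-in synthetic
data generator that plants every structure the analysis is meant to recover.

## What it computes

* **Differential binding** — peaks are filtered at −log10 *P* > 9 and fold
  enrichment > 3, the WT/KO union is formed (≥ 1 bp overlap merges), and each
  union peak is classified by RPKM fold change: *up* if
  RPKM<sub>KO</sub> > 2 × RPKM<sub>WT</sub>, *down* if
  RPKM<sub>KO</sub> < RPKM<sub>WT</sub>/1.5 (strict, pseudocount ε = 0.25).
* **Co-localization enrichment** — for factor peak sets *a*, *b* on a genome
  of *L* bp, score = observed overlap / expected, with
  E[overlap] = cov(*a*)·cov(*b*)/*L* and a binomial tail
  *p* = P(X ≥ obs), X ~ Bin(min cov, max cov/*L*); factors are clustered
  hierarchically (average linkage, correlation distance) on the
  log2(score+1) matrix.  The same observed/expected score is computed per
  chromatin state.
* **Super-enhancer calling (ROSE)** — H3K27ac peaks stitched at ≤ 12.5 kb,
  regions scored as max(0, RPKM<sub>treat</sub> − RPKM<sub>input</sub>) ×
  length, ranked, and split at the geometric inflection point of the
  rescaled ranked-signal curve (slope-1 tangent).  An SE whose signal over
  its span is > 2-fold higher in one condition is unique to it; SEs are
  annotated with every factor overlapping them by ≥ 1 bp.
* **Expression integration** — DE genes require FPKM > 1, fold > 2 and
  q < 0.01; expression classes are cross-tabulated against binding classes
  (±50 kb TSS windows), and gene groups are compared with a two-sample
  rank-sum test plus cumulative-fraction curves.
* **Synthetic data** — a seeded generator plants co-binding (latent-Gaussian
  copula), SE clusters (common / gained / lost), a KO boost on YAP sites
  with coupled OSN/H3K27ac gains, and linked expression changes, writing a
  machine-readable `truth.json` so every stage has a recovery target.

## Worked example

```sh
cd examples && python 01_simulate_dataset.py && python 04_superenhancers.py
```

prints (seed 42):

```
planted sites:        600
SE clusters:          Counter({'common': 21, 'ko_unique': 6, 'wt_unique': 3})
...
wt: 222 stitched regions, 25 SEs (signal cutoff 1582)
ko: 222 stitched regions, 31 SEs (signal cutoff 2030)
unique to KO: 9, unique to WT: 3, common: 44
YAP-bound SEs: 51 / 56
planted-cluster recovery: recall 1.00, precision 0.92, KO-unique recall 1.00
```

The knockout gains super-enhancers exactly where the generator planted its
six `ko_unique` clusters (recall 1.0); most called SEs are YAP-bound, and
the handful of extra KO-side calls are strongly boosted typical enhancers.
`02_differential_binding.py`, `03_colocalization.py` and
`05_expression_integration.py` walk the other stages the same way.

The full pipeline (simulate → differential peaks → co-localization → SEs →
expression) runs as one command and writes a JSON report with all counts
and recovery metrics:

```sh
sescape run --out run1 --seed 42
```

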