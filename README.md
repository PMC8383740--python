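# tracekin

Quantitative tools for dye-dilution (CellTrace/CFSE) T-cell proliferation
analysis and a companion transcriptomic receptor survey, with simulators that
provide ground truth for every stage.

## What it does

- **`tracekin.synthetic_data`** — simulate labeled dilution cohorts
  (log-normal label, 2-fold dilution per division, autofluorescence floor,
  instrument CV, per-generation precursor fractions, quota or multinomial
  assignment), dose series with a configurable undivided-fraction effect, and
  negative-binomial count matrices with planted fold changes and paralog
  gene groups. Every event carries its true generation; every planted gene
  its true fold change.
- **`tracekin.flow_io`** — minimal FCS 3.0/3.1 read and FCS 3.1 write (list
  mode, float/integer data, both byte orders; unsupported dialects are
  rejected loudly), CSV event tables, log10/arcsinh transforms with recorded
  per-channel state, rectangular gates (closed intervals, boundary events
  kept), and seed-deterministic equal-count downsampling.
- **`tracekin.deconvolution`** — replace manual peak gating: a constrained
  1-D Gaussian mixture (means on an arithmetic −log10(2) grid, optionally
  refined ±10%, shared sd) fitted by EM on a compressed histogram yields
  per-generation frequencies X_1..X_{D+1}, MAP event labels, and
  Gen1 / Gen2–5 / Gen6+ binning. Explicit gate boundaries are supported as a
  manual-gating equivalence path.
- **`tracekin.proliferation`** — precursor-normalized statistics:
  Φ₁ = 100·X₁/(X₁ + Σᵢ X_{i+1}/2ⁱ) (percent undivided), the recursive Φ
  series, θᵢ = 100 − Φᵢ curves, cohort division/proliferation/expansion
  indices, two-arm comparisons (percent increase in Φ₁, per-generation
  Welch/pooled t-tests with Holm-Šidák adjustment, Mann-Whitney on division
  medians, one-way ANOVA helper).
- **`tracekin.expression`** — paralog read grouping (counts and lengths
  summed before normalization; defaults FCGR2 = 2A+2B+2C, FCGR3 = 3A+3B),
  median-of-ratios size factors, normalized reads/kilobase, TPM, inclusive
  expression thresholds (1 / 0.5 / 0.25 TPM plus the ≥1.2 basal flag),
  BH adjustment, a convenience NB Wald DEG test (method-of-moments
  dispersion — not a DESeq2 clone; external statistics are the fidelity
  path), the DEG/trend classification rule (adjusted p < 0.05 and fold
  change ≥ 1.5 either direction; trends at p < 0.10), and per-cell CPM of
  gene groups.
- **`tracekin.enrichment`** — Signal2Noise ranking (floored sigmas),
  weighted running-sum enrichment score, gene-set (default) or phenotype
  permutations with NES and null-pool FDR q (enriched at q < 0.25), and
  hypergeometric DEG-overlap tests against an explicit universe (significant
  at q < 0.005 by default). GMT and RNK file I/O.

## CLI

```bash
tracekin simulate --profile 0.5,0.3,0.2 --n 10000 --seed 7 --out events.fcs
tracekin gate events.fcs --channel CellTrace --low 2.5 --high 5 --out gated.fcs
tracekin downsample a.fcs b.fcs --n 7790 --seed 1 --out-dir downsampled/
tracekin deconvolve events.csv --channel CellTrace --max-gen 10 --out fit.json
tracekin prolif fit.json --out prolif.csv
tracekin compare --treated t1.json --treated t2.json \
                 --control c1.json --control c2.json --out compare.csv
tracekin rnaseq-survey --counts counts.tsv --lengths lengths.tsv \
                       --subsets '{"naive": ["s1","s2"]}' --out calls.csv
tracekin deg --counts counts.tsv --lengths lengths.tsv \
             --groups '{"s1":"A","s2":"A","s3":"B","s4":"B"}' --out deg.csv
tracekin enrich --rnk ranked.rnk --gmt sets.gmt --n-perm 1000 --seed 0 --out gsea.csv
tracekin overlap --degs degs.txt --gmt sets.gmt --universe universe.txt --out overlap.csv
```

Events move between FCS and CSV freely (extension decides the format).

## Notes

- Quota generation assignment (largest remainder) makes simulated event
  counts and Φ identities exact; multinomial assignment is available via
  `assignment="multinomial"`.
- Deconvolution requires the channel to be log10-transformed (use
  `flow_io.log10_transform` or `--log10` on the CLI); D (observed divisions)
  is derived from the fitted weights, never user-asserted, unless explicit
  boundaries are supplied.
- Absolute generation indexing is ambiguous when a sample contains no
  undivided cells (the brightest peak could be Gen1 or Gen2). Pass the known
  undivided landmark — e.g. the unstimulated-control peak position — via
  `fit_generations(anchor_mean=...)` or `tracekin deconvolve --anchor` to pin
  Gen1.
- The built-in DEG test needs ≥ 2 replicates per group and is intentionally
  simple; ingest externally computed per-gene statistics for publication-
  grade calls.
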