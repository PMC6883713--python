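# splicegc

Why do some alternative exons need U1 snRNP–side factors to be included
while others depend on the U2 snRNP side? A large body of knockdown
RNA-seq work shows that splicing-factor–activated exons split into two
composition regimes: **GC exons** — GC-rich, embedded in GC-rich genes
with small flanking introns, where the challenge is stable RNA structure
at the donor site — and **AT exons** — AT-rich, flanked by large introns
riddled with decoy branch points and pyrimidine-tract-like signals that
compete for 3′-splice-site recognition. These regimes track genome
organization: GC exons sit in GC-rich isochores, AT exons concentrate in
lamina-associated domains.

`splicegc` is a Python toolkit for running this style of analysis
end-to-end. It is aimed at computational biologists who have regulation
tables (which factor activates which exon, e.g. from differential PSI
calling), a genome, and standard coverage/peak/domain files, and want the
composition classification, splice-signal features, and domain statistics
reproducibly, plus a synthetic-genome generator to validate the whole
chain against planted ground truth.

## What it computes

* **Exon classes** — per-factor activated sets (activated in ≥ 1 sample,
  never repressed by the same factor); factor classification by median
  exon GC (threshold 49.3 %) and median smallest flanking intron
  (threshold 691 bp); exon labels GC / AT / excluded_overlap / none;
  control, U1 (SNRPC, SNRNP70, DDX5/17) and U2 (U2AF2, SF3B4, SF1, SF3A3)
  exon sets.
* **Composition statistics** — base frequencies,
  `RFreq = 100·(median_S − median_C)/median_C` heatmaps against control
  exons, and 20-nt sliding-window junction profiles.
* **Splice signals** — branch-point calls (YTNAY consensus caller, or
  imported external scores) in the last 100 nt of the upstream intron;
  hydrogen bonds between the BP context and the U2 snRNA
  branch-point-binding sequence GUGUAGUA (non-crossing duplex maximum);
  TNA motif and T-rich window counts; junction folding scores (Nussinov-
  style default engine, RNAfold pluggable).
* **V value** — for each spliceosome-associated factor, the signed log10
  empirical p of its GC-exon regulation proportion against 10,000
  size-matched subsamples of the AT set:
  `P_emp = max(min(k,l)/10⁴, 10⁻⁴)`, `v = log10(P_emp)·s` with `s = 1` if
  `k > l`, else −1. Positive v ⇒ regulation concentrated on GC exons.
* **Coverage metaplots** — 1000-bin length-normalized profiles over gene
  parts (drop-first-199 rule for internal exons/introns), exon-window
  mean coverage, the (GC − AT)/max(GC, AT) contrast, and CLIP peak
  positional-proportion maps over −200..+50 around splice sites.
* **Domains** — maximal-overlap assignment of exons to isochores, TADs
  and LADs, per-domain class counts, class proportions per domain kind,
  and exon-vs-domain GC correlations.

## Worked example

Simulate a genome with planted composition structure and run every stage:

```
$ splicegc run-all --seed 1 --bundle-dir bundle --out results
complete: True stages: ['simulate', 'classify', 'features', 'vvalue', 'metaplot', 'domains']

$ cat results/factor_classes.tsv
factor   n_exons  median_gc  median_min_intron  class
HNRNPA1  118      34.19      1124.5             AT-class
HNRNPF   118      59.66      244.5              GC-class
HNRNPM   118      33.15      1120.5             AT-class
PTBP1    118      34.63      1147.5             AT-class
RBFOX2   118      59.42      229.5              GC-class
SRSF9    118      58.66      241.5              GC-class
TRA2A    118      33.21      1191.5             AT-class
```

Each synthetic factor is classified from its own exon set: the three
GC-context factors have median exon GC above 49.3 % and median smallest
flanking introns well below 691 bp, the four AT-context factors the
converse. The V-value table for the simulated spliceosome-associated
factors recovers their planted preferences — U1-like factors (SNRPC,
SNRNP70, DDX5/17) regulate a much higher proportion of GC exons than any
AT subsample reaches (`v = +4`, the saturation value at 10⁴ iterations),
U2-like factors the mirror image:

```
$ cat results/v_values.tsv
factor   n_iter  observed_proportion  k      l      p_emp   v     significant
DDX5/17  10000   0.2549               0      10000  0.0001  4.0   True
SF1      10000   0.0833               10000  0      0.0001  -4.0  True
...
SNRPC    10000   0.2402               0      10000  0.0001  4.0   True
U2AF2    10000   0.1029               10000  0      0.0001  -4.0  True
```

Downstream contrasts point the expected way: GC exons carry ~2.2× the
nucleosome-like coverage of AT exons (`gc_at_ratio = 0.55`), exon GC
correlates with hosting-isochore GC at Pearson r = 0.93, and 60 % of AT
exons versus 0 % of GC exons fall inside LAD-kind domains
(`results/coverage_stats.tsv`, `results/domain_correlations.tsv`,
`results/domain_proportions.tsv`).

The same stages run on real inputs by pointing `--bundle-dir` at a
directory with `genome.fa`, `genes.tsv`, `exons.tsv`, `regulation.tsv`,
`peaks.bed`, `coverage.bedgraph` and `domains.tsv` (formats in
`splicegc/io.py`; coordinates 0-based half-open), or through the library
API (`import splicegc`). A YAML config (`--config`) exposes every
analysis constant under its default value.

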