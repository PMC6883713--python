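# Methods

`splicegc` implements an analysis linking the nucleotide composition of
alternatively spliced exons to the splice signals around them and to the
genomic domains that host them. This note describes the models and
procedures, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Exon classes

Splicing factors are classified from the exons whose inclusion they
support. For each factor, the activated set contains every exon activated
in at least one sample and never repressed by that factor in another
sample; exons regulated in opposite directions by the same factor are
dropped, and a table reporting both directions for the same
(factor, sample, exon) triple is rejected as corrupt.

A factor is **GC-class** when its activated set has a median exon GC
content above `gc_threshold` (default **49.3 %**) *and* a median smallest
flanking intron below `intron_threshold` (default **691 bp**); the
symmetric case is **AT-class**; factors meeting only one criterion (for
example, factors activating GC-rich exons flanked by large introns) stay
unclassified. Both inequalities are strict, so a median sitting exactly on
a threshold leaves the factor unclassified. The default thresholds are the
genome-wide control medians of the human FasterDB annotation; they are
pinned rather than recomputed so classification is deterministic for any
input, and `ClassThresholds.from_control_exons` re-derives them from a
supplied control set when that behavior is wanted. The same two-criterion
rule generalizes to purine/pyrimidine (GA/CT) composition via `base_set`;
for those classes the intron criterion is optional and off by default,
since the composition alone defines them.

Exon labels are factor classes pushed down: an exon is a **GC exon** when
at least one GC-class factor activates it and no AT-class factor does
(symmetrically for **AT exons**); exons claimed by both classes are set
aside as `excluded_overlap` rather than arbitrated; all other exons are
`none`. The control set contains constitutive coding internal exons never
activated by any analyzed factor. Exons missing a flanking intron
(terminal exons) are excluded from smallest-flanking-intron medians
instead of contributing a one-sided value.

## Splice-signal features

All features are computed in transcript orientation, with T standing for
both thymine and uracil. N bases never enter a frequency denominator and
break motif matches.

* **Branch points** — candidate BPs are adenines in the last
  `bp_search` = 100 nt of the upstream intron, scored against the YTNAY
  consensus (positions −3..+1 around the A): score = matches among the
  four constrained positions − 2, i.e. a perfect consensus scores 2 and
  two flank mismatches disqualify. The default retains only
  perfect-consensus sites. This is a deliberate calibration: allowing one
  flank mismatch retains so many sites that essentially every 100-nt
  window of any realistic base composition holds two or more calls, making
  the "≥ 2 branch points" indicator saturate and carry no information;
  `min_score=0` restores the permissive rule for users who want it.
  External caller output (e.g. from a support-vector BP model) can be
  imported from TSV and is used identically downstream. The multi-BP
  indicator `has_2bp` uses k = 2 ("at least two"), exposed as a parameter.
* **U2 snRNA binding** — the 9-nt BP context (5 nt before the adenine,
  3 after) minus the adenine gives an 8-nt target hybridized antiparallel
  to the U2 branch-point-binding sequence GUGUAGUA. The score is the
  maximum total hydrogen-bond count over non-crossing pairings
  (G:C = 3, A:U = 2, G:U wobble = 2), with unpaired bases and loops
  unpenalized, solved by an alignment-style dynamic program against the
  reversed probe. When several BPs are called, the best-scoring one
  (ties broken toward the 3′ ss) is scored.
* **TNA motifs** (SF1-like sites) — positions i with T at i and A at i+2,
  overlaps allowed, in the last `tna_window` = 50 nt of the intron.
* **T-rich low-complexity windows** (U2AF2-like) — 4-nt windows, step 1,
  holding ≥ 3 Ts, in the region −75..−35 nt from the 3′ ss (41 nt,
  38 windows).
* **Junction folding** — a 50-nt window (25 nt intron + 25 nt exon) at
  each splice site is folded by the default engine: Nussinov-style
  maximization of hydrogen bonds over non-crossing pairs with hairpin
  loops ≥ 3 nt, reported negated so lower = more stable. The engine is
  pluggable; `rnafold_engine` shells out to ViennaRNA's RNAfold for
  thermodynamic energies when that behavior is preferred. The engine
  contract is only "real, ≤ 0, lower for more stably paired sequences",
  which is all the downstream class contrasts use.

## Composition statistics

The relative frequency of a feature D between a regulated set S and the
control set C is

    RFreq(D) = 100 · (median(D_S) − median(D_C)) / median(D_C),

with a mean-based variant for count-valued features whose medians are
small integers. Junction profiles slide a 20-nt window, step 1, across
the 3′ ss region (last 100 nt of intron + first 50 nt of exon) or the
5′ ss region (last 50 nt of exon + first 100 nt of intron) and average
the base-set percentage per window across exons. Window values are
assigned to the window center and only full windows are evaluated; the
alternative (window-start anchoring) shifts the x-axis by 10 nt without
changing any comparison.

## The V value

For a spliceosome-associated factor, the observed statistic is the
proportion of GC exons it activates. 10,000 subsamples of the AT exon
set, each of the size of the GC set, give the null distribution of that
proportion; with k subsamples at a proportion ≥ the observed and l at ≤
(ties counted in both),

    P_emp = max(min(k, l)/n_iter, 1/n_iter),
    v = log10(P_emp) · s,  s = 1 if k > l else −1.

Positive v means the factor's regulation is concentrated on GC exons; |v|
saturates at 4 at the default iteration count because of the 1/n_iter
floor; |v| ≥ −log10(0.05) ≈ 1.301 is called significant.

Because factor membership within the AT set is fixed, the hit count in a
without-replacement subsample is exactly hypergeometric, so the sampler
draws hypergeometric counts directly; `method="subsample"` materializes
the draws and a test verifies distributional agreement. Requiring
|AT| ≥ |GC| reflects the design of the procedure (size-|GC| subsamples of
the AT set must exist).

Calibration is stated for the null of *exchangeability*: when the tested
GC set is itself a size-matched subsample of the AT pool, the
ties-inclusive empirical p is super-uniform, so the two-tailed 5% rule
rejects in at most 10% of replicates; tie mass at the default set sizes
brings the realized rate near 7% (measured 6.7% over 3000 replicates).
Note that testing two *independently sampled* sets of near-equal size
against this subsampling null is anti-conservative for any set sizes —
the observed proportion then has strictly larger variance than the
subsample distribution — so the V value should be read as "is the GC set
unusual among AT-sized subsets", not as a two-sample test. No
multiple-testing correction is applied across factors; a
Benjamini-Hochberg column is available as a clearly optional extra.

## Coverage metaplots and CLIP maps

Metaplots length-normalize gene regions to 1000 bins and average bin-wise
across genes with equal gene weight. For the internal-exon and intron
region kinds, per-gene region coverages are concatenated in genomic order
before binning and the first 199 bins are then discarded (promoter-
proximal signal), leaving 801 bins; the drop is applied after per-gene
binning and before cross-gene averaging. Bin b of a length-L vector
averages positions [⌊bL/n⌋, ⌊(b+1)L/n⌋); when L < 1000 the empty bins are
filled by linear interpolation between neighboring non-empty bins, which
preserves constant signals exactly. Exon-level coverage is the mean depth
over a ±100 nt window around the exon center, summarized per class and
contrasted as (GC − AT)/max(GC, AT) ∈ [−1, 1].

CLIP maps report, for each of the 251 offsets from −200 (intronic) to +50
(exonic, boundary base at 0) around a splice site, the fraction of exons
with at least one peak interval overlapping that genomic position; any
overlap counts, not only peak summits.

## Domain architecture

Exons are assigned to the isochore/TAD/LAD (one kind at a time, intervals
of one kind non-overlapping) with which they share the most sequence;
ties break toward the smaller domain start, and exons overlapping no
domain stay unassigned. Per-domain GC/AT exon counts carry a display
filter (≥ 5 exons of either class); class proportions inside a domain
kind and the Pearson correlation between exon GC and hosting-domain GC
are computed per kind. Domain GC is taken from the annotation when
supplied and computed from the genome otherwise. A permutation test for
uneven concentration of classes across domains (variance of the
per-domain GC fraction against label permutations with per-domain totals
preserved) replaces mixed-model likelihood-ratio testing; it is an
addition of this package.

## Synthetic data

The generator emulates the genomic organization the analysis detects, on
a single ~0.8 Mb chromosome that runs end-to-end in seconds:

* nine isochore blocks tiling the chromosome, cycling through GC levels
  35/42/48/55 % — the two lower levels host the AT context, the two
  higher the GC context. The odd block count gives the AT context five of
  nine slots, so the planted AT exon pool is systematically the larger
  one, as in human data (AT exons outnumber GC exons) and as the V-value
  subsampling requires;
* six genes per isochore, 9–15 exons each (lognormal exon lengths, median
  120 nt); intron lengths lognormal with median 300 nt in GC context and
  1500 nt in AT context, straddling the 691 bp threshold;
* gene GC = isochore level + N(0, 1.5); exon GC = gene GC + 6 in GC
  context, − 4 in AT context, which plants the exon–gene and
  exon–isochore GC correlations;
* three GC-context factors and four AT-context factors, each activating
  120 internal exons of its own context across two samples, with a few
  repressed-only exons and two planted activation/repression conflicts
  per factor (eliminated downstream, hence labeled `none` in truth);
* seven spliceosome-associated factors emitted as a *separate* regulation
  table: U1-like factors hit planted GC exons at 30% and AT exons at 10%,
  U2-like factors the reverse — mirroring the separation of class-defining
  splicing factors from the U1/U2-associated factors tested by the V
  value;
* decoy signals planted in the 3′ end of introns upstream of AT exons at
  rate `decoy_enrichment` (≥ 2 perfect BP consensus sites, Poisson-many
  TNA motifs and 5–8 nt T runs in the −75..−35 region); GC exons instead
  receive a 10-nt G/C-rich stem at the 5′ ss written complementarily into
  exon end and intron start, so their donor junctions fold stably;
* CLIP-like ~30 nt peaks placed in the 3′-terminal intron window upstream
  of AT exons with probability 0.6 (GC exons 0.1); coverage = 1.0 with
  ±20% block noise, multiplied by 3 over GC exon bodies (nucleosome-like
  enrichment);
* TADs are isochores split in two; LADs are the lowest-GC isochores.

All draws flow from one seeded generator, so a configuration and seed
fully determine the bundle, byte-for-byte on disk. `null_config()`
removes every planted contrast (uniform 45% GC, equal intron
distributions, no decoys/stems, equal CLIP rates, no coverage boost)
while keeping the factor structure, for calibration tests.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: splice-site consensus sequences (GT/AG
dinucleotides and MaxEnt-scored signals), realistic branch-point score
distributions (the SVM model is out of scope), transcription-coupled
coverage shapes, overlapping genes, chromosome-scale isochore size
distributions (real isochores are ≥ 30 kb and highly variable),
alternative transcript structures, and read-level noise (regulation
tables are emitted directly, standing in for upstream PSI quantification).
Recovery rates near 100% on synthetic data reflect the planted effect
sizes, not expected performance on experimental tables.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open throughout; 1-based inputs must be
  converted at the reader boundary.
* Empty sequences, all-N sequences, empty exon sets, zero control
  medians, zero-variance correlations, and |AT| < |GC| all raise
  immediately rather than propagating NaNs; truncated windows (terminal
  exons, chromosome edges) yield absent values (folding), zero counts
  over the available sequence (motif counters), or no-signal padding
  (CLIP maps).
* The significance line for V values is compared on |v|: the plotted
  threshold −log10(0.05) is positive while log10(0.05) is negative, and
  the sign of v encodes direction, not significance.
* Equal factor medians at a class threshold, and k = l in the V value
  (sign −1), resolve strictly: higher/lower, never at-or-above.
* Pipeline outputs embed the package version, seed, and a configuration
  hash in a header line; stages are idempotent for fixed inputs and seed.

## Problem sizes

Default analyses use the ~0.8 Mb bundle (54 genes, ~650 exons, ~470
planted class exons), 10,000 V-value iterations, 1000 calibration
replicates and 100 sign-recovery replicates; the whole suite and the
acceptance script each run in well under a minute of compute per
invocation on one CPU.
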