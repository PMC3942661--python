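# Methods

This note documents the models, parameter choices and numerical
decisions behind `tissueqc`, and what the synthetic-data results do and
do not establish about real data.

## The data-generating model

### Tissue mixture

A library from the target tissue is modelled as a three-compartment
mixture. The target tissue contains neuron-like cells (fraction φ,
default 0.5) and glia-like cells (1−φ); a physically adjacent
contaminant tissue is admixed at a library-specific fraction c. Bulk
abundance of gene g is

    a(g) = (1−c)·[φ·neuron(g)·k(g) + (1−φ)·glia(g)] + c·contaminant(g)

with k(g)=r (default 0.2) for the knockdown target in
`cell_restricted` mode; in `somatic` mode r applies in every
compartment (a deficiency background rather than a driver-restricted
hairpin). φ is a free configuration parameter, not a biological claim
about the neuron:glia ratio of any real tissue.

Two normalization conventions are deliberate:

- neuron and glia compartments share **one** scale (the φ-weighted
  mixture sums to 100). A ubiquitous gene therefore has equal per-cell
  abundance in both target compartments, which makes the bulk knockdown
  fold change exactly φ·r + (1−φ).
- the contaminant compartment is scaled to the **same total** (100), so
  a marker's expected FPKM is linear in c and the contamination
  estimator ĉ = (obs − ref_target)/(ref_contaminant − ref_target) is
  unbiased under the model.

### Gene classes, markers and knockdown response

Genes fall into four classes (default proportions: neuronal 0.30,
glial 0.10, contaminant-specific 0.15, ubiquitous 0.45; n_genes = 60 by
default). One gene per class serves as a marker with fixed per-cell
abundances: neuron marker 8 (neurons only), glia marker 8 (glia only),
contaminant marker 10 in the contaminant tissue against 0.3 in each
target compartment (a ~33x tissue ratio — the marker is chosen
*because* it is strongly enriched), ubiquitous control and knockdown
target 3 everywhere, transgene 5 in neurons only and on its own
reference sequence, so zero counts are meaningful absence rather than
missing annotation. Remaining genes draw lognormal(0.8, 0.8) baselines
in their class pattern.

A knockdown changes more than its target: a fraction (default 0.3) of
non-marker genes in each endogenous class are responders with log2
effects of ±1.5, applied only in compartments where the knockdown is
active. This is what produces plural differentially expressed genes,
the PCA separation between genotypes, and the class-composition
contrast between restricted and somatic designs (neuronal responders
keep their full fold change in bulk because they are expressed nowhere
else; ubiquitous responders are diluted by φ and by contamination).

### Counts, reads and artifacts

Counts are negative binomial with mean L·a(g)/Σa (L = 3000 fragments
per library by default — pilot scale; tests that assert parameter
recovery use 20,000-100,000) and variance μ + αμ², α = 0.1 by default.
α = 0 falls back to Poisson.

Reads: fragments are placed uniformly on the spliced transcript with
per-fragment insert lengths N(300, 30) clipped at ±3 sd (fragmentation
to an *average* size; a constant length would make the duplicate
signature space one-dimensional and generate large numbers of
coincidental signature collisions). Placements are rejection-sampled
so each 100-bp mate lies inside a single exon, which keeps every truth
alignment a single gapless block; mate orientation is random
(unstranded protocol). Base qualities are 37 with small per-read
offsets. Artifacts, each carried in the per-read truth labels:

- **5' composition bias** over the first 10 cycles: position p favors
  one base with weight 1 + 3·amplitude (default amplitude 0.5, ~0.20
  total-variation distance from the tail composition). Amplitude 0
  leaves reads untouched.
- **PCR duplicates**: whole-pair copies at a fraction
  d = d_max·exp(−λ·input) with d_max = 0.986 and λ = 0.150, chosen so
  nominal inputs of 2-6 ng span duplicate rates 0.73-0.40 — the range
  a low-input pilot produces. Duplicates duplicate both mates at
  identical coordinates, matching the removal signature downstream.
- **QC-failing classes** (defaults 0.2%/0.1%/0.4% of unique pairs,
  under 1% in total): one N at mid-read; a 60-base A-run starting at
  cycle 10; all-20 qualities. The patterns are deterministic so the
  filters can be validated at precision = recall = 1.
- **5'-degraded reads** (default 8%): qualities (10×2, 90×33), mean
  29.9 untrimmed and 33.0 after a 10-cycle trim — the class the
  trimming arm rescues, sized to produce a counted-fragment gain of
  the order seen when trimming real biased libraries.
- **shRNA transgene reads** (off by default): both-orientation
  fragments from the 3' half of the target's transcript at
  `shrna_level` = 9 x the target's endogenous fragment count — heavy
  transgene expression, which drives the targeted-region fraction of
  the target's fragments to ~0.95 in knockdown libraries and the
  interference ratio R to ~1.9.

Everything is reproducible byte-for-byte from the configuration seed;
independent stages use fixed child streams of the seed.

### The default scenario

Seven libraries — four control, three knockdown — mirror a pilot:
contamination (0.6, 0.6, 0, 0, 0.6, 0, 0) and cDNA inputs
(5, 2, 4, 3, 2, 6, 4) ng. Three libraries are heavily contaminated,
leaving 2+2 clean libraries for DE after selection.

## Analysis choices

### Filters and trimming

A pair is dropped when either mate fails any rule; rules are checked
in a fixed order (unknown nucleotides, homopolymer, mean quality) and
the first failure is reported. The mean Phred is per mate; a
homopolymer is a maximal run of one base anywhere in the read, not
extended by N; an empty mate is dropped as low quality. The boundary
is strict: mean exactly 30 is kept. Trimming removes the first k
cycles of both mates and runs before filtering, so degraded 5' cycles
cannot drag an otherwise good read below the quality floor.

### Duplicates and counting

The fragment signature is (reference, leftmost start, rightmost end,
orientation) — stricter than start-only and symmetric to the
generator's whole-pair duplication. Within a signature group the pair
with the highest summed base quality is kept, ties to first
occurrence; the procedure is idempotent. Orphan records are excluded
and tallied. Counting is union-mode at fragment level: the feature set
of a pair is the union of genes whose union-exons overlap either mate,
strand ignored; |set| = 1 counts, ≥ 2 is ambiguous, 0 is no_feature,
and a mate below mapq 10 sends the pair to low_quality before any
overlap test. The four categories partition the fragment total. FPKM
uses the merged union-exon length and the counted-fragment total as
denominator (logged in the report; other denominators are auditable).
Coordinates are 0-based half-open internally; SAM (1-based) and GTF
(1-based closed) conversions happen only at I/O.

### Normalization and differential expression

Size factors are median-of-ratios against the per-gene geometric mean
over libraries, computed on genes nonzero everywhere. Dispersion: per
gene, a method-of-moments estimate α̂ = max(0, (s²−μ̄)/μ̄²) with the
variance pooled within groups; a robust (Huber) linear fit of log α̂
on log μ̄ gives the trend, and the working dispersion is
max(α̂, trend) — conservative, in the spirit of early NB DE tools. The
trend stands in for a local regression: one slope, no bandwidth knobs;
on constant-α data it recovers the truth to well within 30% (the
log-scale fit is biased slightly low at small replicate numbers, a
known property of averaging log χ² variables).

The test is a Wald statistic on the **difference** of normalized group
means with NB variance (μΣ1/s_j + nαμ²)/n², referred to the standard
normal. The difference scale avoids log(0) special cases; fold change
is still reported as a ratio. Two effects offset here by design: a
plug-in normal Wald test with few replicates is anti-conservative,
while the max-of-estimate-and-trend dispersion inflates variances.
Calibration was verified by simulation (2,000 null genes, n = 3+3,
α = 0.1): observed type-I error 0.038-0.05 at nominal 0.05 across
seeds; a t reference with pooled degrees of freedom is far too
conservative (0.003) on top of the dispersion rule. Multiple testing
is Benjamini-Hochberg at 0.05. Genes all-zero across libraries are
excluded before normalization; single-replicate groups are refused
unless a pooled dispersion override is supplied.

`transform_counts` is log2(count/size factor + 1) — a simple
variance-damping stand-in for a parametric variance-stabilizing
transform; concordance diagnostics (Pearson correlations,
average-linkage clustering on 1−r, PCA on gene-centered values) are
computed on it.

### Marker panel thresholds

Thresholds are config-first; the defaults are relative to the panel's
reference FPKMs and were chosen to satisfy an explicit operating
point — per-library sensitivity and specificity ≥ 0.95 for
contamination c ≥ 0.3 versus c = 0 — under the biological noise the
generator assumes (α = 0.1 gives each marker a per-library CV of
~32%, so any threshold within ~2 noise sd of a clean library's mean
misfires at the percent level):

- contaminant-marker ceiling: 3 x its target-tissue reference. With a
  strongly tissue-enriched marker (tissue ratio ~33x), contamination
  of 0.3 lifts the marker ~10x above its clean mean, so the ceiling
  sits ~3.5 noise sd above clean and ~4 sd below contaminated.
  Measured on 400 simulated libraries: 0 false flags at c = 0, 97.8%
  sensitivity at c = 0.3.
- target-marker floor: 0.95 x its target-tissue reference. Dilution
  only reduces a target marker to (1−c) of reference, a signal smaller
  than the noise sd at c = 0.3 — this clause therefore sits close to
  the reference and acts as a pattern check (contaminated libraries
  must also look depleted in target markers), not as the specificity
  barrier; the conjunction with the ceiling supplies specificity.
- transgene floor: 0.25 x the median transgene FPKM of
  reference-conformant (non-contaminated) libraries. A library must
  sit 4x below its peers before driver activity is called low; a
  floor at half the median would misfire on normal replicates at the
  percent level under 32% CV.

A contaminated library is one where *every* contaminant marker exceeds
its ceiling AND *some* target-tissue marker falls below its floor;
low_transgene is a separate flag (driver activity, not tissue
identity) and is only assessed for non-contaminated libraries. The
contamination score log2[(1+mean contaminant FPKM)/(1+mean
target-marker FPKM)] orders libraries by severity and is strictly
increasing in c in expectation.

### Interference audit

The targeted-region fraction f of a library is the fraction of the
target gene's fragments whose spliced-coordinate midpoint falls in the
shRNA-homologous interval (midpoints assign boundary-straddling
fragments uniquely, so f has expectation equal to the region's length
fraction under uniform coverage). R is the mean f of the knockdown
group over the mean f of the control group, flagged above 1.5. The
5'-restricted quantification counts fragments overlapping *only* the
non-targeted interval; because boundary-straddling fragments are
excluded identically in both groups, the restricted fold-change
estimator is unbiased for φ·r + (1−φ) whether or not transgene reads
are present — that is the audit's point. The restricted test reuses
the global size factors (one gene's restriction does not change
library depth) and a supplied dispersion.

### Enrichment statistics

Class percentages are rounded half-up to one decimal. Gene sets are
made pairwise disjoint by dropping genes annotated to multiple classes
(count logged). The two-proportion z-test uses the pooled variance;
degenerate pooled proportions return p = 1 with a warning. The
hypergeometric overlap p-value is the upper tail computed in log
space; the default universe is the set of genes tested for DE.

## Problem sizes

Defaults are desk-scale: 60 genes, ~3,000 fragments per library, seven
libraries (~56,000 read pairs with duplicates and artifacts) for the
read-level pipeline; counts-level studies use 20,000-100,000 fragments
and up to 50 replicates per arm; the calibration study uses 2,000
genes at n = 3+3. These sizes make every stage's statistical claims
testable with comfortable margins while the full suite and the
acceptance script each run in well under a few minutes.

## What passing tests do and do not show

The generator draws from exactly the model the analysis assumes: NB
counts, linear tissue mixing, uniform fragment placement, unambiguous
artifact classes, truth alignments in place of a real aligner. Passing
tests therefore demonstrate *internal correctness* — the estimators
recover the parameters of their own model, the filters and counters
are exact, the flagging rules hit their designed operating point — not
robustness to everything real data adds: mapping error and
multi-mapping, isoform structure, GC and positional coverage bias
beyond the 5' composition effect, sequencing base errors,
non-NB overdispersion, or marker genes whose tissue specificity is
imperfect. Threshold defaults in particular are calibrated to the
assumed noise level and should be revisited (they are configuration,
not constants) when the observed marker CVs differ.

## Known limitations

- The aligner is out of scope; the pipeline consumes ground-truth (or
  externally produced) alignments in a minimal single-block SAM
  dialect.
- The transgene is modelled as a single-exon reference; no UAS/driver
  genetics beyond on/off driver activity per library.
- The NB test is two-group only; no covariates or paired designs.
- `estimate_contamination` assumes the linear mixing model with known
  pure-tissue references; with real references estimated from other
  experiments it inherits their biases.
- The variance-stabilizing transform is log2(x+1), not a fitted
  parametric VST; at very low counts the transformed variance is not
  fully stabilized.
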