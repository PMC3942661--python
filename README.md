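# tissueqc

Biological quality control for tissue-specific bulk RNA-seq of
dissected tissue from transgenic knockdown models.

Profiling a dissected tissue — for example the larval *Drosophila* CNS
of a GAL4/UAS shRNA knockdown strain — runs into problems that standard
read-level QC never sees: pooled dissections carry variable amounts of
physically adjacent tissue (imaginal discs), the target tissue is a
mixture of cell types of which only one carries the knockdown, and the
shRNA transgene itself can in principle contaminate the quantification
of its own target gene. `tissueqc` implements the analytical QC layer
for this setting:

- **read QC**: filters for reads with unknown nucleotides, homopolymer
  runs ≥ 50 nt, or mean Phred < 30; optional trimming of the first 10
  cycles, whose base composition is biased by random-hexamer priming;
  per-position nucleotide-frequency profiling with a scalar bias score
  (max total-variation distance to the within-read tail composition).
- **duplicate handling**: paired-end PCR-duplicate removal on the full
  fragment signature (reference, both fragment ends, orientation) and a
  diagnostic correlating per-library duplicate rates with nominal cDNA
  input.
- **counting**: union-mode fragment counting against union-exon gene
  models with a mapping-quality floor (`-a 10` semantics), and FPKM.
- **marker-panel tissue QC** (the heart of the package): a five-role
  marker panel — neuron marker (*elav*-like), glia marker (*repo*-like),
  driver transgene (GAL4), contaminant-tissue marker (*Pen*-like) and
  ubiquitous control (*Usp7*-like) — flags libraries as *contaminated*
  (contaminant marker elevated AND a target-tissue marker depressed) or
  *low_transgene* (weak driver activity), scores contamination severity,
  estimates the contaminant fraction from linear marker mixing, and
  selects the clean subset for differential expression.
- **differential expression**: median-of-ratios size factors, pooled
  method-of-moments NB dispersions shrunk to a robust mean-dispersion
  trend, a Wald test under the NB model with BH adjustment, and
  correlation / hierarchical-clustering / PCA concordance diagnostics.
- **shRNA interference audit**: fragment coverage along the target gene,
  a targeted-region ratio statistic between knockdown and control
  groups, and a 5'-restricted re-quantification using only fragments
  that cannot originate from the transgene.
- **class enrichment**: tissue-class composition of DE lists with the
  pooled two-proportion z-test and the upper-tail hypergeometric
  overlap test.
- **synthetic data generator**: all of the above is exercised end to end
  on a generator that emulates the full data-generating process, with
  per-read ground truth.

## The mixture model

The target tissue is modelled as a fraction φ of neuron-like cells and
1−φ glia-like cells, contaminated by an adjacent tissue at a
library-specific fraction c. With a knockdown leaving a fraction r of
target-gene expression in neuron-like cells only, a gene g has bulk
abundance

    a(g) = (1−c)·[φ·neuron(g)·k(g) + (1−φ)·glia(g)] + c·contaminant(g),

with k(g)=r for the knockdown target and 1 otherwise. For a
ubiquitously expressed target this gives the *signal dilution* identity:
the bulk fold change of a cell-type-restricted knockdown is

    FC_bulk = φ·r + (1−φ),

e.g. 0.6 at φ=0.5, r=0.2 — a five-fold knockdown appears as a 1.7-fold
change in bulk, which is why such knockdowns can fail to reach
significance while downstream neuron-specific responses remain
detectable. Counts are negative binomial with variance μ + αμ².

## Worked example

Run the default scenario — seven libraries (4 control, 3 knockdown),
three of them heavily contaminated by adjacent tissue, duplicate rates
tied to nominal cDNA input, 5' composition bias, and a small fraction
of QC-failing reads:

```bash
tissueqc run --seed 1 out/
```

or equivalently from Python:

```python
from tissueqc import PipelineConfig, run_pipeline
cfg = PipelineConfig()
cfg.simulation.seed = 1
report = run_pipeline(cfg, "out/")
```

The per-library report:

```
      raw_pairs  kept_pairs  duplicate_rate  fragments_counted  genes_detected
WT_1       6077        5808           0.466               3100              61
WT_2      11307       11048           0.731               2974              61
WT_3       7004        6736           0.541               3089              61
WT_4       8327        8066           0.629               2993              61
KD_1      10962       10710           0.731               2883              61
KD_2       5341        5077           0.402               3038              61
KD_3       6981        6714           0.541               3079              60
```

Duplicate rates range 0.40-0.73 and correlate strongly and negatively
with cDNA input (Pearson r = −0.996): low-input libraries are dominated
by PCR duplicates. The marker panel then flags exactly the contaminated
libraries:

```
      contaminated  low_transgene   pass   score
WT_1          True          False  False   1.19
WT_2          True          False  False   1.57
WT_3         False          False   True  -5.50
WT_4         False          False   True  -5.20
KD_1          True          False  False   0.95
KD_2         False          False   True  -5.61
KD_3         False          False   True  -4.81
```

Positive contamination scores mean contaminant-marker expression
exceeds target-tissue-marker expression — those libraries do not
represent the target tissue. Selection keeps `WT_3, WT_4, KD_2, KD_3`;
the PCA group silhouette rises from −0.05 (all libraries) to 0.27
(selected), i.e. removing flagged libraries restores separation by
genotype. The interference audit reports a targeted-region ratio of
1.05 (not flagged): transgene-derived reads do not distort the target
gene, and the 5'-restricted fold change (0.45) agrees with the
full-gene estimate (0.48), both showing the diluted knockdown. The
trimming arm rescues reads whose 5' cycles drag the mean quality below
threshold, increasing counted fragments by ~8.0% in every library. At
this pilot depth and 2+2 replication the NB test finds 0 significant
genes — the dilution effect in miniature; the acceptance script (below)
shows the fold-change and contamination parameters are nevertheless
recovered accurately at higher replication.

## Layout

```
src/tissueqc/
  sim.py       synthetic mixed-tissue generator (annotation, counts, reads)
  readqc.py    filters, trimming, nucleotide-bias profiling
  quant.py     duplicate removal, union counting, FPKM
  de.py        size factors, dispersion, NB test, concordance
  panel.py     marker panel, contamination estimate, library selection
  audit.py     coverage profile, interference statistic, 5'-restricted DE
  enrich.py    tissue-class composition, z-test, hypergeometric overlap
  pipeline.py  end-to-end orchestration and the run report
  cli.py       command-line interface (tissueqc <subcommand>)
```
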