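# Methods

## Study design being modelled

Two inbred parental species, BSB and TC, are crossed in both maternal
directions; the two hybrids (TBF3: TC mother; BTF3: BSB mother) share
nuclear genetics and differ in maternal origin, which is mirrored by their
mitochondrial reads. Each hybrid is sampled in three tissues (gonad, liver,
muscle) with three biological replicates of short reads, and one pooled
long-read library. All coordinates are 0-based half-open per-gene positions;
GTF output is 1-based inclusive.

## Synthetic cohort generator

The generator (`synthetic.py`) is first-class, tested code, not a fixture.
Per ortholog pair it draws an exon/intron structure (defaults: 6–12 exons of
80–300 bp, introns 60–400 bp), simulates the BSB gene sequence, and derives
the TC copy by substitution divergence; with probability 0.25 the TC copy
gains a private terminal exon, so the pairwise alignment has an indel block
and the cohort has unequal exon numbers and CDS lengths for the structure
statistics. Planted truth:

- **Species-specific SNPs** at rate 0.02/bp on exonic columns at least a
  read length + 20 bp from the transcript ends (keeping per-SNP short-read
  coverage uniform within a gene); 10% of SNP columns are heterozygous in
  BSB but still allele-disjoint. Negative pileup columns (overlapping-het,
  monomorphic, coverage-dropout) are planted per gene and must be rejected
  by discovery.
- **Homoeolog bias**: 30% of genes get a ±1 log2 BSB:TC origin ratio,
  constant across tissues. **DE**: 10% of genes get a ±2 log2 depth shift
  in TBF3 relative to BTF3, applied to both homoeologs (the hybrids share
  nuclear truth).
- **Short reads**: per library and gene, Poisson(depth = 100) reads of
  100 bp at uniform transcript positions; each read records base calls at
  the SNP columns it covers, from its true parent's allele, flipped with
  the per-base error rate (default 0.002). Planted outlier cells (2% of
  SNPs, one random library each) add 10× SNP-local coverage — single-column
  reads, emulating a mutation-site pileup artifact that hits one locus
  rather than a whole read footprint.
- **Long reads**: per gene, isoform chains from the event planter (below),
  two reads per chain per homoeolog per hybrid; 5′-primer, 3′-primer and
  poly(A) flags are independent Bernoulli(0.95), so the full-length
  fraction (~0.95³ ≈ 0.86) sits in the high-80s/low-90s percent range
  typical of such libraries.
- **Mitochondrial reads**: 1000 reads per hybrid, 99.5% from the maternal
  mitogenome.

Randomness uses per-section `numpy` Generator streams keyed on
`(seed, section)`, so a fixed seed gives byte-identical bundles and
`simulate_reads` can regenerate the read tables from a bundle exactly.

### Isoform planting

Each requested AS event gets one variant chain differing from the reference
by exactly that event. Internal events are placed on internal-exon slots
three indices apart, so no two events touch the same exons or introns —
this is what makes "precision = recall = 1 on clean chains" a meaningful
target rather than an accident of collision handling. Offsets are fixed:
alternative splice sites move a boundary 15 bp into the intron, AP shifts a
terminal boundary 20 bp, MXE places a 40 bp alternative exon 10 bp inside
the preceding intron. Requests a gene cannot host (MXE on < 3 exons, more
internal events than slots, > 2 terminal events) raise a capability error.
Across a cohort the planted types rotate by gene index so each class
accrues events evenly. Half the genes (by default) mirror their chains onto
the TC homoeolog through the (identity) coordinate map, giving the
cross-subgenome event-sharing truth.

## Event classification rules

Every unordered pair of distinct exon chains of a gene is compared; events
are deduplicated by `(gene, type, anchor)`:

- **SE** — an internal exon of one chain is absent from the other, and the
  other chain contains the intron joining the flanking splice sites.
  Multi-exon skips do not decompose and fall to OTHER.
- **RI** — an intron of one chain lies inside a single exon of the other
  whose edges equal the outer edges of the intron's flanking exons.
- **A5SS / A3SS** — two introns share one boundary and differ at the
  other, and the exon on the differing side keeps its outer boundary (this
  last condition is what keeps SE/RI patterns from also firing as
  alternative sites). Which of the two is the donor (5′) side depends on
  strand; anchors are strand-independent, so a strand flip maps A5SS ↔ A3SS
  with identical anchors.
- **MXE** — two internal exons, each exclusive to one chain, disjoint, with
  both flanking splice sites shared.
- **AP** — identical junction sets, difference confined to the start of the
  first or the end of the last exon (one event per differing end).
- **OTHER** — the chains differ and none of the named patterns applies;
  anchored on the symmetric difference of the exon sets.

The classification is symmetric in chain order, and distinct chains always
yield at least one event. An independent, deliberately naive implementation
of the same rules lives in `tests/oracle_as.py` and the suite checks
event-for-event agreement on > 1000 random chain pairs.

In the summary table (the study-shaped layout with rows A3SS, A5SS,
Alternative site, SE, RI, Other) MXE events are tallied under *Other*,
since that layout carries no MXE row.

## Statistical choices

- **RBH orthology**: a pair forms iff each gene is the other's unique
  best-scoring hit and both directed hits pass the e-value-like threshold
  (1e-5); tied best hits exclude the gene. For synthetic sequences the
  directed score is k-mer (k = 11) containment on the first 600 bp of the
  transcript — enough to separate true pairs by orders of magnitude at the
  simulated divergence.
- **Structure statistics**: the paired test for exon-number and CDS-length
  differences is the Wilcoxon signed-rank (robust for counts/lengths; the
  choice of test is a documented package decision). All-zero differences
  report p = 1. Pearson r of exon number vs CDS length is computed within
  each subgenome via `scipy.stats.pearsonr`.
- **SNP calling**: a base enters a parent's observed allele set at ≥ 20% of
  the column's reads (suppresses sequencing error); replicate consistency
  is strict set identity by default, with a majority-of-3 mode available.
  Only disjoint parental allele sets are diagnostic and emitted.
- **Read voting**: strict majority of covered SNP alleles; ties, zero
  coverage, or majorities matching neither parent are ambiguous. Long reads
  use the inclusive 85% concordance threshold instead, reflecting their
  many-SNP span.
- **Outlier filter**: the literal per-SNP across-replicates mean ± 2SD rule
  is provably vacuous at n = 3 (max |z| = (n−1)/√n = 2/√3 ≈ 1.155 with
  sample SD), and the suite proves it on adversarial inputs. The default
  mode therefore compares each SNP's count against all SNP counts of the
  same gene in the same library. Two consequences, both unit-tested: a
  single outlier among fewer than ~8 SNPs is masked by its own
  contribution to the SD (max |z| ≤ (n−1)/√n), and a mean ± 2SD cut on
  clean Poisson counts inevitably removes ~4.6% of cells (the normal
  tail) — "no false removals" is not an attainable property of this rule.
  Sample SD uses the n−1 denominator.
- **Normalization**: CPM against the library total (sum of both homoeolog
  channels of one hybrid × tissue × replicate library); the CPM of one
  library sums to 10⁶ before gene filtering. Expression filter: raw count
  ≥ 5 in all three replicates of both groups, per contrast.
- **Exact NB test**: counts are scaled to the geometric-mean library size
  and rounded (the conditional test needs exchangeable sums); the common
  dispersion is the pooled method-of-moments mean of per-gene
  max(0, (s² − m)/m²); the two-sided p sums conditional split
  probabilities ≤ the observed one (no doubling), with the Poisson limit
  handled as a conditional binomial. Tag-wise shrinkage, trends and TMM are
  deliberately out of scope. BH adjustment is implemented directly (five
  lines) and cross-checked against `statsmodels.multipletests` in the
  suite.
- **log2FC** is TBF3 over BTF3 on common-scale group means with a
  half-count offset; **log2CPM** averages the gene's CPM over the six
  libraries of the contrast.
- **Rounding**: all printed percentages use half-even rounding to two
  decimals. Six rounded percentages can drift from 100.00 by up to 0.03 in
  the worst case, which is the self-audit tolerance.

## Problem sizes

Defaults simulate 200 gene pairs at depth 100 — the desk-scale analogue of
the ~20k-pair, tissue-replicated study the pipeline is shaped for. The
verification runs use the sizes at which their targets are statistically
meaningful, chosen once: planted-event recovery on 60 genes with 8–14 exons
(≥ 30 events per named class); homoeolog-ratio recovery on 40 genes at
depth 400 with error-free reads and structurally matched pairs (no TC
private exon — a transcript-length asymmetry otherwise biases the
informative-read ratio, which is a read-sampling artifact rather than a
property of the estimator under test); exact-test calibration on 5000 null
plus 500 four-fold-change genes at φ = 0.1.

## What the simulation does and does not show

The generator has uniform read sampling, position-independent errors, no
mapping bias, no paralogy, no allele-specific mappability, and exact
coordinate maps outside the planted indel blocks. Passing tests therefore
demonstrate the correctness of the *logic* — partitioning, filtering,
counting, testing, event classification — under the stated model, not
robustness to alignment artifacts, reference bias or assembly errors in
real data. The orthology scorer is a containment heuristic standing in for
a protein-level aligner; the AS classifier consumes exon chains and is
agnostic to how they were obtained, but transcript assembly itself is not
implemented.
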