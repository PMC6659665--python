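# Methods

This package analyses sets of closely related (congeneric) insect
mitochondrial genomes: circular molecules of ~15.4 kb carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one A+T-rich control
region. This note records the models and conventions the code implements,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect results.

## Data model and coordinate conventions

Annotations are 1-based inclusive on the majority strand, exactly as
mitogenome organization tables print them. Minority-strand ("R") features
keep majority-strand coordinates with a strand flag; they are never
re-based onto the minority strand. A feature with `end < start` spans the
circular origin; its length is `genome_length - start + 1 + end`.
Converters to 0-based half-open coordinates exist only at the I/O edges
(GenBank import). Gene labels are normalised at parse time (`nd6 = nad6`,
`cytb = cob`, the various "A+T region" spellings = `control_region`),
because the literature mixes spellings between tables; en dashes and
thousands separators in `start-end` cells are accepted.

## Junction accounting

For adjacent features the signed junction length is
`downstream.start - upstream.end - 1`: positive values are intergenic
spacers, negative values overlaps, zero abutting genes. The circle is
closed by a wrap junction of length
`genome_length - last.end + first.start - 1`, giving exactly one junction
per feature and the conservation identity

    sum(feature lengths) + sum(signed junction lengths) = genome length,

which is asserted for every record the pipeline touches. Junctions are
computed on majority-strand coordinates regardless of the strands of the
flanking genes. The control region's flanking junctions stay in the
ledger (the conservation identity needs them) but are excluded from the
spacer *count*, which by convention counts spacers in addition to the
control region. Overlap summaries report what the coordinates imply; for
the kikuchii-type genomes this is seven overlaps (including cob-trnS(UCN)
= -2) even though prose summaries of such genomes usually say six.

## Codon surveys and composition

Start codons are the first sense-strand triplet of each PCG; stops are
reported verbatim, including incomplete stops "TA"/"T" whose length is
`gene length mod 3` (completed to TAA by post-transcriptional
polyadenylation in vivo; the code never auto-completes them, but the
aligner pads them transiently for translation). Composition uses
`AT skew = (A-T)/(A+T)` and `GC skew = (G-C)/(G+C)` on the majority
strand, with N's excluded from every denominator and undefined skews
reported as missing rather than zero.

Codon usage pools in-frame PCGs under the invertebrate mitochondrial code
(translation table 5, so AUA = Met, UGA = Trp, AGR = Ser). Stop codons and
incomplete terminal codons are excluded. Leucine and serine are split into
two synonymous families each by codon block (Leu1 = CUN, Leu2 = UUR,
Ser1 = AGN, Ser2 = UCN). RSCU is the observed codon count divided by its
family's mean count: `rscu(c) = count(c) * family_size / family_total`;
within a family RSCU sums to the family size, and an absent family is
flagged with all-zero RSCU rather than dividing by zero.

## Alignment and concatenation

PCGs are aligned codon-aware: translate (table 5, incomplete stops padded
with A transiently), align the amino acids, back-translate so every
amino-acid gap becomes a 3-base gap; an incomplete terminal codon is
padded to codon width with gap characters, never with invented bases, so
stripping gaps always recovers the input sequence exactly. RNA genes are
aligned at the nucleotide level.

The engine is global Needleman-Wunsch with affine gap costs (a gap of
length g costs `open + (g-1)*extend`; defaults BLOSUM62 with 10/1 on amino
acids, match 2 / mismatch -1 / 8 / 1 on nucleotides) with one deliberate
restriction: a gap in one sequence may not immediately follow a gap in
the other. Optimal alignments of congeneric sequences never need such
adjacent opposing indels under these penalties, and the restriction makes
the recurrence exactly row-vectorisable (the horizontal affine state
reduces to a running maximum). The test oracle enumerates all alignments
under the same scoring. Ties prefer match, then gap-in-second, then
gap-in-first, making output deterministic.

More than two sequences are aligned progressively, profile against
profile (columns as residue-frequency vectors; gaps contribute nothing to
column scores). The merge order comes from greedy nearest-cluster
agglomeration on p-distances over the unaligned shared prefix, with ties
broken lexicographically by record id. For the shallow, nearly co-linear
guide problems this package faces, this yields the same join order as a
guide tree built by neighbor joining while needing no tree machinery; the
scoring choices here are this package's own, configurable defaults.

Concatenation follows canonical genome order. dataset1 holds the 13 PCGs
as 13 partitions; dataset2 holds all 37 genes with the PCG partitions
first, then the 22 tRNAs merged into one partition and the 2 rRNAs into
another (15 partitions), which keeps every partition a contiguous block.
Records missing a gene get an all-gap block with a warning. Writers cover
relaxed PHYLIP, NEXUS with a charset block, FASTA, and RAxML-style
partition files (optionally split by codon position). A substitution-
saturation screen would sit between alignment and concatenation; it is
deliberately out of scope and the partition files are export-compatible
with external model-selection and tree-search tools.

## Distances, correlations, trees

All distances use pairwise deletion: sites with a gap or ambiguous base in
either row of a pair are dropped for that pair only (congeneric
alignments are gap-sparse, and this matches common distance tools).
Models:

* `p`: mismatch proportion.
* `JC69`: `d = -(3/4) ln(1 - 4p/3)`, saturated at p >= 3/4.
* `K80`: `d = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q)` on transition/
  transversion proportions.
* `GTR`: maximum-likelihood branch length under a reversible generator
  `Q_ij = s_ij pi_j` scaled to mean rate 1. By default the stationary
  frequencies are the empirical base frequencies of the pair and the
  exchangeabilities `s_ij` are estimated from the pair's symmetrised
  divergence matrix as `N_ij / (pi_i pi_j)` (normalised); both are
  overridable, and with equal frequencies and exchangeabilities the
  estimate matches JC69 to better than 1e-6. The likelihood
  `sum_ij N_ij log(pi_i P_ij(t))` is maximised in one dimension with
  bounded Brent (`xatol = 1e-10`, bounds `[1e-9, 20]`); `P(t) = exp(Qt)`
  comes from the eigendecomposition of the symmetrised generator.
  Hitting the upper bound is reported as saturation.

Saturated pairs become NaN entries with an explicit flag set; tree
building refuses such matrices and advises a different model.

The correlation matrix correlates *distance profiles*: entry (i, j) is the
Pearson correlation of `d(i, k)` and `d(j, k)` over all taxa k outside
{i, j}, so self-distances and the focal pair's mutual distance never
enter. This profile definition is this package's documented choice among
the possible constructions; values near +1 mean the two taxa see the rest
of the matrix identically (typical within species), and deep splits push
values negative. It needs at least four taxa; zero-variance profiles are
flagged undefined.

Group-collapsed distances (e.g. treating two inseparable sister species
as one taxon) default to mean linkage over all between-member pairs, with
min/max linkage selectable; printed group distances in comparable studies
are treated as ordering constraints, not exact targets, since their
linkage convention is generally unstated.

Neighbor joining is the canonical Saitou-Nei agglomeration with
deterministic tie-breaking (minimal Q, then the lexicographically
smallest pair of cluster labels, a cluster labelled by its smallest
leaf). Negative branch-length estimates are clamped to zero. The
Robinson-Foulds distance counts the symmetric difference of non-trivial
bipartitions; an independent tree library's NJ and RF implementations
serve as cross-checks in the test suite, never as the implementation.

## Sliding-window nucleotide diversity

pi is the mean over unordered row pairs of the proportion of differing
sites. Within each evaluated range, columns containing *any* gap or N are
removed before counting (complete deletion), so numerator and denominator
always refer to the same clean columns; whether classic sliding-window
tools use complete or pairwise deletion within windows is generally
unstated, and complete deletion is this package's documented choice.
Windows default to 100 bp moved in 25 bp steps (the convention of
mitogenome surveys); window count is `floor((L - window)/step) + 1`, a
trailing stretch shorter than one window is dropped, and window
coordinates are reported as 1-based starts (midpoints only for plotting).
A window with no clean columns is undefined (reported as missing, never
as zero). Region ranking sorts by whole-region mean pi, breaking exact
ties lexicographically with a warning.

## The synthetic-data generator

The generator exists so every pipeline stage can be validated against
known truth at desk scale. Its defaults describe a realistic congeneric
pine-moth-like data set:

* **Layout**: the gene lengths, strands and junction plan of a real
  15,417 bp mitogenome (37 genes + control region; overlap set
  {-8, -7, -3, -2, -1, -1}; 18 spacers; the standard trnM-trnI-trnQ
  order), so organization statistics on simulated data have the same
  shape as on real data.
* **Composition**: stationary frequencies (A, C, G, T) =
  (0.405, 0.13, 0.08, 0.385) — A+T 0.79, slightly positive AT skew,
  strongly negative GC skew, as in moth mitogenomes.
* **Substitution model**: GTR with transition-biased exchangeabilities
  (AC, AG, AT, CG, CT, GT) = (1.5, 8, 2, 1, 8, 1), scaled to mean rate 1.
* **Rate heterogeneity**: per-region multipliers ordered
  intergenic > nad6 > cob > cox2 > atp6 > cox3 > nad3 > control > nad1 >
  cox1 > nad2 > nad5 > nad4 > nad4l > atp8 > rRNA > tRNA (values 3.5 down
  to 0.12). The ordering mirrors the variability ranking reported for
  real congeneric moth mitogenomes; the values are this package's, spaced
  so that the configured ordering of the headline regions is statistically
  identifiable from a single ~15 kb genome set — short genes (nad6 is
  531 bp) have high evolutionary variance, so adjacent multipliers must
  differ by enough that observed mean pi separates by several standard
  deviations. Multipliers are normalised by their site-weighted mean, so
  one unit of branch length is one expected substitution per site
  genome-wide and true pairwise distances are patristic path lengths.
* **Truth tree (preset)**: 14 specimens in two clades; a shallow
  punctatus/wenshanensis/tabulaeformis cluster (within-cluster distances
  0.002-0.007), spectabilis at ~0.05 and superans at ~0.07 mean distance
  from that cluster, and a kikuchii + houi clade ~0.11 away. Pairwise
  distances span 0.002-0.112 substitutions/site, the congeneric regime.
* **Ancestor construction**: random sequence at the stationary
  frequencies; PCG bodies are drawn codon-wise with in-frame stops
  rejected; start codons (ATN, CGA for cox1) and complete/incomplete
  stops are stamped per plan, on the correct strand, without disturbing
  overlapping neighbours.
* **Indels**: optional, geometric lengths (mean 2), insertions and
  deletions equally likely, restricted to intergenic spacers and the
  control region with annotations re-coordinated (deletions clip at the
  boundary of the non-coding run), so codon frames and gene lengths
  always survive. The preset default is indel-free: that keeps columns
  homologous by construction and the configured junction ledger exactly
  recoverable; indel behaviour is exercised separately.
* **Determinism**: one global seed; each branch consumes its own
  generator stream keyed by (seed, preorder branch index), so repeated
  runs are byte-identical.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: there is no selection or codon model, so
simulated CDSs drift into internal stop codons at mutation saturation
(real PCGs would not) and the most frequent codon families follow base
composition rather than the Leu2-dominated usage of real moth
mitogenomes; strand-asymmetric composition is only partly reproduced
because minority-strand genes are generated in sense orientation (whole-
strand GC skew lands near -0.1 rather than the -0.23 of real genomes);
tRNA/rRNA evolution ignores secondary structure; rate variation is
region-wise constant with no among-site Gamma component; and the control
region's length hypervariability is only present when indels are enabled.
The exact reconstruction checks of the organization tables, by contrast,
run on real published coordinates and carry no simulator caveat.

A small composition bias is accepted by design: rejecting in-frame stop
codons slightly depletes A/T in PCG bodies, so whole-genome A+T lands
~0.005 below the configured stationary value; the corresponding test band
is +/-0.015 rather than the pure binomial bound.

## Problem sizes

The test suite and the acceptance script keep each check at the smallest
size that is statistically decisive: exact table reconstructions run on
all six published specimen columns (156 junction cells, < 1 s);
distance-engine calibration uses 100 (tests) or 60 (acceptance script)
simulated 15 kb pairs per true distance in {0.01, 0.05, 0.12}; topology
and ordering recovery replicate the full 14-genome preset across 100
seeds in the suite and 25 in the script, using whole-genome,
column-homologous matrices, with the full codon-aware align+concat path
run once per acceptance run; the sliding-window engine is checked against
brute force on 1,000 random gapped alignments. End to end, the suite runs
in about a minute and the acceptance script in well under one.

## Known limitations

GenBank import maps gene/CDS/tRNA/rRNA/D-loop features only and takes the
first `gene`/`product` qualifier as the label; exotic join() locations
beyond a simple origin wrap are not handled. K80 saturation reporting
covers the closed form's log-domain violations only. The progressive
aligner is built for congeneric divergence; at deep divergence its greedy
guide and the no-adjacent-opposing-gaps restriction may both become
visible. The correlation matrix's profile definition, the mean-linkage
group distance and the complete-deletion window convention are documented
choices; alternatives would change numbers, not orderings, in the regimes
tested.
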