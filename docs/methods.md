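# Methods

## The sorting model

An allotetraploid's four alleles at a locus comprise two pairs, one per
parental subgenome. Within a pair, divergence reflects within-lineage
allelic variation; between pairs it reflects the divergence of the two
parental lineages. Sorting exploits that separation of scales: among the
three perfect matchings of four alleles into two pairs, the true one has
the smallest mean within-pair distance, and its advantage over *both*
alternatives is the evidence that the two-subgenome structure is real.

With pairing scores s(π) = ½(d(pair₁) + d(pair₂)) and ratio
r = min alternative score / best score, the decision is:

* **sorted** — r > T strictly (default T = 4). Equality fails.
* **sorted, r = ∞** — best score exactly 0 with both alternatives
  positive. This is the 2:2 heterozygous case (two distinct sequences,
  each doubled): the pairing is forced and maximally supported.
* **homozygous_like** — all three scores ≤ the tie tolerance: no
  information at all (four identical alleles).
* **equivocal** — everything else: ratio at or below threshold, or a tie
  between the two best scores. A tie between two *zero* scores is also
  equivocal, not r = ∞: with two pairings both achieving zero the best
  pairing is ambiguous, so no infinite ratio is claimable.
* **missing_alleles / insufficient_overlap** — fewer than four alleles
  present, or a needed pair distance undefined for lack of comparable
  sites.

Homozygous and 3:1-heterozygous allele sets short-circuit before scoring:
with at most one distinct sequence available per putative pair, no
partition can attest two subgenomes. The 3:1 case would in fact always
produce an exact three-way score tie, so the short-circuit only makes the
reason explicit.

The ratio quantifies over *both* alternative arrangements (minimum
alternative score), reading "any other arrangement" as a universal
quantifier; using the second-best rather than the mean of the two
alternatives is the conservative choice.

### Labelling

The accepted pair whose alleles have the smaller mean pairwise distance
to the designated maternal reference taxon's alleles is homeolog **A**;
the other is **B**. The maternal assignment itself is an input (in
practice it comes from a plastome phylogeny, since the plastid is
maternally inherited). Missing reference alleles at a locus, or a tie in
the two means, downgrade the decision to equivocal (reasons
`no_reference`, `label_tie`) rather than guessing.

## Distances

The preferred distance source is a user-supplied per-locus tree with
branch lengths (e.g. an ML tree); interallelic distances are its
cophenetic (patristic) path sums. Without a tree, the package is
self-contained: uncorrected p-distances (proportion of differing sites
among columns where both residues are A/C/G/T) feed a neighbor-joining
tree, whose cophenetic distances are used. Routing the fallback through
NJ rather than using raw p-distances keeps the two sources structurally
comparable — on additive (tree-like) input NJ is exact, so the fallback
reproduces tree distances wherever the data support a tree.

Neighbor joining is implemented in-package (Saitou–Nei with the standard
Q criterion). Numerical conventions:

* Negative branch-length estimates are clamped to zero with the deficit
  moved to the adjacent (sister) branch, preserving path lengths through
  the joined node and keeping cophenetic distances non-negative.
* Q-matrix ties break by scan order over lexicographically sorted
  labels, making the tree — and every downstream decision — a pure
  function of the input.
* A pair of sequences with fewer than `min_overlap` (default 50)
  comparable sites has no defined distance; any sorting decision that
  needs such a pair reports `insufficient_overlap`. The default is a
  pragmatic floor below which a proportion over so few sites is mostly
  noise for the divergences involved here (≲ 0.05 substitutions/site).

## Haplotype extraction

Phased VCFs give haplotypes only within phase blocks. Per sample, the
block carrying the most phased heterozygous records is retained (ties:
smallest phase-set id); heterozygous variants outside it, and unphased
heterozygous variants, are masked with N in *all* haplotypes, since their
assignment is unknown. Homozygous-alternate variants carry no phase
information and are substituted everywhere. "Longest" is measured in
variant records, not genomic span: the count of phased variants is what
determines how much interallelic information the block contributes. A
`--keep-unphased` escape hatch trusts the GT order of unphased
genotypes instead of masking, for data whose producers guarantee it.

N is transparent throughout the allele-set operations: masking keeps a
column's shared residue when all non-N alleles agree; the majority
consensus counts only A/C/G/T; the IUPAC collapse codes the distinct
non-N bases, with a gap co-occurring with bases coded as N. Alignment
trimming removes columns whose gap fraction strictly exceeds 25%
("more than" a quarter), so exactly-25% columns survive.

## Concatenation and verification

Exons concatenate to genes in gene-map order. Sorted exons contribute
their labelled pairs to the four tetraploid lanes (A₁, A₂, B₁, B₂;
within a pair, ascending original haplotype index — the two alleles of a
homeolog are exchangeable, so any deterministic rule serves); equivocal
exons contribute their masked consensus duplicated into all four lanes
(identical or N columns add no signal to gene-level distances, so no
special-casing is needed); missing exons are N-filled. Sorting is then
re-verified on the gene with the same threshold. Gene-level labels
override exon-level ones — a verification that can also relabel is the
conservative reading — and samples failing verification are removed from
the gene alignment. Completeness filters (loci with ≥ k sorted
tetraploids) yield nested datasets by construction.

## The simulator

The generator instantiates the design scenario: maternal clade (M1, M2),
paternal clade (P1, P2), outgroup, and a tetraploid whose subgenome A is
sister to the maternal clade, B to the paternal clade. Evolution is
Jukes–Cantor: per branch of expected divergence d, each site flips
independently with probability p = ¾(1 − e^(−4d/3)) to one of the other
three bases. Since that p is exactly the JC transition probability, the
per-branch flips compose exactly: the expected p-distance between two
tips equals the JC expectation for their path length, which the tests
check in closed form.

Scaffold geometry (h = d_parental/2): each parental stem runs from the
ingroup root to depth 3h/4, where the subgenome lineage splits from the
two-diploid clade; the clade splits again at 7h/8; all tips reach depth
h. The shallow subgenome split encodes that allopolyploid hybridization
necessarily postdates the divergence of the parental clades, so each
subgenome is only modestly diverged from its parent lineage — the regime
in which maternal labelling is well-posed. Each sample's alleles split
from their species tip at d_allelic/2, giving within-individual
divergence d_allelic.

Defaults: locus length 700 bp (a typical enriched-exon alignment
length), d_parental = 0.05 expected substitutions/site (congeneric
parental lineages a few percent diverged), d_allelic = 0.002 (an order
of magnitude below the within-side splits), one tetraploid sample, two
exons per gene. Randomness derives from a single scenario seed with
per-locus streams keyed by (seed, locus index), so extending a dataset
never reshuffles earlier loci.

The corruption mode emulates homeologous replacement: at a chosen
fraction of loci, one subgenome-A allele is replaced by an extra allele
drawn from the subgenome-B species sequence, yielding a 3:1 mixed-origin
allele set. (A mere exchange of truth labels would leave the four
sequences unchanged and could not exercise failure detection.) A working
sorter should — and does — refuse such loci at markedly elevated rates.

What the simulator does **not** emulate: indels and alignment error,
substitution-rate heterogeneity across sites or lineages, incomplete
lineage sorting and gene-tree discordance, phasing errors, missing data
patterns of real capture experiments, paralogy, or intergenomic
recombination beyond the single-allele replacement mode. Passing the
recovery tests therefore shows the machinery is correct and the
criterion behaves as designed under its own model — not that any
particular empirical dataset will sort at the same rates.

## Numerical choices and degenerate inputs

* Tie tolerance 1e-12 (absolute, on pairing scores and label means):
  far below branch-length noise, it only catches exact arithmetic ties.
* Ratio threshold comparison is strict (>), matching the criterion's
  definition; threshold sweeps are monotone because the same distances
  are reused across thresholds.
* An alignment trimmed to zero length is a flagged-empty alignment and
  its locus is dropped (and counted) by the pipeline.
* Report floats print with 6 significant digits; infinite ratios print
  as `inf`, missing values as `NA`. VCF positions are 1-based, internal
  columns 0-based, reported columns 1-based.

## Known limitations

* Tetraploids only, two subgenomes; no support for higher ploidy or
  probabilistic assignment.
* The NJ fallback inherits p-distance saturation at deep divergences;
  for distant outgroups a supplied ML tree is preferable.
* Labelling needs the maternal reference present at a locus; loci
  without it stay equivocal rather than borrowing labels across loci.
* The exon-level threshold is reused at gene level as specified; no
  evidence combination across exons beyond concatenation is attempted.
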