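# Methods

This note documents the models, parameters and design choices behind
`startyper`, and what the synthetic-evidence tests do and do not establish
about behaviour on real sequencing data.

## The locus model

CYP2D6 and CYP2D7 sit ~13 kb apart on chromosome 22, each with nine exons,
flanked by the near-identical REP6/REP7 repeats; a unique ~1.6 kb *spacer*
lies between CYP2D7 and REP7.  Recombination between the paralogs creates
the clinically relevant structural classes modelled here:

* **gene deletion** (*5): a chromosome with no CYP2D6 unit;
* **duplication** (*1x2 etc.): extra full CYP2D6 units on one chromosome;
* **CYP2D6→CYP2D7 fusion** (*36/*68/*83 class): CYP2D6-derived 5′ of an
  exon-anchored switch point, CYP2D7-derived 3′ of it — the unit carries
  its own spacer copy;
* **CYP2D7→CYP2D6 fusion** (*13 class): the converse.  Deletion-fusions
  (*13) remove the separate CYP2D7 and spacer from their chromosome;
  conversion-type alleles (*4.013) retain them.  This distinction is what
  makes the two classes separable by spacer arithmetic.

Every chromosome otherwise carries one CYP2D7.  Consequently
`CN(spacer) = #CYP2D7 + #CYP2D6→CYP2D7 fusions` and
`CN(total) − CN(spacer) = #full CYP2D6 + #CYP2D7→CYP2D6 fusions`,
the anchor used throughout structural typing.

Coordinates are stored 1-based inclusive for both GRCh37 and GRCh38; the
printed REP7 and spacer intervals share their boundary base, so span
validation permits single-base abutment.

## Depth model

Read counts over the combined gene region are normalized by **one** gene
length — homologous copies pile onto a single gene-length unit — so that
depth in copy-number units puts an SV-free sample at 4.0.  GC correction
scales by the ratio of the global baseline median to the median of
baseline regions in the same 0.05-wide GC bin (clamped to [0.5, 2]); the
baseline emulates ~1000 preselected diploid regions.  Integer CN is the
maximum-posterior component of a fixed Gaussian mixture:

* means at integers 0…10 (covers four-gene tandems with margin),
* shared σ = 0.25 CN units,
* uniform prior, call threshold posterior ≥ 0.95.

σ and the threshold are calibration choices: at 30× the empirical depth
s.d. is ≈0.10 CN units for the gene region, so adjacent-CN confusion is
negligible while half-integer depths no-call.  The spacer region is short
(1553 bp), making its depth the noisiest evidence in the pipeline
(s.d. ≈0.16 CN units at CN 4).  When the spacer posterior is indecisive
the pipeline therefore tries the maximum-likelihood value and its
neighbours and accepts a diplotype only if every candidate that survives
structural reconciliation yields the *same* genotype; conflicting
candidates produce an honest no-call.

## Paralog apportioning and structural typing

At each of the 117 differentiating sites, base calls (BQ ≥ 13) are pooled
from both the CYP2D6 and the CYP2D7 position of the site pair, so a
misplaced read still contributes its allele.  Given CN(total)=N, the
CYP2D6 CN at a site maximises `Binom(n_D6 | n_D6+n_D7, p_i)` with
`p_i = clamp(i/N, 0.01, 0.99)` (the ε floor prevents zero likelihood at
the all-one-paralog boundaries), uniform prior, reporting threshold 0.95.

Sites are grouped into eleven exon-anchored segments (5′ flank, exons 1–9,
3′ flank, ordered 3′→5′ along the minus-strand gene).  Structural typing
is **joint model selection** rather than per-segment thresholding: every
partition of CN(total) into full copies and fusions consistent with
CN(spacer) (at most three fusions per class) implies a segment CN profile,
and partitions are scored by the joint binomial log-likelihood of the
pooled per-segment counts.  The best partition is reported; all partitions
within 10 log-units remain available to the diplotype resolver, because
some structures are genuinely depth-equivalent (a biallelic *13/*68
sample has the same uniform profile as one full CYP2D6 with two CYP2D7)
and only small-variant evidence separates them.  A lack-of-fit guard
no-calls when even the best partition is >30 log-units worse than a
saturated per-segment model.

Read-level pileups violate the independence the binomial assumes: one
150 bp read covers several neighbouring sites.  Pooled per-segment counts
from BAM evidence are therefore deflated by the mean sites-per-read
multiplicity computed from panel geometry; counts-level simulated
evidence draws sites independently and uses multiplicity 1.  A
per-segment consensus profile (pooled binomial call, guarded by per-site
maximum-likelihood votes: no-call when more than a third deviate by more
than one copy, or fewer than three sites are informative) is retained for
reporting and diagnostics.

## Small variants

Only catalogued star-allele-defining variants are genotyped.  For variants
inside the two homology regions, reads are pooled from the CYP2D6 position
and its CYP2D7 mirror; elsewhere CYP2D6-aligned reads only.  The copy
number uses the same binomial machinery with N = the CYP2D6-derived CN at
the variant's segment (hybrid copies whose CYP2D6 part covers it
included).  Indels are matched by CIGAR-declared events within ±5 bp
(left-alignment tolerance); minimum pooled depth 10.

The evidence model treats the CYP2D7 base at a pooled mirror position as a
third allele (neither ref nor alt), so CYP2D7-derived reads fall into an
"other" bucket and the alt fraction among ref+alt reads directly estimates
`copies_alt / N`.  Real loci exist where the CYP2D7 base *equals* the alt
(the g.100C>T / CYP2D7-exon-1 collision); resolving that collision needs
locus-aware weighting that this model deliberately omits — a known
limitation of the synthetic panel relative to real data.

## Diplotype resolution

An exact-cover search assigns star alleles to the structural units: a
cover is valid when the summed defining variants of the assigned alleles
equal the confidently called variant CNs exactly and each fusion unit's
switch segment matches its allele definition.  Variants whose CN call was
indecisive do not veto alleles; instead each cover is scored by the
binomial log-likelihood of those variants' observed counts under the
copies the cover implies, and covers with a likelihood ratio worse than
e^10 against are discarded.  Units are then split across two chromosomes
(≤4 units each; an empty side is the *5 deletion, permitted only for
covers where no non-deletion phasing exists at equal rank) and ranked:

1. no deletion-bearing phasing if avoidable;
2. chromosomes arranged as known tandem conventions (*68+*4, *36+*10,
   *13+*2, *4.013+*4, …) preferred, unconventional multi-unit chromosomes
   penalised, homogeneous duplications neutral;
3. fewest distinct alleles;
4. higher indecisive-variant likelihood;
5. fewest fusions; then a fixed lexicographic order.

A unique survivor (or one strictly better through criterion 5) is PASS;
survivors tied to the lexicographic stage report
`more_than_one_possible_genotype` with alternatives listed; no valid cover
is a no-call carrying the unexplained evidence in its diagnostic.
Phenotype translation sums CPIC activity scores per copy (0 → poor,
<1.25 → intermediate, ≤2.25 → normal, >2.25 → ultrarapid; any
unknown-function allele → indeterminate).

## Synthetic evidence

The simulator emulates a 30× diploid Illumina run: 15× per gene copy,
150 bp reads, 0.2% per-base error, Poisson region counts, multinomial
site/variant read splits, optional per-GC-bin bias, and a 1000-region
diploid baseline.  An `exact` mode replaces draws with rounded
expectations for deterministic worked examples.  BAM mode writes a sorted,
indexed BAM over a miniature synthetic contig that mirrors the chr22
layout through a constant coordinate shim: the CYP2D7 region is a copy of
the CYP2D6 region except at differentiating bases and variant mirrors,
reads in homology regions get MAPQ 0 and are cross-placed between paralogs
with probability ½, and indels are emitted with proper CIGARs.

What passing tests show: the statistical machinery recovers every
modelled structure at realistic depth and noise, and the full pipeline is
exact on noise-free evidence.  What they do not show: robustness to
alignment artefacts beyond symmetric cross-paralog misplacement, indel
realignment idiosyncrasies, coverage waviness beyond a per-bin GC model,
or the fidelity of the shipped panel/definition tables to the real
PharmVar catalogue — both are synthetic curated resources (well-known
variants such as g.100C>T, g.1847G>A, g.2549delA, g.2851C>T, g.4181G>C
keep their customary labels; the remainder are internally consistent
inventions).

## Problem sizes used in validation

Worked examples run single samples; archetype recovery uses 100 seeded
replicates per structure; catalogue round-trips use all 40 validated
alleles plus nine tandem arrangements, noise-free once each and 500
seeded noisy simulations stratified across the catalogue; oracle
equivalence enumerates all read-count pairs up to 200 per paralog and
CN ≤ 8, and 1000 random depths for the mixture caller.

## Known limitations

* Hybrid switch points are reported at exon-segment resolution only.
* At CN(total) ≥ 6 with four-gene tandems, total-CN depth posteriors
  occasionally no-call (~0.5% of simulations); these surface as honest
  no-calls rather than miscalls.
* More than three fusions per class are outside the structural model.
* Population priors enter only through the tandem-convention ranking;
  no allele-frequency-weighted genotype likelihood is computed.
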