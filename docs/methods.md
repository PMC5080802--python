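# Methods

This note documents the models, parameter choices and numerical decisions
behind `equimir`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and formats

All internal coordinates are 0-based, half-open. GFF3 output/input
(1-based, closed) is converted only inside `equimir.io`. Loci, calls and
catalogs use the miRBase-style dialect (`pre_miRNA` features with `miRNA`
children linked by `Derives_from`). Tags travel as a 7-column TSV
(chrom, start, end, sequence, count, strand, n_hits); counts and sample
metadata as TSV matrices.

## Folding model

`discovery.fold_hairpin` maximises a weighted, non-crossing pairing:
pair weights GC = 3, AU = 2, GU = 1; hairpin loops of at least 3 nt; and
one opening penalty of 4 per maximal helix, so an isolated pair is never
favourable and a 2-pair GC stack is barely favourable. The penalty is what
makes the folder usable for discrimination: without it, pure pair
maximisation folds random sequence almost as avidly as a real inverted
repeat. The reported "MFE" is minus the optimal score — an internal
energy-like scale, not kcal/mol; all downstream thresholds
(`mfe_max = −15` for the duplex criterion) are on this scale.

The dynamic program tracks `V[i,j]` (best score with i,j paired, helix
continuation uncharged) and `W[i,j]` (best score of a segment, all
helices charged); traceback tie-breaks are fixed (unpaired before paired,
stacked continuation before a fresh interior, smallest bifurcation
point), so folding is deterministic. The test suite checks the folder
against an independently written right-to-left dynamic program on random
sequences up to 30 nt and against true exhaustive enumeration of every
structure up to 14 nt, scored by an independent energy function.

A thermodynamic folder (e.g. RNAfold) can be substituted by the caller —
every consumer takes `(structure, mfe)` — but the package deliberately
has no external-binary dependency, and all defaults are calibrated to the
internal scale.

## Candidate excision and duplex geometry

A read stack is a cluster of tags sharing a modal 5' end within 3 nt
whose summed count reaches `min_stack_count = 5`. Around the stack's
modal tag a window of ±50 nt is excised and folded. The star arm is
derived from the structure by the Dicer geometry: if the mature arm pairs
at ≥ 60 % of its bases into one near-contiguous partner helix, the star
interval is the partner region shifted to leave 2-nt 3' overhangs at both
duplex ends; otherwise the candidate has no located star and is scored
with a duplex penalty. Stacks falling inside an already-excised window
(typically the star arm of a stronger stack) are absorbed rather than
duplicated. Windows truncated at contig edges are flagged.

## The two discovery modes

**deep mode** scores each candidate with four additive log-odds terms and
calls candidates at score ≥ 1 (configurable):

- *structure*: minus the z-score of the candidate's folding score against
  a null model fitted once per genome (linear regression of MFE on window
  length and GC × length over random genomic windows), clipped to ±8;
- *duplex*: `12 × (q − 0.65)` clipped to [−8, 4], where q is the fraction
  of mature bases paired;
- *reads*: (fraction of supporting read counts on the mature/star arms
  minus the null expectation from arm length) × 2 log2(1 + total count);
  zero when no star arm could be located — without a duplex there are no
  arms to concentrate on;
- *star*: +2 with star-arm reads, −1 with a located but unread star, −2
  with no locatable star.

The composition honours the classic description of probabilistic miRNA
scoring — read positions, read frequencies within the stem-loop, and a
structure-probability term — and is calibrated so that clean planted loci
at 50× depth score well above 1 while background stacks stay below it.
The score is monotone: adding mature-arm reads at the modal position
never decreases it.

**dentify mode** requires all ten stringent criteria: 5' and 3' end
heterogeneity ≤ 0.33 (count fraction off the modal end, 3' ends taken
after trimming untemplated tails), exact 2-nt 3' overhangs at both duplex
ends, duplex energy ≤ −15 and below the flanking-sequence energy,
nucleotide entropy ≥ 1.5 bits, structural entropy of the hairpin region
≤ 2.5 bits (Shannon entropy of the run-length multiset of the dot-bracket
string — a single clean stem has few distinct runs), A/U tailing
(optional, off by default), and a multimap factor ≤ 4. The numeric
thresholds are package defaults (the criteria themselves are standard;
published cutoffs are not), exposed in `DiscoveryConfig` and the YAML
config. On clean synthetic loci this mode keeps roughly half of what the
permissive mode calls — rule-based discovery is expected to be severe.

## Permutation signal-to-noise

Each permutation round relocates every tag uniformly on its chromosome,
preserving length, count, strand and hit count, and re-reads its sequence
from the genome; excise + score is re-run and call counts per integer
cutoff in −10..10 are recorded. SNR is real/mean-permuted (NaN at 0/0;
infinite when permutations yield none). On pure background the real count
falls inside the permuted 2.5–97.5 % band at every cutoff, by symmetry.

## Catalog rules

Calls merge iff same chromosome and strand with both the start and the
end differing by ≤ 2 nt, closed transitively; the rule is order-invariant
(union-find over sorted calls) and idempotent. The representative is the
exact-interval variant seen in the most samples, ties broken by score and
then position. The singleton filter counts distinct samples, not calls,
and is applied per tool before tools are united. Annotation against known
mature miRNAs: equal-within-tolerance same-strand intervals are flagged
known; a same-strand overlap whose difference is confined to one end
(≤ 2 nt) is flagged *near-identical* but keeps a novel identifier (the
behaviour observed for real novel calls a couple of nucleotides short of
an annotated mature); antisense overlaps stay novel with an
*opposite-strand* flag. Clusters chain entries whose hairpin starts are
≤ 3000 nt apart (single linkage, strand-agnostic, ≥ 2 members); the
anchor point (start-to-start) is a package decision since cluster
definitions in the literature rarely state one. Chromosome summaries pool
scaffolds not matching a plain chromosome name as "Unplaced".

## Expression rules

Quantification assigns a tag to a mature-hairpin combination iff strands
match and the tag lies within the mature interval ± 2 nt; a tag matching
several combinations contributes its full count to each (one mature may
derive from more than one hairpin). The < 1 cpm prefilter uses
library-size-only cpm; TMM applies to everything downstream. A row is
removed iff below 1 cpm in ≥ 90 % of all samples; a miRNA is expressed in
a group iff ≥ 10 cpm in ≥ 90 % of the group's libraries (≥ rather than >,
configurable); group-specific means expressed in exactly one group;
universal means expressed in every group; the high-expression report
lists group-specific miRNAs with within-group mean TMM-cpm > 100.

TMM: reference = sample whose upper quartile of non-zero proportions is
closest to the mean upper quartile; M/A over rows positive in both; 30 %
trimmed from each tail of M and 5 % of A; precision weights from the
delta method evaluated at a nominal depth of 10⁶, which makes the factors
a function of count proportions only — exactly invariant to pure depth
changes (the one deliberate departure from computing weights at observed
depths). Factors are rescaled to geometric mean 1. Note the direction: a
sample with a subset of strongly inflated miRNAs gets a factor below 1,
shrinking its effective library size so the unaffected majority is
comparable across samples.

MDS distances are the root-mean-square of the `top_n` (default 500)
largest absolute log2 fold changes between two samples on cpm + 0.5;
coordinates by Torgerson double-centering (sign/rotation arbitrary).
The pseudocount 0.5 is used for every log-ratio in the package.

## Differential expression

Libraries are scaled to the geometric-mean effective size with
largest-remainder rounding (all adjusted columns share one effective
size — the contract the conditional likelihood needs; the full
quantile-mapping construction is summarised by this contract). The common
dispersion maximises the summed conditional log-likelihood given
per-group totals, by a coarse log-grid pass plus golden-section
refinement on log10 φ over [10⁻⁴, 5]. The exact test conditions on the
per-miRNA total; because the group sums are negative binomial with a
shared success probability, the conditional distribution depends only on
the group sizes and φ, and the two-sided p-value sums all splits no more
likely than the observed one (ties included), so the most likely split
has p = 1. p-values are computed by direct vectorised evaluation of the
conditional log-pmf over all splits, which is linear in the per-miRNA
total; the simulated library sizes (~10⁶ over a few hundred miRNAs) keep
this comfortably fast. BH FDR is the standard step-up with capping.
log2FC uses normalized group mean cpm with pseudocount 0.5 and is
therefore always finite. The default DE call is FDR < 0.001 after a
≥ 10 cpm in 90 % of samples prefilter.

Covariate screening is per miRNA: binary covariates (sex) reuse the exact
test path with the covariate as the grouping, so results coincide with a
two-group run; numeric covariates (age, absorbance at 414 nm) use a
Spearman rank correlation on log2(cpm + 0.5) — a deliberately
conservative nonparametric choice, since the appropriate parametric form
for such nuisance covariates is not established.

## Synthetic data: what it emulates and what it does not

`make_toy_genome` draws i.i.d. bases (GC 0.5 by default).
`plant_mirna_loci` writes hairpins (mature + loop + star) into the
genome: the star pairs `mature[0 : L−2]` in reverse complement and
carries two free 3' nucleotides, producing 2-nt 3' overhangs at both
duplex ends by construction; loop bases facing the mature overhang are
chosen non-pairing so chance helix extension does not destroy the planted
geometry; a configurable fraction of star positions is mutated
(`identity_fraction`). A chosen fraction of loci is placed within 3000 nt
of a neighbour to exercise cluster detection; strands are ~50/50.

`simulate_read_stacks` splits per-locus depth multinomially between
mature arm (80 %), star arm (12 %), loop (2 %) and hairpin-wide scatter,
with optional 5'-jitter and untemplated 1–3 nt A/U tails that extend the
tag interval over mismatching genomic bases (as an aligner tolerating
terminal mismatches would report; tail bases are chosen to mismatch the
template, since a matching base would simply have been aligned).
Background fragments follow a two-peak length mixture — 78 % at 30–32 nt
and 4 % at 22–23 nt by default, the shape seen in serum libraries; the
mixture is configurable because tissue-specific shapes differ — at
uniform positions, with a configurable fraction of > 5-hit multimappers.
Read counts are conserved exactly: depth × loci + n_background.

`simulate_counts` draws log-normal baseline abundances, applies planted
log2 fold changes and optional covariate effects multiplicatively,
renormalises each column to its library size (so planted effects displace
other miRNAs exactly as depth competition does) and samples
NB(μ, φ) counts (Poisson at φ = 0). Composition bias multiplies a random
subset of rows in designated samples before renormalisation, which is the
scenario TMM exists to correct. Metadata includes tissue/breed, sex, age
and absorbance414.

Not emulated: sequencing errors, colour-space chemistry, adapter
artefacts, isomiR families beyond 5' jitter and 3' tailing, repeat-driven
multimapping structure (hit counts are simulated metadata, not
re-alignment), and real genome composition (no repeats, no GC
heterogeneity). Passing tests therefore demonstrate the pipeline's
operating characteristics under the biogenesis model, not performance on
real tissue libraries.

## Problem sizes and defaults in the test/acceptance runs

Discovery controls use 20 planted loci on a 100 kb two-chromosome genome
at 50× locus depth with 3,000 background fragments; signal-to-noise uses
100 permutation rounds on a 20 kb genome with 4,000 background fragments;
DE recovery uses 300 miRNAs at the unbalanced 44-vs-5 design with φ = 0.1
and library sizes 0.8–1.2 M; null calibration uses 10,000 null miRNAs.
These sizes give stable statistics while keeping the whole suite and the
acceptance script fast on a single CPU.

## Known limitations

- The folding energy scale is internal; duplex/flanking MFE thresholds do
  not transfer to kcal/mol folders without recalibration.
- The stringent mode's numeric cutoffs are package defaults, not
  published values; on clean synthetic data it accepts ~half of true
  loci, which is in line with the severity expected of rule-based
  discovery but means its absolute yield should not be over-interpreted.
- The score's background model assumes the genome's base composition is
  roughly homogeneous; on highly heterogeneous genomes the z-scores would
  need a stratified null.
- The exact test's direct summation is linear in the per-miRNA total
  count; for totals far beyond ~10⁷ a tail-bounded summation would be
  needed.
- Discovery records mature lengths but does not hard-filter on them;
  length bounds are applied only by the planted-locus generator (19–25 nt).
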