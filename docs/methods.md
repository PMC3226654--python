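# Methods

## Model

A query profile assigns each genome-level taxon a bit: 1 (trait present,
set T1) or 0 (absent, T0). Taxa omitted from the profile are removed from
influence entirely — during scoring they advance neither the depth counter
nor the match counter, which is also how masking is implemented.

For one gene, its homolog list is first normalized: hits sorted by
decreasing significance and deduplicated to the single most significant
hit per taxon. Walking the normalized list, let j be the number of
distinct profile taxa seen so far and h_j how many of them are in T1. The
agreement statistic at depth j is the upper binomial tail

    p_j = P(X >= h_j),   X ~ Binomial(j, p),

the probability of seeing at least h_j positives in j draws if taxa were
hit at random with success probability p. The gene's score is
-log10(p*) with p* = min_j p_j; the reported optimum also carries j*, h*
and the significances flanking the boundary (the deepest in-optimum
positive hit and the next profile taxon beyond the optimum, which at an
optimum is necessarily a mismatch).

The null model treats taxa as independent draws, so phylogenetic
autocorrelation (e.g. a profile that is simply "all members of one clade")
inflates scores for clade-restricted genes; that is inherent to the
statistic, and rank collapsing (below) is the built-in mitigation.

## Prior

p defaults to |T1| / (|T1| + |T0|), the relative frequency of positives.
An override must lie strictly in (0, 1): the binomial model degenerates at
the endpoints, so all-positive or all-negative profiles are representable
but refuse to score until a prior is supplied. Raising p increases the
penalty per absorbed mismatch and steers results toward rare families that
occur *only where* the trait occurs; lowering it tolerates supersets.
For a perfect prefix (h = j) the score is exactly -j·log10(p), which is
how the printed scores of fully-agreeing families arise.

## Determinism and tie-breaking

Depth optima depend on hit order, so ordering is fully specified: BLAST
lists sort by ascending E-value, then descending bit score, then ascending
subject id; HMMER lists by descending full-sequence bit score, then
subject id. E-value is the primary BLAST key because family-boundary
E-values are the quantity the method reports. When several depths achieve
the same minimal tail, the smallest j wins (the smallest family consistent
with the best score). Genes with equal scores rank by gene id. Identical
inputs therefore yield byte-identical outputs.

## Read-ahead pruning

From state (j, h) with r = |T1| - h positives still unseen, the best
possible continuation meets all r immediately, giving tail
P(X >= h + r) at j + r trials. This bound is monotone non-decreasing in
the number of mismatches already absorbed, so once it cannot beat the
incumbent minimum the scan stops. The bound is admissible — pruned and
exhaustive scans return identical results, including flanking
significances (the scanner reads ahead one profile taxon when it stops
exactly at the optimum) — and the equivalence is asserted in the tests
rather than assumed.

Tails are computed via scipy's binomial log-survival function
(regularized incomplete beta in log space); scores beyond 300 would
underflow linear-space summation, and printed scores above 170 occur in
realistic runs.

## Rank collapsing

To damp strain-level redundancy, hits and profile can be collapsed to a
chosen taxonomic rank: each taxon is replaced by its nearest ancestor at
that rank and re-deduplicated so a clade counts once. A collapsed node is
positive if any constituent taxon is (OR semantics — positives must stay
detectable). Taxa whose lineage lacks the requested rank keep their own
id, so every hit remains countable; this fallback is this package's
choice for an underdetermined corner.

## Depth sweep (DPPP)

Given a seed protein, profiles are built at sampled depths d of its
normalized hit list (first d distinct taxa positive, prior d/|universe|),
each scored genome-wide, and every gene keeps its maximum score over
depths (ties to the smallest depth). Default sampling is depths 10 to the
end of the list, stride 10. The seed always matches its own profile
perfectly, so its self-score d·log10(|universe|/d) rises with depth and
carries no information; it is reported, not suppressed. Full re-scoring is
performed at every depth, which makes the max-over-depths aggregation well
defined. A gene homologous to a better-scoring gene in the same genome can
inherit signal through shared hits (paralog contamination); results for
such genes warrant manual caution, and the generator can plant this
scenario.

## Synthetic data

The generator emits a complete mini-study in the external formats
(taxdump nodes/names, 12-column BLAST tabular, HMMER3 tblout, id-to-taxon
TSV, profile TSV, JSON ground truth). Defaults model the package's
reference conditions: 100 genome-level taxa under 20 genera, one planted
10-member system carried by 15 genomes, 40 background families with
taxon frequencies uniform in 0.05–0.9, and 25 cross-family noise hits per
gene. Significance synthesis is the model: within-family E-values are
log-uniform in 1e-120..1e-20, noise in 1e-8..10, so carrier taxa precede
all non-carriers after deduplication and the zero-noise closed-form score
is exact. Leakage removes a member from a carrier (the genome then never
appears in that member's list); contamination adds a member to a
non-carrier at the geometric midpoint of the family band, modelling a
moderate-similarity recruit inside the family boundary — which is what
produces off-by-one agreement optima. Paralog pairs add intermediate-band
(1e-18..1e-10) cross-hits from a background family into a planted member's
carriers.

What the generator does not emulate: actual sequences and alignment-score
physics, compositional biases, unequal evolutionary rates, genome
incompleteness beyond the leakage knob, and realistic taxonomy depth.
Passing tests therefore demonstrate the scoring machinery and its
contracts, not end-to-end discovery performance on real proteomes.

Problem sizes throughout the suite (100 genomes, tens of families, hit
lists of dozens of taxa) are chosen as the smallest scale at which every
claimed behaviour — recovery, off-by-one, pruning, sweep peaking — is
expressed exactly.

## Numerical and edge-case policy

* Degenerate priors raise immediately rather than returning NaN scores.
* An empty hit list, or one touching no profile taxon, scores 0 at
  j* = h* = 0 with no flanking values.
* Depths beyond a requested sweep maximum are clipped with a warning;
  masking absent taxa and combining profiles with disjoint domains are
  silent no-ops on the absent side (absent taxa read as bit 0 in Boolean
  operations — documented prominently because it affects set difference).
* Scores are kept at full precision internally and rounded to 2 decimal
  places only in text output.

## Known limitations

* The binomial null ignores phylogenetic structure within T1/T0.
* No alternative co-occurrence metrics (Hamming, mutual information,
  Jaccard) are implemented; the scoring interface is the extension point.
* The HMM-cutoff utility proposes a threshold (midpoint between the
  boundary hit and the next hit) but does not build families or HMMs.
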