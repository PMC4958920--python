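# Methods

This note documents the models, numerical choices, and the scope of
what the synthetic-data validation does and does not establish.

## Coordinates and sequence handling

All coordinates are 0-based half-open on the forward strand; GenBank's
1-based inclusive convention exists only at the parsing boundary.
Features wrapping the origin of a circular genome are stored as two
ascending intervals plus a flag, so `start < end` is an invariant of
every stored interval. Ambiguity codes other than N are mapped to N with
a logged warning: every downstream consumer (GC denominators, ORF
segments, repeat seeds, codon-model columns) either excludes Ns or
removes the containing column, so the information loss is nil in
practice. N-containing codons break ORF segments because an N can hide a
stop codon.

## ORF discovery

The scan uses the seven-codon plastid start set (ATG, TTG, GTG, CTG,
ATA, ATT, ATC) by default, both strands, with the length threshold
interpreted as *length including the stop codon ≥ 90 bp*; both the
inclusive bound and stop inclusion are configurable because published
descriptions of such filters rarely pin them down. For each stop-anchored
reading frame the maximal ORF (earliest qualifying start after the
previous in-frame stop) is reported; an all-starts mode exists for
nested-ORF questions. Circular genomes are scanned on the doubled
sequence with ORF length capped at the genome length, start coordinates
reduced modulo the length, and duplicates removed — the simplest wrap
handling that is provably complete.

## Repeat detection

Word-seeded (default 9 bp) self-alignment in both orientations, no
low-complexity masking. Co-diagonal seeds are chained (gap tolerance
40 bp), extended greedily while overall identity stays above the floor,
then trimmed to the maximum-scoring subsegment under +1/match, −3/mismatch
— the trim is what keeps an exact planted repeat at identity 1.0 instead
of letting greedy extension accrete flanking sequence at 95%. Overlapping
hits keep the longer, then the higher-identity, then the left-most one.
Inverted hits are found against the reverse complement and mapped back;
a perfect palindrome maps onto itself and is suppressed.

Quadripartite detection seeds on 25-mers matching their own reverse
complement elsewhere; matched position pairs (x, y) share x + y along an
anti-diagonal, are chained per anti-diagonal, and the best chain is
extended outward base-by-base. For exact inverted repeats this recovers
planted boundaries exactly (a property the test suite asserts); the
identity floor (99%) and length floor (1 kb) are configurable. The
detector scans the linear representation of the circle; an IR pair that
itself spans the origin would need rotation first.

## Tandem copy number from mate-pair inserts

A collapsed (or inflated) tandem array shortens (lengthens) the apparent
outer distance of mate pairs that flank it. The estimator iterates:
map, compare the flanking-pair insert mean M_r against a control mean
M_g, add one unit copy if M_r is low, remove one if high, stop when
|M_r − M_g| ≤ τ with τ = max(unit/2, 2·SE of the difference). Half a
unit is the decision boundary between adjacent copy numbers; exact
equality is unattainable with noisy inserts. An oscillation guard stops
when the add/remove sequence revisits a state (or hits the one-copy
floor) and returns the visited state with the smallest discrepancy.
Unit insertion happens at the end of the array; divergent copies are then
reconciled by the polishing loop, mirroring the two-stage procedure the
estimator belongs to. The genome-wide mean is re-estimated after every
edit.

Two sampling-geometry effects matter and are handled explicitly:

* **Length bias.** A pair flanks an interval with probability
  proportional to (insert − interval − 2·read length), so flanking-pair
  means are inflated by ≈ σ²/(μ − interval), which grows with interval
  length — +45 bp for short arrays, +110 bp for 2 kb ones at
  μ = 3000, σ = 300. Comparing against the unconditioned library mean
  would therefore systematically delete copies of short units. M_g is
  instead the insert mean of pairs flanking a *matched-length control
  window* in repeat-free sequence, which cancels the bias exactly.
* **Edge and contamination effects.** Near a template edge long inserts
  lose placements (deflating a control), and control-flanking pairs that
  also span the repeat region inherit its distortion. The control
  window is placed at least the ~99.9th-percentile insert away from both
  template edges and from the region whenever the reference allows, and
  region-spanning pairs are always excluded from control statistics.
  This implies the method wants repeat-free flanks comfortably longer
  than the insert size — true of plastome-scale references, and the
  synthetic studies use 8–9 kb flanks for the same reason.

Physical limits: with μ = 3000 and reads of 100 bp, no pair can flank an
array longer than ≈ μ − 2·read length, so the validation study samples
unit × copies ≤ μ − 3.3σ (≈2 kb); larger arrays are genuinely outside
the method's reach at this insert size. Library depth per replicate is a
power calculation, not a tuning knob: resolving adjacent copy numbers
needs the SE of the mean difference below unit/4, i.e. ≥ 2(4σ/unit)²
flanking pairs per arm (≈1,150 for a 50 bp unit), and pair counts are
sized from that with a conservative yield factor.

The built-in mapper is intentionally minimal — exact 21-mer seeds,
ungapped scoring, coverage ≥ 80% at identity ≥ 99% (99%/98% thresholds
follow the mapping-then-polishing convention the procedure assumes).
Reads with multiple equally best placements are flagged ambiguous and
never contribute to insert statistics, because tandem repeats are
exactly where multi-mapping lies. Externally mapped SAM is accepted for
real data.

## Consensus polishing

Per round: map both mates independently, tally per-position base counts
from unambiguous placements, replace bases where a strict majority
disagrees (ties keep the reference), stop at zero edits (fixed point) or
fail loudly after 20 rounds. Idempotence — a second run performing zero
edits — is asserted in the tests.

## Pairwise dN/dS

*Counting.* Nei–Gojobori sites: each of the nine single-base changes of
a codon contributes ⅓ site, mutations to stop codons counting as
nonsynonymous (S + N = 3 per codon, the original convention). Multi-base
codon differences average synonymous/nonsynonymous step counts over all
minimal mutational pathways, discarding pathways through stop codons
(with an all-pathways fallback when every route is blocked). Note the
widely used Biopython implementation averages over stop-passing pathways
too; the test suite pins the conventions against each other where they
coincide. Jukes–Cantor correction is applied to pS and pN, with a
saturation error at p ≥ 0.75. Because the counting method ignores the
transition/transversion bias, its ω drifts below the ML value as κ
grows — about 15% at κ = 2 — which is a property of the method, not a
bug; the agreement test runs at κ = 1.5.

*Maximum likelihood.* GY94 with F3×4 frequencies estimated from the
cleaned alignment (stop-codon mass renormalised over the 61 sense
codons, with a 1e-10 floor to keep the chain irreducible). The pairwise
likelihood is Σ N_ij log(π_i P_ij(t)) over the codon-pair count matrix;
(t, κ, ω) are optimised in log space by L-BFGS-B with three seeded
restarts and the conventional κ start of 2.0. dN and dS follow the
standard construction: site counts from the ω = 1 version of the fitted
chain, flux proportions from the fitted chain. The ω = 1 refit gives the
neutrality LRT (1 df); the ω standard error comes from the observed
information (central-difference Hessian in the original parameters).

## Site models and branch model

Transition matrices come from the symmetric eigendecomposition of the
reversible generator (D^½ Q D^-½), cached per (κ, ω) so optimiser steps
that only move branch lengths reuse the decomposition. Site classes
share branch lengths; each class's generator advances at its own raw
rate relative to the mixture-average rate, so one unit of branch length
is one expected substitution per codon averaged over classes — the same
scaling the simulator uses, deliberately, so simulation/inference
mismatches indicate bugs rather than convention drift.

M1a optimises branch lengths, κ, p0 (logit), ω0 (logit into (0,1));
M2a adds stick-breaking proportions and ω2 = 1 + exp(·) > 1. Multiple
seeded restarts (default 3) guard the small multimodality these
likelihoods have; convergence is L-BFGS-B's default on the packed
parameters with |lnL| guards against degenerate regions. Site posteriors
are naive empirical Bayes — class likelihood times MLE proportion,
renormalised — and classification is argmax. The M1a-vs-M2a LRT uses
χ² with 2 df, the conventional choice; because p2 collapses to the
boundary under the null, the test is conservative there (measured
type-I error ~1–2% at nominal 5% in the calibration study). Bayes
empirical Bayes is out of scope.

The branch model is free-ratio: one ω per branch, shared κ, branch
lengths in expected substitutions per codon under each branch's own ω.
Branches with fewer than ~5 expected synonymous substitutions are
flagged unstable — a short-branch ω is dominated by noise and should not
be interpreted.

Input branch lengths serve only as optimiser initial values unless
fixed; topologies are never searched. Alignments are inputs (only
gap/ambiguity codon-column removal is implemented, with internal-stop
detection); aligner choice is the user's.

## Tajima relative rate test

On an aligned ingroup pair plus outgroup, m1 counts sites where only the
first ingroup sequence differs, m2 the converse; χ² = (m1−m2)²/(m1+m2)
with 1 df. Columns with gaps or ambiguity are skipped; m1 + m2 = 0 is
reported as p = 1 with an explicit flag rather than an error. Bonferroni
correction multiplies raw p-values by the number of comparisons (default
10, the number of ingroup pairs in a five-taxon study), capped at 1.

## Transmembrane null model

Random ORFs: 999 bp of i.i.d. bases with P(G) = P(C) = gc/2 (the
maximum-entropy split of a GC constraint, since only GC content is
specified), stop codons deleted — not resampled — before translation, so
proteins are ≤ 333 residues. The built-in helix caller is a
Kyte–Doolittle sliding window (19 residues, threshold 1.6, merged runs
≥ 19 kept): a transparent hydropathy heuristic, not a re-implementation
of a full membrane-topology HMM. Boundary windows smear calls up to ~6
residues into hydrophilic flanks; this is inherent to windowed callers
and documented in the tests. Per-residue annotations from an external
predictor can be ingested (two-column text) so published helix masks can
be reproduced exactly while the null machinery stays identical.

The GC sweep runs 0 to 1 in steps of 0.05 (21 points), 1,000 replicates
per point by default, bit-identically reproducible from its seed. The
percentile test generates the null at the query's exact GC, counting
ties as half. Calibration — null-drawn queries land at a mean percentile
of 50 ± 5 — is asserted over 200 queries.

## Synthetic data

The plastome simulator plants an exact-reverse-complement IR pair in the
LSC | IRa | SSC | IRb layout, guards the four IR boundary bases so the
planted pair is provably the maximal reverse-complement match (a chance
complementary flanking base would otherwise extend it), and places
tandem arrays and gene cassettes at spaced offsets in the LSC. Mate-pair
libraries use truncated-Normal inserts (the distribution family is a
choice, exposed in config terms; only means and SDs are ever asserted),
uniform fragment placement, optional wrap on circular templates, and
i.i.d. substitution errors. Pairs are emitted junction-processed in
forward–reverse orientation. Codon alignments evolve root codons drawn
from π down a fixed tree, per-site classes drawn from the proportion
vector, with the exact per-class transition matrices the likelihood
uses. All generators are integer-seeded and bit-reproducible.

What the synthetic validation shows: the estimators are correct and
calibrated when data match the generating assumptions (uniform coverage,
i.i.d. substitution errors, no indels, no rate heterogeneity beyond ω
classes, exact tandem periodicity). What it does not show: robustness to
homopolymer-biased error profiles, indel evolution, alignment error in
divergent regions, or rearrangement breakpoints inside repeats — the
failure modes real plastome data add on top. The accession-backed
checks in `tests/test_acceptance.py` exercise exactly those conditions
but require the deposited records to be supplied locally.

## Validation problem sizes

The replicated studies use: 100 copy-number replicates (units 50/200/500
bp, copies 2–8 under the spannability cap, power-sized libraries);
polishing on 5 kb at 40× with 1% error; pairwise ω on 1,000 codons
averaged over 5 replicates; LRT calibration on 200 replicates of
three-taxon, 150-codon alignments (small on purpose — the statistic's
null calibration does not depend on scale, and 200 refits of both models
stay desk-sized); NEB classification on four taxa × 500 codons; TM
calibration on 200 queries × 1,000 null replicates. These sizes are the
package's chosen study conditions and are asserted as such in the
acceptance tests.
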