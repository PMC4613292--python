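# Methods

## Distance model

Distances are Kimura 2-parameter (K2P) estimates. For a sequence pair, only
*comparable* sites — both residues in {A, C, G, T} — enter the computation;
columns with a gap, N or any other IUPAC code are excluded per pair
(pairwise deletion), which preserves per-pair information when marker
lengths vary. With transition proportion P and transversion proportion Q
over n comparable sites,

    d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q)),

and the delta-method sampling variance uses c1 = 1/(1-2P-Q),
c2 = 1/(1-2Q), c3 = (c1+c2)/2:

    V(d) = [c1^2 P + c3^2 Q - (c1 P + c3 Q)^2] / n.

When 1-2P-Q <= 0 or 1-2Q <= 0 the estimator is undefined (saturation). The
default policy is a hard error, since genus-level barcode distances sit far
from the singularity; `pairwise_matrix(..., on_saturation="missing")`
records such pairs as NaN for exploratory use (downstream summaries refuse
matrices with missing entries). Matrices are written to TSV at 6 decimals;
all in-memory computation uses full precision.

## Divergence metrics

Six summaries of the distance matrix, following the convention of the
barcode-evaluation literature: the "all" metrics pool pairs (all
inter-specific distance over heterospecific pairs, all intra-specific over
conspecific pairs), while theta prime (per-species mean distance to all
heterospecific sequences), the minimum inter-specific distance (per-species
minimum), theta (per-species conspecific mean) and coalescent depth
(per-species conspecific maximum) first form a per-species statistic and
then average it *unweighted* across species. Under per-species averaging
the minimum inter-specific distance can legitimately exceed the all-inter
mean. Choices made where conventions differ:

* Dispersion is the population standard deviation (ddof = 0) over the
  pooled items — pairs for "all" metrics, species otherwise. Reports that
  print "mean ± x" without defining x are read as SD.
* Species with a single sample join the inter metrics but are excluded from
  all three intra metrics; when no species has two samples the intra
  metrics are reported as absent (None), never as zero.
* Species averaging does not weight by sample count.
* Outgroup-flagged species are excluded from the summary by default.

## Barcoding-gap profile and test

Intra- and inter-specific distance lists partition every unordered sequence
pair. Histograms use half-open bins [k·w, (k+1)·w) at w = 0.008 distance
units; zero-distance pairs land in bin 0 and are additionally reported as a
percentage of inter-specific pairs. The overlap threshold for "percentage
of inter-specific distances below t" defaults to the observed
intra-specific maximum (the natural overlap boundary) and counts strict
inequality; it is configurable. The "species with a unique sequence"
statistic counts a multi-sample species when its set of distinct (degapped)
haplotypes is disjoint from every other species' set — one of several
possible readings of that informal notion, chosen because it matches the
identification context.

The inter/intra comparison is a two-sided Wilcoxon rank-sum (Mann-Whitney)
test: exact enumeration when both samples have at most 20 untied values,
otherwise the tie-corrected normal approximation (both via
`scipy.stats.mannwhitneyu`). Pairwise distances are statistically dependent
— each sequence enters many pairs — so the p-value is the conventional
descriptive one of this literature, not a dependence-aware test.

## Identification

Leave-one-out: every sample queries the reference set of all remaining
samples (self excluded, conspecifics retained). The nearest-distance method
predicts the species of all references within 1e-9 of the minimum K2P
distance (the tolerance absorbs float noise between exactly tied pairs);
the best-hit method predicts the species of all references attaining the
maximum Smith-Waterman local-alignment score under affine gaps, computed by
Bio.Align.PairwiseAligner on degapped copies (non-ACGT residues score a
configurable neutral 0). Default scoring is the common nucleotide-BLAST
scheme: match +2, mismatch -3, first gap position -5, each further gap
position -2; integer scores make score ties exact. Verdicts: *correct* when
the predicted set is exactly the true species, *ambiguous* when it contains
the true species among others, *incorrect* otherwise, *unidentifiable* with
an empty reference set. The best-hit search is an exhaustive in-repo
scorer: database heuristics, E-values and seeding play no role because only
the rank of the best hit feeds the verdict. Singleton species stay in the
query set — under leave-one-out they can never be correct — and the
per-query table flags them.

When every species has at least two samples and every species' minimum
heterospecific distance exceeds its maximum conspecific distance, no
incorrect verdict is possible (the positive-gap property asserted in the
tests).

## Per-species separability

For each species: heterogeneity = maximum conspecific distance (0 with a
singleton flag for single-sample species, where the maximum over an empty
pair set is undefined), separability = minimum distance to any
heterospecific sequence, closest relative(s) = the species attaining it
(ties all reported, sorted). A species is separable when separability
exceeds heterogeneity; species with separability exactly 0 share an
identical sequence with another species and are listed as inseparable
pairs. The table is computed on the K2P distance matrix for consistency
with every other stage (the original TaxonGap tool phrases the same
quantities on a similarity matrix).

## Neighbor joining and bootstrap

Saitou-Nei agglomeration on the Q-criterion, joining the pair minimizing
Q(i,j) = (m-2)d(i,j) - r_i - r_j with branch lengths d/2 ± (r_i - r_j)/(2(m-2));
the final three lineages get the closed-form three-taxon lengths. Ties in Q
are broken by the lowest (row, column) index pair, making construction
deterministic. Negative branch-length estimates are clamped to zero by
default (the field's common default), with `clamp_negative=False` exposing
the raw estimates; on additive matrices NJ reconstructs the generating tree
exactly, which the tests verify against an independent path-length oracle
and against scikit-bio's NJ.

Bootstrap: alignment columns are resampled with replacement (default 1000
replicates, seeded), each replicate rebuilt from its own K2P matrix, and
supports attached to the *full-data* tree's internal edges as the
percentage of replicates containing the same bipartition (bipartitions are
normalized to the side not containing the lexicographically first leaf). A
replicate whose resampled matrix has an undefined pair is dropped with a
warning and the denominator adjusted. Rooting places the root at the
midpoint of the edge separating the outgroup leaves from the ingroup; a
non-monophyletic outgroup (no such bipartition) is an error. Supports are
re-mapped by bipartition after rerooting, so annotation is independent of
which node ends up above each edge.

## Synthetic genus generator

The generator emulates the divergence structure the analyses assume: K
species radiating from one root (a star phylogeny), n individuals per
species radiating from their species ancestor. Individuals sit
intra_divergence/2 below their ancestor and ancestors
(inter_divergence − intra_divergence)/2 below the root, so the *expected
pairwise* K2P distance is exactly intra_divergence within species and
inter_divergence between species — the config fields are defined as
expected pairwise divergences, and the defaults (64 species × 6 samples,
248 bp, GC 0.52, intra 0.007, inter 0.18, transition/transversion ratio
kappa = 2) are the study conditions of a short variable nuclear spacer in a
species-rich medicinal-plant genus. Sites evolve independently under the
exact finite-time two-parameter substitution probabilities (in
e1 = exp(-4βt), e2 = exp(-2(α+β)t) with α/β = kappa and α + 2β scaled to
the branch length), so realized distances are unbiased for the path length
at any branch length, not only asymptotically.

A star per level, rather than a birth-death tree, keeps every pairwise
expectation closed-form; the pooled intra/inter summaries do not depend on
within-genus tree shape. Planted identical pairs (n_identical_pairs = k)
assign the first species' ancestor haplotype to *every* sample of both
species in each of the k designated pairs — the situation of sister species
the marker cannot distinguish — which deterministically yields ambiguous
(never incorrect) leave-one-out verdicts and zero separability for exactly
those 2k species. One master seed drives a single generator stream in a
fixed draw order (root, ancestors, individuals), so outputs are
byte-reproducible.

What the generator does **not** emulate: insertions/deletions and alignment
error (output is gap-free and aligned by construction), among-site rate
heterogeneity, base-compositional asymmetry of the substitution process
(the root matches the GC target; the symmetric process relaxes tip GC
toward 0.5 by roughly a percentage point at the default depths), coalescent
population structure within species, and paralogy/multi-copy artifacts of
real ribosomal spacers. Passing tests therefore demonstrate the
correctness of the statistics and decision rules, not robustness to
alignment noise or model misspecification on real data.

## Problem sizes and runtime choices

The test-suite and `scripts/acceptance.py` compute everything at sizes a
laptop handles in seconds: the divergence/gap/nearest-identification block
runs at the full default genus (384 sequences; ~74k pairs), while the
exhaustive best-hit search (quadratic in samples × alignment cost) uses a
24 × 4 genus and the bootstrapped tree a 16 × 4 genus with 100 replicates.
These sizes are stated in the script and are the package's choice of
demonstration scale; the library itself has no such limits, and 1000
bootstrap replicates (the conventional default) remain the API default.

## Known limitations

* Only the K2P model is implemented; no gamma rate correction or other
  substitution models.
* The rank-sum p-value ignores pairwise dependence (documented above).
* The best-hit scorer is exhaustive; for reference databases of many
  thousands of sequences a heuristic search tool would be the practical
  choice.
* Sequences must be pre-trimmed and pre-aligned (or simulated); the package
  performs no alignment and no marker-boundary annotation.
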