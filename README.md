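# barcodegap

Evaluate how well a short DNA barcode marker (such as the nuclear ribosomal
ITS2 spacer) discriminates the species of a genus, from a labeled sequence
dataset. The package is aimed at molecular taxonomists and barcoding studies:
given aligned marker sequences, each tagged with the species it was sampled
from, it answers the three questions such a study asks —

1. **Is there a barcoding gap?** Do between-species genetic distances sit
   clearly above within-species distances?
2. **How often does the marker identify a query correctly?** Leave-one-out
   identification by nearest genetic distance and by best local-alignment
   hit, with correct / ambiguous / incorrect verdicts.
3. **What does the marker say about relationships?** A neighbor-joining tree
   with bootstrap supports, rooted on designated outgroup species.

## The model and statistics

Pairwise distances use the Kimura 2-parameter (K2P) model. Over the sites
where both sequences carry an unambiguous nucleotide (pairwise deletion of
gap/ambiguity columns), let *P* be the proportion differing by a transition
(A↔G, C↔T) and *Q* by a transversion; the distance in expected
substitutions per site is

    d = -(1/2) · ln((1 − 2P − Q) · √(1 − 2Q))

Six divergence metrics summarize the distance matrix, following the
barcoding convention: **all inter-specific distance** (mean ± SD over every
heterospecific pair), **theta prime** (per-species mean distance to all
heterospecific sequences, averaged across species), **minimum
inter-specific distance** (per-species minimum, averaged across species),
**all intra-specific distance** (mean over conspecific pairs), **theta**
(per-species conspecific mean, averaged over multi-sample species) and
**coalescent depth** (per-species conspecific maximum, likewise averaged).

The gap itself is profiled as paired histograms at 0.008 distance-unit bins
plus overlap statistics, and tested with a two-sided Wilcoxon rank-sum
comparison. Per-species discriminability is tabulated TaxonGap-style as
*heterogeneity* (max within-species distance) vs *separability* (min
distance to any other species), flagging species pairs with identical
sequences. Trees come from the Saitou–Nei neighbor-joining algorithm with
non-parametric bootstrap over alignment columns.

A synthetic genus generator (`simulate_genus`) produces ground-truthed
datasets with the same statistical structure — by default 64 species × 6
samples of 248 bp at GC 52%, expected within-species K2P divergence 0.007
and between-species 0.18, optionally with planted species pairs sharing
identical sequences — so every stage can be validated against known truth.

## Worked example

Simulate a 16-species genus and run each analysis from the shell:

```sh
barcodegap simulate --n-species 16 --samples 4 --seed 7 --out demo
barcodegap metrics  demo/simulated.fasta --labels demo/simulated_labels.tsv --out demo/div.json
barcodegap gap      demo/simulated.fasta --labels demo/simulated_labels.tsv --out demo/gap.tsv
barcodegap identify demo/simulated.fasta --labels demo/simulated_labels.tsv --method nearest --out demo/id.tsv
barcodegap taxongap demo/simulated.fasta --labels demo/simulated_labels.tsv --out demo/tg.tsv
```

which prints:

```
64 sequences, mean length 248.0 bp, mean GC 49.8%
All inter-specific distance: 0.171 ± 0.030
Theta prime: 0.171 ± 0.019
The minimum inter-specific distance: 0.129 ± 0.022
All intra-specific distance: 0.006 ± 0.005
Theta: 0.006 ± 0.003
Coalescent depth: 0.010 ± 0.005
inter-specific pairs at zero distance: 0.00%
inter-specific pairs below 0.020: 0.00%
Wilcoxon rank-sum: U=184320.0, two-sided p=1.41e-61
{
  "method": "nearest",
  "n_samples": 64,
  "n_species": 16,
  "pct_correct": 100.0,
  "pct_incorrect": 0.0,
  "pct_ambiguous": 0.0
}
16/16 species separable (100.0%)
```

Reading the output: within-species variation (0.006) sits far below
between-species divergence (0.171) — a wide barcoding gap, confirmed by the
rank-sum test (p ≈ 10⁻⁶¹) and the absence of inter-specific pairs below the
intra-specific maximum (0.020). Consequently every leave-one-out query is
identified correctly and every species is separable. Planting identical
sequences across species pairs (`--identical-pairs k`) turns exactly those
species' queries ambiguous (never incorrect) and their separability to zero.

`barcodegap tree` builds the bootstrapped NJ tree, and `barcodegap run
config.yaml` drives all stages from one declarative config into a single
output directory. The same functionality is available as a library:

```python
from barcodegap import GenusSimConfig, simulate_genus, pairwise_matrix, divergence_summary
aln, truth = simulate_genus(GenusSimConfig(n_species=16, samples_per_species=4, seed=7))
dm = pairwise_matrix(aln)
print(divergence_summary(dm, aln.labels).all_inter_mean)
```

Real datasets enter through `read_labeled_fasta(fasta, labels_tsv)`: an
aligned FASTA plus an `id<TAB>species[<TAB>outgroup]` table (or species
parsed from FASTA headers). Outgroup-flagged species root the tree and are
excluded from the divergence/gap/identification statistics.

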