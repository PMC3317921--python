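# Methods

## Distances

Pairwise distances use the Kimura 2-parameter model. For two aligned
sequences, columns where either has a gap (`-`) or an ambiguous base
(`N`) are excluded ("pairwise deletion"); over the retained sites, P is
the proportion showing a transition difference (A↔G, C↔T) and Q the
proportion showing a transversion, and

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Pairwise deletion is the only gap mode for distances: no substitution
model describes indel evolution, so treating gaps as characters inside a
distance formula has no justification (gaps as a "5th state" exist only
in the haplotype module, where differences are counted, not modelled).
When a log argument falls to zero or below the pair is *saturated*; the
distance is reported as undefined (NaN) and excluded from summaries with
a logged count, never clamped — silently capping distances would bias
every mean and threshold downstream. Non-ACGT IUPAC codes are mapped to
N on input with a warning; sequences are stored uppercase.

## Barcoding gap

The gap for a species is (minimum inter-specific distance involving it)
− (maximum intra-specific distance within it); the dataset-level gap is
the minimum over species, so it is positive only when every species is
separable by a distance threshold. The headline mean intra/inter summary
pools all pairs (per-species averages are also emitted, since the two
conventions differ when sample sizes are uneven). Histograms default to
50 equal-width bins spanning the pooled range — a display choice with no
downstream effect.

## Assignment methods

**MD** assigns the species of the K2P-nearest reference. Distances tied
within ε = 1e-12 across more than one species give status `ambiguous`.

**BCM** additionally requires the best match to fall within a threshold:
the 95th percentile — linear interpolation between order statistics, the
numpy default, since threshold software conventions differ — of all
intraspecific pairwise distances in the reference library. Beyond it the
query is `unidentified`. In leave-one-out runs the threshold is
recomputed per replicate from intraspecific pairs not involving the
query, so the query never informs its own acceptance gate.

Ambiguous and unidentified queries count as failures in success rates
(only a correct, unambiguous assignment is a hit); a lenient tally that
credits ambiguous calls containing the true species is recorded
alongside but never used as the headline.

**BP** is a single-hidden-layer feed-forward network over one-hot
encoded columns (4 indicators per site; gap/N encode as all-zeros, so
missing data contributes nothing to any activation). Sigmoid units, one
output per species, full-batch gradient descent with momentum on the
mean squared error, stopping at MSE ≤ goal. Defaults: learning rate 0.2,
momentum 0.5, goal 1e-5, hidden width 4 × n_species, max 5000 epochs
(non-convergence returns the model with a flag rather than failing —
argmax accuracy typically saturates long before the MSE goal). Weight
initialisation is uniform Xavier from a seeded generator; training is
bitwise reproducible for fixed data, hyperparameters and seed. The
architecture beyond the three stated hyperparameters is this package's
design choice and every piece of it is exposed as a parameter.

## Resampling designs

*Leave-one-out*: each of the `n_reps` (default 500) replicates draws one
specimen uniformly **with replacement** across replicates (500
replicates over ~140 specimens forces this reading) and classifies it
against all remaining specimens. Uniform rather than species-stratified
sampling is used. *Split*: specimens are partitioned at reference:query
= 9:1 or 1:1 with query count = round(N/(r+1)); the partition is redrawn
(up to 100 times, logged) until every species has a reference
representative. BP is evaluated only under the split design — retraining
a network inside every leave-one-out replicate is impractical and the
split is the standard protocol for trained classifiers.

The success rate p̂ = N_hit/N_query gets a Wilson score interval,

    (p̂ + z²/2n ± z·sqrt(p̂(1-p̂)/n + z²/4n²)) / (1 + z²/n),

clipped to [0,1]. The function takes the proportion rather than counts
so intervals can be recomputed from rounded published rates as well as
exact fractions. The *overall* success rate multiplies p̂ by the joint
sequencing fraction (specimens with **all** loci of the barcode
sequenced / specimens submitted); an `independence_product` mode
(p̂ × Π per-locus rates) is available for when joint counts are not
known, and coincides with joint counts for single-locus barcodes.

## Haplotype networks

Two sequences share a haplotype iff their step count is zero under the
chosen gap mode (`missing`: columns with `-` or `N` in either excluded;
`fifth_state`: `-` is a real character, N still missing). Zero distance
under missing data is not transitive, so haplotypes are the connected
components of the zero-difference relation; the representative sequence
is the first member's (arbitrary, documented; step counts between
haplotypes use representatives). The network is a minimum spanning tree
over the complete step-count graph — Kruskal with edges sorted by
(steps, lexicographic id pair), so ties resolve deterministically.
Reticulations and alternative equal-weight edges are deliberately not
represented: an MST is deterministic and testable against exhaustive
enumeration, which matters more here than displaying loops.

## Synthetic data generator

The generator emulates the *statistical* structure of a six-species
sibling-group study, not its genealogy: a star phylogeny, where each
species' ancestral sequence derives from a common root and each specimen
mutates its species ancestor independently. Defaults (the `paper_preset`):
140 specimens in 6 species; the last three species form a close trio
descended from a shared trio ancestor; loci of 652 (COI-like), 804 and
656 (ITS-like) aligned columns; per-locus sequencing dropout 0 / 0.507 /
0.307, so expected success is 100% / 49.3% / 69.3%; transition bias
κ = 2 (transition probability κ/(κ+2) per mutation).

Divergence knobs are expected pairwise K2P-scale distances, so branches
get half the target: `mu_intra = 0.008` (typical within-species COI
divergence for congeneric moths, under 1%), `mu_inter_close = 0.03`,
`mu_inter_far = 0.12`. Mutations are drawn per site independently with
no rate heterogeneity or double-hit modelling — realised distances land
within a few percent of the nominal values at these rates. ITS-like loci
receive deletion-style indels (Poisson count at 0.003 events/site,
geometric lengths) written directly as gap runs, so emitted alignments
need no realignment.

Incomplete lineage sorting is emulated *directly*: with probability
`ils_share_prob` (default 0.1 — no empirical calibration exists, so this
is an exposed free parameter) a close-trio specimen inherits a random
sibling species' ancestral haplotype instead of its own, recorded in the
truth table. One consequence worth knowing: under a star model a single
borrowed specimen that happens to carry few private mutations can become
the nearest neighbour of *most* members of its donor species, so MD/BCM
success under ILS varies substantially between seeds — a sharpened
version of the real phenomenon where one shared haplotype breaks
identification for a whole species. What passing tests on this generator
show is that the pipeline measures what it claims on data with known
structure; they say nothing about PCR chemistry, alignment error,
contamination, or rate variation, none of which are modelled.

## Problem sizes

Default test and script runs use the preset design (140 specimens ×
up to 2112 concatenated columns), 500 leave-one-out replicates (a
precomputed distance matrix makes each replicate a masked argmin), and
single BP trainings of ≤ 5000 epochs; property tests check MD against
exhaustive nearest-neighbour search at ≤ 20 references and MSTs against
full spanning-tree enumeration (Prüfer sequences) at ≤ 8 nodes.
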