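# Methods

`barcodeval` evaluates candidate DNA barcode markers for a set of vouchered
specimens with known species labels. It implements the classical
distance-based evaluation battery — marker variability statistics, the
intra/interspecific distance comparison ("barcoding gap"), the best-close-match
identification test, and species-specific cluster scoring on bootstrap-
annotated neighbor-joining trees — together with a seeded simulator that
produces multi-species, multi-marker datasets with the statistical structure
these analyses assume.

## Distances

All genetic distances are uncorrected p-distances: the proportion of
mismatching sites between two aligned sequences. Comparisons use **pairwise
deletion**: for each pair, any column where either sequence carries `-`, `N`
or `?` is excluded. The three symbols are treated identically because an
ambiguous or absent base cannot evidence a mismatch, and because `?` is the
pad character used for absent marker blocks in concatenations — treating it
differently would make a specimen's distances depend on how its supermatrix
row was assembled. A pair with zero comparable sites (possible in gap-rich
spacer matrices or sparse concatenations) has an *undefined* distance, stored
as NaN; undefined pairs are excluded from every summary and their count is
reported as a diagnostic, because silently letting them enter percentiles or
thresholds would bias everything downstream. No substitution-model correction
is applied anywhere in the analysis path: model-corrected distances change
the scale of the thresholds without changing the ranking of close matches in
the regimes barcode libraries operate in, and uncorrected distances keep the
outputs directly comparable with the established identification tools.

The barcoding-gap summary bins intra- and interspecific distances into
relative-frequency histograms (default bin width 0.01, which resolves the
0–0.2 range typical of plant spacers) and reports the fraction of
interspecific distances **strictly greater** than a reference point x
(default 0.05) and of intraspecific distances **strictly lower** than x,
along with max(intra), min(inter) and an overlap flag (max(intra) ≥
min(inter) means no gap).

## Marker variability

Variability statistics use **complete deletion**: any column containing a
gap/missing symbol in any row is excluded before counting, matching the
convention of standard polymorphism software. Over the remaining "usable"
columns:

* a site is *polymorphic* when ≥ 2 distinct bases occur;
* a site is *parsimony-informative* when ≥ 2 distinct bases each occur in
  ≥ 2 sequences;
* nucleotide diversity π is the mean pairwise mismatch proportion
  (equivalently, the mean off-diagonal of the p-distance matrix restricted
  to usable sites — this equivalence is asserted as a test invariant);
* two sequences share a *haplotype* iff they are identical over usable
  sites; haplotypes are numbered by first occurrence, so the assignment is
  deterministic and permutation-stable in count. Ambiguity codes beyond `N`
  are rejected at read time to keep haplotype collapsing exact.

Sequence length summaries report both the mean and the median of unaligned
(degapped) lengths, since published marker tables are not always explicit
about which of the two they print.

## Best close match

The identification test is leave-one-out: every specimen in a matrix is
queried in turn against all others. The similarity threshold is the
**smallest observed intraspecific distance d such that at least 95% of all
intraspecific distances are ≤ d** (the empirical 95% point on observed
values), computed once per matrix — separately for each marker and each
combination — so markers with different variability get their own limits.
Candidates are all other specimens at a defined distance ≤ threshold:

| outcome | rule |
|---|---|
| `correct` | the tie set at the minimum candidate distance is entirely conspecific |
| `ambiguous` | the tie set mixes conspecifics and heterospecifics |
| `incorrect` | the tie set contains no conspecific |
| `no_match` | no specimen at all lies within the threshold |

The tie tolerance defaults to 0 (exact distance ties only); a nonzero value
is available because some legacy implementations compare at limited printed
precision, but determinism argues for 0. Queries of singleton species — no
conspecific exists anywhere, so `correct` is impossible — are classified by
the same rules and counted separately, and every category percentage is
reported with both denominators (all queries, and non-singleton queries),
since published summaries differ in which they use.

Note one structural property of the test: because the threshold is a 95%
point of the intraspecific distribution, roughly the top 5% of intraspecific
distances lie above it by construction. A query whose conspecifics all fall
in that tail is reported `no_match` even on data with a clean barcoding gap.
This abstention is intentional — it is what the threshold is for — and it is
why `correct` rates saturate slightly below 100% even under idealized
simulation (see the simulator notes below).

## Trees and species-specific clusters

Neighbor joining follows the standard agglomeration on the Q criterion. Two
numerical policies make it deterministic and downstream-safe:

* Q-ties are broken by the lexicographically smallest pair of cluster
  representative labels (the minimum specimen id inside each cluster);
* negative branch lengths (possible on non-additive matrices) are clamped to
  zero with the deficit transferred to the sibling edge, preserving
  tip-to-tip path lengths; newick consumers reject negative lengths.

NJ requires all pairwise distances defined; an undefined pair raises an
error telling the user to impute or drop specimens rather than guessing.

Bootstrap support resamples alignment columns with replacement (seeded),
rebuilds the NJ tree per replicate, and annotates each internal edge of the
**full-data topology** with the percentage of retained replicates containing
its bipartition (supports are mapped onto the full tree, not a consensus,
matching how published barcode trees present a single topology with supports
under branches). Replicates in which some pair loses every comparable site
have no defined matrix; they are dropped, counted, and excluded from the
support denominator. The per-pair mismatch/comparable counts are precomputed
per column, so each replicate's distance matrix is two matrix-vector
products; 1000 replicates on ~100 specimens take seconds. Trivial
(single-leaf) bipartitions are supported at 100 by convention.

Rooting places the root on the edge subtending the smallest clade containing
a user-specified outgroup (which must form one side of a bipartition;
otherwise the error names the offence), splitting that edge's length evenly;
supports are re-attached by bipartition after rerooting so they survive.
When no outgroup is given — e.g. on simulated data with no designated
outgroup taxon — the pipeline midpoint-roots.

A species is a *species-specific cluster* when some clade contains exactly
its specimens and that clade's support meets the cutoff (default 70%). The
headline percentage uses species with ≥ 2 sampled specimens as denominator —
singletons are trivially monophyletic and carry no signal — with the
all-species variant reported alongside. Scoring accepts any rooted,
support-annotated newick, so trees from external ML/MP searches can be
scored with the same code path; tree *search* beyond NJ is out of scope.

## Concatenation schemes

A combination scheme lists its markers, the minimum number a specimen must
actually have (`min_markers_required`), and the pad character. Filtering is
at the **specimen** level — a specimen survives iff it has enough of the
scheme's markers — because distances, identification and trees all operate
on specimens; species-level tallies are derived from the surviving
specimens. Absent blocks are padded with `?` (default), which every
downstream comparison already treats as missing, so padding is neutral with
respect to pairwise-deletion distances. Whether partially sampled specimens
should be dropped or gap-filled is genuinely convention-dependent, so both
behaviors are reachable through `min_markers_required`/`fill_char`. Rows are
emitted in sorted specimen-id order, making the supermatrix independent of
input row order; a block map (marker → column range) is retained and written
alongside.

## The synthetic data generator

The simulator emulates a regional barcode study: `n_species` (default 30)
well-delimited species, `individuals_per_species` (default 3) specimens
each, and four markers whose defaults mirror a typical plant four-marker
panel — two conserved plastid coding regions, one indel-rich plastid spacer,
and one indel-rich nuclear spacer — with aligned lengths 580/939/707/850 bp,
relative substitution rates 0.35/0.85/1.5/1.0 chosen proportional to the
relative nucleotide diversities such panels show, and per-marker dropout
(0.39/0.42/0.20/0.29) emulating realistic amplification-plus-sequencing
failure. All plastid markers share one genealogy per dataset (uniparental
linkage); nuclear markers draw independent within-species genealogies on the
same species tree.

Units: `interspecific_depth` and `intraspecific_theta` are expected
substitutions/site at unit marker rate. Defaults 0.055 and 0.005 give mean
interspecific p-distances near 0.10 and intraspecific near 0.005, i.e. a
clear barcoding gap at the 0.05 reference point. The helpers
`expected_p_distance` (Jukes–Cantor map 0.75·(1−e^(−4d/3))),
`expected_intra_p` (the same map averaged over the exponential coalescent
path-length distribution, 0.75a/(1+a) with a = 4θ/3) and their inverses
convert between divergence and observable p-distance for calibration.

Species relationships come from a pure-birth (Yule) topology whose node
depths are then calibrated in two steps: an affine adjustment fixes the mean
pairwise tip divergence and floors the shallowest split at
`min_divergence_frac` (default 0.25) of the mean; a uniform rescale then
makes the mean pairwise divergence, pushed through the JC map, match
`expected_p_distance(2 × depth)` exactly, so parameter-recovery tests have a
closed-form target with no Jensen bias. The floor is a deliberate design
choice: an unconstrained Yule process routinely places its most recent split
at a few percent of the mean depth, i.e. it generates pairs of "species"
less divergent than the within-species diversity — not a property of a
curated barcode reference library, whose species are established taxa.
Setting `min_divergence_frac = 0` recovers the unconstrained Yule tree for
studies of exactly that failure mode.

Within species, individuals coalesce under a Kingman coalescent with
expected pairwise path length θ, truncated at the species' divergence time
(remaining lineages merge just below it). There is therefore **no incomplete
lineage sorting**: the true genealogy always respects species boundaries.
Sequences evolve by exact Jukes–Cantor transition sampling along the
genealogy. Spacer markers receive indels (Poisson per branch at
`indel_rate`·sites·branch-length; geometric lengths, mean 4): deletions
knock a window out of a subtree, insertions add a subtree-private column
block, and the emitted alignment is the true one — the package never aligns.

What the generator does **not** emulate, and what passing tests therefore do
not certify about real data: alignment error (inputs are true alignments),
heterozygous/paralogous nuclear copies and ambiguity codes, hybridization or
introgression, incomplete lineage sorting, rate variation across sites and
lineages, and base-composition bias. Inserted segments also do not accrue
substitutions after their origin. These simplifications are deliberate: the
simulator's job is to exercise the statistics under controlled truth, not to
be a sequence-evolution benchmark.

## Reproducibility and numerics

Every stochastic component takes an explicit seed; a dataset is
byte-identical for a fixed `SimulationConfig`, and one pipeline seed fans
out to per-analysis-unit seeds by a stable string-keyed derivation, so two
runs of the same config produce byte-identical CSVs and newick files (the
run log records wall-clock timings and is the one deliberately
non-reproducible file). Floats are written at 10 significant digits.
Degenerate inputs fail loudly: ragged alignments, unknown specimen ids,
empty intra-distance sets, non-monophyletic outgroups, fully undefined
distance rows and empty concatenations all raise typed errors naming the
offending stage or input. Test-suite and example problem sizes (hundreds of
random small alignments, 4–6-taxon exhaustive tree enumerations, 30×4
specimen pipelines at 100–1000 bootstrap replicates) were chosen as the
smallest designs at which every statistic is exercised with stable
expectations.
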