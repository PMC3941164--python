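# Methods

`methanodiv` reimplements, as tested library code, the standard clone-library
workflow for surveying methanogen diversity with two marker genes: the
archaeal 16S rRNA gene (DNA, ~1254 bp amplicons) and the deduced amino-acid
sequence of *mcrA*, the α-subunit of methyl coenzyme-M reductase (~160 aa
from a 480 bp amplicon). Input is a pre-aligned multi-FASTA in which each
clone carries a library tag (e.g. `horse`, `pony`); alignment construction
itself is out of scope.

## Distances

Pairwise distances are uncorrected p-distances (mismatches over comparable
sites), optionally Jukes-Cantor corrected for DNA or Poisson corrected for
protein. Sites with a gap or ambiguity code (`N` for DNA, `X` for protein)
in either member of a pair are excluded (pairwise deletion, the default);
complete deletion is available. Percent-similarity OTU criteria are defined
on the p-distance scale: similarity = (1 − d) × 100, so the 98% 16S
criterion is a distance cutoff of 0.02 and the 95% mcrA criterion 0.05.
The source study computed distances with Phylip's `dnadist`/`protodist`
without naming the models; because the OTU thresholds are stated as percent
similarity — which maps exactly onto p-distance and only approximately onto
model-corrected distances — this package deliberately clusters on
p-distances and treats F84/JTT-style corrections as out of scope.

## OTU clustering

OTUs are formed by agglomerative furthest-neighbor (complete-linkage)
clustering: two clusters merge only when **every** inter-cluster sequence
pair lies within the cutoff, merges proceed in non-decreasing
complete-linkage distance, and clustering stops when the smallest feasible
merge exceeds the cutoff. This is the strict OTU definition popularized by
DOTUR/mothur. Distances enter at full precision (no 0.01 binning). Ties
between equal-distance merges are broken toward the pair whose member-id
union has the lexicographically smallest (min id, max id), which makes the
merge trace deterministic across platforms. The cluster-diameter invariant
(max intra-OTU distance ≤ cutoff) holds by construction and is asserted in
tests on every run.

## Diversity statistics

For each library's abundance vector (zero-count OTUs dropped):

* Shannon–Wiener `H' = −Σ pᵢ ln pᵢ` (natural log).
* Evenness in two conventions: the textbook Pielou form `H'/ln(S)`
  (`formula`) and `H'/ln(N)` (`printed`). Published clone-library tables
  frequently normalize by clone count N rather than OTU count S; both are
  first-class here, the convention is recorded in every report, and the
  default (`printed`) follows the published horse/pony table.
* Coverage in two conventions: Good's estimator `(1 − F1/N) × 100`
  (`clones`) and the OTU-denominator variant `(1 − F1/S) × 100` (`otus`),
  where F1 is the number of singleton OTUs. Three of the four published
  coverage cells match the `otus` convention, which is therefore the
  default; the stated Good formula remains available. One published cell
  (pony mcrA, 86%) matches neither convention and is treated as
  unreproducible; the implementation is not tuned toward it.
* Chao-1 richness: the classic `S + F1²/(2·F2)`, with the additive fallback
  `S + F1(F1−1)/2` when no doubletons exist (this fallback, not the
  bias-corrected form, reproduces the published horse-mcrA value of 18).
  Consequently `chao1 = S` exactly when `F1 ≤ 1`.

Statistics are computed at full precision; rendering rounds H′ and evenness
to 2 dp and coverage/Chao-1 to 1 dp, matching the published table. Known
unreproducible published cells (horse 16S H′ printed 1.29 vs 1.2849 from
the counts; the 16S Chao-1 values 12 and 13) are documented and excluded
from any assertion.

## Cross-marker threshold calibration

Because a protein marker accumulates distance faster than 16S rRNA, the 16S
OTU cutoff is mapped to an mcrA cutoff by regressing paired mcrA distances
(Y) on 16S distances (X) **through the origin** over reference taxa:
`slope = Σxy/Σx²`, with the uncentered `R² = 1 − RSS/Σy²` (the standard
definition for no-intercept fits; the centered form can be negative and
misleading). All n(n−1)/2 taxon-pair distances enter the regression. The
mapped cutoff is `slope × 0.02`, and the working similarity criterion is
`floor(100 × (1 − mapped_cutoff))` — flooring, because 0.0439 must yield a
95% (not 96%) criterion. The published slope (2.1944) and R² (0.6196)
depend on 23 reference genomes and unstated distance models and are not
recomputed here; instead the generators plant a known slope and the tests
verify its recovery (±0.05 over 100 seeds at noise σ = 0.05, 253 pairs).

## LIBSHUFF comparison

For libraries X, Y over a pooled distance matrix, homologous coverage
`C_X(D)` is the fraction of X-sequences with another X-sequence (self
excluded) within distance D, and heterologous coverage `C_XY(D)` the
fraction with a Y-sequence within D. The statistic is the discretized
Cramér–von Mises integral `ΔC_XY = Σ_D (C_X(D) − C_XY(D))² · step` on a
grid from 0 to the maximum observed pooled distance in steps of 0.01.
Multiplying by the step is a convention recorded in the result; because the
same grid serves observed and permuted statistics, p-values are invariant
to it. Significance comes from label permutations with library sizes fixed
(default 999) with the add-one estimator
`p = (1 + #{permuted ≥ observed}) / (1 + n)`; ties count as exceedances,
keeping the test valid. Both reciprocal directions are tested and the
verdict uses the experiment-wise corrected per-comparison threshold
`1 − (1 − α)^(1/2)`.

Two behaviors worth knowing:

* ΔC is exactly 0 for identical libraries **provided every sequence has a
  within-library duplicate** (the realistic clone-library case, where each
  OTU is sampled repeatedly). For duplicate-free identical libraries the
  homologous curve sits below 1 at small D while the heterologous curve is
  1, so ΔC is positive even though the p-value stays large. Whenever the
  observed ΔC is 0, p = 1 follows automatically from the add-one estimator.
* The permutation test is exact only under exchangeability of the pooled
  sample. The synthetic null generator therefore draws both libraries'
  clone counts as full-length multinomials (zero categories kept) over one
  common ancestor pool, making the 100 pooled clones i.i.d.; with this
  construction the simulated type-I error at the 1254-bp default world is
  statistically indistinguishable from nominal (checked over 1000
  simulations in the test suite).

## Neighbor-joining trees

Saitou–Nei neighbor joining with the standard Q-criterion
`Q(i,j) = (m−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k)`. Q is evaluated on the upper
triangle only (floating-point addition order would otherwise make Q(i,j)
and Q(j,i) differ in the last ulp), and ties are broken toward the pair
with the lexicographically smallest representative leaf labels. Negative
branch lengths are clamped to zero with the deficit transferred to the
sister branch (Kuhner–Felsenstein), preserving path lengths; on additive
matrices the tree reproduces all leaf-to-leaf path lengths within 1e−9.
The unrooted tree is stored with a trifurcating root and can be rooted on
an outgroup's pendant edge (split at its midpoint), which preserves
patristic distances exactly.

Bootstrap support resamples alignment **columns** (not matrix entries)
with replacement, rebuilds the distance matrix and tree per replicate, and
attaches `round(100 × recovery frequency)` of each internal bipartition of
the reference tree. Replicates whose resample produces an incomparable or
saturated pair are skipped and tallied, and supports are normalized by the
successful-replicate count.

## Synthetic data

The generators state a world resembling the published libraries: 50 clones
per library, a geometric abundance model with dominance θ = 0.6 over
S = 8 OTUs (dominant OTU ≈ 60% of clones, matching the observed 58–74%
range, with a singleton/doubleton tail), 1254 bp DNA sequences, maximum
intra-OTU divergence 0.005 and minimum inter-OTU ancestor divergence 0.20.
An explicit abundance mode replays printed count vectors verbatim.

Per-OTU ancestors are rejection-sampled uniform sequences with all pairwise
p-distances ≥ the inter bound; clones are ancestor copies mutated at up to
`floor(intra · L / 2)` distinct sites (i.i.d. uniform replacement, no
indels), so intra-OTU p-distances are ≤ intra and cross-OTU clone distances
≥ inter − intra **by construction**, with no need to trust the sampler.
Every generator emits its planted truth alongside the data and is
byte-deterministic given a seed.

What the generator does *not* emulate — rate heterogeneity, indels,
chimeras, PCR/sequencing error, phylogenetic correlation among OTU
ancestors — bounds what a green test establishes: recovery results certify
the algorithms on cleanly separated communities, not robustness to
alignment artifacts or chimeric reads.

Paired-marker calibration inputs are simulated directly on the distance
scale: x uniform on [0.01, 0.35] per taxon pair, y = slope·x plus Gaussian
noise truncated at zero.

## Numerical and interface choices

* Distance-matrix files are phylip-style (count header), square or
  lower-triangle, written with 6 decimals for bit-stable diffs.
* A coverage comparison `d ≤ D` uses a 1e−12 slack so grid points equal to
  an observed distance count as covered regardless of rounding direction.
* Permutation and bootstrap randomness comes from `numpy` PCG64 generators
  seeded explicitly; every result object records its seed.
* The pipeline writes a JSON manifest naming the config, conventions,
  seed, and artifact paths; identical config + inputs give byte-identical
  artifacts.
* Degenerate inputs fail loudly with typed exceptions (empty libraries,
  saturated corrections, incomparable pairs, non-positive regressors);
  an empty distance matrix clusters to an empty assignment rather than
  erroring.

## Known limitations

* Corrected distances (JC69/Poisson) are not used for OTU thresholds; the
  percent-similarity criteria are p-distance constructs.
* LIBSHUFF is implemented for exactly two libraries; multi-library designs
  require pairwise runs with an external correction.
* Newick output supports integer bootstrap labels on internal nodes but
  the package does not parse Newick back (round trips in tests go through
  dendropy).
* The published tree figures and the real horse/pony LIBSHUFF verdicts
  depend on deposited sequences and external references and are not
  reproduced; property-based simulations stand in for them.
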