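# Methods

This note documents the models and estimators implemented in `ovismt`,
the parameter choices that matter, what the synthetic generators do and
do not emulate, and the numerical decisions a maintainer would want
written down.

## Haplogroup classification

The classifier operates on five diagnostic control-region positions
(AF010406 coordinates 15459, 15476, 15484, 15509, 15512; 1-based,
inclusive). Each non-reference haplogroup is defined by the complete set
of derived bases it carries (A: T@15459 + A@15484; C: G@15509; E:
C@15476 + G@15509); HPG B is the reference haplogroup (reference base at
every site).

Matching rules, in order:

1. A sample matches a haplogroup when it carries **all** of that
   haplogroup's derived bases. Extra private variants at the remaining
   diagnostic sites do not block a match — ancient samples do carry such
   variants, and requiring the full five-site vector to be exactly the
   canonical one would throw those samples away.
2. When more than one signature is completed, the most specific rule
   (whose position set strictly contains the others') wins. This is what
   makes C (G@15509) and E (C@15476 + G@15509) coexist: a sample with
   both E bases is E, not ambiguous.
3. A sample matching nothing is HPG B if every readable site carries the
   reference base, otherwise unassigned. Partial signatures are never
   resolved to the nearest haplogroup: template damage in ancient DNA
   makes nearest-match calling unsafe.
4. Sites reading 'N'/'-' count as missing; more than `max_missing`
   (default 0) missing sites forces unassigned (with the count recorded),
   not an exception.

HPG D and the wild anatolica-X haplotype have no published signature in
this five-site scheme; the shipped table carries them as empty rules that
can never match, and users may extend the table (`extra_rules`) when they
have their own diagnostics. The synthetic generator's X panel uses an
explicitly synthetic extension (15466→T) for round-trip testing only.

## Tandem-repeat clusters

The CR tandem repeat is located by self-similarity rather than a fixed
coordinate: within ±30 bp of position 15640, the parser finds the offset
whose next 75-mer best matches the 75-mer after it (allowing the second
unit to be 76 bp), because published coordinates for the repeat start
differ by ~10 bp between sources and real sequences indel-shift. Units
are then matched greedily against the first unit, each unit allowed
length 75 or 76 with at most `d_max = 5` internal mismatches. The first
unit is always 75 bp; clusters are called from the later units (all 75 →
cluster i; all 76 → cluster ii; mixed → undetermined). Unit counts
outside 3–5 draw a warning rather than an error.

## Diversity statistics

* Haplotype diversity: h = n(1 − Σp²)/(n − 1); variance per Nei (1987,
  eq. 8.12). The 2-sequence/2-haplotype case gives exactly 1.000 ± 0.500.
* Nucleotide diversity per site: mean pairwise difference count over
  C(n,2) pairs divided by the mean compared length; variance per Nei
  (1987, eq. 10.7).
* Dxy: mean per-site differences over all cross-group pairs.

Missing data is excluded pairwise (pairwise deletion), matching the
behaviour of the standard desktop tools for this data type; haplotype
collapsing merges sequences identical at all mutually readable sites
(greedy in input order — pairwise-deletion identity is not transitive).
By default diversity is computed on whatever alignment is supplied; the
analysis drivers exclude the tandem-repeat region by construction
(repeat-unit number varies between individuals, so the repeat region is
not alignable column-wise).

## Coalescent machinery and its time scale

All simulation-based p-values and the synthetic sequence generator share
one Kingman-coalescent engine with infinite-sites mutation. Time is in
*pairwise mutational units*: per-lineage mutation rate 1/2, pair
coalescence hazard 1/θ, so E[pairwise differences] = θ at equilibrium and
E[S] = a₁θ. The sudden-expansion demography switches the scaled size
from θ₁ (present) to θ₀ at time τ backward. The payoff of this scale is
that a τ fitted from a mismatch distribution is directly comparable to
the generator's τ. The engine is validated against an independent
simulator (msprime) on the distribution of segregating sites.

## Neutrality tests

* Tajima's D with the standard 1989 constants; D undefined (not 0) at
  S = 0. The p-value is an equal-tail two-sided simulation p: ≥ 10⁴
  constant-size replicates (configurable down for tests) at θ = S/a₁,
  p = min(1, 2·min(P(D_sim ≤ D), P(D_sim ≥ D))) with the +1 correction.
  The equal-tail form was chosen because the null distribution of D is
  skewed; the calibration test confirms ~5% rejection at nominal 5%.
* Fu's Fs: S′ = P(K ≥ k_obs) under the Ewens sampling formula at
  θ̂ = mean pairwise differences (Fu's estimator choice), with unsigned
  Stirling numbers of the first kind computed by the log-space
  recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| (float-exact to ~1e-12
  for n ≤ 200, verified symbolically to n = 12 and by Σₖ P(K=k) = 1).
  Fs = ln(S′/(1−S′)); undefined at k_obs = 1 or θ̂ = 0. p = P(Fs_sim ≤
  Fs_obs) with θ fixed at θ̂, each simulated sample evaluated at its own
  pairwise θ̂ — the convention of the simulation-based software this
  field uses.

## Mismatch distributions and the sudden-expansion model

The observed mismatch distribution is the histogram of pairwise
difference counts (pairwise deletion); its mean equals θ̂π identically,
which the tests assert on every input.

The model distribution derives from integrating the Poisson mutation
kernel over the pair-coalescence time under the two-phase demography:

    F_j = F̂_j(θ₁) · P(j+1, τ(1+θ₁)/θ₁)
        + e^{τ(1/θ₀ − 1/θ₁)} · F̂_j(θ₀) · Q(j+1, τ(1+θ₀)/θ₀)

with F̂_j(θ) = θʲ/(1+θ)ʲ⁺¹ and P/Q the regularized incomplete gamma
functions. Limits: τ=0 → F̂(θ₀) (the expansion has just happened; all
pairwise coalescences predate it) and θ₀=θ₁ → F̂(θ) for any τ. For
τ/θ₀ > 500 the ancestral term switches to its θ₀→0 Poisson limit to
avoid overflow. The derivation is held to the coalescent simulator —
total variation < 0.03 at (τ=4, θ₀=1, θ₁=100) — rather than trusted on
paper.

Fitting minimizes the sum of squared deviations over classes 0..j_max:
a coarse grid (τ ∈ [0, 2·mean], θ₀ ∈ [0, mean], θ₁ ∈ {10,100,1000}·mean)
followed by Powell refinement in a smooth square-root parameterization
(τ = x₀², θ₀ = x₁², θ₁ = θ₀ + x₂²) that enforces positivity and
θ₀ ≤ θ₁ without constraint walls. θ₁ is capped at 10⁵·mean because the
likelihood surface is flat in θ₁ once the wave has detached (an
unidentifiable ridge). The fit is deterministic given the input.

The SSD goodness-of-fit p is a parametric bootstrap: simulate n_boot
coalescent datasets of the same n under the fitted (τ, θ₀, θ₁), refit
each with the identical optimizer settings, and report the fraction with
SSD ≥ observed. n_boot < 100 is refused (unstable p); the default is
1000. Calibration (data simulated under an expansion model, tested
against their own fit) holds P(p < 0.05) within (1%, 10%).

## Spatial autocorrelation

Smouse–Peakall multivariate autocorrelation on the binary haploid
distance (d² = 0 same haplogroup, 1 different; the statistic is
invariant to haplogroup relabeling). The squared-distance matrix is
double-centered, and per distance class
r(h) = Σ c_ij / Σ ½(c_ii + c_jj) over the pairs of that class. Distance
classes are half-open 150-km bins (boundary pairs go up); members of a
flock share the flock's coordinates, so class 1 always contains the
within-flock pairs. Geographic distance is haversine for lat/lon and
Euclidean for planar synthetic maps — the choice of metric is a
configuration, not an inference.

The null belt is the 2.5/97.5 percentile band of r under ≥999
permutations of individuals over locations; per-class CIs bootstrap the
pairs within the class (≥1000 replicates); the per-class p is equal-tail
two-sided with the +1 correction, making it valid (if slightly
conservative), which the calibration test checks at α = 0.05 and 0.001.

## Trees and networks

TN93 distances use the closed form with empirical base frequencies
pooled over the input and no rate heterogeneity; a non-positive log
argument flags saturation as an infinite distance. The implementation is
checked to 1e-10 against distances computed independently with R/ape.
Neighbor-joining delegates agglomeration to scikit-bio with taxa sorted
lexicographically first (deterministic tie resolution) and negative
branch lengths clamped to zero. Bootstrap support resamples alignment
columns, rebuilds TN93+NJ, and counts recurrences of each original
bipartition (canonical split encoding anchored at the lexicographically
smallest taxon). Tree construction excludes the tandem-repeat region —
with variable unit counts it is not column-alignable.

Median-joining networks follow Bandelt–Forster–Röhl: minimum spanning
network (union of all MSTs, relaxed by ε; default ε = 0) under weighted
Hamming distance (uniform weight 10 per position, the NETWORK
program's convention, configurable per position); candidate quasi-medians
are generated from node triples sharing MSN links (majority state per
position; all-different positions branch, capped at 27 candidates per
triple) and added greedily — one per iteration, largest MST-weight
reduction, lexicographic tie-break — until no median shortens the MST;
finally, median vectors of degree < 3 in the MSN are pruned iteratively.
Termination is guaranteed because each accepted median strictly reduces
the MST weight over a finite candidate universe. Columns containing any
missing state are removed before construction (complete deletion) to
keep the distance a metric.

## Synthetic data: what it does and does not emulate

The panel generator emulates: the diagnostic-site structure of the five
haplogroup signatures, the 75/76-bp repeat-length dichotomy tied to the
two clusters, unit-count variation (3–5, mode 4, matching the observed
~92% four-unit frequency), haplogroup frequencies of a modern survey
panel (A:70, B:88, C:69, E:11 of 238 classifiable sequences), and
Poisson private substitutions kept off the diagnostic sites. The
reference it mutates is an explicitly synthetic stand-in with the real
coordinate layout (15391–16616, repeat at 15640) but pseudo-random
bases.

It does not emulate: ancient-DNA damage patterns (deamination,
fragmentation), recurrent mutation or indels (infinite sites),
recombination (absent in mtDNA anyway), selection, heteroplasmy, or a
realistic mutation-rate spectrum across the CR. Passing round-trip tests
therefore demonstrate classifier logic, not robustness to damage; the
`max_missing` / unassigned pathway is the package's answer to damaged
sites, and is tested directly.

The spatial generator places flocks uniformly on a plane and draws each
individual's haplogroup from a linear west-east frequency cline
(location-independent when the cline is off). It does not model breed
structure, isolation by distance within haplogroups, or sampling
imbalance.

## Problem sizes in the shipped tests and drivers

The test suite runs every stochastic check at sizes chosen to keep the
whole suite in the ~10-minute range while leaving the statistical
assertions well-powered: coalescent moment checks at 2000 replicates,
the mismatch-model/simulator comparison at 2000 replicates of n=10, τ
recovery at 100 fits of n=50, SSD calibration at 100 tests × 150
bootstraps of n=30, permutation calibration at 200 seeds × 199
permutations, and NJ recovery over 50 random 6–10-taxon trees. The
analysis drivers use survey-scale sizes (e.g. 30 flocks × 10
individuals; 999 permutations / 1000 bootstraps for report-grade
correlograms).

## Known limitations

* The five-site scheme cannot call HPG D or wild-X without user-supplied
  rules; such samples are reported unassigned by design.
* Ewens/Stirling machinery is float-log-space, not exact rational; at
  n ≲ 200 the error (~1e-12) is far below any decision threshold.
* The sudden-expansion SSD bootstrap refits with the same optimizer
  budget as the observed fit; a constant-size truth sits on the τ=0
  boundary of the model family, where the bootstrap p is conservative
  rather than exact.
* The MJ implementation generates medians only from triples with at
  least two MSN links (the standard heuristic); pathological inputs
  could in principle require medians from unlinked triples.
* `anchor_to_reference` seeds on an exact shared 20-mer; heavily
  diverged or heavily damaged sequences should be pre-aligned and
  supplied gap-aligned instead.
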