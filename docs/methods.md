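# Methods

This note documents the statistical models, estimators and numerical
conventions implemented in `msatpop`, the scope of the synthetic data
generator, and known limitations. It makes no empirical claims beyond
what the package computes.

## Data model

Genotypes are diploid multilocus microsatellite calls. Files carry
fragment sizes in bp; all genetics operates on repeat counts, converted
at the I/O boundary as `repeats = round((size − offset) / repeat_len)`
with round-half-away-from-zero, where `offset` is the non-repeat flanking
length and `repeat_len` the repeat-unit length of the locus. Conversions
more than 0.2 repeat units off the integer ladder are logged as possible
off-ladder alleles; negative repeat counts are errors. Missing data is an
empty cell or `NA` in files (never 0, which is a legal repeat difference)
and the sentinel −1 internally; a half-missing locus is treated as fully
missing. Allele pairs are stored in canonical order (A1 ≤ A2).

## Bruvo distance

Per allele pair, `d(x, y) = 1 − 2^(−|x − y|)` on repeat counts. For a
diploid locus the distance is the minimum over the two one-to-one
assignments of the alleles of one genotype to the other, of the mean
per-pair distance. The genotype distance is the unweighted mean over loci
non-missing in both genotypes; a pair with no shared typed locus is an
error (rather than a silent 0 or 1). Distances are therefore in [0, 1],
symmetric, and zero on the diagonal.

## Strain delineation

Isolate MLGs are collapsed into strains by agglomerative clustering of
the Bruvo distance matrix — farthest-point (complete) linkage by default,
with nearest and average available — cut at a distance threshold with a
strict `<` comparison: two isolates join a strain only through merge
heights strictly below the threshold. Consequences used as boundary
semantics: threshold 0 collapses only identical MLGs (one strain per
unique genotype) and threshold 1 collapses everything into one strain.
The default analysis threshold is 0.3.

`suggest_threshold` sorts the critical merge heights and proposes the
midpoint of the largest gap, additionally reporting a histogram-based
bimodality flag on the pairwise distances; it errors when all heights are
equal ("no gap"). Each strain's representative is the member minimizing
the summed distance to the other members (ties broken by first
appearance). Matching against reference strain MLGs assigns the nearest
reference strictly below the threshold; unmatched strains are named
serially per vintage; ties between references are resolved
lexicographically and logged.

Sampling effort is equalized by rarefaction: each (vineyard, barrel,
stage) sample is subsampled without replacement to a fixed isolate count
(default 32) with a seeded generator; undersized samples are a named
error, not a silent pass-through. Rarefaction is a single draw, not an
average over draws.

## Diversity, ordination and permutation tests

Strain counts per sample feed Simpson's index of diversity `1 − Σp²` and
Shannon's `H = −Σ p ln p` (natural log). Sample dissimilarity is
Bray–Curtis `Σ|x−y| / Σ(x+y)` on untransformed counts. PCoA is the
classical Gower construction (double-centering of −½D², symmetric
eigendecomposition); negative eigenvalues are reported and retained as
imaginary axes with no Cailliez/Lingoes correction.

PERMANOVA is the one-way design: `SST = (1/N) Σ_{i<j} d²_ij`,
`SSW = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij`, pseudo-F =
`(SSA/(a−1)) / (SSW/(N−a))`, with raw group labels permuted. PERMDISP
computes each sample's distance to its group centroid in the PCoA
embedding — squared imaginary components subtract from squared real ones,
clamped at zero — and applies one-way ANOVA F with residual permutation.
Both tests use `p = (1 + count) / (1 + n_perm)`, giving a p-value floor
of 0.001 at 999 permutations. The repeated-measures structure of barrels
sampled across stages is not modelled; significant results should be
inspected alongside the ordination.

## Allele-frequency statistics

Per locus: observed heterozygosity Ho, expected `He = 1 − Σp²`, unbiased
`uHe = (2N/(2N−1)) He`. Probability of identity per locus is
`Σp⁴ + Σ_{i<j} (2 p_i p_j)²`, multiplied across loci for the overall PI
(a random-mating construction, conservative under selfing). Fixation
indices per locus: `F_ST = (Ht − Hs) / Ht` with Ht from individuals
pooled across subpopulations and Hs the unweighted mean subpopulation He;
`F_IS = (Hs − mean Ho) / Hs`. Loci with Ht = 0 (F_ST) or Hs = 0 (F_IS)
are excluded and logged. Summaries are unweighted means ± SE
(sd/√L) across retained loci.

## Ancestry model

The admixture model with inbreeding: for K clusters, cluster allele
frequencies `p_kl ~ Dirichlet(λ=1)` per locus, memberships
`q_i ~ Dirichlet(α)`, and at each (individual, locus) the two allele
copies are identical by descent with probability `s` (one origin drawn
from `q_i`, one allele from that cluster, copied) or independent
otherwise. The scalar `s` captures the homozygote excess produced by
selfing; it deliberately simplifies samplers that model selfing
generations or per-cluster rates.

All latent variables (IBD indicators, origins) are Gibbs-sampled; Q and P
have conjugate Dirichlet updates; `s` has a conjugate
Beta(1 + n_IBD, 1 + n_obs − n_IBD) full conditional under its uniform
prior; `α` moves by Metropolis–Hastings on the log scale with a uniform
prior on (0, 10]. Model choice across K uses
`DIC = 2·D̄ − D(θ̄)` with deviance `D = −2 log L` recorded every kept
sweep and θ̄ the posterior mean of (Q, P, s); the DIC table flags
plateaus where an extra cluster improves the best DIC by less than 2.

Replicate chains are aligned with a greedy scheme: runs are added one at
a time in many random orders, each column-permuted (Hungarian assignment
on summed squared column distances) to best match the running set; the
order maximizing the mean pairwise similarity
`G(A,B) = 1 − ‖A−B‖_F / √(2N)` (H = mean pairwise G) is kept. A strain's
dominant inferred ancestor is the arg-max cluster when its coefficient is
≥ 0.75 (inclusive). How much predefined populations explain ancestry
profiles is quantified by `R² = 1 − SSW/SST` on Q rows with a
label-permutation p-value and leave-one-population-out contributions.

## Phylogeny

Neighbour-joining (exact on additive matrices) on Bruvo distances among
strain representatives; negative branch lengths are clamped to zero with
the total deficit recorded on the tree. Branch support resamples the
*loci* with replacement (default 1000 replicates), recomputing distances
and the tree; a node's support is the fraction of replicates containing
its bipartition (canonicalized for unrooted comparison). Newick export
labels internal nodes with supports ≥ 0.5 only.

## Synthetic generator

The generator's defaults describe the target study system and are the
conditions under which the estimators are characterized: 11 loci with
3–18 alleles each, K = 5 ancestral clusters, ~100 strains founded from
Dirichlet(0.2) admixture profiles with IBD probability 0.8, two
vineyards × 3 barrels × 3 stages with 47 isolates per sample, and ±1
repeat mutations at 0.005 per allele copy per locus. Four strains are
dominant (58% of abundance mass): two shared across vineyards and two
vineyard specialists (strong at home, rare away); minor strains decay
geometrically (ratio 0.98).

Founders are placed by rejection sampling at a minimum pairwise Bruvo
distance of 0.35, because strains are by construction distinct lineages
relative to the 0.3 delineation threshold; generation fails loudly if the
separation cannot be achieved. Under these defaults the realized
between-vineyard F_ST is on the order of 0.02–0.04 — weak,
compositional differentiation driven by the vineyard-specialist dominant
strains rather than deep divergence. The generator is an estimator
test-bed, not a fermentation model: strains are clonal within a vintage
(no recombination), abundances do not drift across stages, and there are
no null alleles or genotyping errors.

## Numerical conventions

* Seeded `numpy.random.default_rng` everywhere randomness appears;
  pipelines derive per-stage seeds from one base seed, so runs are
  byte-reproducible.
* Threshold comparisons in delineation are strict (`<`); the dominant
  ancestor cutoff and the dominant-strain abundance rule (≥ 10% relative
  abundance in ≥ 2 samples) are inclusive (`>=`).
* Ties are deterministic and logged: strain representatives by lowest
  index, reference matches lexicographically.
* Permutation p-values use the (1 + count)/(1 + n_perm) convention.
* The pipeline degrades gracefully when strain representatives all come
  from one vineyard: strain-level F-statistics and the ancestry-vs-
  population R² are skipped with a warning rather than aborting.

## Desk-scale versus full-scale MCMC

Production analyses should use long chains (hundreds of thousands of
sweeps, several chains per K) and inspect the alignment similarity H.
The test suite and the acceptance script use desk-scale sweep counts
(hundreds of sweeps), which are sufficient for strongly separated
clusters but have a known artefact on weakly separated ones: labels
switch *within* a chain, flattening the posterior-mean Q toward uniform.
Dominant-ancestor fractions computed from such runs are therefore
conservative (biased toward "no dominant ancestor"); DIC-based K
selection degrades more gracefully but can also prefer smaller K than
the generating value when clusters overlap.

## Limitations

* One-way PERMANOVA/PERMDISP only; no repeated-measures or nested
  designs.
* A single scalar inbreeding rate `s` shared across individuals and
  clusters; no explicit selfing-generation model.
* PI and He assume random mating within the frequency pool; under strong
  selfing PI understates MLG sharing probability among close relatives.
* No modelling of null alleles, allelic dropout or scoring error.
* Rarefaction is one random draw, not an expectation over draws.
* The NJ tree is a distance summary; with clonal, partially selfing
  lineages it should be read as a relatedness dendrogram, not a species
  phylogeny.
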