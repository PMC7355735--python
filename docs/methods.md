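# Methods

This note documents the models, conventions and design choices behind
`assemblage`, in the spirit of a statistical-software methods appendix.

## Process partitioning (the core)

**βMNTD.** For communities *A*, *B* with relative abundances *f* and a
cophenetic (patristic) distance matrix *d*,
βMNTD = ½[Σᵢ∈A fᵢ minⱼ∈B d(i,j) + Σⱼ∈B fⱼ minᵢ∈A d(i,j)].
Abundance weighting is the default; the presence/absence variant is the
pooled mean of all nearest-taxon minima over both directions (so it
matches the convention of the standard R implementation, against which
the package was cross-checked during development). Identical
communities score 0 by construction.

**βNTI.** The null distribution re-computes βMNTD after each of
`n_null` (default 999) independent permutations of taxon labels across
**all tips of the supplied tree**, not merely the taxa present in the
analysed table. This matters: when an entire table is environmentally
filtered, its occupied taxa are already a biased subset of the tree,
and shuffling only within that subset erases the clustering signal the
statistic exists to detect. Within one analysis run the same shuffles
are reused for every pair, which matches a one-tree-per-dataset
randomisation and makes large runs affordable. A pair whose null has
zero spread (e.g. both communities occupy exactly the same taxa, so
every shuffle leaves βMNTD unchanged) raises a degenerate-null error
from `bnti()`; inside `assembly_analysis()` such pairs are assigned
βNTI = 0 and fall through to the taxonomic null, since an observation
equal to every null draw deviates from the null in no direction.

**RC_bray.** Each null replicate assembles a random counterpart per
observed community preserving its richness *r* and total abundance
*N*: *r* taxon identities are drawn without replacement with
probability ∝ regional occupancy (implemented by Gumbel-top-k keys,
equivalent to successive weighted sampling and verified against
numpy's sequential sampler), one individual seeds each chosen taxon,
and the remaining *N − r* individuals follow a multinomial on regional
mean relative abundance restricted to the chosen taxa. With obs the
observed Bray-Curtis and the null sample {b₁…b₉₉₉},
RC = 2·[(#b < obs) + ½(#b = obs)]/n_null − 1, ties counted at half
weight (numeric ties at 1e−12). The regional pool defaults to all
samples of the analysed group (per nucleic-acid fraction): occupancy =
number of samples with a positive count, abundance weight = mean
relative abundance.

**Classification.** βNTI > 2 → variable selection; βNTI < −2 →
homogeneous selection; otherwise RC > 0.95 → dispersal limitation,
RC < −0.95 → homogenizing dispersal, else undominated. All
inequalities are strict; values exactly on a boundary fall to the
weaker (stochastic/undominated) claim, resolving a measure-zero
ambiguity conservatively.

**Pair scopes.** `all` (every pair within a fraction),
`within_stage_temporal` (same stage, different months — temporal
turnover), `within_timepoint_spatial` (same month, different stages).
Process summaries report the fraction of pairs per process and group;
fractions sum to 1 exactly.

## Surrounding statistics

*Rarefaction* draws without replacement (multivariate hypergeometric),
so subsampled counts never exceed the originals and sums hit the depth
exactly; samples below depth are dropped and reported rather than
erroring, since a mixed-depth table is the common real case. *Shannon*
uses natural logs so Pielou = H/ln(richness); single-taxon and empty
samples yield NaN with a warning instead of a silent zero. *UniFrac*
(scikit-bio) defaults to the unnormalized weighted variant. *PCoA*
reports negative eigenvalues unchanged (no Cailliez/Lingoes
correction) and computes explained proportions over positive
eigenvalues only.

*PERMANOVA* is the McArdle–Anderson trace form with sequential (Type I)
sums of squares: for Gower-centred **G** and nested hat matrices
H₀ ⊂ H₁ ⊂ …, SS(term k) = tr[(Hₖ−Hₖ₋₁)G]. Factor lists expand to the
full factorial (A, B, C, A:B, …, A:B:C); projections use SVD so
aliased designs are handled; df come from rank increments, and a term
adding no rank raises. p-values use free permutation of sample
identities, one scheme for all terms, with a 1e−8 relative tolerance
when comparing permuted to observed F so exact ties (mirror
relabelings) are counted. Verified against vegan::adonis2 during
development on a frozen fixture (the expected values live in the test
suite).

*Wilcoxon signed-rank* returns the signed statistic T⁺ − T⁻ and a
two-sided p: exact by sign-flip convolution for n ≤ 25 (midranks make
tie handling exact too), normal approximation beyond. For the DNA/RNA
turnover comparison, values are paired by identical
(stage, month-pair, replicate-pair) keys — the only bijection the
paired design affords.

*Mantel correlogram.* Distance classes partition (0, max patristic
distance] into equal-width bins, Sturges' rule on the pair count when
unspecified. The class statistic is the Pearson correlation between
niche distances and the 0/1 class indicator, sign-inverted so positive
values mean within-class similarity (checked value-for-value against
vegan::mantel.correlog on shared break points). Significance comes
from joint row/column permutations of the niche matrix with a
**two-tailed** count; the direction-of-the-sign one-tailed convention
was measured here to double the type-I rate (0.11 at nominal 0.05 on
permuted traits), so the calibrated two-tailed test is used and
"signal" is read as positive r with small p. Progressive correction
applies a Holm adjustment within the first k classes for class k.
Niche optima are abundance-weighted means of the environment over the
samples where a taxon occurs; taxa with occurrence ≤ 5 are excluded by
default.

## The simulator

**What it emulates.** A 100-year salt-marsh-style soil chronosequence:
5 successional stages along a monotone environmental gradient, sampled
in up to 4 months with 3 replicate plots, each sample profiled as both
a DNA and an RNA fraction. The latent gradient maps to four observed
soil variables (pH and sodium decreasing, organic carbon and water
content increasing) with small independent measurement noise.

**Mechanisms.**
- *Phylogeny*: Yule (pure-birth) tree, rescaled to height 1.
- *Niche trait*: Brownian motion, rate σ² = 4 (tip SD 2), giving the
  short-range phylogenetic signal βNTI requires.
- *Regional pool*: lognormal abundances (σ = 1).
- *Dispersal lottery*: each site draws an accessible colonist pool —
  every pool taxon independently available with probability 0.3 — so
  local communities are sparse on the tree and only partially shared.
  Without it, communities share nearly all taxa and both null models
  lose their contrast.
- *Local assembly*: taxon weight ∝ [m·pool + (1−m)·local] ×
  exp(−(trait − env)²/(2σ_sel²)), multinomially sampled to the
  community size (default 2000). m = 0.5 balances mass effects against
  last month's community; σ_sel = 0.5. σ_sel = ∞ disables selection
  and a value below 1e−8 applies the deterministic nearest-trait
  limit.
- *Monthly environment*: stage baseline (linspace −2…2) plus a shared
  monthly fluctuation (SD 1.0, comparable to one stage step) — large
  enough that within-stage variable selection genuinely occurs in the
  active fraction.
- *Relic pool and the DNA fraction*: per site, an exponentially
  decaying running mixture of past RNA compositions (decay 0.5 per
  month), **seeded with the site's pre-study filtered community** —
  relic DNA is the residue of past selected assemblages, not of the
  raw regional pool. DNA sample = multinomial resample of
  (1−φ)·current RNA + φ·relic, φ = 0.5 by default. With φ = 0 and no
  month noise the fractions are exchangeable up to resampling noise
  (the negative control).

**Single-process regimes** (for parameter-recovery tests):
- *variable_selection*: per-community optima spread across the
  1st–99th trait percentiles, narrow kernel.
- *homogeneous_selection*: one shared optimum at the 90th trait
  percentile. The tail location is deliberate: under Brownian motion
  the trait mode coincides with the root value, where every clade has
  density, so a central optimum selects a phylogenetically dispersed
  set with no clustering signal; a stringent real-world filter is
  likewise extreme relative to the ancestral state.
- *dispersal_limitation*: no selection; availability lottery plus a
  gamma abundance lottery (shape 0.3) make colonisation idiosyncratic.
- *homogenizing_dispersal*: every community resampled from one shared
  state that drift has moved away from the pool average (plus a 10%
  pool trickle so taxon sets are not exactly identical).
- *drift*: independent multinomial sampling from the pool. A known
  property of occupancy-informed Raup-Crick nulls is that pure blind
  sampling drift registers as *more* dissimilar than the null (the
  null's occupancy-weighted identity draw is better informed than
  blind sampling), so this regime tends to the dispersal-limitation
  side rather than "undominated"; it is provided as a mechanism, and
  no recovery claim is attached to it.

**What the simulator does not model** — and hence what passing tests do
not establish about real data: sequence-level error, PCR and 16S
copy-number effects, taxon interactions, multivariate niches (one
dominant gradient only), immigration from outside the pool, and
realistic pool sizes (thousands of taxa rather than tens of
thousands). Recovery rates measured here are for the simulator's
conditions, not guarantees for field data.

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen to keep the full suite in
minutes: regime recovery uses 8 communities and a 2000-taxon pool
(4000 for variable selection, whose adjacent-optima pairs need denser
trait bands — βNTI magnitude grows roughly with the square root of
per-sample richness; 1000 for dispersal limitation, whose signal is
size-robust), 99 null replicates per pair, 10 seeds per claim; the
DNA/RNA contrast uses the 5-stage design with 3 months × 3 replicates
at the same null count. The acceptance script runs that design once at
199 nulls and 999 PERMANOVA permutations. Default analysis parameters
remain 999 nulls / 9999 permutations. βMNTD null computation is
vectorised over shuffles with adaptive chunking (≈25M-element
gathers); one βNTI+RC pass over the 270 temporal pairs of the default
design takes on the order of a minute.

Cross-implementation checks (R picante::comdistnt, vegan::adonis2,
vegan::mantel.correlog) were computed once on small fixtures during
development; the expected values are frozen verbatim in the test
suite, so the tests rerun without R.

## Known limitations

- The RC null's identity stage uses occupancy from the analysed group
  itself; for very small groups (few samples) occupancy is coarse and
  RC resolution is limited by `n_null`.
- Sequential PERMANOVA R² depends on factor order, as in any Type-I
  decomposition; the pipeline fixes the order dataset → stage → month.
- The correlogram tests classes independently up to the progressive
  correction; no spatial-autocorrelation-aware variance adjustment is
  attempted.
- `assembly_analysis` holds one cophenetic matrix (n_tips²) in memory;
  ~20k tips ≈ 3 GB would need a chunked implementation.
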