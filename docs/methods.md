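# Methods

This note documents the models, the defaults and the numerical choices
behind `coevostab`, and what the synthetic-data tests do and do not
establish.

## Multi-hit gene detection

### Filtering and collapsing

Variant calls enter as one row per (population, position, alternate
allele) with a functional class and an allele frequency. Three rules are
applied before any statistics:

1. **Frequency floor**, per species (defaults LP 0.05, SC 0.30,
   inclusive). The floors reflect minimum read support at each species'
   typical sequencing depth — 5% of ~200× and 30% of ~50× are both on the
   order of ten reads (`min_read_support`). They are parameters, not
   constants.
2. **Intergenic calls are dropped.** The null model is defined over the
   protein-coding gene catalog only.
3. **Collapsing.** An identical mutation observed in several populations
   is almost certainly standing genetic variation present at the start of
   the experiment rather than repeated de novo mutation, so it is counted
   once, in the first population (lexicographic by population id unless
   an explicit order is given). Within one population, any number of
   distinct mutations in the same gene count as a single "hit" — the unit
   of evidence is "this population hit this gene", not the mutation
   count. The number of records surviving rule 3's first step is M, the
   draw count fed to the null.

By default the parallelism analyses use amino-acid-changing classes
(nonsynonymous, nonsense, in-ORF indels); synonymous inclusion is a
caller-level choice (`filter_mutations(classes=...)`).

### The length-weighted null

Under neutrality, mutations land in genes roughly in proportion to their
mutational target size. The null model therefore draws M gene indices
with replacement, gene i with probability ℓᵢ/Σℓ, and repeats this 10,000
times (`numpy.random.Generator.choice`; replicates aggregated by sorted
sparse counting, which is distribution-identical to tallying the draws
directly and keeps hundreds of null simulations cheap). Per gene the
result retains the maximum count over replicates and the full tail counts
(#replicates with ≥ k draws).

Two deliberate asymmetries with the observed side are documented rather
than "fixed": the null has no population structure (draws are not
collapsed per population) and no standing-variation rule. Both make the
null's per-gene counts stochastically *larger* than collapsed
observations, i.e. the test errs conservative.

**Significance rule.** A gene is a significant multi-hit gene iff it is
hit in ≥ 2 populations *and* its observed hit count strictly exceeds that
gene's maximum over all 10,000 null replicates. Ties are not significant.
This is a family-wise-style criterion: in calibration runs with no
planted signal (200 experiments, 3006 genes, ~30 mutations per population
× 10 populations), fewer than 5% of experiments produce even one
significant call. Empirical tail p-values use the +1 pseudo-count
estimator, (1 + r)/(1 + n_reps), so they are never zero; both the
max-rule decision and the p-value are reported because the two do not
collapse into each other.

**Detection floor.** The max rule's conservatism has a price that users
should know: a gene must beat the ~99.99th percentile of its own null. A
modest enrichment (say 5×) over a typical per-gene null expectation can
essentially never satisfy this — either the gene is short (null max 2–3,
but 5× of a tiny rate still almost never reaches 4 populations) or long
(reaching 4+ populations is possible, but the null max is then itself
5–7). Strong, sweep-like signals (tens-fold enrichment, or one gene hit
in most populations) are what this rule detects. The test suite encodes
this honestly: a 5×-enrichment recovery test fails at its stated 90%
target, by design of the rule, not by defect of the implementation.

### Hit-count / gene-size histogram

Observed genes are grouped by hit count; each class reports its gene
count and mean length. The matched null histogram applies the same
grouping to the per-gene maxima over replicates. Under neutrality the
high-hit classes are few and long; an excess of genes — especially short
ones — at high hit counts indicates genome-wide selection.

## Coexistence analysis

All quantities are empirical (density-based), not model fits:
m = ln(Nf/Ni); S_LP = m_LP − m_Y (antisymmetric by construction); fitness
difference = log₁₀(K_LP/K_Y); niche overlap = ΔS_LP/ΔP_LP between the
LP-common and LP-rare treatments; strength = the smaller of the two
invasion-from-rare selection coefficients, taking each species from the
treatment where *it* is rare (LP from R, Y from C) — the literal
per-treatment reading "min(S_LP_R, S_Y_R)" would grade the yeast's
invasion while it is common, which contradicts mutual invasibility.

Choices that were genuinely open:

- **Ancestral normalisation is subtraction** (ancestral pairing ↦ 0), so
  "more negative than the ancestor" reads directly as a niche-overlap
  decrease.
- **Regressions use |fitness difference|**: the direction of the K ratio
  is an arbitrary labelling, and theory predicts the magnitude erodes
  coexistence. The signed value is stored for every pairing.
- **Extinction** (Nf = 0) gives m = −∞ and an `extinct` flag. Selection
  coefficients propagate the infinity (strength −∞ ⇒ no coexistence);
  niche overlap is undefined (NaN); `fit_predictors` excludes flagged
  pairings with a logged warning rather than imputing a pseudo-count.
- **Initial frequencies are recomputed** from inoculum densities
  (P_LP = Ni_LP/(Ni_LP+Ni_Y)) instead of stored separately, so the
  P-vs-Ni consistency invariant holds by construction. Treatment labels
  are validated (C needs P_LP > 0.5, R needs P_LP < 0.5).
- Carrying capacities may be OD or CFU; only the ratio is used, and a
  pairing must use one unit system.

## The synthetic community

### Model

Two species, three substitutable resources, Monod kinetics:

dN_s/dt = N_s Σ_r μ_{s,r} R_r/(K_{s,r}+R_r)
dR_r/dt = −Σ_s N_s μ_{s,r} R_r/((K_{s,r}+R_r) Y_{s,r}) + σ N_SC for r = lp_private

Resources: shared `glucose`, an LP-only pool (`lp_private`, replenished by
SC secretion at rate σ — the commensal (+, 0) link), and an SC-only pool.
This is the minimal structure that can express all four behaviours the
package needs: distinct niches, one-way facilitation, ecological release
(a parameter edit moving LP onto glucose), and fitness-driven exclusion.
There is no evolution inside the simulator; scenarios are parameter
edits.

### Scenarios and calibration

Parameters are explicitly non-biological; they are calibrated only to
qualitative orderings:

- **stable**: LP nearly off glucose (μ = 0.04/h) and strong on its
  private pool (0.50/h); SC on glucose (0.45/h) and its own pool
  (0.35/h); σ = 8×10⁻¹² chosen so the co-culture equilibrium LP frequency
  is ≈ 0.5 (measured 0.49), matching the experimental community's
  equilibrium near one half. LP monoculture saturates far below its
  co-culture density (facilitation), SC is indifferent to LP.
- **released**: μ_LP,glucose = 0.40/h, μ_LP,private = 0.01/h. Alone this
  type reaches ~10× the stable type's density (it can exhaust glucose);
  in co-culture it loses the glucose race against SC, has no refuge, and
  declines to extinction — invasion assays give strength < 0.

Serial transfer: 32-fold dilution every 48 h (five doublings to regrow);
extinction threshold 250 cells/mL ≈ one cell per 4 µL transferred volume,
applied deterministically at transfers; an optional Poisson bottleneck
(pass an `rng`) adds demographic noise. Invasion assays mix saturated
monoculture stocks to initial LP frequencies 0.9/0.1 and run 1 transfer
by default (48 h of growth, like the plate assay); the acceptance sweep
uses 2.

### Numerics

LSODA via `scipy.integrate.solve_ivp`, rtol 1e-8, atol 1e-3 cells/mL for
densities and 1e-14 for resources; states are clamped at zero inside the
RHS and on output (integrator undershoot only). Dilution is exact
floating division by D, so the dilution-exactness invariant is bit-level.
Fixed seeds give bit-identical trajectories and null-model results; the
null's batch size is part of the reproducibility contract (fixed at
2000).

### Mutation-table generator

Per population, a rounded-normal(30, 8, clipped ≥ 0) number of mutations
— "a few dozen", the scale of ~1000-generation bacterial E&R experiments;
classes from a fixed mix (55% nonsynonymous / 20% synonymous / 5%
nonsense / 10% indel / 10% intergenic); coding mutations choose genes
length-weighted with optional per-gene enrichment multipliers (planted
selection); positions uniform within the gene on a concatenated
coordinate system; frequencies from a near-fixed ∪ low-frequency mixture
(U[0.9, 1] with weight 0.3, else U[0.05, 0.3]). `shared_mutations`
injects identical variants into every population to exercise the
standing-variation collapsing rule. The default catalog is 3006 genes
with log-normal lengths (median 900 bp, σ = 0.45, floor 90 bp).

What the generator does *not* emulate: linkage and clonal interference,
mutation-rate heterogeneity along the genome, frequency trajectories over
time, sequencing error, or copy-number changes. A green test against this
generator establishes that the statistics behave correctly for
independent, length-weighted mutation placement — not that real data meet
those assumptions.

## Known limitations

- The GenomeDiff reader supports SNP/INS/DEL mutation lines with
  `frequency=`, `gene_name=`, `snp_type=` attributes only; evidence lines
  and the rest of the GD vocabulary are ignored by design.
- The max-rule detection floor (above): weak polygenic enrichment is
  invisible by construction; use the reported per-gene tail p-values for
  exploratory ranking.
- Simulator parameters are qualitative stand-ins; absolute densities and
  rates carry no biological meaning, only their orderings do.
- Invasion-derived quantities are two-point (initial/final) statistics;
  transient dynamics within a batch are not used.
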