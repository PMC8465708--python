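# Methods

## Gene model and neighborhood distance

Genes are 1-based inclusive intervals (GFF3 convention) ordered per contig
by start coordinate, ties broken by end then gene id; the rank of a gene in
this order is its *ordinal*.  Distance between genes is counted in
intervening genes (ordinal difference minus one), never in base pairs, and
strand is ignored throughout — the neighborhood criterion is purely
positional.  "Fewer than three genes away" is implemented as
`max_intervening = 2` and exposed as a parameter.

## Role calling

Each profile confers one role; a hit passes when its full-sequence e-value
is at or below the role's cutoff (cutoffs are inclusive).  Defaults: 1e-100
for the custom PLP-decarboxylase profile, 1e-40 for PF02329 (pyruvoyl
*hdcA*), PTHR42770 (antiporter) and the accessory profiles (*hdcB*,
*hisRS*, *adiA*, *aaxB*).  Among passing hits the smallest e-value wins;
exact ties break on profile id so results are deterministic.  The
full-sequence e-value is used rather than the per-domain one because it is
hmmscan's headline statistic.  Antiporter subtype (gadC/aaxC/adiC) is
carried as configuration on the winning profile rather than inferred, since
subtype assignment is not algorithmically specified anywhere; users mapping
their own profile databases attach subtypes in `profile_role_map`.
Proteins with no passing hit are silently role-less.  In place of manual
curation of borderline matches, `near_threshold_report` lists failing hits
within 10× of their cutoff for human review.

## Cluster detection

Detection seeds on every (hdcA, antiporter) pair at most `max_intervening`
genes apart, greedily extends with any role-bearing gene within that
distance of a member, and merges overlapping seeds.  The fixed point of
this procedure has a clean closed form, which is what the code computes:
chain the role-bearing genes of a contig (consecutive role genes at most
`max_intervening` apart belong to one chain) and keep every chain that
contains a qualifying decarboxylase–antiporter pair.  A chain containing
both roles only farther apart (e.g. hdcA … hisRS … antiporter with the
ends out of range) is not a cluster.  The test suite verifies exact
equivalence with brute-force subset enumeration (all subsets satisfying the
chain and seed-pair conditions, maximality included) on hundreds of random
contigs.

Pathway is PYR, PLP or BOTH from the decarboxylase roles present in one
locus; a genome with two separate loci (one PYR, one PLP) yields two
clusters, not one BOTH cluster.  `duplicated_antiporter` requires two
antiporters with a decarboxylase between them; `three_component` requires
an arginine decarboxylase (adiA or aaxB) in the locus.

## Species prevalence

A genome counts once toward `n_with_cluster` regardless of cluster
multiplicity.  "More than 50% of strains" is strict: prevalence exactly 0.5
is strain-specific, not histamine-secreting.  Pathways present are the
union over the species' clusters.

## Enrichment statistics

Filtering order matters and is fixed: samples below one million total
counts are removed first, then a taxon is retained iff its relative
abundance reaches 1e-4 in at least 10% of the remaining samples (the
retained-if-common reading of the rare-taxon rule; both thresholds
inclusive).

Per-method enrichment criteria use strict inequalities (effect strictly
above, q strictly below).  The built-in differential-abundance routine —
plumbing so synthetic end-to-end runs need no external fits — uses a
two-sided rank-sum test on relative abundances with Benjamini–Hochberg
correction and effect log2((mean_rel_disease + ε)/(mean_rel_control + ε)),
ε = 1e-6; its thresholds equal the DESeq2-like ones (log2 effect > 1,
q < 0.05).  It is not a substitute for DESeq2/MaAsLin2/LEfSe on real data,
whose result tables the package consumes directly.

The two-proportion Z-test shrinks the difference of proportions by
c = (1/n₁ + 1/n₂)/2, clamped at zero so the correction never flips the
sign, and divides by the pooled standard error.  A degenerate pooled
proportion (0 or 1) is defined as z = 0, p = 0.5.  This z is algebraically
identical to the signed square root of the Yates-corrected chi-square for
the 2×2 table, which the tests exploit as an independent oracle.

The comparison groups follow the stated design literally: HSB versus *all*
species, with HSB a subset of the reference group.  Because the two
proportions then share members, the pooled-variance estimate overstates the
variance of their difference and the test is conservative under the null —
a property, not a bug, that the suite verifies directly (rejection rate
well below nominal when effects are planted at equal rates in HSB and
non-HSB species).  A disjoint HSB-versus-non-HSB variant is available via
`overlap=False` for sensitivity analysis; since it matches the independent-
binomial sampling model the statistic assumes, it is also the comparison on
which the test's null calibration is measured (rejection ≈ 4% at α = 0.05
— slightly under nominal, as expected for a continuity-corrected test;
measured 0.042 over 1000 simulated null cohorts of 500 species, 100 HSB,
each species affected independently with probability 0.25 in both groups).

## Operon abundance

CPM = reads on operon / total mapped × 10⁶, after dropping samples under
one million mapped reads.  The one-sided rank-sum test (disease > control)
uses midranks, tie-corrected variance and a 0.5 continuity correction; for
n₁ + n₂ ≤ 12 without ties it switches to exact enumeration of rank
assignments.  Reference-genome construction and read alignment are outside
the package; it consumes pre-tabulated per-sample counts.  When preparing
real inputs, the reference set should use each species' representative
genome, swapped for an operon-bearing conspecific genome when the
representative lacks the operon.

## Synthetic data design

Genome simulation plants, per species, exactly round(n_strains ×
prevalence) operons (strains chosen by seeded permutation) at a random
locus among 30 decoy genes per contig, with 0–2 decoy genes between
adjacent members; gap patterns that would push every
decarboxylase–antiporter pair beyond the detection distance are shrunk, so
planted clusters are detectable by construction.  Member e-values are drawn
log-uniformly in [cutoff × 1e-20, cutoff], exercising the inclusive
boundary; decoy hits fail their cutoffs, a configurable fraction landing
within 10× of them.  Identifiers follow `species_sN_gK`.  What this does
*not* emulate: sequence homology (hits are planted), fragmented assemblies,
annotation errors, or profile cross-reactivity — so perfect recovery on
synthetic data demonstrates the neighborhood logic, not the discriminative
power of the underlying HMM profiles on real proteomes.

Abundance simulation: species baseline compositions log-normal (σ = 1),
library sizes log-normal around 3M reads (σ = 0.25), counts gamma-Poisson
with dispersion 0.3 — overdispersion typical of shotgun profiles.  Disease
samples multiply affected species' means by the planted fold change
(default 8) without renormalising columns; the analysis side works on
relative abundances, so the compositional compression of effects is present
exactly as it would be in real profiles (with 25% of species affected
8-fold, the realised relative-abundance effect is ≈ 1.5 log2 units).
Default cohort sizes are 30 + 30 samples, 200 species of which 40 HSB,
with 50% of HSB and 5% of other species affected — the planted-effect
regime for the power study (power ≈ 1 over 200 replicate cohorts).
Affected species are an exact-count subset by default; `random_affected`
switches to independent Bernoulli assignment, which is the right sampling
model for calibration studies (with exact counts the only per-replicate
variability is detection noise, which deflates the Z-test's rejection rate
to ~0 and makes "calibration" meaningless).

Operon read counts are binomial per sample with success probability
`length_weight` × (relative abundance mass of operon-bearing species);
`length_weight` defaults to 8e-4, roughly a 2.5 kb operon over a 3 Mb
genome.

## Problem sizes and numerics

The shipped studies use: 500 random contigs (≤ 12 genes) for the
brute-force equivalence check; a 10,000-point random grid (n ≤ 100) for
the Z-test oracle, at 1e-10 agreement in z; 1000 replicate cohorts for
null calibration and 200 for power; 200 seeds for the detection
Monte-Carlo.  These sizes make every oracle check exhaustive or
high-resolution while the whole suite stays fast.  Floating-point
comparisons on derived statistics use absolute tolerances stated per test;
exact integer expectations (counts, boundaries) are asserted exactly.

## Known limitations

* Architecture classification reports role order only; it does not model
  operon transcription units or promoter structure.
* The HSB-vs-all Z-test inherits the conservativeness of overlapping
  groups; effect sizes large enough to matter biologically remain
  detectable (see power study), but marginal associations may be missed.
* The built-in differential-abundance routine ignores covariates and
  library-specific normalisation subtleties (TMM, poscounts); supply real
  DESeq2/MaAsLin2/LEfSe tables for production analyses.
* Species labels, not strain phylogenies, define prevalence; clade
  structure within species is not modelled.
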