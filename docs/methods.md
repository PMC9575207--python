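# Methods

This note documents the models, estimators and numerical choices behind
`parevo`, and what the synthetic-data generator does and does not emulate.

## Substitution counting

Substitutions are counted by direct parent/child comparison on alignments
that include reconstructed ancestral node sequences. Each difference is
collapsed by strand symmetry (a purine-ancestral change is mapped to its
reverse complement) into one of seven classes: C>A, C>G, C>T (non-CpG),
CpG>TpG, T>A, T>C, T>G. CpG context is read from the *parent* sequence only,
so a single substitution can never change its own classification; a C>T
whose required 3' ancestral neighbour is undefined (block edge,
non-contiguous coordinate after filtering, gap or N) is unscorable and
enters no class, and such columns are excluded from the CpG opportunity
count. Columns with a gap or N in any node are dropped globally before
counting so every branch is scored on the identical column set.

The counting estimator observes at most one substitution per branch-column
and is therefore biased slightly downward relative to probabilistic
(expected-count) estimators at divergences of 0.01–0.03; published
divergence values produced by such estimators are treated as consistency
anchors rather than bit-exact targets. Per-year rates divide the per-site
divergence by a branch duration in years; those durations are external
inputs.

Neutral-site filtering removes columns intersecting any exclusion feature
(coding, CpG island, repeat, conserved), given as 0-based half-open BED
intervals on the alignment's reference coordinates, plus the global gap/N
rule. The filter is idempotent.

## Equilibrium GC content

With r_WS the AT→GC count per ancestral A/T site and r_SW the GC→AT count
per ancestral G/C site (CpG>TpG included among GC→AT), the equilibrium GC
content is GC\* = r_WS / (r_WS + r_SW); the deviation GC\* − GC measures
distance from compositional equilibrium, and the AT→GC/GC→AT count ratio is
1 in expectation at equilibrium. Uncertainty comes from a site bootstrap
(alignment columns resampled with replacement; resampled columns read CpG
context from their sampled neighbours, the standard site-bootstrap
approximation — no block structure is assumed because none is specified for
these data). The regression of deviation on per-year rate, ts:tv and
chromosome length uses OLS with chromosome length in Mb. Partial Spearman
correlations rank-transform all variables (average ranks on ties),
residualise the two focal rank vectors on the control ranks, and use the
t approximation with n − 2 − k degrees of freedom.

## Diversity

A position is callable iff its depth d satisfies 1.5·n ≤ d ≤ 2·n·cov, with
n the number of haploid genomes and cov the mean per-haploid coverage; both
bounds are inclusive (the literal reading of the rule; the boundary
behaviour is unit-tested). Statistics live on the fixed grid
[10000k, 10000(k+1)) and are reported only where a window has strictly more
than 2,500 callable sites.

π sums 2p̂(1−p̂)·n/(n−1) over sites using the site-specific number of
non-missing chromosomes; S, θ_W = S/(a_n·callable) and Tajima's D (standard
1989 constants) use segregating sites with complete data only. Single-genome
heterozygosity is the count of heterozygous callable sites over callable
sites. The sex-differential scan builds a 2×2 allele-by-sex table per
segregating site, tests it with Fisher's exact test, and controls the FDR by
Benjamini–Hochberg (the discrete exact test makes the procedure
conservative, which the calibration tests account for).

## Recombination

ρ maps on the 10-kb grid are converted to cM/Mb by rescaling so the mean
over usable windows equals a target sex-averaged rate (default 9.01 cM/Mb);
the operation is scale-invariant in the input units and reproduces the
target mean exactly. Windows are labelled low (≤ 4.25 cM/Mb), medium
(≤ 11.29) or high (> 11.29) — the defaults are pooled terciles of the
study's nine maps, and `pooled_tercile_cuts` recomputes cuts for any map
set. Genus-mean maps average per window over the maps where the window is
usable. Correlations are Spearman with average ranks, over windows usable
in both maps.

## Population parameters

N_e = ρ/(4r) with r the region's sex-averaged genetic length in Morgans
(default 0.2285, i.e. 22.85 cM), rounded to the nearest individual for
reporting. μ per generation follows from π/ρ = μ/r; per-year rates divide
by generation time (defaults: 25 y chimpanzee/bonobo, 19 y gorilla, 26 y
orangutan). The crossover-mutagenesis fraction attributes to the single
obligate male crossover a window of w bp (default ±20 kb, 40 kb total)
mutating at an elevated local rate against a background rate; the excess is
divided by the total *including* the excess by default (~3.5% with the
default rates; the alternative denominator, giving ~3.6%, is exposed as an
option). All of these constants live in a versioned JSON data file
(`parevo/data/constants.json`), not in code.

## GC-biased gene conversion

The conversion strength B = 4N_e·b enters the stationary frequency density
of segregating GC-changing sites as φ(x;B) = (1 − e^{−B(1−x)}) /
((1 − e^{−B}) x(1−x)), with the analytic 1/x limit at B = 0 (used for
|B| < 1e-8 rather than an ε-perturbation; the expm1 form is stable across
the full bound |B| ≤ 50). Expected category intensities for GC counts
i = 1..n−1 combine the weak→strong polarity at +B and the strong→weak
polarity at −B, weighted by θ_WS and θ_SW. Integrals are evaluated by
Gauss–Legendre quadrature with max(80, n + 40) nodes; the binomial×φ
integrand is polynomial times a smooth exponential factor, and the
quadrature matches adaptive integration and a 10⁶-point Riemann sum to
better than 1e-6 relative error in tests. The node polynomial matrix is
precomputed per sample size, so a likelihood evaluation is two small
matrix-vector products.

Likelihood: independent Poisson counts per untrimmed category (equivalent
to multinomial up to the fitted total). The two most extreme categories are
always trimmed before fitting — they are the ones most distorted by
mis-polarisation and mutation-process artefacts. Optimisation is L-BFGS-B
over (B, log θ_WS, log θ_SW) restarted from B ∈ {−2, 0, 2}, B bounded to
[−50, 50]. Bootstrap uncertainty resamples the category counts
multinomially with the total held fixed (a site bootstrap, not genomic
blocks — the sites are modelled as exchangeable) and refits per replicate.

**Identifiability.** When θ_WS = θ_SW the expected spectrum is *exactly*
neutral-shaped for every B (the identity g(x;B) + g(1−x;−B) = 1 where g is
the fixation-bias factor), so B is unidentifiable under symmetric mutation.
Real mutation is AT-biased (θ_SW ≈ 2·θ_WS), which is the regime the
estimator operates in; the synthetic generator's defaults encode that bias,
and recovery tests use asymmetric intensities. No demographic nuisance
terms are fit; a distortion correction from GC-conservative sites is a
possible extension but is off by default.

Large samples (count scheme beyond 50 categories) switch to 50 equal-width
GC-frequency bins, half-open with the last bin closed at 1; expected bin
intensities aggregate the count-category intensities.

## Hominin phylogenetics

Diploid genotypes are haploidised by picking one allele uniformly at random
per heterozygous site (deterministic under a seed). Distances are raw
p-distances — at divergences near 0.002 a multiple-hit correction is far
below the sampling noise; Jukes–Cantor is available as an option. Neighbor
joining follows Saitou–Nei with the standard Q-criterion; ties are broken
deterministically by taxon-label order, and the implementation is
cross-checked against an independent library implementation on random
matrices. Bootstrap support resamples alignment columns, rebuilds the tree,
and counts replicates containing each internal bipartition of the
point-estimate tree (reported out of the replicate count). Rooting on the
outgroup is for display only.

## Synthetic data

The generator reproduces the *structure* of the study inputs so that every
stage runs without external downloads:

- **Alignment**: a root sequence drawn from the generator's stationary
  composition evolves down the fixed great-ape tree (H, C, G, O with
  ancestors HC, HCG, HCGO and macaque outgroup) by exact Gillespie
  simulation with thinning. Default branch lengths are the per-site PAR1
  divergences of each branch; default length 240,000 columns, the size of
  the study's filtered neutral alignment. The base process is HKY with
  κ = 4 and stationary GC 0.45 (ts:tv flux ≈ 2, matching pseudoautosomal
  telomeres), and the C→T/G→A rate of a CpG dinucleotide is multiplied by
  10, the canonical CpG hypermutability scale. Every substitution event is
  logged, giving an exact oracle for the counting estimator.
- **Polymorphism**: per mutation class, segregating-site counts are Poisson
  with intensity θ_class·L·(stationary sampling spectrum under ±B); default
  per-class θ sum to ~2.1e-3 (between the chimpanzee and orangutan
  estimates), with CpG transitions enriched and strong→weak intensity about
  twice weak→strong. Default B is 0.7 for non-CpG GC-changing classes and
  1.5 for CpG transitions (PAR-scale conversion strength, strongest at CpG
  sites). Derived alleles are placed on chromosomes at the drawn count and
  paired into Hardy–Weinberg genotypes; a reference string is constructed
  consistent with every site's annotated CpG context. Sites are independent
  — there is no linkage — which suffices for every estimator here except
  LD-based map inference, which the package consumes rather than infers.
- **Depth**: per-site Poisson(n_haploid × 15) by default (study-scale
  population coverage).
- **Recombination maps**: peak × exp(−position/decay) × lognormal noise,
  emulating the telomere-proximal rate concentration; two maps drawn from
  the shared profile correlate positively, as the real within-genus maps
  do.

What passing tests on these data do *not* show: robustness to alignment
error, ancestral-state misreconstruction, linked selection, demographic
non-equilibrium, or genotyping error — none of which the generator
produces. Results on real data depend on those upstream steps.

## Bundled reference tables

`parevo.datasets` ships the published per-branch divergence rates, the
per-population parameter table (ρ, π, θ, Tajima's D, B, generation times and
the published N_e/μ they imply), divergence by recombination bin, and the
analysis constants. The derivation functions recompute N_e and μ from these
inputs; three of the eight published N_e values differ by 1–2 individuals
when recomputed from the *printed* (rounded) ρ, so the full-table check
asserts relative agreement at 1e-4 while the two values quoted in running
text are asserted exactly.

## Problem sizes in the test suite

Simulation-based tests use 15–120 kb alignments, 0.25–2.7 Mb population
regions, and 20–100 bootstrap replicates — sizes chosen so each statistical
check has clear power while the whole suite stays interactive; the
estimators themselves are O(sites) or O(categories) and run unchanged on
full-scale data.
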