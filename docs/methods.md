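# Methods

This note documents the statistical models behind each module, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical choices a maintainer should know about.

## Genotype representation

Genotypes are stored as SNP-allele dosages (0 = reference homozygote,
1 = heterozygote, 2 = SNP homozygote; −9 missing). DArTseq two-state
scores use a different convention ("1" = SNP homozygote, "2" =
heterozygote) and are converted at the boundary by the swap 1↔2, which is
its own inverse. Every estimator below consumes dosages, so conversion
happens exactly once, at import.

STRUCTURE files are read in both common dialects (two rows per individual
with one allele per row, or one row with two adjacent columns per locus),
auto-detected from the column count. Per locus the numerically smaller of
the two observed allele codes is taken as the reference allele; a genotype
with either allele missing is treated as wholly missing. An external
individual→population map can override the in-file population column, for
deposits that rely on a printed site order.

## Filter cascade

Clone deduplication keeps one SNP per genomic locus: highest call rate,
ties broken by highest PIC (computed on pooled frequencies,
PIC = 1 − (p² + q²) − 2p²q²), remaining ties by lexicographic locus ID so
the result is deterministic. The quality stages then run in a fixed
order — call rate ≥ 0.95, mean read depth strictly > 8, PIC ≥ 0.01,
per-population MAF, repeatability ≥ 0.95 — and the report records the
telescoping locus counts per stage.

The MAF stage is ambiguous in common usage ("2% per population"): the
default keeps a locus that reaches MAF ≥ 0.02 in *at least one* population
(removal only when rare everywhere), preserving locally informative
variants; a strict all-populations mode is selectable.

**Hardy–Weinberg.** For biallelic loci the Markov-chain exact test reduces
to full enumeration of the Levene distribution of the heterozygote count
conditional on allele counts, so enumeration is used for determinism; the
two-sided p-value sums all outcomes no more probable than the observed one
(with a 1 + 1e−12 relative tolerance on the equality comparison). Tests
run per locus per population and are corrected across loci within each
population by Benjamini–Hochberg at α = 0.05; an uncorrected mode exists.
On thousands of loci an uncorrected exact screen would flag hundreds of
loci by chance alone, which is why correction is the default.

## Diversity statistics

Per population and locus with n typed individuals and SNP frequency p:
Hₒ = heterozygotes/n, Hₙ.ᵦ. = (2n/(2n−1))(1 − p² − q²); population values
are means across loci (loci with n < 2 are skipped for Hₙ.ᵦ.). Fᵢₛ is the
Weir–Cockerham (1984) single-population f, combined across loci as a ratio
of variance-component sums (the estimator Genetix reports); the naive
1 − Hₒ/Hₙ.ᵦ. is exposed as `fis_simple` for comparison. MLH is the plain
proportion of an individual's typed loci that are heterozygous — no
standardisation, since standardised MLH would not track Hₒ the way survey
tables do.

Allelic richness counts, per locus, the alleles whose within-population
frequency clears a floor (default 5%), giving A ∈ [1, 2]; the percentage
of polymorphic loci is then (A − 1)·100 identically, a consistency
invariant the tests enforce. The effective number of alleles is the mean
of 1/(p² + q²). Locally common alleles clear the floor in the focal
population while doing so in fewer than half of all populations.

**Private allelic richness** uses hierarchical rarefaction: with N_k genes
typed in population k of which c carry the allele,
Q_k(g) = 1 − C(N_k − c, g)/C(N_k, g) is the probability the allele shows up
in a standardized draw of g genes, and the private richness of population
i at a locus is Σ_alleles Q_i(g) · Π_{k≠i}(1 − Q_k(g)). g defaults to the
smallest per-locus typed gene count across populations and is clamped per
locus. The companion count of "private loci" is stricter: an allele at
frequency ≥ 5% in the focal population and entirely absent elsewhere.
Combinatorial ratios are evaluated in log-gamma space.

**LD effective population size.** For every pair of loci above the MAF
floor (pcrit, default 0.02 to mirror the panel's MAF filter), r² is the
squared Pearson correlation of dosages times the Burrows small-sample
factor (S/(S−1))² — the composite estimator whose no-drift expectation is
E[r²] = 1/S + 3.19/S² (S ≥ 30; 0.0018 + 0.907/S + 4.44/S² below), with S
the harmonic-mean shared sample size. Subtracting that expectation leaves
the drift signal r²′ and Nₑ = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′) for
S ≥ 30 (constants 0.308, 0.308², 2.08 below); r²′ ≤ 0 or a negative
discriminant reports infinity, the estimator's natural boundary.

Two confidence intervals are offered. The *parametric* CI (default)
treats the number of pairwise comparisons as chi-square degrees of
freedom; with thousands of loci it is extremely narrow because pairs
sharing a locus are not independent, which is exactly how the very tight
brackets in survey tables arise. The *jackknife* CI leaves out one
individual at a time, matches a chi-square to the jackknife coefficient of
variation of mean r², and has calibrated coverage — it is the interval the
recovery tests validate (20/20 coverage of the true N over replicate
Wright–Fisher simulations). Memory scales with (number of loci)²; panels
beyond ~10⁴ loci should be thinned or chunked.

## Differentiation

**θ (WC84).** Per-locus variance components a (among populations), b
(among individuals), c (within individuals) from the standard
moment formulas with missing-aware per-locus sample sizes; the multilocus
estimate is Σa/Σ(a+b+c). Negative per-locus components are retained in the
sums. Significance: individuals are permuted between the two populations
(sizes fixed), p = (#{θ_perm ≥ θ_obs} + 1)/(n_perm + 1) — never exactly
zero. The default 10,000 permutations follows the survey's methods text
(its table caption says 1,000; both are configurable).

**Nei's Ds (1978).** Unbiased gene identities Ĵ_x = (2n Σp² − 1)/(2n − 1)
per locus, J_xy = Σ p_x p_y, averaged across loci *before* the logarithm;
Ds = −ln(J̄_xy/√(J̄_x J̄_y)), clipped at 0 from below, +∞ when the shared
identity is zero. Loci with non-positive Ĵ (tiny n) are skipped with a
warning.

**AMOVA.** Allele-level sums of squares in three strata, per locus with
per-locus sample sizes and coefficients (each heterozygote contributes 0.5
to the within-individual SS; the among-population coefficient is the usual
n_c), variance components summed across loci, percentages of the summed
total. F-statistics are the component ratios. P-values permute
individuals among populations (for the among-population component) and
re-pair alleles among individuals within populations (for the
among-individual component). Components can be individually negative;
an all-monomorphic matrix raises rather than reporting percentages of
zero.

**Mantel.** Pearson correlation of off-diagonal entries, joint row/column
permutation of one matrix, upper-tail +1-smoothed p. The genetic matrix
fed by the pipeline is linearised Fst, θ/(1−θ); raw θ or Ds can be
supplied instead. Geographic distances are haversine great circles on a
6,371 km sphere.

## Relatedness

Each within-population pair is scored under the four k-coefficient models
U (1,0,0), HS (½,½,0), FS (¼,½,¼), PO (0,1,0):
P(g₁,g₂|model) = k₀P(g₁)P(g₂) + k₁P₁(g₁,g₂) + k₂P(g₁)[g₁=g₂], with HWE
genotype probabilities at the focal population's own frequencies
(pair included — the behaviour of the standard ML tool) and the one-IBD
transition terms derived from gamete sharing. Logs are summed over
mutually typed polymorphic loci; structural zeros (opposite homozygotes
under PO) give −∞. Classification is pure argmax with ties resolved
toward the less related model (U > HS > FS > PO). No genotyping-error
model and no simulation-based significance — pairs near decision
boundaries will flip with marker count, as the family-recovery tests
quantify (≥90% of true full-sib pairs recovered as FS/PO and ≥95% of true
unrelated pairs as U at 2,000 informative loci).

## Networks

1−IBS distance: per pair, shared alleles per locus are 2 − |d₁ − d₂|,
summed over mutually typed loci. The mutual kNN rule links i and j only
when each is in the other's k nearest list (the Netview mkNN
construction; a union rule is available by flag). Distance ties break by
node order so graphs are reproducible. Default k = 30, the threshold at
which the published survey visualised its network; neighbourhood
connectivity (mean neighbour degree) is attached to nodes for sizing.

## Dispersal model

Velocity fields are daily snapshots on a regular lon/lat grid (the
1/12° daily resolution of global hindcast models is the reference);
interpolation is bilinear in space and linear in time, with land nodes
contributing zero velocity without weight renormalisation (a particle
skirting the coast feels a reduced current rather than an extrapolated
one). Advection is explicit Euler with configurable substeps per day
(default 24) and an isotropic random walk, ξ ~ N(0, √(2K dt)) per
component; positions update in degrees via the spherical metric (lon
scaled by 1/cos φ). The radius-conservation tests on a solid-body
rotation field confirm first-order convergence in the substep size.

Eddy diffusivity K is a free parameter — hindcast-forced studies rarely
print it — with default 5 m²/s, a typical coastal horizontal diffusivity
order. Land handling: a step that would land in a land cell (or leave the
domain) is refused; after 3 consecutive refusals the particle is flagged
beached (a hold-in-place mode is selectable). Settlement: particles aged
between the pelagic larval duration (default 25 d) and PLD + settlement
window (default 5 d) settle into the first declared sink polygon that
contains them; self-recruitment into the source polygon is allowed and
reported. Seeding: uniform points by rejection sampling inside each
polygon, split across polygons by area (or equally), over the first 3 days
of the run; the full-scale reference configuration of 256,000
particles/day is configurable down to desk scale. Particle bookkeeping
(active + settled + beached + expired = seeded) is asserted every day.

The connectivity matrix row for source i holds the fraction of its
particles settling in each sink plus unsettled/beached/expired fractions;
rows sum to 1.

## Synthetic generators

*Island model* (Balding–Nichols): per locus an ancestral frequency is
drawn from U(0.05, 0.95) and each deme's frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes Binomial(2, p_deme), missing
calls masked at a fixed rate. F is the target fixation index by
construction, which is why this generator (rather than a coalescent) backs
the θ-recovery tests. `study_conditions_spec` freezes the surveyed
layout: six demes labelled KA/LA/MA/RA/SA/YA with 22/45/25/46/42/31
diploids, background F = 0.034 and LA elevated to 0.06, missing rate 0.02.

What it does *not* emulate: inbreeding (Fis ≈ 0, so the AMOVA
among-individual stratum is empty, unlike surveys with heterozygote
deficits), linkage, family structure within demes, or ascertainment of the
SNP panel. Passing tests therefore validate the estimators, not any claim
about a particular wild population.

*Family pairs*: founders drawn under HWE, offspring by Mendelian gamete
transmission; each labelled pair (U/HS/FS/PO) uses its own founders so
pairs are mutually unrelated.

*Wright–Fisher*: discrete generations, two distinct parents per offspring,
unlinked loci initialised at 0.5. The LD-Ne recovery tests run 20
generations — enough burn-in for drift LD to equilibrate (at 10
generations estimates were still ~10% high for N = 100).

## Problem sizes in the standard checks

The shipped tests and `scripts/acceptance.py` run at desk scale, chosen
once as the smallest sizes at which each property is statistically
decisive: 2,000-locus surveys at the study's sample layout, 5,000 loci for
the θ = 0.05 recovery, 400 loci × sample 40 for LD-Ne, 10⁴ particles for
the diffusion and gyre runs, 10⁵ draws for the Monte-Carlo HWE oracle.
The full-scale published simulation (4.6 million particles on hindcast
currents) is out of scope; the dispersal model is validated by its
analytic-field oracles plus a scaled-down synthetic-gyre run.

## Known limitations

* Pairwise r² computation materialises loci × loci matrices; very large
  panels need chunking.
* The dispersal model is 2-D surface advection: no tides, wind drift,
  vertical behaviour, mortality or competency.
* The rotation synthetic field uses a planar approximation; keep test
  domains within a few degrees of the equatorial band or accept a small
  metric distortion.
* Nei's Ds averages identities over loci typed in both populations; with
  extreme missingness the locus sets entering J̄_x and J̄_xy can differ
  slightly from tool-specific conventions.
* AMOVA handles missing data by per-locus sample sizes; programs that
  impute or drop incomplete individuals will differ at the margin (the
  ±1-point tolerance on published percentage comparisons reflects this).
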