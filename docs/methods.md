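# Methods

This note documents the statistical models implemented in `kdrscape`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where conventions diverge.

## Data model and conventions

All analyses operate on haploid, pre-aligned DNA sequences over
`{A,C,G,T,-,N}`. Coordinates are 1-based inclusive; after a region
extraction, site positions are always reported in original-fragment
coordinates via the returned column map. The packaged *kdr* fragment layout
— exon(1–74) / intron-1(75–979) / exon(980–1166) / intron-2(1167–1230) /
exon(1231–1285), codon at 1160–1162 — is the unique arrangement consistent
with the published segment lengths (74+905+187+64+55 = 1285 bp) and with
the reported positions of intron and codon polymorphisms.

Missing-data handling follows the common DnaSP-style convention: site-based
statistics (S, η, η_s) use complete deletion (columns containing `-` or `N`
are dropped), while pairwise differences (K, mismatch distributions) use
pairwise deletion; both are configurable. Haplotype identity is exact
string match, with gaps and N as ordinary states, so indel variants remain
distinguishable. π is reported as K/L over all analysed sites. (Published
per-population tables for this locus print π ≈ K/65, i.e. normalised by the
polymorphic-site count rather than the analysed length; the implementation
deliberately reports the per-site quantity and does not emulate that
normalisation.)

Multi-allelic columns contribute k−1 mutations to η but one site to S
(infinite-sites accounting, as required by the Fu & Li tests); η_s counts
alleles observed exactly once, capped at the column's mutation count.

## Neutrality tests

- **Tajima's D** uses the standard 1989 coefficients computed from n, with
  the fixed-S variance form D = (K − S/a₁)/√(e₁S + e₂S(S−1)).
- **Fu & Li's D\*, F\*** are the outgroup-free versions with the corrected
  variance coefficients of Simonsen, Churchill & Aquadro (1995). Singletons
  are counted without an outgroup: any column where some base occurs
  exactly once (so derived counts of both 1 and n−1 qualify).
- **Fu's Fs** is ln(S′/(1−S′)) with S′ = Pr(#alleles ≥ h_obs | θ = K) under
  the Ewens sampling distribution. Unsigned Stirling numbers of the first
  kind are built by the integer recurrence in log space and cached, which
  is numerically exact to well past n = 600 (the largest published sample
  here is 2N = 546 chromosomes); both tails of Fs are reported because the
  literature is inconsistent about which tail earns a star.
- **R2** follows Ramos-Onsins & Rozas: R2 = √(Σᵢ(Uᵢ − K/2)²/n)/S with Uᵢ
  the number of singleton sites at which sequence i carries the unique
  base, computed over complete-deletion columns (K is computed over the
  same column set for internal consistency).

Significance is empirical: `reps` neutral constant-size coalescent samples
are simulated **conditioned on the observed S** (mutations placed
multinomially on branches proportionally to length — the DnaSP-style
fixed-S convention, which removes the nuisance dependence on θ). Tails are
two-sided for D, D\*, F\* and lower for Fs and R2; p-values use add-one
smoothing (b+1)/(reps+1). Across populations, p-values are adjusted by
Benjamini–Hochberg FDR (statsmodels). Calibration on 2,000 neutral samples
(n = 30, θ = 5) gives mean D within ±0.1 of zero and 5%-level rejection
rates of all five tests inside [0.03, 0.07] (see the acceptance suite).

## Sudden-expansion model

The expected mismatch distribution under a stepwise expansion of age τ
(mutational units) from θ₀ to θ₁ is the equilibrium geometric law
F̂ⱼ(θ) = θʲ/(1+θ)ʲ⁺¹ combined with Poisson(τ) accumulation:

Fⱼ = F̂ⱼ(θ₁) + e^{−τ(θ₁+1)/θ₁} Σᵢ (τᶦ/i!) [F̂ⱼ₋ᵢ(θ₀) − F̂ⱼ₋ᵢ(θ₁)]

which reduces to the geometric law at τ = 0 and to Poisson(τ) as θ₀ → 0,
θ₁ → ∞ (both limits are tested). Vectors are truncated, clipped at zero
and renormalised.

Fitting: the **moment** method uses Rogers' estimators θ̂₀ = √max(v−m, 0),
τ̂ = m − θ̂₀ from the mean and variance of pairwise differences (θ₁ treated
as effectively infinite and reported at the stabilising cap); **least
squares** minimises the SSD between observed and expected relative
frequencies over a coarse grid followed by Nelder–Mead refinement, with
θ₁ ≥ θ₀ enforced by parameterising θ₁ = θ₀ + δ and capped at 10× the
largest mismatch class to stabilise the flat likelihood ridge. SSD is
always on relative frequencies (this fixes the scale ambiguity in
published SSD values). Harpending's raggedness is r = Σ(xᵢ − xᵢ₋₁)² with a
trailing zero class.

Goodness of fit is a parametric bootstrap: samples of size n are simulated
under the fitted demography (single-deme coalescent with a size step at
τ/θ₁ coalescent units and Poisson(θ₁/2 × branch length) mutations), refit
with the same method, and p = (1 + #{sim ≥ obs})/(reps+1) for SSD and r.
Because the expansion family nests the equilibrium case (τ = 0), data from
a constant-size population are *not* systematically rejected — the test is
calibrated, which the suite verifies; rejections indicate shapes the
family cannot produce. τ converts to years as t = τ/(2μ) only when the
user supplies a per-locus mutation rate; no rate is assumed.

## AMOVA, pairwise differentiation, trees

AMOVA follows the Excoffier sums-of-squares formulation on squared
inter-individual distances: haplotype identity (0/1) for frequency-based
F-statistics, pairwise nucleotide difference counts for Φ-statistics. The
analysis is haploid throughout (sequences, not genotypes). Variance
components use the standard unequal-sample-size coefficients; percentages
always sum to 100 and F_ST = 1 − (1−F_CT)(1−F_SC) holds on the components.
Permutation schemes: individuals among all populations (F_ST), individuals
among populations within groups (F_SC), whole populations among groups
(F_CT); 1,000 permutations by default with explicit seeds. Pairwise
F_ST/Φ_ST estimates are two-population one-level AMOVAs; negative
estimates are reported as computed (clamping is opt-in). For the many
pairwise comparisons both FDR (default) and Bonferroni counting are
available — the source study's methods and results sections name different
corrections, so the choice is surfaced as configuration.

Nei's (1978) unbiased distance treats the fragment as one locus with
haplotypes as alleles; zero shared identity maps to a logged finite cap.
UPGMA is implemented directly (not via a library) to guarantee the
documented deterministic tie-break — among equal-distance pairs, the
lexicographically smallest label pair joins first — and emits Newick with
ultrametric branch lengths; it is oracle-tested against average-linkage
cophenetic matrices.

## Spatial analyses

Geographic distances are haversine great circles (R = 6371 km). The Mantel
test correlates upper-triangle entries (Pearson), with one-tailed p from
joint row/column permutations; genetic distances enter as F_ST/(1−F_ST)
with values at 1 clipped to a large finite linearisation. SAMOVA runs
independent simulated-annealing chains per K (proposal: move one population
to another group, rejecting moves that empty a group; Metropolis acceptance
on F_CT; geometric cooling, T₀ = 0.05, factor 0.999 — the original
publication does not specify a schedule, these values were chosen for
acceptance-rate stability and are exposed as arguments). Proposals are not
geographically constrained, matching the unconstrained mode of the original
method. F_CT evaluation is O(P²) per proposal via precomputed
population-pair distance aggregates, and the annealer is oracle-tested
against exhaustive partition enumeration on ≤8 populations.

The genetic-landscape surface builds a Delaunay triangulation over
population coordinates (equirectangular projection about the mean latitude
— an approximation documented as such; collinear layouts fall back to the
complete graph with a flag), assigns each edge midpoint the genetic
distance of its endpoints, and interpolates a uniform grid (default 80×80)
by inverse-distance weighting with exponent α (default 1). Surface heights
are convex combinations of midpoint values, hence bounded by the input
distances. Population centroids (not individuals) are interpolated.

## Haplotype network and origin counting

Network states are haplotypes over the informative sites: intron columns
whose minor-allele frequency exceeds the threshold (default 10%) plus the
codon's variable positions. The network is a minimum-spanning network:
candidate edges (Hamming distance ≤ the two-step connection limit) are
added in increasing step order, skipping edges whose endpoints are already
connected at smaller or equal cost while retaining all co-minimal ties;
the 0.95 parsimony probability of the original software is carried as
metadata, not recomputed — the step limit is fixed by design. Root
probability is frequency share within a component (frequency correlates
with haplotype age).

An **origin event** is an edge whose endpoints differ in codon class:
wild→resistant edges count as an origin of the resistant class regardless
of which endpoint is more frequent (a sweep typically leaves the derived
allele *more* common than its wild ancestor, so frequency cannot polarise
these edges); between two resistant classes the higher-root-probability
endpoint is treated as ancestral and the event credits the derived class.
Components containing no wild-type node contribute their highest-frequency
resistant node as one founding event, making all reported counts lower
bounds. The report lists each event's allele class and intron background,
plus the numbers of distinct backgrounds and resistant haplotypes.

## Synthetic-data generator

The generator is an event-driven structured coalescent: lineages carry deme
labels; within-deme pairs coalesce at rate 1/size_d(t); each lineage
migrates at the configured rate with targets drawn from a weight matrix
(island, stepping-stone, or region-structured — within-region weight 1,
cross-region weight scaled down by a configurable factor). Deme sizes are
piecewise constant: a sudden expansion of age τ (mutational units) is a
size step at τ/θ_locus coalescent units from size×ratio to size. Mutations
fall on branches as Poisson(θ_locus/2 × length) and occupy unique intron
columns (infinite sites; if mutations outnumber eligible columns the
generator recycles positions and flags the finite-sites fallback). Exons
are invariant and every simulated chromosome starts with the wild-type
leucine codon. The simulator is cross-checked against msprime (segregating
site yield at equal parameters) and against closed-form coalescent
expectations (E[TMRCA], Watterson's E[S]).

The selective sweep is phenomenological: in each target deme the most
frequent haplotypes provide `background_count` intron backgrounds, the
resistant codon is written onto them, and chromosomes are resampled so the
resistant classes reach the configured final frequency. This reproduces
exactly the observables the analyses consume — near-fixed resistant
frequencies on few backgrounds with collapsed flanking intron diversity —
without simulating selection forward in time; it does not generate partial
sweep trajectories, recombinant backgrounds, or soft-sweep allele-frequency
dynamics.

`paper_mimic_config` packages the study conditions: 15 demes of 20
chromosomes in three regions (southwest 3, south 7, central 5),
θ = 0.02/site over the 969 intron columns (θ_locus ≈ 19), sudden expansion
of τ = 6 with a deep (1%) pre-expansion size everywhere except two small
constant southwest demes, region-structured migration (within-region rate
100, cross-region scaled by 0.001), and an L1014F sweep to 95% on one
background in the five central demes. Within-region migration is set fast
relative to the expansion age so demes inside a region stay nearly
homogeneous (low F_SC) while regions are strongly isolated (large, reliably
significant F_CT); with slower mixing, the meeting time of lineages —
not deme size — dominates coalescence and inflates within-deme diversity
far above the published scale. Because the whole fragment is one
non-recombining locus, all demes share a single genealogy per replicate:
quantities like F_CT and Mantel correlations are genealogically noisy in a
way multi-locus data would not be. For the same reason the
isolation-by-distance power experiment uses a 12-deme stepping-stone chain
(a 5-deme chain leaves a Mantel test on one locus with little power at any
sample size).

What passing tests show — and do not show — about real data: the suite
demonstrates correctness of the statistics (oracle equivalence, exact
arithmetic, calibration) and recoverability of the generating signals
under the model's own assumptions (no recombination, no sequencing error,
equilibrium migration, a single sampling time). It does not validate the
demographic realism of any particular field system.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; dataset simulation is
byte-deterministic under seed. Default analysis settings (1,000
permutations/bootstrap replicates) match common practice; the test suite
and the acceptance script use the experiment sizes stated in their
docstrings — e.g. 2,000 null coalescent samples for calibration, 200
replicates for τ recovery, 200 random instances per oracle-equivalence
check, 12–20 seeded runs for the end-to-end geographic pattern — chosen as
standard Monte-Carlo sizes for the tolerances being asserted.

## Known limitations

- No recombination anywhere (coalescent, tests, network); the *kdr*
  fragment and mtDNA are treated as single non-recombining loci.
- Fu's Fs p-values come from the fixed-S null rather than the original
  conditional-on-θ simulation; the conventional "test at 0.02 for a 0.05
  decision" note is configuration, not default.
- The landscape surface uses a planar projection and population centroids;
  it is an interpolation diagnostic, not a barrier-inference method.
- The TCS parsimony-probability computation is intentionally out of scope;
  the two-step limit is fixed.
- Bayesian haplotype phasing and migration-rate estimation are out of
  scope; inputs are assumed phased.
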