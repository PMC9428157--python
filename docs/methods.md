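# Methods

This note documents the models behind `plasmidfate`, the parameters that
matter, the design choices made where several conventions were defensible,
and what the synthetic-data generator does and does not emulate.

## Decay model

Marker-gene abundances *C*(t) (copies per g dry weight) are assumed to
decay log-linearly within a phase: lg *C*(t) = lg *C*₀ − t/D, where D is
the decimal reduction time in days. The biphasic model splits the series at
a breakpoint day (default 15, the end of fast thermophilic decay) and fits
two independent OLS segments on (day, lg *C*ₜ/*C*₀); the breakpoint day
belongs to phase I. Fits use plain least squares — no weighting, no
continuity constraint at the breakpoint — because with three replicate
reactors per treatment there is too little data to support a constrained
segmented regression, and unconstrained segments are what D-value tables
conventionally report.

*Breakpoint grid search.* When the breakpoint is estimated rather than
fixed, candidates are the observed sampling days that leave at least two
distinct days per segment, and the selected day minimizes total residual
sum of squares. During selection the candidate day anchors **both**
segments: for a continuous piecewise line the kink sample lies on both
branches, and without sharing it the splits "kink day in phase I" and
"kink day in phase II" are statistically indistinguishable (both partition
the data into two exactly collinear subsets with the same total residual
degrees of freedom). The returned fits then follow the phase-I convention.

*Below-detection values* (zero concentration) are excluded from regression
rather than substituted, since the assay's detection limit is not part of
the data model; substituting half the smallest observed value is a common
alternative but invents a limit.

*Replicate handling.* Fits are per replicate by default, summarized as the
spread of per-fit D-values; a pooled mode (replicate means per day) is also
available because published decay analyses do not always state which was
used.

*Group comparisons* use one-way ANOVA followed by Tukey's HSD (studentized
range distribution, via scipy). Where a Duncan multiple-range test is
requested the Tukey procedure is substituted — slightly conservative — and
the result carries an explicit note. Compact display letters are assigned
to the maximal cliques of the non-significance graph at p < 0.05, ordered
by descending group mean, so groups sharing a letter are never
significantly different.

## Spread potential

SP = (C_gfp − C_dsRed) / (C_16S/k − C_dsRed) with k the 16S rRNA gene
copies per cell. The default divisor is k = 4, exactly as the statistic is
conventionally printed, even though rRNA-database surveys estimate the
average closer to 4.1; both are supported and the choice moves SP by less
than 3 % whenever recipients outnumber donors a hundredfold (a bound
asserted in the test suite). Negative numerators — gfp reading below dsRed,
which can only be measurement noise if every donor carries one plasmid —
are clamped to zero and flagged; a non-positive recipient denominator
invalidates the sample (flagged, SP = NaN) rather than producing a negative
ratio. Replicates aggregate by geometric mean because SP spans orders of
magnitude.

## Diversity and ordination

All indices are computed from their estimator formulas (verified against
scikit-bio in the tests, which is never used as the implementation):

- Sobs: taxa with nonzero counts.
- Chao1 (bias-corrected): Sobs + F₁(F₁−1)/(2(F₂+1)).
- ACE with rare cutoff 10 (the Mothur default); when every rare taxon is a
  singleton the ACE coverage is zero and the Chao1 value is substituted.
- Shannon in natural log (Mothur convention; typical transconjugant-pool
  values of 2–3.3 are consistent with nats).
- Simpson as dominance Σpᵢ² — low is diverse.
- Good's coverage 1 − F₁/N.

Bray–Curtis is Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on raw counts. No rarefaction is applied
by default (seeded rarefaction to a common depth is available); with equal
simulated depths rarefaction is a no-op anyway, and for real tables the
indices should then be interpreted per-sample-depth.

PCoA is classical metric scaling: double-center −D²/2, eigendecompose,
scale eigenvectors by √λ. Negative eigenvalues (possible for non-Euclidean
dissimilarities) are reported unmodified — no Lingoes/Cailliez correction —
and excluded from the retained axes and the proportion-explained
denominator. Axis signs follow a deterministic convention (largest-
magnitude loading positive) so repeated runs are identical.

PERMANOVA partitions squared dissimilarities into among/within-group sums
(pseudo-F with a−1 and N−a degrees of freedom) and obtains
p = (#{F\* ≥ F} + 1)/(B + 1) from B seeded label permutations. The smallest
attainable p is therefore 1/(B+1).

*Taxonomy conventions.* Lineages are `k__;p__;c__;o__;f__;g__` strings.
OTUs unresolved at the requested rank are labeled by the nearest resolved
ancestor's bare name (so an unresolved-genus Bacillaceae OTU aggregates
under "Bacillaceae", matching how family-level "genera" appear in
composting host-range figures); fully unresolved lineages bucket under
"unclassified". Host-range "shared percentage" is reported under both
plausible denominators — |core|/|union| and |core|/|group| — because the
published figure does not define one.

## The synthetic-data generator

The generator emulates a two-treatment composting microcosm experiment
(NT: natural thermophilic phase, sampled to day 27; CT: thermophilic phase
extended to day 27 by external heating, sampled to day 40; sampling days
0, 1, 4, 7, 11, 15, 19, 27, 40; three replicates). Phases are assigned as
IP at day 0, TP through the thermophilic end day (NT: 11, CT: 27), MP
afterwards. It imposes outcomes — it does not model conjugation mechanism
(no mass-action transfer dynamics), extraction or sorting losses.

**Trajectories.** Both marker genes start at the measured initial
concentrations (dsRed 3.30 × 10⁶, gfp 1.04 × 10⁷ copies/g DW) and decay
with phase-I D = 7.0 days to the day-15 breakpoint. Afterwards NT rebounds
at +0.02 log₁₀/day (a "slight increase" during maturation) while CT
continues slow decay. The total 16S pool is held constant — a
simplification; real total bacterial loads shift severalfold during
composting, so SP recovery tests exercise the estimator, not 16S dynamics.
The two free parameters the study never printed — the total 16S
concentration and the CT slow-phase D-value — are solved in closed form so
that ground-truth SP(day 0) = 3.91 × 10⁻⁴ and SP(day 40, CT) = 2.54 × 10⁻⁶
transconjugants per recipient (`solve_trajectory_parameters`); the solved
defaults are ≈7.3 × 10¹⁰ copies/g DW and ≈563 days (an almost-plateau).
Replicate-level biological variation is lognormal with σ = 0.1 log₁₀ by
default.

**ddPCR.** Standard QX200-style Poisson occupancy: each of 20 000 droplets
of 0.85 nL is positive with probability 1 − e^(−λv); the estimator inverts
the observed positive fraction, λ̂ = −ln(1 − p̂)/v. Saturated reactions
(all positive) are flagged unquantifiable; all-negative reactions return 0
with a below-detection flag. Per-gene dilution factors map copies/g DW to
copies/µL and default to 10⁻⁴ for the marker genes and 2 × 10⁻⁸ for 16S,
keeping occupancies in the quantifiable range at the initial
concentrations. The estimator's relative bias is below 2 % for occupancies
in [0.05, 0.95] (asserted over 1000 simulations).

**Communities.** Five sample groups (IP, NT-TP, NT-MP, CT-TP, CT-MP) draw
OTU counts Dirichlet-multinomially: proportions from a Dirichlet with mean
equal to the group template and precision 500 (moderate between-replicate
overdispersion, on the order seen in sorted-pool replicates), then a
multinomial read draw at 60 000 reads/sample, so column sums are exact.
Templates anchor the dominant genera at published-composition values
(e.g. Oceanobacillus 27.41 % in raw material, Bacillus 44.66 % in CT-TP,
Bacillus 48.41 % in NT-MP), encode phylum totals with Firmicutes at
75–90 % and a Proteobacteria rebound at maturation (4.3 → 16.8 % NT,
8.2 → 22.2 % CT), and spread the remaining mass over a rare tail whose
size per group follows the observed richness ordering (NT-TP richest,
CT-TP poorest). Tail membership rotates between groups so groups share a
realistic core without being identical; tail weights span 1.5 decades.
Rare-tail taxa carry synthetic placeholder names; only the anchored genera
are real. Because very rare template taxa are not always observed at
finite depth and Dirichlet precision, realized richness sits somewhat
below template richness — the preserved property is the ordering between
groups, not absolute Sobs values.

**What passing tests do and do not show.** Recovery tests demonstrate that
the estimators are correct for the stated noise models (binomial droplets,
lognormal replicates, Dirichlet-multinomial reads). Real composting data
add effects the generator omits — 16S pool dynamics, extraction and
sorting biases, PCR chimeras and classification error, day-to-day
temperature variation — so passing recovery here does not certify accuracy
under those distortions.

## Numerical and procedural choices

- Log base 10 throughout for concentrations ("lg"); Shannon in nats.
- OLS r² is clipped to [0, 1]; an exactly constant series gets r² = 1.
- D-value = |1/slope| for negative slopes, ∞ for flat or rising segments.
- PERMANOVA requires ≥ 99 permutations; p-values are never 0 by
  construction.
- All randomness flows from `numpy.random.default_rng` generators seeded
  explicitly; a fixed seed makes every stage byte-reproducible, including
  file outputs.
- Simulation sizes in the test and acceptance suites (200 fit seeds, 1000
  droplet simulations, 25-replicate community batches) were chosen as the
  smallest sizes at which Monte-Carlo error is comfortably inside the
  stated tolerances.

## Known limitations

- The constant-16S assumption makes SP trajectories exactly proportional
  to the marker difference; real SP series also reflect total-community
  dynamics.
- The Duncan-to-Tukey substitution is conservative: letter groupings may
  merge groups a genuine Duncan test would separate.
- Biphasic fits are unconstrained, so the two segments generally disagree
  at the breakpoint; the breakpoint grid search assumes at most one kink.
- The community templates are a synthetic composite; they reproduce
  composition anchors and richness ordering, not the full covariance
  structure of real transconjugant pools.
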