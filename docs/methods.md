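# Methods

## Scope and model of the study design

The package simulates and evaluates a genomic-selection study design in
which two related species' diversity panels serve as candidate training
populations for predicting breeding values in interspecific F₂ families.
Everything is organized around three experiments:

1. **within-panel** — replicated 5-fold cross-validation (10 replicates)
   inside one panel, comparing RR-BLUP trained on the whole training fold,
   on a random subset, on a CDmean-optimized subset, and a PC-only model;
2. **cross-panel** — seven training configurations (random-200 /
   CDmean-200 / whole subsets of each panel, plus the summed GEBVs of the
   two whole-panel models) evaluated on an external target population with
   1,000 bootstrap resamples;
3. **simulation** — the same configurations evaluated on 50 simulated F₂
   families under five QTN-sharing scenarios and three genetic
   architectures.

## Population simulation

Panels are drawn from the Balding–Nichols model: each marker receives an
ancestral frequency p ~ Uniform(0.05, 0.95); each subpopulation's
frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean p and
differentiation F (the Fst parameter); haplotype alleles are independent
Bernoulli draws at the subpopulation frequency. Two species panels share
one ancestral vector and are separated by an extra Balding–Nichols step
with a `divergence` parameter before within-species structure is applied.
Individuals are split evenly across subpopulations (remainder to the first
ones), which makes panel composition deterministic and testable.

Defaults: 300 individuals per panel, 3 subpopulations, within-species
Fst 0.25, divergence 0.3, on a 356-marker / 19-linkage-group map with
150 cM groups. The real germplasm this emulates does not come with
published Fst or subpopulation counts; these defaults are chosen once as
representative of strongly structured perennial-grass panels and exposed
as configuration knobs. The generator reproduces the features downstream
analyses rely on — PCA-recoverable subpopulation clusters, reduced
cross-species kinship, segregating and occasionally monomorphic markers —
but not linkage disequilibrium decay, missing data, or genotyping error.
Monomorphic markers are retained rather than re-drawn, because the trait
scenarios explicitly handle non-segregating QTNs. Passing tests therefore
demonstrate internal consistency of the method chain under idealized
frequency-model data, not performance on any real panel.

## Meiosis and F₂ families

Gametes follow a Markov walk along each linkage group: the source
haplotype of a group's first marker is chosen fairly, and between adjacent
markers the source switches with probability equal to the Haldane
recombination fraction r(d) = (1 − e^(−2d/100))/2 of the inter-marker
distance d in cM. Without crossover interference this walk is the exact
marginal law of the gamete, so explicit crossover-point placement is
unnecessary. Linkage groups segregate independently; there is no mutation
and no segregation distortion.

An F₂ family crosses one founder from each panel, produces 50 F₁ (one
gamete per founder each), and intermates the F₁ into 216 F₂. F₂ parents
are drawn uniformly with replacement across matings, but selfing is
disallowed — a deliberate choice consistent with self-incompatible
outcrossing species; single-locus F₂ genotype distributions are unaffected
by this choice. Founders taken from simulated panels carry true phase;
imported unphased dosages are phased uniformly at random once (seeded),
which is exact for single-locus F₂ distributions and approximate for
founder LD.

## Trait simulation

A trait architecture draws 20 additive QTNs, plus 4 dominance QTNs
(`A20D4E0`) or 4 epistatic loci (`A20D0E4`), all loci disjoint within a
panel. The epistatic architecture is implemented as **2 disjoint locus
pairs**, each contributing one additive×additive effect on the product of
the two loci's {−1,0,1} codes; the alternative reading (4 pairs / 8 loci)
is not used because the architecture code counts loci. Effects are uniform
magnitudes — U(0,1), except the large/small scenarios where the named
panel draws U(0.5, 0.99) and the other U(0, 0.25) — and each effect
receives a random ± sign (`signed_effects=True` by default), since only
magnitude ranges are specified by the design; the flag allows all-positive
effects.

Scenario semantics: `S.QTN` gives both panels identical loci and effects;
`P.QTN` shares half of each mechanism's QTNs (identical locus and effect)
with panel-private, mutually disjoint remainders; the `D.*` scenarios use
completely disjoint panel sets. Dominance acts on the heterozygote
indicator (F∞ parameterization, consistent with the {−1,0,1} additive
code). In F₂ families the union of both panels' QTNs contributes, with
shared QTNs counted once — a shared QTN is one biological locus, not two.

Noise is calibrated per population: σ²_e = Var(g)(1 − H²)/H² with H² =
0.60 for panels and 0.37 for F₂ families, the F₂ noise variance recomputed
per family from that family's genetic variance (a fixed family-level H² is
only achievable per family, since families differ in segregating QTNs).
The recorded `realized_h2` is the sample ratio Var(g)/Var(y) of the draw,
capped at 1 because sampling covariance between g and e can push the raw
ratio slightly above 1 at small n. A family in which no QTN segregates has
zero genetic variance; it raises a `DegenerateTraitError` naming the
family rather than producing an undefined trait.

## RR-BLUP and REML

The mixed model y = 1β₀ + Xβ + ε with β ~ N(0, Iσ²_β) is fitted through
the n×n kernel K = XXᵀ. The restricted likelihood is evaluated on an
explicit orthonormal basis of the orthocomplement of the intercept
(a Householder reflector), *not* by pruning eigenvectors of the centered
kernel: when K is rank-deficient (duplicated or monomorphic markers,
n > rank X) the projected kernel's zero eigenspace is degenerate and an
eigenvector-pruning approach can leak the intercept into the rotated data.
In that basis the rotated observations are independent with variance
σ²_β(θᵢ + λ), so REML reduces to a 1-D minimization over log λ: a 41-point
grid on [−10, 10] followed by bounded refinement between the flanking grid
points (tolerance 1e-8 on log λ). Marker BLUPs are
β̂ = Xᵀ(K + λ̂I)⁻¹(y − 1β̂₀) with β̂₀ the GLS intercept at λ̂ — identical to
the dense primal ridge solution by the Woodbury identity, but O(n³)
instead of O(p³). GEBVs are reported without the intercept, which cancels
in correlation-based accuracy.

Genomic heritability is σ̂²_u/(σ̂²_u + σ̂²_E) with σ̂²_u scaled by the mean
diagonal of the column-centered kernel (centering does not change REML,
which only sees the intercept-projected kernel). `narrow_h2` runs the same
machinery with K replaced by the genomic relationship matrix.

The relationship matrix is the centered cross-product A = XcXcᵀ/c with c
chosen so the mean diagonal is 1, plus a 1e-6 diagonal ridge for
invertibility. This standard estimator replaces fancier kinship estimators
deliberately: CDmean only requires a valid PSD relationship matrix, and
the estimator is swappable.

The PC-only model computes marker PCA once per panel from genotypes of all
individuals (phenotypes cannot leak through a genotype-only basis) and
regresses the training phenotypes on the top q = 7 scores. A per-fold PCA
is available by passing the training matrix as its own reference.

## CDmean and the exchange search

CD(c) = cᵀ(A − λ(ZᵀMZ + λA⁻¹)⁻¹)c / (cᵀAc), with M the within-training-set
centering projector and Z the training incidence; CDmean averages over
contrasts cᵢ = eᵢ − 1/N for each targeted individual. Contrast targets are
the currently *unselected* calibration individuals, re-derived after each
accepted swap. The exchange search makes exactly `n_iter` proposals
(default 3,000), swapping one selected against one unselected individual
and accepting only strict improvement — ties are rejected so the accepted
trace is strictly increasing and runs are reproducible. A⁻¹ is computed
once per run; each proposal re-solves the inner system rather than using
rank-one updates (correctness first; at N ≤ ~600 a full solve per proposal
is tractable).

λ is the only trait-dependent input to CDmean. It is estimated as
σ̂²_e/σ̂²_u from a GBLUP REML fit on the calibration set's phenotypes, so
different traits select different subsets; without phenotypes the fallback
is λ = 1 (h² = 0.5).

## Evaluation

Accuracy is the sample Pearson correlation; zero-variance cases are
flagged NaN, excluded and counted — never imputed as 0. In simulation
experiments accuracy correlates GEBVs with simulated *phenotypes*; the
correlation with true genetic values is emitted as a diagnostic column.
Prediction uses all mapped markers including the QTN markers themselves,
mirroring a marker set that doubles as QTN pool; a study that excluded
QTNs from prediction can do so by masking columns. For panels too small
for the full-scale subset size of 200, the random/CDmean subset size
scales to round(half the training-set size) so the three-way comparison
stays meaningful at desk scale.

## Problem sizes in the shipped tests and acceptance script

The test suite runs the full-scale map (356 markers / 19 groups) and
panel size (300) where the check is about calibration (heritability
targets, REML recovery), and smaller worlds (60–120 markers, 40–60
individuals, 10–120 exchange iterations) where the check is a contract or
an oracle identity that is scale-free. The acceptance script uses 300
individuals per panel, one 50 F₁ → 216 F₂ family, and 100 replicate
traits/noise draws per calibration. The F₂-ordering experiment uses 10
families — enough for stable mean orderings across seeds while keeping a
laptop-scale runtime.

## Known limitations

* No LD-realistic haplotypes (no coalescent simulation), no missing data,
  no genotyping-error or read-depth model.
* Founder phasing of imported unphased data ignores founder LD.
* The prediction model is additive RR-BLUP only; dominance and epistasis
  exist in the trait generator, not in the predictor.
* No crossover interference, sex-specific maps, or polyploid meiosis.
* Real-data phenomena that depend on the particular germplasm — e.g.
  which training configuration wins on observed field traits — are outside
  what synthetic panels can establish.
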