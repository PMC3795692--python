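# Methods

This note documents the models, conventions and numerical choices behind
`rotbreed`, and what its synthetic-data machinery does and does not emulate.

## Pedigree inbreeding

Relationships are computed by the tabular (Emik–Terrill) recursion in a
topologically sorted copy of the pedigree and mapped back to input order, so
all results are invariant to row permutations. Founders — animals with both
parents unknown — are defined to be unrelated and non-inbred; every F is
therefore the *increase* in autozygosity accrued inside the recorded pedigree,
not an absolute value (real colony founders from a heterogeneous stock are
related through their unrecorded history). The matrix is dense; at the scale
of a 28-generation colony (thousands of animals) this is a few hundred MB and
seconds of work, which we prefer over sparse-inverse machinery for
transparency.

Rates of change of a generation-mean series are reported in two conventions,
both exposed because both appear in colony reports: `absolute_points`
((mean_last − mean_first)/steps × 100, used for F) and `relative`
((mean_first − mean_last)/mean_first/steps × 100, used for heterozygosity).
Because a 27- vs 28-step divisor is a recurring ambiguity in such reports,
rate helpers take explicit spans and the acceptance script prints both.

## The rotational scheme

A female of family *i* mates, in rotation *r*, the male of family
((i − 1 + r′) mod n) + 1, with r′ the rotation index collapsed onto 1..n−1
(same-family offsets skipped). Generation-*g* breeders use rotation *g*;
founder pairs (G0) are formed within family, which is harmless — founders are
unrelated — and is the convention under which the scheme's first inbreeding
loop closes at G4 and the first cousin-mating generation is G7. Offspring
belong to the dam's family (configurable in loaded pedigrees; fixed in the
idealized builder). First-cousin pairings arise exactly when consecutive
effective rotations sum to n; with 13 families that is every 6 generations,
producing mean-F spikes at G8/G14/G20/G26 of the idealized pedigree.

Because the trajectory is cyclic, endpoint-based rates alias the cycle phase:
G0→G28 (a trough endpoint) shows a 45.6% slowdown vs random mating while
G0→G26 (a spike endpoint) shows 34.7% and the least-squares slope 39.2%. The
package's convention for "overall rate" of a rotational trajectory is a
whole number of half-cycles (G0→G26 for 28 generations); this is the value
the comparison functions and tests use.

## Drift expectations and their exactness

`expected_F_random_series` / `expected_H_random_series` implement the
textbook separate-sexes recursions with c_n = (N_f+N_m)/(8 N_f N_m)
(equivalently 1/(2N_e), N_e = 4N_mN_f/(N_m+N_f)). These are *lag-free*
approximations: the exact recursion for bisexual populations is Wright's
two-generation form F_{t+1} = c(1 + F_{t−1}) + (1 − 2c)F_t, whose asymptotic
rate is ~2% below c at N_m = N_f = 13 and which any realized pedigree —
monogamous or not — follows. Consequently the random-mating pedigree builder
(monogamous couples with multinomial litters by default; an independent-draw
mode is provided and is statistically indistinguishable) tracks the exact
lagged recursion, and sits ~1.5 generations' worth of drift below the
lag-free series at finite horizons. Tests validate the builder against the
exact form and the recursions against their own algebra (monotonicity,
bounds, the identity 1 − F_n = H_n/H_0, increment halving under doubled
counts).

## Gene drop and the synthetic panel

Founder haplotypes are mosaics of K inbred strains: per marker each strain
carries a fixed 0/1 allele (frequency uniform in [0.1, 0.9] by default), and
each haplotype switches strain ancestry along the cM map as a Poisson process
(default 0.3 switches/cM — an emulation knob producing multi-Mb blocks
consistent with a few tens of generations of stock mixing, not a measured
value). Expected founder heterozygosity is 2f(1−f) with f the strain-weighted
allele frequency. Transmission uses Haldane's model (crossover count Poisson
in map length, positions uniform, no interference) — the simplest model
consistent with no recombination data; maps default to a 2.75 Gb genome at
1 cM ≈ 2 Mb over 20 autosomes + X. Males are hemizygous for X (stored as a
duplicated maternal haplotype, transmitted unrecombined to daughters only).
Uniform missingness can be injected to exercise QC; no mutation or
genotyping-error model is included.

What passing simulation tests show, and what they do not: the synthetic panel
reproduces the *structural* properties the colony's genotype analyses rest on
(drift-driven heterozygosity loss matching pedigree autozygosity, rising
between-line AMOVA/MDS separation under divergent selection, LD decaying
over Mb scales, ROH expansion). They cannot reproduce the colony's absolute
values (e.g. H₀ = 0.379 at G5, LD crossing r² = 0.3 at 3 Mb), which depend on
the real panel's ascertainment and the stock's true haplotype structure; the
original genotypes were never deposited.

## SNP-panel statistics

QC stages run in a fixed, recorded order: exact-duplicate columns (first kept)
→ missingness > 10% → Hardy–Weinberg exact test p < 0.001 (Levene/Haldane
conditional distribution via the standard recurrence, no mid-p) → *panel 1* →
windowed LD pruning (10-marker windows, step 2, drop the later-indexed marker
of any pair with r² > 0.05, composite genotype-correlation r²) → MAF < 5% →
*panel 2*. Every stage's removed + surviving counts reconcile; the
corresponding published stage arithmetic is internally inconsistent, so the
package reports its own counts only.

ROH are maximal runs of consecutive homozygous, non-missing calls (strictest
reading; any heterozygous or missing call breaks the run) with ≥4 markers and
density ≥ 1 marker per 500 kb; length is the bp span first→last marker,
1-based inclusive coordinates, and genome fraction divides by a configurable
genome size (default 2.75 Gb). With sparse demonstration panels the density
threshold should be relaxed proportionally (see `examples/popgen_panel.py`).

LD r² for unphased genotypes comes from two-locus EM haplotype frequencies
(only the double-heterozygote class is ambiguous); direct haplotype counting
is used when phased data are available and the two agree exactly on
unambiguous data. Decay curves average r² in 500 kb bins to 5 Mb; the
r² = 0.3 crossing is linearly interpolated between bin centers.

AMOVA partitions allele-indicator sums of squares among/within two groups per
locus and combines variance components as a ratio of sums across loci
(equivalent to a Weir–Cockerham-style FST without the within-individual
tier; verified against an independently coded θ on toy panels). IBD Z0/Z1/Z2
use the classic method-of-moments from IBS-state counts and allele
frequencies, projected onto the simplex; no small-sample corrections. Sex
inference thresholds X heterozygosity midway across the largest gap in the
sorted values — not midway between cluster means, which drifts toward the
larger cluster — and flags animals within a ±0.025 band (configurable) or
everything when the distribution is unimodal.

## Quantitative genetics

Phenotypes are strictly additive: y = Σ x_q a_q + N(0, σ²_E), with σ²_E
calibrated against the realized genetic variance of a founder panel so the
founder h² hits its target (h² = 0 means zero effects by construction).
The selection driver runs two lines from one shared founder pool (defaults:
186 founders, 13 families/line, litters of 8, 26 generations, 800 markers on
10 autosomes + X, 30 QTL, founder h² 0.4 — a desk-scale rendition of the
colony design) with within-family truncation selection and rotational
pairing. Under within-family selection the expected response per unit of
measured selection differential is (V_A/2)/(V_A/2 + V_E) — only the
Mendelian-sampling half of V_A segregates within families — not the
mass-selection h²; the simulator reproduces this quantitatively.

Animal-model REML rotates the phenotyped subset by the eigenvectors of its
relationship matrix (EMMA-style), profiles the likelihood down to h², and
maximizes by a 41-point grid scan plus bounded Brent refinement (xatol 1e-6);
the SE comes from the numerical curvature at the optimum and estimates are
clipped to [0, 1]. Midparent regression residualizes covariates first, groups
offspring by parent pair, and regresses family-mean residuals on midparent
residuals; under directional selection the generation trend must be included
among the covariates or it inflates the slope. The Castle–Wright estimator
uses the standard unlinked-equal-effect form; its known biases (linkage,
unequal effects, epistasis) make it an order-of-magnitude statistic, which is
how results are phrased.

Between-line divergence from by-sex summary tables uses sex-averaged means
for fold changes and, for SD units, a combined-sex SD reconstructed from
per-sex n/mean/SD by the two-component mixture variance — the only
convention that reconstructs a pooled SD from a by-sex table. Vertical
treadmill work is distance[m] × mass[g] × sin(15°) × 9.8/1000 joules.
Heritability of running distance is conventionally computed on log distance;
weight and work untransformed.

## Problem sizes and determinism

All stochastic components take explicit integer seeds (numpy Generator) and
are reproducible bit-for-bit for a given seed; CLI artifacts embed the seed
and package version in a manifest. Test and example problem sizes (hundreds
of markers, 8–26 generations, tens of seeds) are chosen as the smallest
scales at which the statistical assertions have adequate power; all scale up
linearly via configuration. Monte-Carlo tolerances are stated in SEM units
(usually 3) computed from the seeds actually run. Rate estimates from noisy
cohort means use geometric endpoint rates, which are near-unbiased where
mean-of-ratios estimators are not.

## Known limitations

No mutation, genotyping error beyond uniform missingness, crossover
interference, epistasis, maternal effects, or litter-size modeling; the
loader accepts out-of-schedule and substitute matings in recorded pedigrees,
but the idealized builder never generates them; haplotype phasing beyond
two-locus EM and genotype-based kinship beyond IBS/IBD moments are out of
scope. The recorded-colony acceptance analytics (animal-level pedigree file)
require the original supplementary data, which cannot ship with the package.
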