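# Methods

## Data model and scope

The package analyses haploid multilocus genotypes: one allele per SSR
locus (integer fragment sizes, binned upstream by the fragment-analysis
software) plus the mating-type idiomorph of a bipolar heterothallic
system. Coordinates are planar metres from a projected survey; the
package never touches latitude/longitude. Missing data are handled by
whole-sample exclusion: a record with any missing SSR or MAT call is
kept in the dataset but never enters a genetic analysis. This mirrors
how such surveys are scored — partial profiles cannot be assigned to an
MLG safely in a low-diversity panel. Per-site panel subsets are
supported (`Panel.subset`) because markers are sometimes dropped for a
tissue type or site; the active panel is whatever the records carry.

## MLG calling and the clonality test

MLG identity is the exact allele vector over all SSR loci plus MAT.
Two samples equal at every SSR but opposite at MAT are different
individuals by construction — the MAT locus is a marker for identity
but is excluded by default from frequency-based statistics (p_gen, uHe,
kinship, Φ_PT), because it is a two-state functional locus under
balancing selection, not a neutral microsatellite. A switch
(`include_mat`) exposes the alternative.

The probability that a given haploid profile arises from one sexual
event is `p_gen = ∏ℓ p(aℓ)` with allele frequencies taken from the
clone-corrected sample (one representative per MLG) by default —
frequencies from raw ramet counts would be dominated by the very clones
under test. A leave-one-MLG-out (round-robin) variant is provided
(`p_gen_round_robin`); unobservable alleles under leave-one-out receive
the smallest observable frequency.

For an MLG seen `n ≥ 2` times among `N` samples,
`P_sex = P[X ≥ n], X ~ Binomial(N, p_gen)` — the probability that the
repeats are independent sexual events. An alternative convention that
conditions on the first observation (`P[X ≥ n−1]` among `N−1`) is
available via `method="parks_werth"`. Significance is decided against a
Monte-Carlo null: `n_sim` (default 1000) datasets of `N` genotypes are
drawn locus-wise independently from the frequency table, the `P_sex`
values of every repeated profile they produce are pooled, and an
observed MLG is a *true clone* when its `P_sex` falls below the
α-quantile (default 0.05) of that pool. Ties resolve to non-significant
(conservative). Degenerate cases: with no polymorphic locus, or when
the null never produces a repeat, every observed repeat is flagged
significant. All Monte-Carlo operations take an explicit seed
(package default 1962, an arbitrary documented constant).

Clone correction keeps one representative per significant MLG, placed
at the arithmetic centroid of its ramets, and keeps *every* ramet of a
non-significant repeated MLG as a distinct genotype — a chance repeat
is treated as several individuals, not one.

## Diversity indices

`R = (G−1)/(N−1)`; unbiased Simpson `D* = 1 − Σnᵢ(nᵢ−1)/(N(N−1))`;
`uHe = n/(n−1)(1 − Σp²)` per locus, averaged over SSR loci. Evenness
`ED*` is `D*` rescaled between its minimum (G−1 singletons plus one
dominant clone) and maximum (counts as equal as possible) attainable at
the observed (N, G) — a Fager-type rescaling verified against
brute-force enumeration of all ramet-count compositions for N ≤ 8.
Published GenClone evenness values computed with that program's own
(unpublished) formula are therefore not expected to match digit-for-digit;
the index here is documented, bounded in [0, 1], and 1 exactly at equal
counts.

## Paternal inference and zygotes

Pooled ascospores carry both parental genomes, so a spore extract shows
1–2 alleles per locus. Inference is Mendelian subtraction: the paternal
allele is the non-maternal one, or the maternal allele when the locus
set is monomorphic; the paternal MAT is always the idiomorph opposite
the gleba's. A locus set lacking the maternal allele, or any set with
more than two alleles, rejects the fruitbody (contamination or a second
father — the model assumes one father per fruitbody). Rejected
fruitbodies are excluded from all zygote statistics, with a logged
reason.

`F_is = 1 − H̄ₒ/H̄ₑ` over polymorphic loci: Hₒ is the fraction of
heterozygous zygotes, Hₑ = 1 − Σp² from the pooled zygote alleles (two
per zygote), both unweighted means across loci, no small-sample
correction — this is the plain definition the statistic is usually
reported under for reconstructed zygotes. Hermaphrodites are MLGs whose
ramets appear in both roles; by default only significant (true-clone)
MLGs count, since a non-significant repeat shared across roles may be
two individuals.

## Spatial statistics

**Aggregation index.** `Ac = (P_nn − P_all)/(1 − P_all)`, with `P_nn`
the proportion of samples whose nearest neighbour shares their label
(ties averaged over co-nearest neighbours) and `P_all` the probability
that two random distinct samples share a label. The published
description of this index is verbal; this algebraic form is the one
that satisfies both printed anchors — expectation 0 under random
labelling and 1 when every nearest neighbour matches — and is flagged
here because other rescalings exist. Significance: one-sided
permutation of labels over fixed positions with add-one smoothing,
`p = (1 + #{Ac_perm ≥ Ac_obs})/(n_perm + 1)`.

**Loiselle kinship.** For haploid 0/1 allele indicators,
`F_ij = [Σℓ Σa ((xᵢ−p)(xⱼ−p) + p(1−p)/(n−1))] / Σℓ Σa p(1−p)`, with
frequencies from the analysed (clone-corrected) sample. The
`p(1−p)/(n−1)` term makes the all-pairs mean approximately zero, which
is the natural reference when frequencies are estimated from the sample
itself.

**Autocorrelation and Sp.** Distance classes default to 13 classes
with approximately equal pair counts (explicit edges accepted);
per-class two-sided p-values come from permuting spatial locations
among individuals. The regression behind `Sp = −b/(1−F₁)` uses
pair-level `F_ij` on ln(distance) (SPAGeDi's convention), excluding
zero-distance pairs; an optional distance cap restricts the regression
to the first metres, where maternal structure is typically steepest.

**Mantel.** Pearson correlation of off-diagonal entries with
simultaneous row/column permutation of one matrix, one-sided for
positive isolation by distance; genetic distance defaults to the count
of differing loci. The implementation carries its own seeded RNG; the
test suite cross-checks the statistic against scikit-bio's `mantel`.

## Φ_PT

Squared genetic distance = number of differing SSR loci. The AMOVA
partitions `SS_total = Σᵢ<ⱼ d²ᵢⱼ/N` into within-group terms
`Σ d²/n_g`, giving `σ²_within = MS_within` and
`σ²_among = (MS_among − MS_within)/n₀` with the standard unequal-size
coefficient `n₀`. Negative among-group estimates are truncated to zero
(flagged in the components), so `Φ_PT ∈ [0, 1]`. Pairwise values are
computed per group pair with label-permutation p-values.

## qPCR quantification

`efficiency = 10^(−1/slope) − 1`; a curve is reliable iff R² ≥ 0.997
and efficiency ∈ [90%, 110%]. Quantification back-transforms each Cq of
a triplicate through the inverse curve, so the CV (sd/mean × 100) is
computed on copy numbers, not Cq values — Cq is log-scale and its CV
would understate the variation that matters; the flagging threshold
(default 15%) is configurable because no standard cutoff exists.
Scaling to copies per g dried soil uses the encoded extraction defaults
(250 mg soil, 100 µl eluate, 5 µl template, 1:10 dilution), all
overridable. Mass conversion: 9.37×10¹⁰ ITS copies per g dried
mycelium. Ring geometry: the centre defaults to a least-squares circle
fit (centroid fallback below 6 points); the growth rate is the
least-squares slope of mean annual radius on calendar year, and age is
`⌊radius/rate⌋` whole years.

## Synthetic generators

The generators encode the population structure the analysis assumes,
so that every statistic can be validated against a known truth.

*Fairy ring* (`RingSimConfig`): fruitbodies per year on an annulus of
radius `r₀ + g·t` (defaults 3.7 m + 0.30 m/yr, radial σ = 0.15 m,
205 fruitbodies over 4 years); the maternal genotype is a dominant
genet with frequency 0.976 (a rare second genet takes the rest);
fathers are single meiotic recombinants of the maternal genome and a
pool haplotype, with a small probability (0.04) of re-using an earlier
father (persistent paternal individuals); spore extracts are the
per-locus union of the two parental alleles, and only a fraction
(default 0.32) of fruitbodies yield a complete spore genotype —
ascospore DNA is sparse and most extracts fail in practice, which is
why paternal sample sizes are far below maternal ones.

*Allele frequencies*: per-locus allele counts in 1–8 with 5 of 14 loci
monomorphic, skewed Dirichlet frequencies so one allele usually
dominates — the low-diversity regime of isolated natural sites. A
consequence worth noting: chance repeats of common paternal profiles do
occur, exactly as in real low-diversity panels, and the P_sex machinery
is what separates them from clones.

*Multi-genet site* (`MultiGenetConfig`): genets from a Thomas-type
clustered point process; haplotypes propagated from already-placed
neighbours chosen with weight `exp(−d/scale)` plus per-locus
resampling, which yields isolation by distance; mating types assigned
by nearest patch seed (patch scale configurable); fathers drawn among
opposite-MAT genets with weight `exp(−d/mating_scale)`. The panmixia
limit (`mating_scale → ∞`) drives F_is to zero; tight kernels inflate
it — both checked in tests.

*ECM/soil* (`simulate_ecm_and_soil`): radial transects with cores every
0.30 m; the soil ITS field is a Gaussian ridge on the current ring
radius with a decayed interior and an optional interior patch of the
opposite mating type spanning five consecutive cores; ECM root tips
appear where the field is high and always carry the dominant maternal
genet (maternal-only root colonisation); Cq triplicates come from a
configured standard curve with Gaussian noise (σ = 0.12 cycles).

What the generators do *not* emulate: genotyping error and allele
dropout, multi-father fruitbodies, temporal change in allele
frequencies, anisotropic dispersal, and real soil-mycelium dynamics
inside the ring (the interior-decay profile is phenomenological). Tests
passing on synthetic data therefore validate the estimators under the
model's assumptions, not robustness to those artefacts.

## Problem sizes and numerical choices

Default test and acceptance runs use the configured study shapes
(~200 samples per site, 50 replicate rings of ~280 fruitbodies,
permutation counts 200–2000 in tests versus the 999–10000 defaults of
the API). Exhaustive-permutation oracles are used up to 8 points
(aggregation), 4 individuals (Mantel) and 7 genotypes (Φ_PT), where
full enumeration is exact and cheap. Add-one smoothing is applied to
every permutation p-value, so p > 0 always. Floating-point guards: ring
age adds 1e-9 before flooring so exact radius/rate ratios survive
binary representation; Ac nearest-neighbour ties are averaged rather
than broken arbitrarily.
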