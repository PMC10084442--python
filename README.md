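# clonering

Clonal and spatial population genetics for heterothallic truffle-like
fungi genotyped at microsatellite (SSR) panels plus the mating-type
locus.

## The problem

Truffles (e.g. the Burgundy truffle *Tuber aestivum*) are heterothallic
ascomycetes: a haploid mycelium carries one of two mating-type
idiomorphs (*MAT 1-1* / *MAT 1-2*) and needs a partner of the opposite
type to fruit. The maternal partner builds the fruitbody tissue (gleba)
and colonises ectomycorrhizal root tips; the paternal partner only
contributes genes and can be recovered by genotyping pooled ascospores
and subtracting the maternal haplotype. Field surveys of such
populations ask: which samples are ramets of one genet (clone) rather
than chance repeats of a common genotype? How diverse, persistent and
spatially structured are maternal and paternal individuals? How much
mycelium sits in the soil, and does a fruiting ring expand over time?

`clonering` implements that analysis chain for haploid multilocus
genotype (MLG) data, and ships seeded generators of synthetic fairy-ring
and multi-genet sites so every stage is testable without field data.

## What it computes

- **MLG calling and clonality** — exact-match MLG assignment over all
  SSR loci plus MAT; `p_gen = ∏ℓ p(aℓ)`; the clonality test
  `P_sex = P[X ≥ n]` with `X ~ Bin(N, p_gen)` judged against a
  Monte-Carlo null (simulated datasets of N independent genotypes);
  clone correction collapsing each significant genet to its ramet
  centroid.
- **Diversity** — genotypic richness `R = (G−1)/(N−1)`, unbiased Simpson
  diversity `D* = 1 − Σ nᵢ(nᵢ−1)/(N(N−1))`, Simpson evenness `ED*`
  (D* rescaled between its attainable extremes at fixed N, G), unbiased
  gene diversity `uHe = n/(n−1)(1 − Σp²)`.
- **Mating system** — paternal inference by Mendelian subtraction from
  spore-pool allele sets, zygote reconstruction, hermaphrodite detection
  (one genotype in both roles), persistence tables, and the zygote
  inbreeding coefficient `F_is = 1 − H̄ₒ/H̄ₑ`.
- **Spatial structure** — aggregation index
  `Ac = (P_nn − P_all)/(1 − P_all)` with label-permutation tests, clonal
  subrange, Mantel isolation-by-distance, Loiselle kinship `F_ij` for
  haploid data, kinship autocorrelation by distance class and the
  `Sp = −b/(1 − F₁)` statistic.
- **Differentiation** — haploid AMOVA `Φ_PT` with permutation p-values.
- **Soil qPCR** — standard-curve fit and QC (R² ≥ 0.997, efficiency
  90–110%), absolute ITS copy quantification from Cq triplicates,
  conversion 9.37×10¹⁰ ITS copies = 1 g dried mycelium, mating-type
  co-detection along transects, fairy-ring growth rate and age.

## Worked example

Simulate a fairy-ring site (205 gleba samples over four years, one
dominant maternal genet on an annulus expanding 0.30 m/yr) and run the
pipeline:

```python
from clonering import *

ds, spores, truth = simulate_fairy_ring(RingSimConfig(seed=11))
recs = ds.resolved_records
mlgs = assign_mlgs(recs)
freqs = allele_frequencies(recs, clone_corrected=True)
p_sex_significance(mlgs, freqs, seed=11)
s = diversity_summary(mlgs)
print(f"N={s.n_samples}  G={s.n_mlgs}  R={s.richness:.3f}  "
      f"D*={s.simpson_d:.3f}  ED*={s.evenness:.3f}  uHe={s.uhe_mean:.3f}")
dom = max(mlgs, key=lambda m: m.n_ramets)
print(f"dominant MLG: {dom.mlg_id}  ramets={dom.n_ramets}  P_sex={dom.p_sex:.3g}  "
      f"significant={dom.significant}  subrange={dom.subrange:.2f} m")
zyg = build_zygotes({r.sample_id: r.genotype for r in recs}, spores)
print(f"zygotes={len(zyg)}  F_is={fis(zyg):.3f}")
by_year = {}
for r in ds.records:
    by_year.setdefault(r.year, []).append(r.position)
g = ring_growth_rate(by_year)
print(f"ring growth rate = {g['rate_m_per_yr']:.3f} m/yr -> "
      f"age at 4 m radius = {ring_age(4.0, g['rate_m_per_yr'])} yr")
```

Output:

```
N=205  G=2  R=0.005  D*=0.019  ED*=0.020  uHe=0.286
dominant MLG: MLG001  ramets=203  P_sex=6.73e-241  significant=True  subrange=9.73 m
zygotes=60  F_is=-0.050
ring growth rate = 0.306 m/yr -> age at 4 m radius = 13 yr
```

Reading: the 205 fruitbodies collapse to two maternal genets
(richness `R = 1/204 ≈ 0.005`); the dominant genet's `P_sex` is
vanishingly small, so its 203 ramets are a true clone spanning 9.7 m.
`F_is ≈ 0` says the reconstructed zygotes look like random mating, and
the estimated radial outgrowth (0.306 m/yr, true value 0.30) dates a
4 m ring at 13 years.

A thin CLI wraps the same functions:
`clonering simulate ring --seed 11 --out ring.csv`, then
`clonering mlg ring.csv`, `clonering spatial ring.csv`,
`clonering validate ring.csv`, `clonering export-genepop ring.csv out.gen`.

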