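"""Multilocus genotype (MLG) calling, clonality significance and diversity.

A genet — one genetic individual — is approximated by an MLG: the exact
combination of alleles over every SSR locus plus the mating-type
idiomorph.  Repeated observations of one MLG may be true clones (ramets
of one genet) or independent sexual events that happened to produce the
same profile.  P_sex quantifies the latter probability: for an MLG with
genotype probability p_gen observed n times among N samples,

    P_sex = P[X >= n],  X ~ Binomial(N, p_gen),

and significance is judged against a Monte-Carlo null distribution of
P_sex values from datasets of N independently drawn genotypes.  Clone
correction then collapses each significant MLG to a single representative
placed at the centroid of its ramets, while ramets of non-significant
repeated MLGs are kept as distinct genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import Dataset, HaploidGenotype, SampleRecord


@dataclass
class MLG:
    """A candidate genet: the set of samples sharing one exact profile."""

    mlg_id: str
    genotype: HaploidGenotype
    ramets: list  # of SampleRecord
    p_gen: Optional[float] = None
    p_sex: Optional[float] = None
    significant: bool = False
    roles: set = field(default_factory=set)

    @property
    def n_ramets(self) -> int:
        return len(self.ramets)

    @property
    def years(self) -> set:
        return {r.year for r in self.ramets}

    @property
    def centroid(self) -> Optional[tuple]:
        """Arithmetic mean of ramet coordinates; None if none are placed."""
        pts = [r.position for r in self.ramets if r.position is not None]
        if not pts:
            return None
        xs, ys = zip(*pts)
        return (float(np.mean(xs)), float(np.mean(ys)))

    @property
    def subrange(self) -> float:
        """Largest pairwise distance between placed ramets (0 for singletons)."""
        pts = [r.position for r in self.ramets if r.position is not None]
        if len(pts) < 2:
            return 0.0
        arr = np.asarray(pts, dtype=float)
        from scipy.spatial.distance import pdist

        return float(pdist(arr).max())


def assign_mlgs(records: Sequence[SampleRecord]) -> list:
    """Partition resolved records into exact-match MLGs.

    Identity is the full SSR allele vector plus the mating type; ids are
    assigned in first-seen sample order (MLG001, MLG002, ...).
    """
    lengths = {len(r.genotype.alleles) for r in records if r.genotype is not None}
    if len(lengths) > 1:
        raise ValueError("records mix panels of different length")
    groups: dict = {}
    order: list = []
    for rec in records:
        if rec.genotype is None:
            continue
        key = rec.genotype.key
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    mlgs = []
    for i, key in enumerate(order):
        ramets = groups[key]
        mlgs.append(
            MLG(
                mlg_id=f"MLG{i + 1:03d}",
                genotype=ramets[0].genotype,
                ramets=ramets,
                roles={_role_of(r) for r in ramets} - {None},
            )
        )
    return mlgs


def _role_of(rec: SampleRecord) -> Optional[str]:
    # gleba and ECM root tips carry the maternal partner; a paternal role
    # is attached to inferred-father records by the mating_system module.
    if rec.role in ("gleba", "ecm"):
        return "maternal"
    if rec.role == "ascospore":
        return "paternal"
    return None


def allele_frequencies(
    records: Sequence[SampleRecord],
    *,
    clone_corrected: bool = False,
    include_mat: bool = False,
) -> dict:
    """Per-locus allele frequencies from resolved records.

    ``clone_corrected=True`` counts one representative per MLG instead of
    every ramet, removing the weight of large clones.  The MAT locus is
    excluded unless ``include_mat``; it is not a neutral SSR marker.
    """
    resolved = [r for r in records if r.genotype is not None]
    if not resolved:
        raise ValueError("no resolved records to compute frequencies from")
    if clone_corrected:
        reps: dict = {}
        for rec in resolved:
            reps.setdefault(rec.genotype.key, rec)
        resolved = list(reps.values())
    n_loci = len(resolved[0].genotype.alleles)
    freqs: dict = {}
    n = len(resolved)
    for i in range(n_loci):
        counts: dict = {}
        for rec in resolved:
            a = rec.genotype.alleles[i]
            counts[a] = counts.get(a, 0) + 1
        freqs[i] = {a: c / n for a, c in sorted(counts.items())}
    if include_mat:
        counts = {}
        for rec in resolved:
            counts[rec.genotype.mat] = counts.get(rec.genotype.mat, 0) + 1
        freqs["MAT"] = {m: c / n for m, c in sorted(counts.items())}
    return freqs


def p_gen(genotype: HaploidGenotype, freqs: dict, *, include_mat: bool = False) -> float:
    """Probability of drawing this haploid multilocus profile at random.

    Product over loci of the frequency of the carried allele.  Alleles
    with zero estimated frequency (possible under leave-one-out schemes)
    are substituted by the smallest observable frequency at that locus.
    """
    p = 1.0
    n_loci = len(genotype.alleles)
    for i in range(n_loci):
        locus_freqs = freqs[i]
        f = locus_freqs.get(genotype.alleles[i], 0.0)
        if f <= 0.0:
            f = min(v for v in locus_freqs.values() if v > 0)
        p *= f
    if include_mat and "MAT" in freqs:
        f = freqs["MAT"].get(genotype.mat, 0.0)
        if f <= 0.0:
            f = min(v for v in freqs["MAT"].values() if v > 0)
        p *= f
    return p


def p_gen_round_robin(
    genotype: HaploidGenotype, records: Sequence[SampleRecord]
) -> float:
    """Leave-one-MLG-out variant of :func:`p_gen`.

    Frequencies at each locus are recomputed from clone-corrected
    representatives excluding the focal genotype's own MLG; alleles then
    unobserved get the smallest observable frequency 1/n.
    """
    reps: dict = {}
    for rec in records:
        if rec.genotype is not None:
            reps.setdefault(rec.genotype.key, rec.genotype)
    others = [g for key, g in reps.items() if key != genotype.key]
    if not others:
        raise ValueError("round-robin needs at least one other MLG")
    n = len(others)
    p = 1.0
    for i, allele in enumerate(genotype.alleles):
        count = sum(1 for g in others if g.alleles[i] == allele)
        p *= count / n if count else 1.0 / (n + 1)
    return p


def p_sex(
    pgen: float, n_copies: int, n_samples: int, *, method: str = "binomial"
) -> float:
    """Tail probability that >= n_copies of a profile with genotype
    probability ``pgen`` occur among ``n_samples`` independent sexual
    events.  Undefined for singletons; returns 1.0 then.

    ``method="binomial"`` evaluates P[X >= n], X ~ Bin(N, pgen);
    ``method="parks_werth"`` conditions on the first observation and
    evaluates P[X >= n-1], X ~ Bin(N-1, pgen).
    """
    if not 0.0 < pgen <= 1.0:
        raise ValueError("p_gen must be in (0, 1]")
    if n_copies < 2:
        return 1.0
    if n_copies > n_samples:
        raise ValueError("n_copies cannot exceed the sample size")
    # P[X >= k] = sf(k - 1)
    if method == "binomial":
        return float(stats.binom.sf(n_copies - 1, n_samples, pgen))
    if method == "parks_werth":
        return float(stats.binom.sf(n_copies - 2, n_samples - 1, pgen))
    raise ValueError(f"unknown P_sex method {method!r}")


def p_sex_significance(
    mlgs: Sequence[MLG],
    freqs: dict,
    *,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 1962,
) -> list:
    """Annotate MLGs with p_gen, P_sex and a Monte-Carlo clonality flag.

    The null model draws ``n_sim`` datasets of N genotypes, locus-wise
    independently from ``freqs``, and pools the P_sex values of every
    repeated profile they contain.  An observed repeated MLG is a
    significant (true) clone when its P_sex lies below the alpha-quantile
    of that null pool; ties resolve to non-significant.  With no
    polymorphic locus the null is degenerate and every repeated MLG is
    flagged significant.
    """
    n_samples = sum(m.n_ramets for m in mlgs)
    rng = np.random.default_rng(seed)
    ssr_keys = [k for k in freqs if k != "MAT"]
    polymorphic = [k for k in ssr_keys if len(freqs[k]) > 1]

    for m in mlgs:
        m.p_gen = p_gen(m.genotype, freqs)
        m.p_sex = p_sex(m.p_gen, m.n_ramets, n_samples) if m.n_ramets >= 2 else 1.0

    repeated = [m for m in mlgs if m.n_ramets >= 2]
    if not repeated:
        return list(mlgs)
    if not polymorphic:
        for m in repeated:
            m.significant = True
        return list(mlgs)

    null_psex = _null_psex_pool(freqs, ssr_keys, n_samples, n_sim, rng)
    if null_psex.size == 0:
        # the null never produced a repeat: any observed repeat is rarer
        for m in repeated:
            m.significant = True
        return list(mlgs)
    crit = float(np.quantile(null_psex, alpha))
    for m in repeated:
        m.significant = bool(m.p_sex < crit)
    return list(mlgs)


def _null_psex_pool(freqs, ssr_keys, n_samples, n_sim, rng) -> np.ndarray:
    alleles_per_locus = []
    probs_per_locus = []
    for k in ssr_keys:
        items = sorted(freqs[k].items())
        alleles_per_locus.append(np.array([a for a, _ in items]))
        probs_per_locus.append(np.array([p for _, p in items]))
    pool = []
    for _ in range(n_sim):
        draws = np.column_stack(
            [
                rng.choice(a, size=n_samples, p=p)
                for a, p in zip(alleles_per_locus, probs_per_locus)
            ]
        )
        profiles, counts = np.unique(draws, axis=0, return_counts=True)
        for profile, count in zip(profiles, counts):
            if count < 2:
                continue
            pg = 1.0
            for k, allele in zip(ssr_keys, profile):
                pg *= freqs[k][int(allele)]
            pool.append(p_sex(pg, int(count), n_samples))
    return np.asarray(pool)


def clone_correct(mlgs: Sequence[MLG]) -> list:
    """Clone-corrected sample set.

    Each significant MLG contributes one representative record placed at
    the centroid of its ramets; every ramet of a non-significant repeated
    MLG (and every singleton) is retained as a distinct genotype.
    Returned entries are (genotype, position, mlg_id, source_record)
    tuples; position is None when no ramet is placed.
    """
    out = []
    for m in mlgs:
        if m.significant and m.n_ramets >= 2:
            out.append((m.genotype, m.centroid, m.mlg_id, m.ramets[0]))
        else:
            for rec in m.ramets:
                out.append((m.genotype, rec.position, m.mlg_id, rec))
    return out


# ---------------------------------------------------------------------------
# genotypic and genetic diversity indices


def genotypic_richness(n_samples: int, n_mlgs: int) -> float:
    """R = (G - 1)/(N - 1): 0 when one clone dominates everything,
    1 when every sample is its own genotype."""
    if n_samples < 2:
        raise ValueError("richness needs at least 2 samples")
    if n_mlgs < 1 or n_mlgs > n_samples:
        raise ValueError("need 1 <= G <= N")
    return (n_mlgs - 1) / (n_samples - 1)


def simpson_diversity(ramet_counts: Sequence[int]) -> float:
    """Unbiased Simpson index on MLG ramet counts:
    D* = 1 - sum n_i (n_i - 1) / (N (N - 1))."""
    counts = np.asarray(list(ramet_counts), dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("Simpson diversity needs N >= 2")
    return float(1.0 - (counts * (counts - 1)).sum() / (n * (n - 1)))


def _extreme_counts(n: int, g: int):
    skewed = [1] * (g - 1) + [n - g + 1]
    base, extra = divmod(n, g)
    even = [base + 1] * extra + [base] * (g - extra)
    return skewed, even


def simpson_evenness(ramet_counts: Sequence[int]) -> float:
    """Simpson evenness ED*: D* rescaled between its attainable minimum
    (G-1 singletons plus one dominant clone) and maximum (equal counts)
    at the observed N and G; 1 means all MLGs equally frequent.
    """
    counts = [int(c) for c in ramet_counts]
    n, g = sum(counts), len(counts)
    if g < 2:
        raise ValueError("evenness undefined for a single MLG")
    d = simpson_diversity(counts)
    skewed, even = _extreme_counts(n, g)
    d_min = simpson_diversity(skewed)
    d_max = simpson_diversity(even)
    if d_max == d_min:  # e.g. all-singleton data: every composition equal
        return 1.0
    return float((d - d_min) / (d_max - d_min))


def unbiased_gene_diversity(freqs: dict, n: int) -> dict:
    """Per-locus unbiased gene diversity uHe = n/(n-1) (1 - sum p^2)
    and its mean over SSR loci."""
    if n < 2:
        raise ValueError("uHe needs n >= 2")
    per_locus = {}
    for k, locus_freqs in freqs.items():
        if k == "MAT":
            continue
        p = np.array(list(locus_freqs.values()))
        per_locus[k] = float(n / (n - 1) * (1.0 - (p**2).sum()))
    mean = float(np.mean(list(per_locus.values()))) if per_locus else math.nan
    return {"per_locus": per_locus, "mean": mean}


@dataclass
class DiversitySummary:
    """Row of a genotypic-diversity table: N, G, R, D*, ED*, uHe."""

    n_samples: int
    n_mlgs: int
    richness: float
    simpson_d: float
    evenness: Optional[float]
    uhe_mean: Optional[float]


def diversity_summary(
    mlgs: Sequence[MLG], *, clone_corrected_uhe: bool = True
) -> DiversitySummary:
    """Summarise a set of MLGs as one diversity-table row.

    uHe uses clone-corrected allele frequencies by default (one
    representative per MLG), matching how gene diversity is reported for
    clonal organisms.
    """
    counts = [m.n_ramets for m in mlgs]
    n, g = sum(counts), len(counts)
    reps = [m.ramets[0] for m in mlgs]
    uhe = None
    if g >= 2:
        freqs = allele_frequencies(reps) if clone_corrected_uhe else allele_frequencies(
            [r for m in mlgs for r in m.ramets]
        )
        uhe = unbiased_gene_diversity(freqs, g if clone_corrected_uhe else n)["mean"]
    return DiversitySummary(
        n_samples=n,
        n_mlgs=g,
        richness=genotypic_richness(n, g) if n >= 2 else math.nan,
        simpson_d=simpson_diversity(counts) if n >= 2 else math.nan,
        evenness=simpson_evenness(counts) if g >= 2 else None,
        uhe_mean=uhe,
    )
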