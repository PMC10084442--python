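"""Synthetic truffle-population generators.

Two site archetypes are generated, mirroring the structure of natural
Burgundy-truffle populations:

* a *fairy-ring* site: one dominant maternal genet whose fruiting front
  expands radially (~30 cm/yr default), a rare second maternal genet,
  and many singleton paternal partners with annual turnover arising as
  recombinant ascospore offspring;
* a *multi-genet* site: tens of genets placed by a clustered point
  process, haplotypes propagated from spatial neighbours so that
  isolation by distance emerges, mating types laid out in patches, and
  fathers drawn by a distance-decaying mating kernel.

Both emit the same CSV-ready objects the readers consume, plus a truth
record sufficient to score every downstream inference.  All draws come
from a single seeded generator: a fixed seed reproduces the dataset
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mating import SporeExtractProfile
from .qpcr import StandardCurve
from .types import (
    MAT1_1,
    MAT1_2,
    Dataset,
    HaploidGenotype,
    Locus,
    Panel,
    SampleRecord,
    opposite_mat,
)

# ---------------------------------------------------------------------------
# allele-frequency profiles


def low_diversity_frequencies(
    rng: np.random.Generator,
    *,
    n_loci: int = 14,
    n_monomorphic: int = 5,
    max_alleles: int = 8,
    concentration: float = 0.4,
) -> list:
    """Per-locus allele frequencies with low diversity.

    Allele counts per locus range from 1 to ``max_alleles`` with
    ``n_monomorphic`` monomorphic loci; polymorphic loci get skewed
    Dirichlet frequencies so one allele usually dominates.  Allele
    labels are plausible fragment sizes (base pairs).
    """
    mono = set(rng.choice(n_loci, size=n_monomorphic, replace=False).tolist())
    freqs = []
    for i in range(n_loci):
        base = 100 + 14 * i
        if i in mono:
            freqs.append({base: 1.0})
            continue
        k = int(rng.integers(2, max_alleles + 1))
        p = np.sort(rng.dirichlet([concentration] * k))[::-1]
        p = p / p.sum()
        freqs.append({base + 2 * j: float(p[j]) for j in range(k)})
    return freqs


def _draw_haplotype(rng: np.random.Generator, freqs: Sequence[dict]) -> tuple:
    alleles = []
    for locus_freqs in freqs:
        items = sorted(locus_freqs.items())
        a = [x for x, _ in items]
        p = np.array([x for _, x in items])
        alleles.append(int(rng.choice(a, p=p / p.sum())))
    return tuple(alleles)


def _recombine(rng: np.random.Generator, h1: tuple, h2: tuple) -> tuple:
    """One meiotic recombinant: independent locus assortment."""
    pick = rng.integers(0, 2, size=len(h1))
    return tuple(h1[i] if pick[i] == 0 else h2[i] for i in range(len(h1)))


def panel_for(freqs: Sequence[dict], *, prefix: str = "ssr") -> Panel:
    loci = tuple(
        Locus(f"{prefix}{i + 1:02d}", "SSR", frozenset(f.keys()))
        for i, f in enumerate(freqs)
    )
    return Panel(loci)


# ---------------------------------------------------------------------------
# fairy-ring site


@dataclass
class RingSimConfig:
    """Single-genet fairy-ring site.

    Defaults describe a ring whose fruiting front expands 0.30 m/yr with
    0.15 m radial scatter, a dominant maternal genet carrying ~97.6% of
    fruitbodies, and paternal partners that are almost always singletons
    (small persistence probability lets a few fathers recur).
    """

    seed: int = 1962
    years: tuple = (2016, 2017, 2018, 2019)
    center: tuple = (0.0, 0.0)
    initial_radius: float = 3.7
    growth_rate: float = 0.30
    annulus_sd: float = 0.15
    fruitbodies_per_year: tuple = (52, 51, 51, 51)
    n_loci: int = 14
    n_monomorphic: int = 5
    max_alleles: int = 8
    dominant_fraction: float = 0.976
    paternal_persistence_prob: float = 0.04
    hermaphrodite_rate: float = 0.0
    #: fraction of fruitbodies whose pooled-spore extract genotypes
    #: completely (ascospore DNA is sparse; most extracts fail)
    spore_success_rate: float = 0.32
    maternal_mat: str = MAT1_1
    site: str = "RING"

    def __post_init__(self):
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if len(self.fruitbodies_per_year) != len(self.years):
            raise ValueError("fruitbodies_per_year must match years")
        if sum(self.fruitbodies_per_year) == 0:
            raise ValueError("config generates zero fruitbodies")
        if not 0.0 <= self.dominant_fraction <= 1.0:
            raise ValueError("dominant_fraction must be in [0,1]")


def simulate_fairy_ring(cfg: RingSimConfig):
    """Generate a fairy-ring dataset.

    Returns ``(dataset, spore_profiles, truth)``: gleba records on the
    expanding annulus, one pooled-spore profile per fruitbody, and a
    truth record with every parent assignment and the generating
    parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = low_diversity_frequencies(
        rng,
        n_loci=cfg.n_loci,
        n_monomorphic=cfg.n_monomorphic,
        max_alleles=cfg.max_alleles,
    )
    panel = panel_for(freqs)
    dominant = HaploidGenotype(_draw_haplotype(rng, freqs), cfg.maternal_mat)
    # the minor maternal genet differs at >=1 polymorphic locus
    minor = dominant
    for _ in range(200):
        cand = HaploidGenotype(_draw_haplotype(rng, freqs), cfg.maternal_mat)
        if cand.key != dominant.key:
            minor = cand
            break

    records, spores, fathers = [], [], {}
    persistent_pool: list = []
    cx, cy = cfg.center
    fid = 0
    for t, (year, n_fb) in enumerate(zip(cfg.years, cfg.fruitbodies_per_year)):
        radius = cfg.initial_radius + cfg.growth_rate * t
        for _ in range(n_fb):
            fid += 1
            sid = f"{cfg.site}-{year}-{fid:04d}"
            theta = rng.uniform(0, 2 * np.pi)
            r = radius + rng.normal(0.0, cfg.annulus_sd)
            x, y = cx + r * np.cos(theta), cy + r * np.sin(theta)
            maternal = dominant if rng.random() < cfg.dominant_fraction else minor
            if persistent_pool and rng.random() < cfg.paternal_persistence_prob:
                paternal = persistent_pool[rng.integers(len(persistent_pool))]
            else:
                # germinating ascospore: recombinant of the resident
                # maternal genome and a pool haplotype
                pool = _draw_haplotype(rng, freqs)
                paternal = HaploidGenotype(
                    _recombine(rng, maternal.alleles, pool),
                    opposite_mat(maternal.mat),
                )
                persistent_pool.append(paternal)
            records.append(
                SampleRecord(sid, cfg.site, year, "gleba", x, y, maternal)
            )
            if rng.random() < cfg.spore_success_rate:
                spores.append(
                    SporeExtractProfile(
                        fruitbody_id=sid,
                        allele_sets=tuple(
                            frozenset((m, p))
                            for m, p in zip(maternal.alleles, paternal.alleles)
                        ),
                        mat11_present=True,
                        mat12_present=True,
                    )
                )
            fathers[sid] = paternal

    truth = {
        "config": cfg,
        "allele_frequencies": freqs,
        "dominant_maternal": dominant,
        "minor_maternal": minor,
        "father_by_fruitbody": fathers,
        "radius_by_year": {
            y: cfg.initial_radius + cfg.growth_rate * t
            for t, y in enumerate(cfg.years)
        },
    }
    return Dataset(panel, records), spores, truth


# ---------------------------------------------------------------------------
# multi-genet site


@dataclass
class MultiGenetConfig:
    """Multi-genet site with isolation by distance and patchy mating types.

    ``relatedness_scale`` controls haplotype propagation between
    neighbouring genets (small = strong local relatedness),
    ``mating_scale`` the distance-decaying father choice (small = local
    fertilization), ``mat_patch_scale`` the size of same-mating-type
    patches.
    """

    seed: int = 1962
    extent: float = 200.0
    n_genets: int = 60
    n_clusters: int = 8
    cluster_sd: float = 8.0
    relatedness_scale: float = 15.0
    resample_prob: float = 0.15
    mating_scale: float = 10.0
    mat_patch_scale: float = 40.0
    n_loci: int = 14
    n_monomorphic: int = 2
    max_alleles: int = 8
    years: tuple = (2011, 2013, 2019)
    fruitbodies_per_year: tuple = (33, 39, 31)
    hermaphrodite_rate: float = 0.035
    site: str = "SITE"

    def __post_init__(self):
        for name in ("relatedness_scale", "mating_scale", "mat_patch_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.fruitbodies_per_year) != len(self.years):
            raise ValueError("fruitbodies_per_year must match years")


def _propagate_haplotypes(rng, positions, freqs, scale, resample_prob):
    """Assign genet haplotypes by neighbour propagation, yielding IBD.

    Genets are processed in random order: each copies the haplotype of
    an already-placed genet chosen with probability exp(-d/scale), then
    resamples each locus from the site pool with ``resample_prob``.
    """
    n = len(positions)
    order = rng.permutation(n)
    haplos: dict = {}
    placed: list = []
    for g in order:
        if not placed:
            h = list(_draw_haplotype(rng, freqs))
        else:
            d = np.hypot(
                positions[placed, 0] - positions[g, 0],
                positions[placed, 1] - positions[g, 1],
            )
            w = np.exp(-d / scale)
            w = w / w.sum()
            parent = placed[rng.choice(len(placed), p=w)]
            h = list(haplos[parent])
            for i in range(len(h)):
                if rng.random() < resample_prob:
                    h[i] = _draw_haplotype(rng, [freqs[i]])[0]
        haplos[g] = tuple(h)
        placed.append(g)
    return [haplos[g] for g in range(n)]


def _patchy_mats(rng, positions, patch_scale):
    """Mating types from nearest patch seed; seeds alternate idiomorphs."""
    extent = positions.max(axis=0) - positions.min(axis=0)
    n_seeds = max(2, int(np.ceil(extent.max() / patch_scale)) ** 2)
    seeds = rng.uniform(positions.min(axis=0), positions.max(axis=0), size=(n_seeds, 2))
    seed_mats = [MAT1_1 if i % 2 == 0 else MAT1_2 for i in range(n_seeds)]
    mats = []
    for p in positions:
        d = np.hypot(seeds[:, 0] - p[0], seeds[:, 1] - p[1])
        mats.append(seed_mats[int(np.argmin(d))])
    if len(set(mats)) < 2:  # degenerate layout: force both types present
        mats[0] = opposite_mat(mats[0])
    return mats


def simulate_multigenet_site(cfg: MultiGenetConfig):
    """Generate a multi-genet site dataset.

    Returns ``(dataset, spore_profiles, truth)``.  Gleba records carry
    the maternal genet's haplotype at a fruitbody position near the
    genet; fathers are genets of opposite mating type drawn with weight
    exp(-d/mating_scale) (hermaphroditism emerges whenever a genet acts
    in both roles).
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = low_diversity_frequencies(
        rng,
        n_loci=cfg.n_loci,
        n_monomorphic=cfg.n_monomorphic,
        max_alleles=cfg.max_alleles,
    )
    panel = panel_for(freqs)

    # Thomas-type clustered genet positions
    parents = rng.uniform(0, cfg.extent, size=(cfg.n_clusters, 2))
    assignment = rng.integers(0, cfg.n_clusters, size=cfg.n_genets)
    positions = parents[assignment] + rng.normal(0, cfg.cluster_sd, size=(cfg.n_genets, 2))
    positions = np.clip(positions, 0, cfg.extent)

    haplos = _propagate_haplotypes(
        rng, positions, freqs, cfg.relatedness_scale, cfg.resample_prob
    )
    mats = _patchy_mats(rng, positions, cfg.mat_patch_scale)
    genotypes = [HaploidGenotype(h, m) for h, m in zip(haplos, mats)]

    records, spores, truth_parents = [], [], {}
    fid = 0
    for year, n_fb in zip(cfg.years, cfg.fruitbodies_per_year):
        mothers = rng.integers(0, cfg.n_genets, size=n_fb)
        for mother in mothers:
            fid += 1
            sid = f"{cfg.site}-{year}-{fid:04d}"
            mx, my = positions[mother] + rng.normal(0, 1.0, size=2)
            maternal = genotypes[mother]
            opposite = [
                j
                for j in range(cfg.n_genets)
                if mats[j] != maternal.mat and j != mother
            ]
            if not opposite:
                continue
            d = np.hypot(
                positions[opposite, 0] - positions[mother][0],
                positions[opposite, 1] - positions[mother][1],
            )
            w = np.exp(-d / cfg.mating_scale)
            w = w / w.sum()
            father = opposite[rng.choice(len(opposite), p=w)]
            paternal = genotypes[father]
            records.append(
                SampleRecord(sid, cfg.site, int(year), "gleba", float(mx), float(my), maternal)
            )
            spores.append(
                SporeExtractProfile(
                    fruitbody_id=sid,
                    allele_sets=tuple(
                        frozenset((m, p))
                        for m, p in zip(maternal.alleles, paternal.alleles)
                    ),
                )
            )
            truth_parents[sid] = {"maternal": mother, "paternal": father}

    truth = {
        "config": cfg,
        "allele_frequencies": freqs,
        "genet_positions": positions,
        "genet_genotypes": genotypes,
        "parents_by_fruitbody": truth_parents,
    }
    return Dataset(panel, records), spores, truth


# ---------------------------------------------------------------------------
# ECM root tips, soil cores and qPCR plates


@dataclass
class SoilGridConfig:
    """Radial soil-core transects across a fairy ring (cores every 0.3 m)."""

    n_transects: int = 4
    transect_length: float = 6.6
    core_spacing: float = 0.30
    ridge_peak_ug_per_g: float = 550.0
    ridge_width: float = 0.6
    interior_decay: float = 0.05  # interior field as a fraction of the peak
    ecm_threshold_ug_per_g: float = 30.0
    interior_patch: bool = True
    patch_positions: int = 5
    cq_sd: float = 0.12
    curve_slope: float = -3.35
    curve_intercept: float = 38.0


def simulate_ecm_and_soil(ring_truth: dict, grid: SoilGridConfig, *, seed: int = 1962):
    """ECM and soil sampling over a simulated fairy ring.

    The soil ITS copy field is a Gaussian ridge on the current ring
    radius with decayed interior; an optional interior patch of the
    opposite mating type spans ``patch_positions`` consecutive cores on
    one transect.  ECM root tips appear where the field is high and
    always carry the dominant maternal genet (maternal-only root
    colonisation).  Cq triplicates are generated from the configured
    standard curve with Gaussian noise.

    Returns ``(ecm_records, soil_rows, plate, curve_true)`` where
    ``soil_rows`` is a list of per-core dicts and ``plate`` a list of
    standard-curve dilution points (copies, Cq) for curve refitting.
    """
    from .qpcr import DEFAULT_DILUTION, DEFAULT_ELUATE_UL, DEFAULT_SOIL_MASS_G, DEFAULT_TEMPLATE_UL, mass_to_copies

    rng = np.random.default_rng(seed)
    cfg: RingSimConfig = ring_truth["config"]
    cx, cy = cfg.center
    radius_now = max(ring_truth["radius_by_year"].values())
    dominant: HaploidGenotype = ring_truth["dominant_maternal"]
    curve = StandardCurve(grid.curve_slope, grid.curve_intercept, 1.0)

    soil_rows, ecm_records = [], []
    patch_transect = 0 if grid.interior_patch else -1
    n_cores = int(np.floor(grid.transect_length / grid.core_spacing)) + 1
    patch_start = max(1, n_cores // 3)
    core_id = 0
    for t in range(grid.n_transects):
        theta = 2 * np.pi * t / grid.n_transects
        for j in range(n_cores):
            core_id += 1
            # transects run outward through the ring, centred on it
            r = radius_now - grid.transect_length / 2 + j * grid.core_spacing
            x, y = cx + r * np.cos(theta), cy + r * np.sin(theta)
            ridge = np.exp(-((r - radius_now) ** 2) / (2 * grid.ridge_width**2))
            interior = grid.interior_decay if r < radius_now else 0.0
            ug_per_g = grid.ridge_peak_ug_per_g * max(ridge, interior)
            in_patch = (
                t == patch_transect and patch_start <= j < patch_start + grid.patch_positions
            )
            if in_patch:
                ug_per_g = max(ug_per_g, 0.15 * grid.ridge_peak_ug_per_g)
            copies_per_g = mass_to_copies(ug_per_g)
            copies_per_rx = (
                copies_per_g
                * DEFAULT_SOIL_MASS_G
                / (DEFAULT_ELUATE_UL / DEFAULT_TEMPLATE_UL)
                / DEFAULT_DILUTION
            )
            if copies_per_rx > 1:
                cq = [
                    curve.cq(copies_per_rx) + rng.normal(0, grid.cq_sd)
                    for _ in range(3)
                ]
            else:
                cq = None  # below detection
            positive = ug_per_g > 1.0
            soil_rows.append(
                {
                    "sample_id": f"SOIL-{core_id:03d}",
                    "transect": t + 1,
                    "offset_m": j * grid.core_spacing,
                    "x": x,
                    "y": y,
                    "true_ug_per_g": ug_per_g,
                    "cq_triplicate": cq,
                    "mat11_present": positive and not in_patch,
                    "mat12_present": positive and in_patch,
                }
            )
            if ug_per_g >= grid.ecm_threshold_ug_per_g and not in_patch:
                ecm_records.append(
                    SampleRecord(
                        f"ECM-{core_id:03d}", cfg.site, max(cfg.years), "ecm",
                        x, y, dominant,
                    )
                )
    # 6-point tenfold dilution series from the true curve, noiseless
    plate = [(10.0**k, curve.cq(10.0**k)) for k in range(2, 8)]
    return ecm_records, soil_rows, plate, curve
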