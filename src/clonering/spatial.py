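"""Fine-scale spatial genetic structure for haploid clonal populations.

Implements the spatial aggregation index Ac with a label-permutation
test, the clonal subrange, a Mantel isolation-by-distance test, the
Loiselle kinship coefficient F_ij for haploid genotypes, and kinship
autocorrelation by distance class with the Sp statistic

    Sp = -b / (1 - F_1),

where b is the slope of the regression of pairwise F_ij on ln(distance)
and F_1 the mean kinship in the first distance class.

The Ac index is specified here as

    Ac = (P_nn - P_all) / (1 - P_all),

with P_nn the proportion of samples whose nearest neighbour carries the
same label (averaged over co-nearest neighbours at ties) and P_all the
probability that two random distinct samples share a label.  This form
satisfies the two published anchors: expectation 0 under random labels
and 1 when every nearest neighbour shares its label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform


@dataclass
class AggregationResult:
    ac: float
    p_value: float
    n_permutations: int
    label_kind: str = "MLG"


@dataclass
class AutocorrResult:
    class_edges: np.ndarray
    class_mean_fij: np.ndarray
    class_p_values: np.ndarray
    class_n_pairs: np.ndarray
    slope: float
    f1: float
    sp: float


def _nn_same_label(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean same-label indicator of nearest neighbours (ties averaged)."""
    n = len(labels)
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    total = 0.0
    for i in range(n):
        row = d[i]
        m = row.min()
        nn = np.flatnonzero(row == m)
        total += float(np.mean(labels[nn] == labels[i]))
    return total / n


def _ac_value(dist: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    _, counts = np.unique(labels, return_counts=True)
    p_all = float((counts * (counts - 1)).sum() / (n * (n - 1)))
    if p_all >= 1.0:
        raise ValueError("all labels identical: Ac undefined")
    p_nn = _nn_same_label(dist, labels)
    return (p_nn - p_all) / (1.0 - p_all)


def aggregation_index(
    positions: Sequence,
    labels: Sequence,
    *,
    n_perm: int = 1000,
    seed: int = 1962,
    label_kind: str = "MLG",
) -> AggregationResult:
    """Spatial aggregation index Ac with a one-sided permutation test.

    Labels are permuted over the fixed positions; the p-value is the
    add-one-smoothed fraction of permutations with Ac >= observed.
    """
    pos = np.asarray(positions, dtype=float)
    # labels may be any hashable objects (MLG keys, MAT strings): encode
    codes: dict = {}
    labels = np.array([codes.setdefault(l, len(codes)) for l in labels])
    if len(pos) < 3:
        raise ValueError("Ac needs at least 3 positioned samples")
    if len(codes) < 2:
        raise ValueError("Ac needs at least 2 distinct labels")
    dist = squareform(pdist(pos))
    observed = _ac_value(dist, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _ac_value(dist, perm) >= observed:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return AggregationResult(float(observed), float(p), n_perm, label_kind)


def clonal_subrange(positions: Sequence) -> float:
    """Farthest distance between two samples of one MLG (0 for <2 points)."""
    pts = [p for p in positions if p is not None]
    if len(pts) < 2:
        return 0.0
    return float(pdist(np.asarray(pts, dtype=float)).max())


def mantel_ibd(
    genetic: np.ndarray,
    geographic: np.ndarray,
    *,
    n_perm: int = 999,
    seed: int = 1962,
) -> tuple:
    """Mantel correlation between genetic and geographic distance matrices.

    Pearson r over off-diagonal entries; one-sided (positive IBD) p-value
    by simultaneous row/column permutation of one matrix, add-one rule.
    """
    g = np.asarray(genetic, dtype=float)
    d = np.asarray(geographic, dtype=float)
    if g.shape != d.shape or g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(g, g.T) and np.allclose(d, d.T)):
        raise ValueError("matrices must be symmetric")
    n = g.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 individuals")
    gv, dv = squareform(g, checks=False), squareform(d, checks=False)
    if gv.std() == 0 or dv.std() == 0:
        raise ValueError("zero-variance distance matrix: r undefined")
    r_obs = float(np.corrcoef(gv, dv)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        rv = squareform(g[np.ix_(idx, idx)], checks=False)
        if np.corrcoef(rv, dv)[0, 1] >= r_obs:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


def hamming_distance_matrix(genotypes: Sequence) -> np.ndarray:
    """Pairwise count of differing SSR loci between haploid genotypes."""
    arr = np.asarray([g.alleles for g in genotypes])
    return squareform(pdist(arr, metric="hamming") * arr.shape[1])


# ---------------------------------------------------------------------------
# Loiselle kinship and autocorrelation


def _indicator_matrix(genotypes: Sequence, freqs: dict):
    """Stack per-locus 0/1 allele indicators and reference frequencies."""
    cols, ps = [], []
    for k in sorted(kk for kk in freqs if kk != "MAT"):
        locus_freqs = freqs[k]
        if len(locus_freqs) < 2:
            continue
        for allele, p in sorted(locus_freqs.items()):
            cols.append([1.0 if g.alleles[k] == allele else 0.0 for g in genotypes])
            ps.append(p)
    if not cols:
        raise ValueError("no polymorphic loci: kinship undefined")
    return np.asarray(cols, dtype=float).T, np.asarray(ps, dtype=float)


def loiselle_kinship_matrix(genotypes: Sequence, freqs: dict) -> np.ndarray:
    """Pairwise Loiselle F_ij for haploid multilocus genotypes.

    Multilocus ratio estimator: the numerator sums, over loci and
    alleles, (x_i - p)(x_j - p) + p(1-p)/(n-1); the denominator sums
    p(1-p).  The small-sample term keeps the all-pairs mean near zero
    when frequencies are estimated from the analysed sample itself.
    """
    x, p = _indicator_matrix(genotypes, freqs)
    n = x.shape[0]
    if n < 2:
        raise ValueError("kinship needs at least 2 genotypes")
    dev = x - p
    pq = p * (1.0 - p)
    numer = dev @ dev.T + pq.sum() / (n - 1)
    return numer / pq.sum()


def equal_count_class_edges(
    distances: np.ndarray, n_classes: int, *, min_dist: float = 0.0,
    max_dist: Optional[float] = None
) -> np.ndarray:
    """Distance-class edges with approximately equal pair counts."""
    d = np.asarray(distances, dtype=float)
    d = d[d > 0]
    if max_dist is not None:
        d = d[d <= max_dist]
    d = d[d >= min_dist] if min_dist > 0 else d
    if d.size == 0:
        raise ValueError("no positive pairwise distances in range")
    qs = np.linspace(0, 1, n_classes + 1)
    edges = np.quantile(d, qs)
    edges[0] = min(edges[0], d.min()) - 1e-9
    return np.unique(edges)


def spatial_autocorrelation(
    positions: Sequence,
    genotypes: Sequence,
    freqs: dict,
    *,
    class_edges: Optional[Sequence] = None,
    n_classes: int = 13,
    n_perm: int = 10000,
    seed: int = 1962,
    max_regression_dist: Optional[float] = None,
) -> AutocorrResult:
    """Kinship autocorrelation by distance class and the Sp statistic.

    Per-class mean F_ij with two-sided p-values from permuting spatial
    locations among individuals; the Sp regression uses pair-level F_ij
    against ln(distance) (zero-distance pairs excluded), optionally
    restricted to pairs closer than ``max_regression_dist``.
    """
    pos = np.asarray(positions, dtype=float)
    fij = loiselle_kinship_matrix(genotypes, freqs)
    n = len(pos)
    dist = squareform(pdist(pos))
    iu = np.triu_indices(n, k=1)
    dvec, fvec = dist[iu], fij[iu]

    if class_edges is None:
        class_edges = equal_count_class_edges(dvec, n_classes)
    edges = np.asarray(class_edges, dtype=float)
    which = np.digitize(dvec, edges) - 1
    n_cls = len(edges) - 1

    means = np.full(n_cls, np.nan)
    counts = np.zeros(n_cls, dtype=int)
    for c in range(n_cls):
        mask = which == c
        counts[c] = mask.sum()
        if counts[c]:
            means[c] = fvec[mask].mean()

    # permutation null: shuffle locations among individuals
    rng = np.random.default_rng(seed)
    ge = np.zeros(n_cls, dtype=int)  # null >= observed
    le = np.zeros(n_cls, dtype=int)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        pd_ = dist[np.ix_(idx, idx)][iu]
        pw = np.digitize(pd_, edges) - 1
        for c in range(n_cls):
            mask = pw == c
            if not mask.any() or counts[c] == 0:
                continue
            m = fvec[mask].mean()
            if m >= means[c]:
                ge[c] += 1
            if m <= means[c]:
                le[c] += 1
    p_vals = np.full(n_cls, np.nan)
    for c in range(n_cls):
        if counts[c]:
            one_sided = min(ge[c] + 1, le[c] + 1) / (n_perm + 1)
            p_vals[c] = min(1.0, 2.0 * one_sided)

    reg_mask = dvec > 0
    if max_regression_dist is not None:
        reg_mask &= dvec <= max_regression_dist
    if reg_mask.sum() < 2:
        raise ValueError("too few positive-distance pairs for the Sp regression")
    slope = float(
        stats.linregress(np.log(dvec[reg_mask]), fvec[reg_mask]).slope
    )
    f1 = float(means[np.flatnonzero(counts)[0]])
    if f1 >= 1.0:
        raise ValueError("F_1 = 1: Sp undefined")
    sp = -slope / (1.0 - f1)
    return AutocorrResult(edges, means, p_vals, counts, slope, f1, float(sp))
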