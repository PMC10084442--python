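"""Haploid AMOVA differentiation (Phi_PT) between sites or genetic groups.

Phi_PT is the AMOVA analogue of F_ST for haploid/binary data: pairwise
squared genetic distance (count of differing SSR loci) is partitioned
into among- and within-group variance components, and

    Phi_PT = sigma2_among / (sigma2_among + sigma2_within),

with significance from random permutation of genotypes across groups.
Negative among-group variance estimates are truncated to zero, the
standard AMOVA convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class AMOVAResult:
    groups: list
    phi_pt: np.ndarray  # pairwise matrix, zero diagonal
    p_values: np.ndarray
    variance_components: dict = field(default_factory=dict)


def squared_distance_matrix(genotypes: Sequence) -> np.ndarray:
    """Squared genetic distance = number of differing SSR loci."""
    arr = np.asarray([g.alleles for g in genotypes])
    return squareform(pdist(arr, metric="hamming") * arr.shape[1])


def _phi_from_distances(d2: np.ndarray, labels: np.ndarray) -> tuple:
    """AMOVA variance components from a squared-distance matrix.

    SS_total = sum_{i<j} d2_ij / N; SS_within = sum over groups of the
    within-group pair sum / n_g.  sigma2_within = MS_within and
    sigma2_among = (MS_among - MS_within)/n0 with the standard unequal
    group-size coefficient n0.
    """
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    k = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for grp, ng in zip(groups, counts):
        idx = np.flatnonzero(labels == grp)
        if ng >= 2:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (n - (counts**2).sum() / n) / df_among
    sigma_within = ms_within
    sigma_among = max(0.0, (ms_among - ms_within) / n0)
    total = sigma_among + sigma_within
    phi = sigma_among / total if total > 0 else 0.0
    return phi, sigma_among, sigma_within


def phi_pt(
    genotypes: Sequence,
    labels: Sequence,
    *,
    n_perm: int = 999,
    seed: int = 1962,
) -> AMOVAResult:
    """Pairwise Phi_PT between all groups with permutation p-values.

    Works on clone-corrected genotypes; each group needs >= 2 members.
    p-values are the add-one-smoothed fraction of label permutations
    with Phi_PT >= observed.
    """
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("Phi_PT needs at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValueError(f"groups with <2 genotypes: {small}")
    d2 = squared_distance_matrix(genotypes)
    rng = np.random.default_rng(seed)
    k = len(groups)
    phi = np.zeros((k, k))
    pvals = np.zeros((k, k))
    components: dict = {}
    for a in range(k):
        for b in range(a + 1, k):
            idx = np.flatnonzero((labels == groups[a]) | (labels == groups[b]))
            sub_d2 = d2[np.ix_(idx, idx)]
            sub_labels = labels[idx]
            obs, s_a, s_w = _phi_from_distances(sub_d2, sub_labels)
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub_labels)
                if _phi_from_distances(sub_d2, perm)[0] >= obs:
                    hits += 1
            phi[a, b] = phi[b, a] = obs
            pvals[a, b] = pvals[b, a] = (hits + 1) / (n_perm + 1)
            components[(str(groups[a]), str(groups[b]))] = {
                "sigma_among": s_a,
                "sigma_within": s_w,
            }
    return AMOVAResult(list(groups), phi, pvals, components)
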