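"""Paternal inference from ascospore extracts and zygote-level statistics.

In heterothallic truffles the gleba is maternal tissue, while pooled
ascospores carry both parental genomes.  At each SSR locus a spore
extract therefore shows one or two alleles: the paternal allele is the
one differing from the maternal call, or equals it when the extract is
monomorphic.  The paternal mating type is always the idiomorph opposite
to the gleba's — mating requires compatible idiomorphs.  Reconstructed
zygotes (maternal + paternal haplotype per fruitbody) support a diploid
inbreeding coefficient F_is = 1 - mean(Ho)/mean(He).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .clonality import MLG
from .types import HaploidGenotype, SampleRecord, opposite_mat


@dataclass
class SporeExtractProfile:
    """Pooled-ascospore genotyping of one fruitbody.

    ``allele_sets`` holds one set of 1-2 alleles per SSR locus; the MAT
    flags record which idiomorphs amplified from the spore DNA.
    """

    fruitbody_id: str
    allele_sets: tuple  # tuple of frozensets, one per locus
    mat11_present: bool = True
    mat12_present: bool = True

    def __post_init__(self):
        sets = tuple(frozenset(int(a) for a in s) for s in self.allele_sets)
        if any(len(s) == 0 for s in sets):
            raise ValueError("each locus must show at least one spore allele")
        if any(len(s) > 2 for s in sets):
            raise ValueError(">2 alleles at a locus: probable contamination")
        object.__setattr__(self, "allele_sets", sets)


@dataclass
class Zygote:
    """Reconstructed diploid for one fruitbody."""

    fruitbody_id: str
    maternal: HaploidGenotype
    paternal: HaploidGenotype

    @property
    def diploid(self) -> tuple:
        """Per-locus unordered allele pair."""
        return tuple(
            frozenset((m, p))
            for m, p in zip(self.maternal.alleles, self.paternal.alleles)
        )


class PaternalInferenceError(ValueError):
    """Spore profile incompatible with the maternal genotype."""


def infer_paternal(
    gleba: HaploidGenotype, spores: SporeExtractProfile
) -> HaploidGenotype:
    """Mendelian subtraction of the maternal haplotype from a spore pool.

    Raises :class:`PaternalInferenceError` when any locus set lacks the
    maternal allele (contamination or sample mismatch).
    """
    if len(spores.allele_sets) != len(gleba.alleles):
        raise ValueError("spore profile does not cover the active panel")
    paternal_alleles = []
    for i, (maternal_allele, spore_set) in enumerate(
        zip(gleba.alleles, spores.allele_sets)
    ):
        if maternal_allele not in spore_set:
            raise PaternalInferenceError(
                f"locus {i}: spore alleles {sorted(spore_set)} lack the "
                f"maternal allele {maternal_allele}"
            )
        others = spore_set - {maternal_allele}
        paternal_alleles.append(next(iter(others)) if others else maternal_allele)
    return HaploidGenotype(tuple(paternal_alleles), opposite_mat(gleba.mat))


def build_zygotes(
    glebas: Dict[str, HaploidGenotype],
    spores: Sequence[SporeExtractProfile],
    *,
    log: Optional[list] = None,
) -> list:
    """One :class:`Zygote` per fruitbody with a successful paternal inference.

    Unmatched ids and rejected inferences are skipped; reasons are
    appended to ``log`` when provided.
    """
    zygotes = []
    for profile in spores:
        gleba = glebas.get(profile.fruitbody_id)
        if gleba is None:
            if log is not None:
                log.append(f"{profile.fruitbody_id}: no matching gleba genotype")
            continue
        try:
            paternal = infer_paternal(gleba, profile)
        except PaternalInferenceError as exc:
            if log is not None:
                log.append(f"{profile.fruitbody_id}: rejected ({exc})")
            continue
        zygotes.append(Zygote(profile.fruitbody_id, gleba, paternal))
    return zygotes


def fis(zygotes: Sequence[Zygote]) -> float:
    """Zygote inbreeding coefficient F_is = 1 - mean(Ho)/mean(He).

    Ho per locus is the fraction of heterozygous zygotes; He is the
    expected heterozygosity 1 - sum p^2 from the pooled zygote allele
    frequencies (two alleles per zygote).  Monomorphic loci drop out of
    both means; with no polymorphic locus F_is is undefined.
    """
    if len(zygotes) < 2:
        raise ValueError("F_is needs at least 2 zygotes")
    n_loci = len(zygotes[0].maternal.alleles)
    ho, he = [], []
    for i in range(n_loci):
        pairs = [(z.maternal.alleles[i], z.paternal.alleles[i]) for z in zygotes]
        pooled = [a for pair in pairs for a in pair]
        alleles, counts = np.unique(pooled, return_counts=True)
        if len(alleles) < 2:
            continue
        p = counts / counts.sum()
        he.append(1.0 - float((p**2).sum()))
        ho.append(float(np.mean([m != f for m, f in pairs])))
    if not he:
        raise ValueError("all loci monomorphic: F_is undefined")
    return float(1.0 - np.mean(ho) / np.mean(he))


def detect_hermaphrodites(mlgs: Sequence[MLG], *, significant_only: bool = True) -> dict:
    """MLGs observed in both the maternal and the paternal role.

    Returns the hermaphrodite MLGs, their fraction of all MLGs, and
    per-MLG persistence (years spanned).  ``significant_only`` restricts
    the hermaphrodite count to significant (true-clone) MLGs, since a
    non-significant repeat may be two distinct individuals.
    """
    herms = []
    for m in mlgs:
        if m.roles != {"maternal", "paternal"}:
            continue
        if significant_only and not m.significant:
            continue
        years = sorted(m.years)
        herms.append(
            {
                "mlg_id": m.mlg_id,
                "n_ramets": m.n_ramets,
                "years": years,
                "span_years": years[-1] - years[0] + 1,
            }
        )
    n_total = len(mlgs)
    return {
        "hermaphrodites": herms,
        "n_hermaphrodites": len(herms),
        "n_mlgs": n_total,
        "percent_of_mlgs": round(100.0 * len(herms) / n_total, 2) if n_total else 0.0,
    }


def persistence_table(mlgs: Sequence[MLG]) -> pd.DataFrame:
    """Per-MLG persistence: first/last year, span, ramet counts by year and role."""
    rows = []
    for m in mlgs:
        years = sorted(m.years)
        counts: dict = {}
        for rec in m.ramets:
            role = "maternal" if rec.role in ("gleba", "ecm") else "paternal"
            counts[(rec.year, role)] = counts.get((rec.year, role), 0) + 1
        rows.append(
            {
                "mlg_id": m.mlg_id,
                "n_ramets": m.n_ramets,
                "roles": "+".join(sorted(m.roles)),
                "first_year": years[0],
                "last_year": years[-1],
                "span_years": years[-1] - years[0] + 1,
                "counts_per_year_role": {
                    f"{y}:{role}": c for (y, role), c in sorted(counts.items())
                },
            }
        )
    return pd.DataFrame(rows)
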