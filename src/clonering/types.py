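"""Domain types for haploid multilocus genotype datasets.

The objects here model a field survey of a heterothallic ascomycete:
georeferenced samples (fruitbody gleba, ascospore extracts, ectomycorrhizal
root tips, soil cores) genotyped at a panel of SSR loci plus the single
mating-type locus with its two idiomorphs (MAT1-1 / MAT1-2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

MAT1_1 = "MAT1-1"
MAT1_2 = "MAT1-2"
MAT_IDIOMORPHS = (MAT1_1, MAT1_2)

#: Sample roles; gleba and ECM root tips carry the maternal genotype,
#: ascospore extracts carry maternal+paternal allele mixtures.
ROLES = ("gleba", "ascospore", "ecm", "soil")


def opposite_mat(mat: str) -> str:
    """The idiomorph compatible with ``mat`` (heterothallism)."""
    if mat == MAT1_1:
        return MAT1_2
    if mat == MAT1_2:
        return MAT1_1
    raise ValueError(f"unknown mating-type idiomorph: {mat!r}")


@dataclass(frozen=True)
class Locus:
    """A marker locus: a microsatellite (SSR) or the mating-type locus.

    SSR alleles are integer fragment sizes in base pairs; the MAT locus
    has exactly the two idiomorphs.  ``allele_domain`` is optional for
    SSRs: when given, reads are validated against it.
    """

    name: str
    kind: str = "SSR"  # "SSR" | "MAT"
    allele_domain: Optional[frozenset] = None

    def __post_init__(self):
        if self.kind not in ("SSR", "MAT"):
            raise ValueError(f"locus kind must be SSR or MAT, got {self.kind!r}")
        if self.kind == "MAT":
            object.__setattr__(self, "allele_domain", frozenset(MAT_IDIOMORPHS))
        elif self.allele_domain is not None:
            dom = frozenset(int(a) for a in self.allele_domain)
            if any(a <= 0 for a in dom):
                raise ValueError("SSR allele labels must be positive integers")
            object.__setattr__(self, "allele_domain", dom)


@dataclass(frozen=True)
class Panel:
    """Ordered locus panel shared by every record in a dataset.

    The MAT locus is stored separately from the SSR loci: it enters MLG
    identity but is excluded by default from frequency-based statistics.
    """

    ssr_loci: tuple
    mat_locus: Locus = Locus("MAT", kind="MAT")

    def __post_init__(self):
        names = [l.name for l in self.ssr_loci] + [self.mat_locus.name]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique within a panel")
        if any(l.kind != "SSR" for l in self.ssr_loci):
            raise ValueError("ssr_loci must all have kind SSR")
        object.__setattr__(self, "ssr_loci", tuple(self.ssr_loci))

    @property
    def ssr_names(self) -> tuple:
        return tuple(l.name for l in self.ssr_loci)

    def subset(self, names: Iterable[str]) -> "Panel":
        """Reduced panel keeping only the named SSR loci (order preserved)."""
        keep = set(names)
        return Panel(tuple(l for l in self.ssr_loci if l.name in keep), self.mat_locus)

    def __len__(self):
        return len(self.ssr_loci)


@dataclass(frozen=True)
class HaploidGenotype:
    """One allele per SSR locus plus the mating-type idiomorph."""

    alleles: tuple
    mat: str

    def __post_init__(self):
        object.__setattr__(self, "alleles", tuple(int(a) for a in self.alleles))
        if self.mat not in MAT_IDIOMORPHS:
            raise ValueError(f"invalid mating type {self.mat!r}")

    @property
    def key(self) -> tuple:
        """Hashable identity over all SSR alleles and the mating type."""
        return self.alleles + (self.mat,)

    def validate_against(self, panel: Panel) -> None:
        if len(self.alleles) != len(panel.ssr_loci):
            raise ValueError(
                f"genotype has {len(self.alleles)} alleles, panel has "
                f"{len(panel.ssr_loci)} SSR loci"
            )
        for locus, allele in zip(panel.ssr_loci, self.alleles):
            if locus.allele_domain is not None and allele not in locus.allele_domain:
                raise ValueError(
                    f"allele {allele} outside declared domain of locus {locus.name}"
                )


@dataclass
class SampleRecord:
    """A georeferenced, dated, role-tagged sample.

    ``genotype`` is None for unresolved records (any missing SSR or MAT
    call); unresolved records are kept in the dataset but excluded from
    genetic analyses.  Positions are planar metres (projected upstream).
    """

    sample_id: str
    site: str
    year: int
    role: str
    x: Optional[float] = None
    y: Optional[float] = None
    genotype: Optional[HaploidGenotype] = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        for coord in (self.x, self.y):
            if coord is not None and not math.isfinite(coord):
                raise ValueError(f"non-finite coordinate in sample {self.sample_id}")

    @property
    def resolved(self) -> bool:
        return self.genotype is not None

    @property
    def position(self) -> Optional[tuple]:
        if self.x is None or self.y is None:
            return None
        return (self.x, self.y)


@dataclass
class Dataset:
    """A locus panel plus the sample records sharing it."""

    panel: Panel
    records: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        for rec in self.records:
            if rec.genotype is not None:
                rec.genotype.validate_against(self.panel)

    @property
    def resolved_records(self) -> list:
        return [r for r in self.records if r.resolved]

    def by_site(self) -> dict:
        sites: dict = {}
        for rec in self.records:
            sites.setdefault(rec.site, []).append(rec)
        return sites

    def subset(self, *, site=None, role=None, resolved_only=False) -> "Dataset":
        recs = self.records
        if site is not None:
            recs = [r for r in recs if r.site == site]
        if role is not None:
            roles = (role,) if isinstance(role, str) else tuple(role)
            recs = [r for r in recs if r.role in roles]
        if resolved_only:
            recs = [r for r in recs if r.resolved]
        return Dataset(self.panel, list(recs), dict(self.metadata))

    def __len__(self):
        return len(self.records)
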