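"""Readers, writers and validation for genotype tables.

The on-disk schema is a delimited text table, one row per sample::

    id,site,year,role,x,y,<ssr locus 1>,...,<ssr locus k>,MAT

SSR cells hold integer fragment sizes, the MAT cell holds ``MAT1-1`` or
``MAT1-2``; the missing code (default ``NA``) may appear in any genotype
or coordinate cell.  Rows with any missing SSR or MAT call are retained
but left unresolved: only unambiguously complete profiles (including the
mating type) enter genetic analyses.
"""

from __future__ import annotations

import json
from collections import Counter
from typing import Optional

import pandas as pd

from .types import (
    MAT_IDIOMORPHS,
    Dataset,
    HaploidGenotype,
    Panel,
    ROLES,
    SampleRecord,
)

META_COLUMNS = ["id", "site", "year", "role", "x", "y"]
MAT_COLUMN = "MAT"


def read_genotype_table(
    path,
    panel: Panel,
    *,
    missing: str = "NA",
    delimiter: str = ",",
) -> Dataset:
    """Read a genotype table into a :class:`Dataset`.

    Rows with a missing SSR or MAT call become unresolved records
    (``genotype is None``); missing coordinates are allowed and simply
    exclude the sample from spatial statistics.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    expected = META_COLUMNS + list(panel.ssr_names) + [MAT_COLUMN]
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype table lacks columns: {missing_cols}")

    records = []
    for _, row in df.iterrows():
        role = row["role"].strip()
        if role not in ROLES:
            raise ValueError(f"unknown role label {role!r} in sample {row['id']!r}")
        x = None if row["x"] == missing or row["x"] == "" else float(row["x"])
        y = None if row["y"] == missing or row["y"] == "" else float(row["y"])

        raw_alleles = [row[name] for name in panel.ssr_names]
        raw_mat = row[MAT_COLUMN]
        unresolved = raw_mat == missing or any(a == missing for a in raw_alleles)
        if not unresolved and raw_mat not in MAT_IDIOMORPHS:
            raise ValueError(
                f"invalid mating type {raw_mat!r} in sample {row['id']!r}"
            )
        genotype = None
        if not unresolved:
            genotype = HaploidGenotype(tuple(int(a) for a in raw_alleles), raw_mat)
        records.append(
            SampleRecord(
                sample_id=row["id"],
                site=row["site"],
                year=int(row["year"]),
                role=role,
                x=x,
                y=y,
                genotype=genotype,
            )
        )
    return Dataset(panel, records)


def write_genotype_table(
    ds: Dataset, path, *, missing: str = "NA", delimiter: str = ","
) -> None:
    """Write a :class:`Dataset` in the schema :func:`read_genotype_table` reads."""
    rows = []
    for rec in ds.records:
        row = {
            "id": rec.sample_id,
            "site": rec.site,
            "year": rec.year,
            "role": rec.role,
            "x": missing if rec.x is None else repr(float(rec.x)),
            "y": missing if rec.y is None else repr(float(rec.y)),
        }
        if rec.genotype is None:
            for name in ds.panel.ssr_names:
                row[name] = missing
            row[MAT_COLUMN] = missing
        else:
            for name, allele in zip(ds.panel.ssr_names, rec.genotype.alleles):
                row[name] = str(allele)
            row[MAT_COLUMN] = rec.genotype.mat
        rows.append(row)
    cols = META_COLUMNS + list(ds.panel.ssr_names) + [MAT_COLUMN]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=delimiter, index=False)


def write_genepop(ds: Dataset, path, *, title: Optional[str] = None) -> None:
    """Export resolved records as a haploid Genepop file, one POP per site.

    SSR alleles are written as zero-padded 3-digit codes; fragment sizes
    over 999 bp fall back to rank codes for that locus (Genepop caps
    codes at 999).  The mating-type locus is exported as a pseudo-locus
    with codes 001/002.
    """
    resolved = ds.resolved_records
    codes = []
    for i, locus in enumerate(ds.panel.ssr_loci):
        alleles = sorted({r.genotype.alleles[i] for r in resolved})
        if len(alleles) > 999:
            raise ValueError(f">999 distinct alleles at locus {locus.name}")
        if alleles and alleles[-1] <= 999:
            codes.append({a: f"{a:03d}" for a in alleles})
        else:
            codes.append({a: f"{rank + 1:03d}" for rank, a in enumerate(alleles)})
    mat_code = {"MAT1-1": "001", "MAT1-2": "002"}

    lines = [title or "clonering haploid export"]
    lines += [l.name for l in ds.panel.ssr_loci]
    lines.append(ds.panel.mat_locus.name)
    by_site: dict = {}
    for rec in resolved:
        by_site.setdefault(rec.site, []).append(rec)
    for site, recs in by_site.items():
        lines.append("POP")
        for rec in recs:
            tokens = [codes[i][a] for i, a in enumerate(rec.genotype.alleles)]
            tokens.append(mat_code[rec.genotype.mat])
            lines.append(f"{rec.sample_id} ,  " + " ".join(tokens))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def validate(ds: Dataset) -> dict:
    """Report-only dataset diagnostics.

    Lists unresolved records, duplicated coordinates, per-site monomorphic
    loci, and per-site sample counts broken down by role and year.
    """
    report: dict = {
        "n_records": len(ds.records),
        "n_resolved": len(ds.resolved_records),
        "unresolved_ids": [r.sample_id for r in ds.records if not r.resolved],
        "duplicate_coordinates": [],
        "monomorphic_loci_per_site": {},
        "counts_per_site": {},
    }
    seen: dict = {}
    for rec in ds.records:
        if rec.position is not None:
            seen.setdefault(rec.position, []).append(rec.sample_id)
    report["duplicate_coordinates"] = [
        {"position": list(pos), "sample_ids": ids}
        for pos, ids in sorted(seen.items())
        if len(ids) > 1
    ]
    for site, recs in ds.by_site().items():
        resolved = [r for r in recs if r.resolved]
        mono = []
        for i, locus in enumerate(ds.panel.ssr_loci):
            alleles = {r.genotype.alleles[i] for r in resolved}
            if len(alleles) <= 1:
                mono.append(locus.name)
        report["monomorphic_loci_per_site"][site] = mono
        counts: dict = {}
        for rec in recs:
            counts.setdefault(rec.role, Counter())[rec.year] += 1
        report["counts_per_site"][site] = {
            role: dict(sorted(year_counts.items()))
            for role, year_counts in counts.items()
        }
    return report


def write_validation_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
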