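"""Absolute quantification of soil mycelium from ITS qPCR.

Standard-curve fit and QC (a curve is reliable when R^2 >= 0.997 and
amplification efficiency is between 90% and 110%), back-calculation of
ITS copies per g dried soil from triplicate Cq values, conversion of
copy numbers to mycelium dry mass (1 g dried mycelium = 9.37e10 ITS
copies), mating-type co-detection summaries along soil transects, and
fairy-ring growth-rate / age arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

#: ITS copies per gram of dried mycelium.
ITS_COPIES_PER_G_MYCELIUM = 9.37e10

#: Default extraction scaling: 250 mg dry soil per extraction, 100 ul
#: eluate, 5 ul template per reaction at 1:10 dilution.
DEFAULT_SOIL_MASS_G = 0.25
DEFAULT_ELUATE_UL = 100.0
DEFAULT_TEMPLATE_UL = 5.0
DEFAULT_DILUTION = 10.0

R2_THRESHOLD = 0.997
EFFICIENCY_RANGE = (0.90, 1.10)


@dataclass
class StandardCurve:
    """Least-squares fit of Cq against log10(ITS copies per reaction)."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency 10^(-1/slope) - 1 (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def reliable(self) -> bool:
        lo, hi = EFFICIENCY_RANGE
        return self.r_squared >= R2_THRESHOLD and lo <= self.efficiency <= hi

    def cq(self, copies: float) -> float:
        return self.slope * math.log10(copies) + self.intercept

    def copies(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass
class SoilSample:
    sample_id: str
    position: Optional[tuple]
    triplicate_copies: tuple  # copies per reaction
    copies_per_g: float
    cv_percent: float
    mycelium_ug_per_g: float
    mat11_present: bool = False
    mat12_present: bool = False
    flags: list = field(default_factory=list)


def fit_standard_curve(points: Sequence) -> StandardCurve:
    """Fit a standard curve from (copies_per_reaction, Cq) dilution points."""
    pts = [(float(c), float(q)) for c, q in points]
    if len(pts) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    log_copies = np.log10([c for c, _ in pts])
    cq = np.array([q for _, q in pts])
    fit = stats.linregress(log_copies, cq)
    return StandardCurve(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def quantify(
    curve: StandardCurve,
    cq_triplicate: Sequence,
    *,
    sample_id: str = "",
    position: Optional[tuple] = None,
    dilution: float = DEFAULT_DILUTION,
    soil_mass_g: float = DEFAULT_SOIL_MASS_G,
    eluate_ul: float = DEFAULT_ELUATE_UL,
    template_ul: float = DEFAULT_TEMPLATE_UL,
    cv_threshold: float = 15.0,
    force: bool = False,
    mat11_present: bool = False,
    mat12_present: bool = False,
) -> SoilSample:
    """Back-calculate ITS copies per g dried soil from triplicate Cq values.

    Copies per reaction from the inverse curve; scaled by dilution and
    by the eluate/template volume ratio per g of extracted soil.  The
    triplicate CV (sd/mean x 100) is computed on back-transformed copy
    numbers.  Refuses unreliable curves unless ``force``.
    """
    if not curve.reliable and not force:
        raise ValueError(
            f"standard curve unreliable (R^2={curve.r_squared:.4f}, "
            f"efficiency={curve.efficiency:.3f}); pass force=True to override"
        )
    copies = np.array([curve.copies(q) for q in cq_triplicate])
    mean_copies = float(copies.mean())
    cv = float(copies.std(ddof=1) / mean_copies * 100.0) if len(copies) > 1 else 0.0
    per_g = mean_copies * dilution * (eluate_ul / template_ul) / soil_mass_g
    flags = []
    if cv > cv_threshold:
        flags.append(f"CV {cv:.1f}% exceeds {cv_threshold:.0f}%")
    if not curve.reliable:
        flags.append("unreliable standard curve (forced)")
    return SoilSample(
        sample_id=sample_id,
        position=position,
        triplicate_copies=tuple(float(c) for c in copies),
        copies_per_g=float(per_g),
        cv_percent=cv,
        mycelium_ug_per_g=copies_to_mass(per_g),
        mat11_present=mat11_present,
        mat12_present=mat12_present,
        flags=flags,
    )


def copies_to_mass(copies_per_g: float) -> float:
    """ITS copies per g soil -> ug dried mycelium per g dried soil."""
    if copies_per_g < 0:
        raise ValueError("copy number cannot be negative")
    return copies_per_g / ITS_COPIES_PER_G_MYCELIUM * 1e6


def mass_to_copies(ug_per_g: float) -> float:
    if ug_per_g < 0:
        raise ValueError("mass cannot be negative")
    return ug_per_g * 1e-6 * ITS_COPIES_PER_G_MYCELIUM


def mat_cooccurrence(samples: Sequence[SoilSample], *, by_site: bool = False) -> dict:
    """Mating-type co-detection among MAT-PCR-positive soil samples.

    Reports counts and percentages of positives showing one vs both
    idiomorphs, plus maximal runs of consecutive same-single-MAT samples
    (patches) in the given sample order (transect order).
    """
    positives = [s for s in samples if s.mat11_present or s.mat12_present]
    both = [s for s in positives if s.mat11_present and s.mat12_present]
    single = [s for s in positives if not (s.mat11_present and s.mat12_present)]
    summary = {
        "n_positive": len(positives),
        "n_both": len(both),
        "n_single": len(single),
        "percent_both": round(100.0 * len(both) / len(positives), 1)
        if positives
        else 0.0,
        "patches": _mat_patches(samples),
    }
    return summary


def _mat_patches(samples: Sequence[SoilSample]) -> list:
    """Runs of >=2 consecutive samples positive for exactly one idiomorph."""
    patches = []
    run_mat, run_ids = None, []
    for s in list(samples) + [None]:
        mat = None
        if s is not None:
            if s.mat11_present and not s.mat12_present:
                mat = "MAT1-1"
            elif s.mat12_present and not s.mat11_present:
                mat = "MAT1-2"
        if mat is not None and mat == run_mat:
            run_ids.append(s.sample_id)
        else:
            if run_mat is not None and len(run_ids) >= 2:
                patches.append({"mat": run_mat, "length": len(run_ids), "sample_ids": run_ids})
            run_mat, run_ids = mat, [s.sample_id] if mat else []
    return patches


# ---------------------------------------------------------------------------
# fairy-ring geometry


def fit_ring_center(positions: Sequence) -> tuple:
    """Least-squares circle centre; centroid fallback for <6 points."""
    pts = np.asarray(positions, dtype=float)
    centroid = tuple(pts.mean(axis=0))
    if len(pts) < 6:
        return centroid

    def residuals(c):
        r = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        return r - r.mean()

    sol = optimize.least_squares(residuals, x0=np.asarray(centroid))
    return (float(sol.x[0]), float(sol.x[1]))


def ring_growth_rate(
    positions_by_year: dict, *, center: Optional[tuple] = None
) -> dict:
    """Radial outgrowth rate of a fairy ring in m/yr.

    Mean distance of each year's fruitbodies to the ring centre
    (annulus-fit over all fruitbodies unless supplied), then the
    least-squares slope of mean annual radius against calendar year.
    """
    years = sorted(positions_by_year)
    if len(years) < 2:
        raise ValueError("growth rate needs >= 2 distinct years")
    if center is None:
        all_pts = [p for y in years for p in positions_by_year[y]]
        center = fit_ring_center(all_pts)
    cx, cy = center
    radii = {}
    for y in years:
        pts = np.asarray(positions_by_year[y], dtype=float)
        radii[y] = float(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy).mean())
    fit = stats.linregress(years, [radii[y] for y in years])
    return {
        "rate_m_per_yr": float(fit.slope),
        "center": (float(cx), float(cy)),
        "mean_radius_by_year": radii,
    }


def ring_age(radius_m: float, rate_m_per_yr: float) -> int:
    """Whole-year age of a ring of the given radius at a constant rate."""
    if radius_m <= 0 or rate_m_per_yr <= 0:
        raise ValueError("radius and rate must be positive")
    # epsilon guards exact ratios against binary-float representation
    return int(math.floor(radius_m / rate_m_per_yr + 1e-9))
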