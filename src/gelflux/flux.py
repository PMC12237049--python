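"""Number and carbon fluxes from gel counts and bulk filter masses.

The observation model is microscopy counting of sinking particles embedded in
a polyacrylamide gel at the bottom of a sediment-trap tube: a count ``N`` of
cells over a surveyed gel area ``A`` (m^2) during a collection period ``T``
(days) estimates the number flux ``N / (A T)`` in cells m-2 d-1. Counting is
treated as Poisson, so the 1-sigma counting uncertainty is ``sqrt(N) / (A T)``
— the usual square-root-of-counts error of microscopy abundance estimates.

Bulk particulate organic carbon (POC) fluxes come from replicate volume splits
of the pooled brine tubes: mean split mass divided by the split fraction, the
collection duration and the combined tube area.

Carbon per cell uses a spherical biovolume at a representative diameter and a
diatom allometric carbon-biovolume regression ``C = a V^b`` (pg C, V in µm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UnitError, UserInputError
from .profiles import FluxProfile

__all__ = [
    "CELLS",
    "CARBON",
    "PERCENT",
    "DIMENSIONLESS",
    "PG_C_PER_MMOL_C",
    "POISSON_ZERO_UPPER",
    "FluxRecord",
    "TrapSample",
    "CellCarbonModel",
    "number_flux",
    "bulk_poc_flux",
    "depth_average_flux",
    "fold_change",
    "sphere_volume",
    "cell_carbon",
    "percent_of_bulk_poc",
    "solitary_fraction",
    "fluxes_from_counts",
]

# Unit strings carried on every FluxRecord; mixing them raises UnitError.
CELLS = "cells m-2 d-1"
CARBON = "mmol C m-2 d-1"
PERCENT = "percent"
DIMENSIONLESS = "dimensionless"

#: pg of carbon in one mmol of carbon (12.011 g/mol).
PG_C_PER_MMOL_C = 12.011e9

#: Upper 68% confidence bound (in counts) on the Poisson mean given 0 observed
#: counts; used for the uncertainty of ratios with a zero-count numerator,
#: where sqrt(0) = 0 would understate the uncertainty.
POISSON_ZERO_UPPER = 1.84


@dataclass(frozen=True)
class FluxRecord:
    """A flux value with symmetric 1-sigma uncertainty and units.

    ``n_counted`` and ``per_count`` are populated for count-derived records:
    ``per_count`` is the flux contributed by a single counted cell,
    ``1 / (area * duration)``, which lets downstream ratios bound the
    uncertainty of zero counts.
    """

    value: float
    sigma: float
    units: str = CELLS
    n_counted: int | None = None
    per_count: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise UserInputError(f"flux value must be finite and >= 0, got {self.value}")
        if not math.isfinite(self.sigma) or self.sigma < 0:
            raise UserInputError(f"flux sigma must be finite and >= 0, got {self.sigma}")

    @property
    def relative_sigma(self) -> float:
        """sigma / value; infinite for a zero value with nonzero sigma."""
        if self.value == 0:
            return 0.0 if self.sigma == 0 else math.inf
        return self.sigma / self.value

    def _require_units(self, other: "FluxRecord") -> None:
        if self.units != other.units:
            raise UnitError(f"cannot combine {self.units!r} with {other.units!r}")


@dataclass(frozen=True)
class TrapSample:
    """One sediment-trap collection at a site, deployment, platform and depth.

    ``tube_area_m2`` is the single cylindrical tube cross-section (0.0113 m^2);
    ``combined_area_m2`` the duplicate brine tubes pooled for bulk chemistry
    (2 x 0.0113 = 0.0226 m^2). ``gel_area_surveyed_m2`` maps each microscopy
    magnification tier to the gel area actually surveyed at that tier.
    """

    site: str
    deployment: int
    platform: str
    depth_m: float
    duration_d: float
    tube_area_m2: float = 0.0113
    combined_area_m2: float = 0.0226
    gel_area_surveyed_m2: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_d <= 0:
            raise UserInputError("duration must be positive")
        if self.depth_m <= 0:
            raise UserInputError("depth must be positive")
        if self.tube_area_m2 <= 0 or self.combined_area_m2 <= 0:
            raise UserInputError("areas must be positive")
        if self.platform not in ("STT", "NBST"):
            raise UserInputError(f"platform must be STT or NBST, got {self.platform!r}")
        for tier, a in self.gel_area_surveyed_m2.items():
            if not 0 < a <= self.tube_area_m2:
                raise UserInputError(
                    f"surveyed area for tier {tier!r} must be in (0, tube area]"
                )

    @property
    def sample_id(self) -> str:
        return f"{self.site}-d{self.deployment}-{int(round(self.depth_m))}m-{self.platform}"


@dataclass(frozen=True)
class CellCarbonModel:
    """Allometric carbon content of a spherical cell: C[pg] = a * V[µm^3]^b.

    Defaults are the diatom carbon-biovolume regression widely used for
    biovolumes above ~3000 µm^3 (a = 0.288 pg µm^-3b, b = 0.811) applied at a
    representative cell diameter of 45 µm, the midpoint of the 10–80 µm range
    of measured sinking cells. Both coefficients are configuration, not truth.
    """

    diameter_um: float = 45.0
    allometric_a: float = 0.288
    allometric_b: float = 0.811

    def __post_init__(self) -> None:
        if not 10.0 <= self.diameter_um <= 80.0:
            raise UserInputError("diameter must be within the measured 10-80 µm range")
        if self.allometric_a <= 0:
            raise UserInputError("allometric_a must be positive")
        if not 0 < self.allometric_b <= 1:
            raise UserInputError("allometric_b must be in (0, 1]")

    def carbon_per_cell_pg(self) -> float:
        """pg C per cell at the model diameter."""
        return cell_carbon(sphere_volume(self.diameter_um), self)


def number_flux(count: int, surveyed_area_m2: float, duration_d: float) -> FluxRecord:
    """Number flux from a microscopy count: ``count / (area * duration)``.

    The 1-sigma counting uncertainty is ``sqrt(count) / (area * duration)``
    (Poisson counting error).
    """
    if count < 0 or count != int(count):
        raise UserInputError(f"count must be a non-negative integer, got {count}")
    if surveyed_area_m2 <= 0:
        raise UserInputError("surveyed area must be positive")
    if duration_d <= 0:
        raise UserInputError("duration must be positive")
    per = 1.0 / (surveyed_area_m2 * duration_d)
    n = int(count)
    return FluxRecord(
        value=n * per, sigma=math.sqrt(n) * per, units=CELLS, n_counted=n, per_count=per
    )


def bulk_poc_flux(
    split_masses: Sequence[float],
    split_fraction: float,
    duration_d: float,
    area_m2: float,
    units: str = CARBON,
) -> FluxRecord:
    """Bulk POC flux from replicate split masses.

    ``mean(masses) / split_fraction / duration / area``; masses are
    PIC-corrected POC per split, in the mass unit of ``units``. The sigma is
    the standard error of the replicate mean scaled the same way; a single
    replicate yields sigma 0 flagged ``single_replicate``.
    """
    masses = np.asarray(list(split_masses), dtype=float)
    if masses.size == 0:
        raise UserInputError("at least one replicate split mass is required")
    if np.any(masses < 0):
        raise UserInputError("split masses must be non-negative")
    if not 0 < split_fraction <= 1:
        raise UserInputError("split fraction must be in (0, 1]")
    if duration_d <= 0 or area_m2 <= 0:
        raise UserInputError("duration and area must be positive")
    scale = 1.0 / (split_fraction * duration_d * area_m2)
    value = float(masses.mean()) * scale
    if masses.size == 1:
        return FluxRecord(value=value, sigma=0.0, units=units, flags=("single_replicate",))
    sigma = float(masses.std(ddof=1)) / math.sqrt(masses.size) * scale
    return FluxRecord(value=value, sigma=sigma, units=units)


def depth_average_flux(profile: FluxProfile, scheme: str = "mean") -> FluxRecord:
    """Depth-averaged flux over the sampled trap depths.

    ``scheme='mean'`` (default) is the unweighted arithmetic mean over depths
    with quadrature sigma; ``scheme='trapezoid'`` depth-weights unevenly
    spaced traps by the trapezoidal integral divided by the depth range.
    """
    f = profile.values
    s = profile.sigmas if profile.sigmas is not None else np.zeros_like(f)
    if scheme == "mean":
        n = f.size
        value = float(f.mean())
        sigma = float(np.sqrt(np.sum(s**2))) / n
    elif scheme == "trapezoid":
        if f.size < 2:
            raise UserInputError("trapezoid depth average needs at least 2 depths")
        z = profile.depths_m
        span = z[-1] - z[0]
        w = np.zeros_like(f)
        w[:-1] += np.diff(z) / 2
        w[1:] += np.diff(z) / 2
        w /= span
        value = float(np.sum(w * f))
        sigma = float(np.sqrt(np.sum((w * s) ** 2)))
    else:
        raise UserInputError(f"unknown depth-average scheme {scheme!r}")
    return FluxRecord(value=value, sigma=sigma, units=profile.units)


def fold_change(later: FluxRecord, earlier: FluxRecord) -> FluxRecord:
    """Ratio later/earlier with relative sigmas added in quadrature."""
    later._require_units(earlier)
    if earlier.value <= 0:
        raise UserInputError("fold change undefined for a zero earlier flux")
    ratio = later.value / earlier.value
    rel = math.hypot(later.relative_sigma, earlier.relative_sigma)
    if not math.isfinite(rel):
        rel = 0.0
    return FluxRecord(value=ratio, sigma=ratio * rel, units=DIMENSIONLESS)


def sphere_volume(diameter_um: float) -> float:
    """Volume of a sphere in µm^3: (π/6) d^3."""
    if diameter_um <= 0:
        raise UserInputError("diameter must be positive")
    return math.pi / 6.0 * diameter_um**3


def cell_carbon(volume_um3: float, model: CellCarbonModel) -> float:
    """Carbon per cell in pg: a * V^b."""
    if volume_um3 <= 0:
        raise UserInputError("volume must be positive")
    return model.allometric_a * volume_um3**model.allometric_b


def percent_of_bulk_poc(
    cell_flux: FluxRecord, carbon_per_cell_pg: float, bulk_poc: FluxRecord
) -> FluxRecord:
    """Solitary-cell POC flux as a percentage of the bulk-trap POC flux.

    The cell number flux is converted to mmol C m-2 d-1 via the per-cell
    carbon content; the uncertainty combines the counting uncertainty and the
    bulk POC measurement uncertainty in relative quadrature.
    """
    if cell_flux.units != CELLS:
        raise UnitError(f"cell flux must be in {CELLS!r}")
    if bulk_poc.units != CARBON:
        raise UnitError(f"bulk POC flux must be in {CARBON!r}")
    if carbon_per_cell_pg <= 0:
        raise UserInputError("carbon per cell must be positive")
    if bulk_poc.value <= 0:
        raise UserInputError("bulk POC flux must be positive")
    cell_c = cell_flux.value * carbon_per_cell_pg / PG_C_PER_MMOL_C
    pct = 100.0 * cell_c / bulk_poc.value
    rel = math.hypot(cell_flux.relative_sigma, bulk_poc.relative_sigma)
    if not math.isfinite(rel):
        rel = 0.0
    return FluxRecord(value=pct, sigma=pct * rel, units=PERCENT)


def _co_deployed(a: TrapSample, b: TrapSample, depth_tol_m: float = 1.0) -> bool:
    return (
        a.site == b.site
        and a.deployment == b.deployment
        and abs(a.depth_m - b.depth_m) <= depth_tol_m
    )


def solitary_fraction(
    gel_flux: FluxRecord,
    bulk_flux: FluxRecord,
    gel_sample: TrapSample | None = None,
    bulk_sample: TrapSample | None = None,
) -> FluxRecord:
    """Fraction of a taxon's bulk-trap cell flux accounted for by solitary cells.

    A ratio of 1 means the entire sinking population was captured as solitary
    individuals in the gel; < 1 means part of the population sank embedded in
    detritus. Values above 1 (sampling noise) are allowed but flagged
    ``exceeds_unity``. If the gel count is zero the ratio uncertainty uses the
    upper 68% Poisson bound on zero counts (1.84 counts) instead of sqrt(0).
    """
    gel_flux._require_units(bulk_flux)
    if bulk_flux.value <= 0:
        raise UserInputError("bulk flux must be positive")
    if gel_sample is not None and bulk_sample is not None:
        if not _co_deployed(gel_sample, bulk_sample):
            raise UserInputError(
                "gel and bulk samples must be co-deployed (same site, deployment, depth)"
            )
    ratio = gel_flux.value / bulk_flux.value
    if gel_flux.value == 0:
        if gel_flux.per_count is not None:
            sigma = POISSON_ZERO_UPPER * gel_flux.per_count / bulk_flux.value
        else:
            sigma = 0.0
        flags = ("zero_numerator_bound",) if sigma > 0 else ()
        return FluxRecord(value=0.0, sigma=sigma, units=DIMENSIONLESS, flags=flags)
    rel = math.hypot(gel_flux.relative_sigma, bulk_flux.relative_sigma)
    flags = ("exceeds_unity",) if ratio > 1 else ()
    return FluxRecord(value=ratio, sigma=ratio * rel, units=DIMENSIONLESS, flags=flags)


def fluxes_from_counts(
    counts: pd.DataFrame, samples: Mapping[str, TrapSample]
) -> pd.DataFrame:
    """Tidy per-sample, per-taxon number fluxes from a tiered count table.

    ``counts`` has columns ``sample_id, taxon, tier, count``; each (taxon,
    tier) contributes ``count / (surveyed_area[tier] * duration)`` and tiers
    are summed per taxon (a taxon surveyed at two magnifications has
    independent counting errors per tier, combined in quadrature).

    Returns a DataFrame with columns ``sample_id, taxon, flux, sigma,
    n_counted`` in cells m-2 d-1.
    """
    required = {"sample_id", "taxon", "tier", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise UserInputError(f"count table missing columns: {sorted(missing)}")
    rows = []
    for (sid, taxon), grp in counts.groupby(["sample_id", "taxon"], sort=True):
        if sid not in samples:
            raise UserInputError(f"count table references unknown sample {sid!r}")
        sample = samples[sid]
        value = sigma2 = 0.0
        n_tot = 0
        for _, row in grp.iterrows():
            tier = row["tier"]
            if tier not in sample.gel_area_surveyed_m2:
                raise UserInputError(
                    f"sample {sid!r} has no surveyed area for tier {tier!r}"
                )
            rec = number_flux(
                int(row["count"]), sample.gel_area_surveyed_m2[tier], sample.duration_d
            )
            value += rec.value
            sigma2 += rec.sigma**2
            n_tot += rec.n_counted or 0
        rows.append(
            {
                "sample_id": sid,
                "taxon": taxon,
                "flux": value,
                "sigma": math.sqrt(sigma2),
                "n_counted": n_tot,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "taxon", "flux", "sigma", "n_counted"])
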