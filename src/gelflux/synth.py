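"""Synthetic sediment-trap gel datasets with known ground truth.

The generator emulates the four input tables of a gel-trap field campaign —
trap deployment metadata, tiered taxon count tables, replicate bulk POC
masses, and image-derived POC fluxes per detrital particle class — with the
statistical structure the downstream analysis assumes:

* Counting is Poisson: the expected count of a taxon equals its true flux
  times the surveyed gel area at its magnification tier times the collection
  duration, so the square-root-of-counts uncertainty model holds exactly.
* Replicate trap platforms at the same depth and time differ by a lognormal
  multiplier whose coefficient of variation matches the observed 22-79%
  replicate-platform spread.
* True fluxes follow a configurable depth shape: exponential decay (bloom
  export from the surface), monotone increase, or a Gaussian subsurface layer
  that translates rigidly downward at a configured speed between deployments
  (the signal the sinking-speed inversion recovers).
* The small-detrital POC flux is rank-coupled to the total cell flux through
  a Gaussian copula at a configurable Spearman correlation.

Every dataset carries a truth sidecar: the noise-free fluxes, the layer
centers per deployment, and the configured parameters, so recovery tests can
compare estimates to exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UserInputError
from .flux import CellCarbonModel, PG_C_PER_MMOL_C, TrapSample

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_scenario",
    "sample_counts",
    "DETRITAL_CLASSES",
]

#: Detrital particle classes with image-derived POC fluxes.
DETRITAL_CLASSES = (
    "small_detrital",
    "aggregates",
    "long_fecal_pellets",
    "short_ovoid_pellets",
    "salp_pellets",
    "large_particles",
)

_DEFAULT_TAXA = {
    "Thalassiosira": 4.0e5,
    "Thalassionema": 3.0e5,
    "Fragilariopsis": 1.0e6,
    "Chaetoceros": 1.5e5,
    "Pseudo-nitzschia": 1.0e5,
    "coccolithophore": 5.0e4,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic trap campaign.

    Defaults describe a three-deployment, five-depth campaign with paired
    STT/NBST platforms, 7 days between deployments and 5-day collections —
    the cadence of a month-long process study. ``platform_cv`` must lie
    within the observed 0.22-0.79 replicate-platform band.
    """

    site_label: str = "SYN"
    n_deployments: int = 3
    depths_m: tuple[float, ...] = (50.0, 100.0, 200.0, 300.0, 500.0)
    deployment_gap_d: float = 7.0
    duration_d: float = 5.0
    platforms: tuple[str, ...] = ("STT", "NBST")
    true_flux_surface: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TAXA)
    )
    depth_shape: str = "decay"
    decay_scale_m: float = 200.0
    increase_scale_m: float = 500.0
    layer_taxon: str | None = None
    layer_center_m: float = 330.0
    layer_width_m: float = 40.0
    layer_speed_m_d: float = 0.0
    deployment_fold: float = 1.0
    detrital_coupling: float = 0.0
    platform_cv: float = 0.40
    bulk_split_cv: float = 0.10
    cell_poc_fraction_of_bulk: float = 0.03
    split_fraction: float = 0.125
    n_bulk_replicates: int = 3
    gel_area_fine_m2: float = 5.0e-4
    gel_area_coarse_m2: float = 0.0113
    rare_taxa: tuple[str, ...] = ("coccolithophore",)
    carbon_model: CellCarbonModel = field(default_factory=CellCarbonModel)
    seed: int = 0

    def __post_init__(self) -> None:
        z = np.asarray(self.depths_m, dtype=float)
        if z.size == 0 or np.any(np.diff(z) <= 0):
            raise UserInputError("depths must be strictly increasing")
        if np.any(z <= 0) or np.any(z > 1000):
            raise UserInputError("depths must lie in (0, 1000] m")
        if self.n_deployments < 1:
            raise UserInputError("need at least one deployment")
        if self.deployment_gap_d <= 0 or self.duration_d <= 0:
            raise UserInputError("gap and duration must be positive")
        if any(v < 0 for v in self.true_flux_surface.values()):
            raise UserInputError("true fluxes must be non-negative")
        if self.depth_shape not in ("decay", "increase", "layer"):
            raise UserInputError(f"unknown depth_shape {self.depth_shape!r}")
        if self.layer_speed_m_d < 0:
            raise UserInputError("layer speed must be non-negative")
        if not -1 <= self.detrital_coupling <= 1:
            raise UserInputError("detrital_coupling must be in [-1, 1]")
        if not 0.22 <= self.platform_cv <= 0.79:
            raise UserInputError(
                "platform_cv must lie within the observed 0.22-0.79 band"
            )
        if self.depth_shape == "layer" and self._layer_taxon() is None:
            raise UserInputError("layer shape needs a layer taxon")
        # native types so configs serialise cleanly and hash deterministically
        object.__setattr__(self, "depths_m", tuple(float(d) for d in self.depths_m))
        object.__setattr__(
            self,
            "true_flux_surface",
            {str(k): float(v) for k, v in self.true_flux_surface.items()},
        )

    def _layer_taxon(self) -> str | None:
        if self.layer_taxon is not None:
            return self.layer_taxon
        if "Fragilariopsis" in self.true_flux_surface:
            return "Fragilariopsis"
        taxa = list(self.true_flux_surface)
        return taxa[0] if taxa else None

    def layer_center(self, deployment: int) -> float:
        """Analytic center of the Gaussian layer for a deployment (1-based)."""
        return self.layer_center_m + self.layer_speed_m_d * self.deployment_gap_d * (
            deployment - 1
        )

    def true_flux(self, taxon: str, depth_m: float, deployment: int) -> float:
        """Noise-free flux (cells m-2 d-1) of a taxon at a depth/deployment."""
        f0 = self.true_flux_surface[taxon] * self.deployment_fold ** (deployment - 1)
        if self.depth_shape == "layer" and taxon == self._layer_taxon():
            c = self.layer_center(deployment)
            return f0 * math.exp(-0.5 * ((depth_m - c) / self.layer_width_m) ** 2)
        if self.depth_shape == "increase":
            z_ref = max(self.depths_m)
            return f0 * (0.2 + 0.8 * depth_m / z_ref)
        # 'decay' and the non-layer taxa of a 'layer' scenario
        return f0 * math.exp(-depth_m / self.decay_scale_m)

    @classmethod
    def north_atlantic_like(cls, seed: int = 0) -> "ScenarioConfig":
        """Bloom-export conditions: decaying profiles, fluxes rising between
        deployments, cell and small-detrital fluxes positively rank-coupled."""
        return cls(
            site_label="NA",
            depth_shape="decay",
            deployment_fold=2.0,
            detrital_coupling=0.7,
            platform_cv=0.40,
            seed=seed,
        )

    @classmethod
    def north_pacific_like(cls, seed: int = 0, layer_speed_m_d: float = 6.6) -> "ScenarioConfig":
        """Recycling-system conditions: an order of magnitude lower fluxes, a
        deep Gaussian layer of one diatom translating downward between
        deployments, weak negative detrital coupling."""
        return cls(
            site_label="NP",
            depth_shape="layer",
            true_flux_surface={k: v / 10 for k, v in _DEFAULT_TAXA.items()},
            layer_center_m=420.0,
            layer_speed_m_d=layer_speed_m_d,
            detrital_coupling=-0.3,
            platform_cv=0.40,
            seed=seed,
        )


def sample_counts(
    true_flux: float, surveyed_area_m2: float, duration_d: float, seed: int, size: int | None = None
) -> int | np.ndarray:
    """Draw Poisson counts with mean ``true_flux * area * duration``."""
    if true_flux < 0 or surveyed_area_m2 < 0 or duration_d < 0:
        raise UserInputError("flux, area and duration must be non-negative")
    lam = true_flux * surveyed_area_m2 * duration_d
    rng = np.random.default_rng(seed)
    if size is None:
        return int(rng.poisson(lam))
    return rng.poisson(lam, size=size)


@dataclass(frozen=True)
class SyntheticTruth:
    """Noise-free ground truth behind a synthetic dataset."""

    cell_flux: pd.DataFrame  # sample_id, taxon, true_flux (no platform noise)
    layer_centers: dict[int, float] | None
    layer_taxon: str | None
    layer_speed_m_d: float
    bulk_poc_flux: pd.DataFrame  # sample_id, true_bulk_poc (mmol C m-2 d-1)
    platform_multipliers: pd.DataFrame  # sample_id, multiplier
    cell_poc_fraction_of_bulk: float

    def flux_max_depth(self, deployment: int) -> float:
        """Depth of the layer taxon's true flux maximum (the analytic layer
        center) for a deployment."""
        if self.layer_centers is None:
            raise UserInputError("scenario has no translating layer")
        return self.layer_centers[deployment]


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete synthetic campaign: samples, counts, bulk masses, detrital
    class fluxes, and the truth sidecar."""

    config: ScenarioConfig
    trap_samples: tuple[TrapSample, ...]
    counts: pd.DataFrame  # sample_id, taxon, tier, count
    bulk_masses: pd.DataFrame  # sample_id, replicate, mass_mmol
    detrital_class_fluxes: pd.DataFrame  # sample_id, particle_class, poc_flux
    truth: SyntheticTruth

    @property
    def samples_by_id(self) -> dict[str, TrapSample]:
        return {s.sample_id: s for s in self.trap_samples}


def _lognormal_mult(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multipliers with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    s2 = math.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2, sigma=math.sqrt(s2), size=size)


def generate_scenario(config: ScenarioConfig) -> SyntheticDataset:
    """Generate a synthetic dataset under a scenario configuration.

    Expected counts equal true flux x platform multiplier x surveyed area x
    duration; one lognormal platform multiplier is shared by all taxa and the
    bulk catch of a trap sample, which induces realistic cross-taxon
    correlation within a trap.
    """
    rng = np.random.default_rng(config.seed)
    taxa = list(config.true_flux_surface)
    samples: list[TrapSample] = []
    for dep in range(1, config.n_deployments + 1):
        for depth in config.depths_m:
            for platform in config.platforms:
                samples.append(
                    TrapSample(
                        site=config.site_label,
                        deployment=dep,
                        platform=platform,
                        depth_m=float(depth),
                        duration_d=config.duration_d,
                        gel_area_surveyed_m2={
                            "fine": config.gel_area_fine_m2,
                            "coarse": config.gel_area_coarse_m2,
                        },
                    )
                )
    mults = _lognormal_mult(rng, config.platform_cv, len(samples))

    count_rows = []
    truth_rows = []
    bulk_rows = []
    bulk_truth_rows = []
    carbon_pg = config.carbon_model.carbon_per_cell_pg()
    realized_cell_flux = np.zeros(len(samples))
    for i, s in enumerate(samples):
        total_true = 0.0
        for taxon in taxa:
            f_true = config.true_flux(taxon, s.depth_m, s.deployment)
            total_true += f_true
            tier = "coarse" if taxon in config.rare_taxa else "fine"
            area = s.gel_area_surveyed_m2[tier]
            lam = f_true * mults[i] * area * s.duration_d
            count_rows.append(
                {
                    "sample_id": s.sample_id,
                    "taxon": taxon,
                    "tier": tier,
                    "count": int(rng.poisson(lam)),
                }
            )
            truth_rows.append(
                {"sample_id": s.sample_id, "taxon": taxon, "true_flux": f_true}
            )
        realized_cell_flux[i] = total_true * mults[i]
        # bulk POC flux set so cell carbon is the configured fraction of bulk
        cell_poc = total_true * carbon_pg / PG_C_PER_MMOL_C  # mmol C m-2 d-1
        bulk_true = cell_poc / config.cell_poc_fraction_of_bulk
        bulk_truth_rows.append({"sample_id": s.sample_id, "true_bulk_poc": bulk_true})
        mass_base = (
            bulk_true
            * mults[i]
            * config.split_fraction
            * s.duration_d
            * s.combined_area_m2
        )
        for rep, noise in enumerate(
            _lognormal_mult(rng, config.bulk_split_cv, config.n_bulk_replicates), start=1
        ):
            bulk_rows.append(
                {
                    "sample_id": s.sample_id,
                    "replicate": rep,
                    "mass_mmol": mass_base * noise,
                }
            )

    detrital = _detrital_fluxes(config, rng, samples, realized_cell_flux, carbon_pg)

    layer = config.depth_shape == "layer"
    truth = SyntheticTruth(
        cell_flux=pd.DataFrame(truth_rows, columns=["sample_id", "taxon", "true_flux"]),
        layer_centers=(
            {d: config.layer_center(d) for d in range(1, config.n_deployments + 1)}
            if layer
            else None
        ),
        layer_taxon=config._layer_taxon() if layer else None,
        layer_speed_m_d=config.layer_speed_m_d if layer else 0.0,
        bulk_poc_flux=pd.DataFrame(bulk_truth_rows, columns=["sample_id", "true_bulk_poc"]),
        platform_multipliers=pd.DataFrame(
            {"sample_id": [s.sample_id for s in samples], "multiplier": mults}
        ),
        cell_poc_fraction_of_bulk=config.cell_poc_fraction_of_bulk,
    )
    return SyntheticDataset(
        config=config,
        trap_samples=tuple(samples),
        counts=pd.DataFrame(count_rows, columns=["sample_id", "taxon", "tier", "count"]),
        bulk_masses=pd.DataFrame(bulk_rows, columns=["sample_id", "replicate", "mass_mmol"]),
        detrital_class_fluxes=detrital,
        truth=truth,
    )


def _detrital_fluxes(
    config: ScenarioConfig,
    rng: np.random.Generator,
    samples: list[TrapSample],
    realized_cell_flux: np.ndarray,
    carbon_pg: float,
) -> pd.DataFrame:
    """Image-derived POC fluxes per detrital particle class (mmol C m-2 d-1).

    ``small_detrital`` and ``aggregates`` are rank-coupled to the realized
    total cell flux at the configured Spearman correlation via a Gaussian
    copula; ``long_fecal_pellets`` at 0.8x that coupling, ``salp_pellets`` at
    -0.5x (opposing mechanism); the remaining classes are independent
    lognormal noise. Magnitudes are pegged to the cell POC flux scale so the
    classes are comparable features for the PCA.
    """
    n = len(samples)
    cell_poc = realized_cell_flux * carbon_pg / PG_C_PER_MMOL_C
    scale = float(np.median(cell_poc)) if np.median(cell_poc) > 0 else 1e-3
    # normal scores of the realized cell flux (Gaussian copula margin)
    ranks = stats.rankdata(realized_cell_flux, method="average")
    z_cell = stats.norm.ppf((ranks - 0.5) / n)
    class_coupling = {
        "small_detrital": 1.0,
        "aggregates": 1.0,
        "long_fecal_pellets": 0.8,
        "short_ovoid_pellets": 0.0,
        "salp_pellets": -0.5,
        "large_particles": 0.0,
    }
    class_scale = {
        "small_detrital": 3.0,
        "aggregates": 10.0,
        "long_fecal_pellets": 8.0,
        "short_ovoid_pellets": 1.0,
        "salp_pellets": 5.0,
        "large_particles": 6.0,
    }
    rows = []
    for cls in DETRITAL_CLASSES:
        rho_s = config.detrital_coupling * class_coupling[cls]
        rho_s = max(-1.0, min(1.0, rho_s))
        # Pearson correlation of normal scores giving Spearman rho_s
        r = 2 * math.sin(math.pi * rho_s / 6)
        eps = rng.standard_normal(n)
        z = r * z_cell + math.sqrt(max(0.0, 1 - r**2)) * eps
        flux = scale * class_scale[cls] * np.exp(0.6 * z)
        for s, f in zip(samples, flux):
            rows.append(
                {"sample_id": s.sample_id, "particle_class": cls, "poc_flux": float(f)}
            )
    return pd.DataFrame(rows, columns=["sample_id", "particle_class", "poc_flux"])
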