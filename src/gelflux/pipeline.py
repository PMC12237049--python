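"""End-to-end analysis orchestration.

``run_pipeline`` chains the stages in field-campaign order — number/carbon
fluxes from counts, bulk POC fluxes from split masses, percent-of-bulk POC,
community dissimilarity + PERMANOVA + MDS + threshold network, covariation
(Spearman, PCA), and the rigid-translation sinking-speed inversion — and
writes every product as commented delimited text plus a run manifest. The
whole bundle is deterministic under a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    CommunityMatrix,
    bray_curtis_matrix,
    build_similarity_network,
    mds_embed,
    network_cluster_composition,
    permanova,
)
from .covariation import pca_first_two_loadings, spearman_rho
from .errors import StageError, UserInputError
from .flux import (
    PG_C_PER_MMOL_C,
    CellCarbonModel,
    FluxRecord,
    bulk_poc_flux,
    fluxes_from_counts,
    percent_of_bulk_poc,
)
from .io import (
    config_hash,
    read_bulk_table,
    read_counts_table,
    read_detrital_table,
    read_samples_table,
    write_table,
)
from .sinking import RigidTranslationModel

log = logging.getLogger("gelflux")

__all__ = ["AnalysisConfig", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of a full analysis run.

    Defaults follow common gel-trap analysis choices: a Bray-Curtis network edge
    threshold of 0.25 (strict), a 5% display floor for cluster compositions,
    and a 45 µm representative cell diameter for carbon conversion.
    """

    input_dir: str
    output_dir: str
    site_label: str = ""
    carbon_model: CellCarbonModel = field(default_factory=CellCarbonModel)
    network_threshold: float = 0.25
    display_min: float = 0.05
    bray_curtis_transform: str | None = None
    depth_average_scheme: str = "mean"
    permanova_group_by: str = "deployment"
    split_fraction: float = 0.125
    n_perm: int = 999
    sinking_taxon: str | None = None
    sinking_deployments: tuple[int, int] | None = None
    deployment_gap_d: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.network_threshold <= 1:
            raise UserInputError("network threshold must be in (0, 1]")
        if not 0 <= self.display_min < 1:
            raise UserInputError("display_min must be in [0, 1)")
        if self.n_perm < 99:
            raise UserInputError("n_perm must be at least 99")


def _meta_frame(samples) -> pd.DataFrame:
    meta = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "site": s.site,
                "deployment": s.deployment,
                "depth_m": s.depth_m,
                "platform": s.platform,
                "duration_d": s.duration_d,
            }
            for sid, s in samples.items()
        ]
    ).set_index("sample_id")
    return meta


def _community_matrix(flux_table: pd.DataFrame, meta: pd.DataFrame) -> CommunityMatrix:
    wide = flux_table.pivot(index="sample_id", columns="taxon", values="flux").fillna(0.0)
    wide = wide.sort_index()
    return CommunityMatrix(data=wide, meta=meta.loc[wide.index])


def _pick_sinking_target(
    flux_table: pd.DataFrame, meta: pd.DataFrame
) -> tuple[str, tuple[int, int]] | None:
    """Choose the taxon/deployment pair with the largest depth-integrated
    flux loss between consecutive deployments (the translation signal)."""
    best = None
    deployments = sorted(meta["deployment"].unique())
    for taxon, grp in flux_table.groupby("taxon"):
        g = grp.copy()
        g["deployment"] = meta.loc[g["sample_id"], "deployment"].to_numpy()
        g["depth_m"] = meta.loc[g["sample_id"], "depth_m"].to_numpy()
        by_dep = {
            dep: sub.groupby("depth_m")["flux"].mean().sort_index()
            for dep, sub in g.groupby("deployment")
        }
        for d1, d2 in zip(deployments[:-1], deployments[1:]):
            if d1 not in by_dep or d2 not in by_dep:
                continue
            p1, p2 = by_dep[d1], by_dep[d2]
            common = p1.index.intersection(p2.index)
            if len(common) < 2:
                continue
            z = common.to_numpy(dtype=float)
            loss = float(
                np.trapezoid(p1.loc[common].to_numpy(), z)
                - np.trapezoid(p2.loc[common].to_numpy(), z)
            )
            if best is None or loss > best[0]:
                best = (loss, taxon, (int(d1), int(d2)))
    if best is None or best[0] <= 0:
        return None
    return best[1], best[2]


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage and write the result bundle to ``config.output_dir``.

    Returns a dict of in-memory results keyed by stage. Any stage failure
    raises :class:`StageError` after removing the partial outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    # hash the scientific configuration only, not filesystem locations, so
    # identical analyses in different directories produce identical bundles
    h = config_hash({k: v for k, v in cfg_dict.items() if k not in ("input_dir", "output_dir")})
    seed = config.seed
    written: list[Path] = []
    results: dict = {}

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        written.append(write_table(df, outdir / name, seed, h, index=index))

    stage = "read-inputs"
    try:
        indir = Path(config.input_dir)
        samples = read_samples_table(indir / "samples.csv")
        counts = read_counts_table(indir / "counts.csv")
        bulk = read_bulk_table(indir / "bulk.csv")
        detrital = read_detrital_table(indir / "detrital.csv")
        meta = _meta_frame(samples)
        log.info("read %d samples, %d count rows", len(samples), len(counts))

        stage = "fluxes"
        flux_table = fluxes_from_counts(counts, samples)
        emit(flux_table, "cell_fluxes.csv")
        bulk_records: dict[str, FluxRecord] = {}
        bulk_rows = []
        for sid, grp in bulk.groupby("sample_id", sort=True):
            s = samples[sid]
            # each replicate split is split_fraction of the pooled catch
            rec = bulk_poc_flux(
                grp["mass_mmol"].to_numpy(),
                split_fraction=config.split_fraction,
                duration_d=s.duration_d,
                area_m2=s.combined_area_m2,
            )
            bulk_records[sid] = rec
            bulk_rows.append({"sample_id": sid, "poc_flux": rec.value, "sigma": rec.sigma})
        bulk_table = pd.DataFrame(bulk_rows, columns=["sample_id", "poc_flux", "sigma"])
        emit(bulk_table, "bulk_poc_fluxes.csv")

        carbon_pg = config.carbon_model.carbon_per_cell_pg()
        pct_rows = []
        totals = flux_table.groupby("sample_id")[["flux"]].sum()
        sigmas = (
            flux_table.assign(v=flux_table["sigma"] ** 2).groupby("sample_id")["v"].sum()
            ** 0.5
        )
        for sid in totals.index:
            if sid not in bulk_records:
                continue
            cell_rec = FluxRecord(
                value=float(totals.loc[sid, "flux"]), sigma=float(sigmas.loc[sid])
            )
            pct = percent_of_bulk_poc(cell_rec, carbon_pg, bulk_records[sid])
            pct_rows.append(
                {"sample_id": sid, "percent_of_bulk_poc": pct.value, "sigma": pct.sigma}
            )
        pct_table = pd.DataFrame(
            pct_rows, columns=["sample_id", "percent_of_bulk_poc", "sigma"]
        )
        emit(pct_table, "percent_of_bulk_poc.csv")
        results["fluxes"] = {
            "cell_fluxes": flux_table,
            "bulk": bulk_table,
            "percent_of_bulk_poc": pct_table,
        }

        stage = "community"
        cm = _community_matrix(flux_table, meta)
        D = bray_curtis_matrix(cm, transform=config.bray_curtis_transform)
        emit(D.to_frame(), "dissimilarity.csv", index=True)
        groups = cm.meta[config.permanova_group_by].to_numpy()
        perm = permanova(D, groups, n_perm=config.n_perm, seed=seed)
        mds = mds_embed(D)
        emit(mds.coordinates, "mds_coordinates.csv", index=True)
        net = build_similarity_network(D, cm.meta, threshold=config.network_threshold)
        edges = pd.DataFrame(net.edges, columns=["sample_a", "sample_b", "dissimilarity"])
        emit(edges, "network_edges.csv")
        emit(net.membership(), "network_clusters.csv")
        comp = network_cluster_composition(net, cm, display_min=config.display_min)
        emit(comp, "cluster_composition.csv", index=True)
        results["community"] = {
            "dissimilarity": D,
            "permanova": perm,
            "mds": mds,
            "network": net,
            "composition": comp,
        }

        stage = "covariation"
        carbon_flux = totals["flux"] * carbon_pg / PG_C_PER_MMOL_C
        wide_det = detrital.pivot(
            index="sample_id", columns="particle_class", values="poc_flux"
        )
        features = wide_det.join(carbon_flux.rename("solitary_cell_poc")).dropna()
        sp = spearman_rho(
            features["solitary_cell_poc"].to_numpy(),
            features["small_detrital"].to_numpy(),
            n_perm=config.n_perm,
            seed=seed,
        )
        sp_table = pd.DataFrame(
            [
                {
                    "x": "solitary_cell_poc",
                    "y": "small_detrital",
                    "rho": sp.rho,
                    "p_value": sp.p_value,
                    "n": sp.n,
                }
            ]
        )
        emit(sp_table, "spearman.csv")
        pca = pca_first_two_loadings(features)
        emit(pca.loadings, "pca_loadings.csv", index=True)
        emit(pca.scores, "pca_scores.csv", index=True)
        results["covariation"] = {"spearman": sp, "pca": pca}

        stage = "sink-speed"
        target = (
            (config.sinking_taxon, config.sinking_deployments)
            if config.sinking_taxon and config.sinking_deployments
            else _pick_sinking_target(flux_table, meta)
        )
        if target is None:
            sink_row = {"taxon": "", "speed_m_d": 0.0, "sink_depth_m": 0.0,
                        "delta_t_d": config.deployment_gap_d, "flags": "no_net_loss"}
        else:
            taxon, deps = target
            fit = RigidTranslationModel.from_flux_table(
                flux_table, meta, taxon, deps, delta_t_d=config.deployment_gap_d
            ).fit()
            results["sinking"] = fit
            sink_row = {
                "taxon": taxon,
                "speed_m_d": fit.speed_m_d,
                "sink_depth_m": fit.sink_depth_m,
                "delta_t_d": fit.estimate.delta_t_d,
                "flags": ";".join(fit.estimate.assumptions),
            }
        emit(pd.DataFrame([sink_row]), "sinking_speed.csv")

        stage = "manifest"
        manifest = {
            "gelflux_version": __version__,
            # filesystem locations omitted: the manifest describes the
            # analysis, and identical analyses yield identical bundles
            "config": {
                k: v for k, v in cfg_dict.items() if k not in ("input_dir", "output_dir")
            },
            "config_hash": h,
            "seed": seed,
            "outputs": sorted([p.name for p in written] + ["manifest.json"]),
            "permanova": {"pseudo_f": perm.pseudo_f, "p_value": perm.p_value},
            "spearman": {"rho": sp.rho, "p_value": sp.p_value},
            "sinking_speed_m_d": sink_row["speed_m_d"],
        }
        man_path = outdir / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        written.append(man_path)
        results["manifest"] = manifest
    except Exception as e:  # noqa: BLE001 - abort with stage name, clean partials
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, e) from e
    return results
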