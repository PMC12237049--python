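"""Delimited-text readers and writers for all tables.

All tables are comma-delimited text with a one-line ``#`` header comment
carrying the package version, the configuration hash and the seed, so every
output is traceable to the run that produced it. Column dictionaries:

* ``samples.csv``   — sample_id, site, deployment, platform, depth_m,
  duration_d, tube_area_m2, combined_area_m2, then one
  ``gel_area_<tier>_m2`` column per magnification tier.
* ``counts.csv``    — sample_id, taxon, tier, count (non-negative integers).
* ``bulk.csv``      — sample_id, replicate, mass_mmol (PIC-corrected POC per
  split, mmol C).
* ``detrital.csv``  — sample_id, particle_class, poc_flux (mmol C m-2 d-1).
* ``truth_cell_flux.csv`` + ``truth.yaml`` — noise-free sidecar of a
  synthetic dataset.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError, UserInputError
from .flux import CellCarbonModel, TrapSample
from .synth import ScenarioConfig, SyntheticDataset, SyntheticTruth

log = logging.getLogger("gelflux")

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_dataset",
    "read_dataset",
    "read_counts_table",
    "read_samples_table",
    "read_bulk_table",
    "read_detrital_table",
]

# 17 significant digits on write + round-trip parsing on read keep floats lossless
def _fmt_float(x) -> str:
    return format(float(x), ".17g")


def to_native(obj):
    """Recursively convert numpy scalars/arrays and tuples for YAML/JSON."""
    if isinstance(obj, dict):
        return {to_native(k): to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_native(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_native(v) for v in obj.tolist()]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def config_hash(obj) -> str:
    """Short deterministic hash of a configuration mapping or dataclass."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    payload = yaml.safe_dump(to_native(obj), sort_keys=True, default_flow_style=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(seed, cfg_hash: str | None) -> str:
    parts = [f"# gelflux v{__version__}"]
    if cfg_hash is not None:
        parts.append(f"config_hash={cfg_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"


def write_table(
    df: pd.DataFrame,
    path: Path | str,
    seed: int | None = None,
    cfg_hash: str | None = None,
    index: bool = False,
) -> Path:
    """Write a DataFrame as commented, comma-delimited text."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(_header(seed, cfg_hash))
    df.to_csv(buf, index=index, float_format=_fmt_float, lineterminator="\n")
    path.write_text(buf.getvalue())
    return path


def read_table(path: Path | str, index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"no such file: {path}")
    # keep_default_na=False so a site labelled "NA" stays a string; only
    # truly empty cells are missing
    return pd.read_csv(
        path,
        comment="#",
        index_col=index_col,
        float_precision="round_trip",
        keep_default_na=False,
        na_values=[""],
    )


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")


def read_counts_table(path: Path | str) -> pd.DataFrame:
    """Read and validate a tiered count table.

    Counts must be non-negative integers; violations are reported with the
    (1-based, data) row number. An empty-but-headered file returns an empty
    table with a logged warning.
    """
    df = read_table(path)
    _require_columns(df, {"sample_id", "taxon", "tier", "count"}, path)
    if df.empty:
        msg = f"{path}: count table is empty"
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
        return df
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0) | (counts != counts.round())]
    if len(bad):
        row = int(bad[0]) + 1
        raise SchemaError(
            f"{path}: row {row}: count must be a non-negative integer "
            f"(got {df.loc[bad[0], 'count']!r})"
        )
    df = df.copy()
    df["count"] = counts.astype(int)
    return df


def read_samples_table(path: Path | str) -> dict[str, TrapSample]:
    """Read trap deployment metadata into TrapSample objects keyed by id."""
    df = read_table(path)
    required = {
        "sample_id",
        "site",
        "deployment",
        "platform",
        "depth_m",
        "duration_d",
        "tube_area_m2",
        "combined_area_m2",
    }
    _require_columns(df, required, path)
    tier_cols = [c for c in df.columns if c.startswith("gel_area_") and c.endswith("_m2")]
    samples: dict[str, TrapSample] = {}
    for i, row in df.iterrows():
        areas = {
            c[len("gel_area_") : -len("_m2")]: float(row[c])
            for c in tier_cols
            if pd.notna(row[c])
        }
        try:
            s = TrapSample(
                site=str(row["site"]),
                deployment=int(row["deployment"]),
                platform=str(row["platform"]),
                depth_m=float(row["depth_m"]),
                duration_d=float(row["duration_d"]),
                tube_area_m2=float(row["tube_area_m2"]),
                combined_area_m2=float(row["combined_area_m2"]),
                gel_area_surveyed_m2=areas,
            )
        except UserInputError as e:
            raise SchemaError(f"{path}: row {int(i) + 1}: {e}") from e
        samples[str(row["sample_id"])] = s
    return samples


def read_bulk_table(path: Path | str) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, {"sample_id", "replicate", "mass_mmol"}, path)
    masses = pd.to_numeric(df["mass_mmol"], errors="coerce")
    bad = df.index[masses.isna() | (masses < 0)]
    if len(bad):
        raise SchemaError(
            f"{path}: row {int(bad[0]) + 1}: mass must be a non-negative number"
        )
    return df


def read_detrital_table(path: Path | str) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, {"sample_id", "particle_class", "poc_flux"}, path)
    flux = pd.to_numeric(df["poc_flux"], errors="coerce")
    bad = df.index[flux.isna() | (flux < 0)]
    if len(bad):
        raise SchemaError(
            f"{path}: row {int(bad[0]) + 1}: poc_flux must be a non-negative number"
        )
    return df


def _samples_frame(samples) -> pd.DataFrame:
    tiers = sorted({t for s in samples for t in s.gel_area_surveyed_m2})
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "site": s.site,
            "deployment": s.deployment,
            "platform": s.platform,
            "depth_m": s.depth_m,
            "duration_d": s.duration_d,
            "tube_area_m2": s.tube_area_m2,
            "combined_area_m2": s.combined_area_m2,
        }
        for t in tiers:
            row[f"gel_area_{t}_m2"] = s.gel_area_surveyed_m2.get(t, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(ds: SyntheticDataset, outdir: Path | str) -> dict[str, Path]:
    """Write the four input tables, the scenario config, and the truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(ds.config)
    cfg["true_flux_surface"] = dict(ds.config.true_flux_surface)
    h = config_hash(cfg)
    seed = ds.config.seed
    paths = {
        "samples": write_table(_samples_frame(ds.trap_samples), outdir / "samples.csv", seed, h),
        "counts": write_table(ds.counts, outdir / "counts.csv", seed, h),
        "bulk": write_table(ds.bulk_masses, outdir / "bulk.csv", seed, h),
        "detrital": write_table(
            ds.detrital_class_fluxes, outdir / "detrital.csv", seed, h
        ),
        "truth_cell_flux": write_table(
            ds.truth.cell_flux, outdir / "truth_cell_flux.csv", seed, h
        ),
        "truth_bulk": write_table(
            ds.truth.bulk_poc_flux, outdir / "truth_bulk_poc.csv", seed, h
        ),
        "truth_multipliers": write_table(
            ds.truth.platform_multipliers, outdir / "truth_platform_multipliers.csv", seed, h
        ),
    }
    sidecar = {
        "layer_centers": ds.truth.layer_centers,
        "layer_taxon": ds.truth.layer_taxon,
        "layer_speed_m_d": ds.truth.layer_speed_m_d,
        "cell_poc_fraction_of_bulk": ds.truth.cell_poc_fraction_of_bulk,
        "config_hash": h,
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(to_native(sidecar), sort_keys=True))
    (outdir / "config.yaml").write_text(yaml.safe_dump(to_native(cfg), sort_keys=True))
    paths["truth_yaml"] = outdir / "truth.yaml"
    paths["config"] = outdir / "config.yaml"
    return paths


def _config_from_dict(cfg: dict) -> ScenarioConfig:
    cfg = dict(cfg)
    for key in ("depths_m", "platforms", "rare_taxa"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = tuple(cfg[key])
    if isinstance(cfg.get("carbon_model"), Mapping):
        cfg["carbon_model"] = CellCarbonModel(**cfg["carbon_model"])
    return ScenarioConfig(**cfg)


def read_dataset(indir: Path | str) -> SyntheticDataset:
    """Round-trip reader for a written synthetic dataset (truth included)."""
    indir = Path(indir)
    cfg = _config_from_dict(yaml.safe_load((indir / "config.yaml").read_text()))
    samples = read_samples_table(indir / "samples.csv")
    sidecar = yaml.safe_load((indir / "truth.yaml").read_text())
    truth = SyntheticTruth(
        cell_flux=read_table(indir / "truth_cell_flux.csv"),
        layer_centers=(
            {int(k): float(v) for k, v in sidecar["layer_centers"].items()}
            if sidecar["layer_centers"]
            else None
        ),
        layer_taxon=sidecar["layer_taxon"],
        layer_speed_m_d=float(sidecar["layer_speed_m_d"]),
        bulk_poc_flux=read_table(indir / "truth_bulk_poc.csv"),
        platform_multipliers=read_table(indir / "truth_platform_multipliers.csv"),
        cell_poc_fraction_of_bulk=float(sidecar["cell_poc_fraction_of_bulk"]),
    )
    return SyntheticDataset(
        config=cfg,
        trap_samples=tuple(samples.values()),
        counts=read_counts_table(indir / "counts.csv"),
        bulk_masses=read_bulk_table(indir / "bulk.csv"),
        detrital_class_fluxes=read_detrital_table(indir / "detrital.csv"),
        truth=truth,
    )
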