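"""Study orchestration: preprocessing -> metrics -> dynamics -> tables.

``run_study`` drives the whole analysis for a dataset of networks and
produces an :class:`AnalysisTable` with one network-level row per network
(structure metrics plus guild-level mean persistence) and one species-level
row per surviving species (persistence, closeness, d').  These tables are
the analysis-ready inputs for downstream beta-error mixed models, which are
deliberately left to dedicated statistics packages.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import DynamicsConfig, IntegrationError, run_persistence
from .metrics import AnnealingConfig, find_modules, species_metrics
from .network import (
    InteractionNetwork,
    NetworkValidationError,
    StudyDataset,
    preprocess,
)

__all__ = [
    "StudyOptions",
    "AnalysisTable",
    "run_study",
    "summarize_contrast",
    "export_model_table",
    "compute_metrics_table",
]

logger = logging.getLogger(__name__)

NETWORK_COLUMNS = [
    "network_id",
    "site",
    "treatment",
    "period",
    "n_plants",
    "n_pollinators",
    "n_links",
    "total_count",
    "nodf",
    "modularity_q",
    "n_modules",
    "mean_persistence_plants",
    "mean_persistence_pollinators",
    "mean_persistence_all",
]

SPECIES_COLUMNS = [
    "network_id",
    "site",
    "treatment",
    "period",
    "species_id",
    "guild",
    "persistence",
    "weighted_closeness",
    "d_prime",
]


@dataclass(frozen=True)
class StudyOptions:
    """Pipeline switches: guild filtering and which stages to run."""

    exclude_vertebrates: bool = True
    compute_metrics: bool = True
    compute_persistence: bool = True
    annealing: AnnealingConfig = field(default_factory=AnnealingConfig)


@dataclass
class AnalysisTable:
    """Joined analysis tables plus a structured run report."""

    networks: pd.DataFrame
    species: pd.DataFrame
    report: dict

    def __post_init__(self) -> None:
        bad = self.species["persistence"].dropna()
        if len(bad) and ((bad < 0) | (bad > 1)).any():
            raise ValueError("persistence values outside [0, 1]")


def _metrics_seed(base_seed: int, network_id: str) -> np.random.Generator:
    import zlib

    ss = np.random.SeedSequence(
        entropy=base_seed, spawn_key=(zlib.crc32(network_id.encode()), 0xA11)
    )
    return np.random.default_rng(ss)


def run_study(
    dataset: StudyDataset,
    cfg: DynamicsConfig,
    options: StudyOptions | None = None,
) -> AnalysisTable:
    """Run the full per-network analysis over a dataset.

    Each network is preprocessed (optional invertebrate guild filter, then
    largest connected component), measured (NODF, annealed modularity,
    weighted closeness, d'), and simulated (replicate persistence runs).
    Networks that fail any stage are excluded and listed in the run report.
    """
    options = options or StudyOptions()
    net_rows: list[dict] = []
    sp_frames: list[pd.DataFrame] = []
    exclusions: list[dict] = []
    timings: list[dict] = []
    unsettled_total = 0
    for net in dataset:
        t0 = time.perf_counter()
        try:
            prepped = preprocess(net, options.exclude_vertebrates)
            row: dict = {
                "network_id": prepped.network_id,
                "site": prepped.site_id,
                "treatment": prepped.treatment.value,
                "period": prepped.period,
                "n_plants": prepped.n_plants,
                "n_pollinators": prepped.n_pollinators,
                "n_links": prepped.n_links,
                "total_count": prepped.total_count,
                "nodf": np.nan,
                "modularity_q": np.nan,
                "n_modules": np.nan,
                "mean_persistence_plants": np.nan,
                "mean_persistence_pollinators": np.nan,
                "mean_persistence_all": np.nan,
            }
            species = pd.DataFrame(
                {
                    "network_id": prepped.network_id,
                    "site": prepped.site_id,
                    "treatment": prepped.treatment.value,
                    "period": prepped.period,
                    "species_id": list(prepped.species_ids()),
                    "guild": ["plant"] * prepped.n_plants
                    + ["pollinator"] * prepped.n_pollinators,
                }
            )
            if options.compute_metrics:
                structure = find_modules(
                    prepped,
                    options.annealing,
                    rng=_metrics_seed(cfg.seed, prepped.network_id),
                )
                per_species = species_metrics(prepped)
                row["nodf"] = structure.nodf
                row["modularity_q"] = structure.modularity_q
                row["n_modules"] = structure.n_modules
                species["weighted_closeness"] = [
                    per_species.weighted_closeness[s] for s in species["species_id"]
                ]
                species["d_prime"] = [
                    per_species.d_prime[s] for s in species["species_id"]
                ]
            else:
                species["weighted_closeness"] = np.nan
                species["d_prime"] = np.nan
            if options.compute_persistence:
                result = run_persistence(prepped, cfg)
                unsettled_total += result.n_unsettled
                row["mean_persistence_plants"] = result.persistence_plants
                row["mean_persistence_pollinators"] = result.persistence_pollinators
                row["mean_persistence_all"] = result.persistence_all
                persistence = result.to_frame().set_index("species_id")["persistence"]
                species["persistence"] = [
                    persistence[s] for s in species["species_id"]
                ]
            else:
                species["persistence"] = np.nan
            net_rows.append(row)
            sp_frames.append(species)
        except (NetworkValidationError, IntegrationError, ValueError) as exc:
            logger.warning("excluding %s: %s", net.network_id, exc)
            exclusions.append({"network_id": net.network_id, "reason": str(exc)})
        finally:
            timings.append(
                {
                    "network_id": net.network_id,
                    "seconds": round(time.perf_counter() - t0, 3),
                }
            )
    networks = pd.DataFrame(net_rows, columns=NETWORK_COLUMNS)
    species_table = (
        pd.concat(sp_frames, ignore_index=True)[SPECIES_COLUMNS]
        if sp_frames
        else pd.DataFrame(columns=SPECIES_COLUMNS)
    )
    report = {
        "level": dataset.level,
        "n_networks_in": len(dataset),
        "n_networks_analysed": len(net_rows),
        "exclusions": exclusions,
        "unsettled_runs": int(unsettled_total),
        "preprocessing": {
            "exclude_vertebrates": options.exclude_vertebrates,
            "order": ["filter_guild", "largest_component"],
        },
        "dynamics_config": asdict(cfg),
        "timings": timings,
    }
    return AnalysisTable(networks=networks, species=species_table, report=report)


def compute_metrics_table(
    dataset: StudyDataset, options: StudyOptions | None = None, seed: int = 0
) -> AnalysisTable:
    """Structure/centrality metrics only (no simulations)."""
    options = options or StudyOptions()
    options = StudyOptions(
        exclude_vertebrates=options.exclude_vertebrates,
        compute_metrics=True,
        compute_persistence=False,
        annealing=options.annealing,
    )
    return run_study(dataset, DynamicsConfig(seed=seed, n_runs=1), options)


def summarize_contrast(
    table: AnalysisTable, group_by: Sequence[str] = ("treatment", "period")
) -> pd.DataFrame:
    """Descriptive per-group statistics of persistence and structure.

    Returns one row per group with mean, SD and n of plant / pollinator /
    overall persistence and of NODF and modularity.
    """
    allowed = {"treatment", "period", "site"}
    keys = list(group_by)
    unknown = set(keys) - allowed
    if unknown:
        raise ValueError(f"unknown grouping keys: {sorted(unknown)}")
    if table.networks.empty:
        raise ValueError("empty analysis table")
    grouped = table.networks.groupby(keys, observed=True)
    out = grouped.agg(
        n_networks=("network_id", "count"),
        plant_persistence_mean=("mean_persistence_plants", "mean"),
        plant_persistence_sd=("mean_persistence_plants", "std"),
        pollinator_persistence_mean=("mean_persistence_pollinators", "mean"),
        pollinator_persistence_sd=("mean_persistence_pollinators", "std"),
        all_persistence_mean=("mean_persistence_all", "mean"),
        all_persistence_sd=("mean_persistence_all", "std"),
        nodf_mean=("nodf", "mean"),
        nodf_sd=("nodf", "std"),
        modularity_mean=("modularity_q", "mean"),
        modularity_sd=("modularity_q", "std"),
    )
    return out.reset_index()


def export_model_table(table: AnalysisTable, outdir: str | Path) -> dict[str, Path]:
    """Write model-ready CSVs for external beta-error mixed-model fitting.

    The network table gains a total-species column and its square (richness
    covariates); the species table gains per-network max-scaled centrality.
    All grouping columns needed for by-site / by-species / by-network random
    intercepts are carried along.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    networks = table.networks.copy()
    networks["n_species_total"] = networks["n_plants"] + networks["n_pollinators"]
    networks["n_species_total_sq"] = networks["n_species_total"] ** 2
    species = table.species.copy()
    if not species.empty:
        scale = species.groupby("network_id")["weighted_closeness"].transform("max")
        species["closeness_scaled"] = np.where(
            scale > 0, species["weighted_closeness"] / scale, 0.0
        )
    else:
        species["closeness_scaled"] = pd.Series(dtype=float)
    paths = {
        "networks": outdir / "network_table.csv",
        "species": outdir / "species_table.csv",
    }
    networks.to_csv(paths["networks"], index=False, float_format="%.10g")
    species.to_csv(paths["species"], index=False, float_format="%.10g")
    return paths
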