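"""Bipartite plant–pollinator interaction networks: data model, I/O, preparation.

The central object is :class:`InteractionNetwork`, a weighted bipartite count
matrix (rows = plants, columns = pollinators) carrying site / treatment /
period metadata and per-species taxonomic annotations.  The preparation
operations mirror a field study's workflow: restrict the pollinator guild to
invertebrates, keep only the largest connected component of compartmentalised
networks, and pool monthly networks into early- and late-season aggregates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Treatment",
    "SpeciesInfo",
    "InteractionNetwork",
    "StudyDataset",
    "NetworkFormatError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "read_species_meta",
    "write_species_meta",
    "load_dataset",
    "save_dataset",
    "filter_guild",
    "largest_component",
    "pool_season",
    "preprocess",
    "EARLY_MONTHS",
    "LATE_MONTHS",
]

#: Calendar months belonging to the early flowering season (Sep–Dec) and the
#: late season (Jan–Apr).  Months are encoded as ISO "YYYY-MM" labels.
EARLY_MONTHS = frozenset({9, 10, 11, 12})
LATE_MONTHS = frozenset({1, 2, 3, 4})


class NetworkFormatError(ValueError):
    """Raised when an input file cannot be parsed as an interaction network."""


class NetworkValidationError(ValueError):
    """Raised when network contents violate the data-model invariants."""


class Treatment(str, Enum):
    RESTORED = "restored"
    UNRESTORED = "unrestored"


@dataclass(frozen=True)
class SpeciesInfo:
    """Per-species annotation: guild membership and coarse taxonomy."""

    guild: str  # "plant" or "pollinator"
    taxon_group: str = "unknown"
    is_vertebrate: bool = False


@dataclass
class InteractionNetwork:
    """A weighted bipartite plant–pollinator network for one site and period.

    Parameters
    ----------
    plant_ids, pollinator_ids
        Ordered, unique species identifiers for each guild.
    counts
        Non-negative integer matrix of shape ``(len(plant_ids),
        len(pollinator_ids))`` giving the observed interaction frequency
        (number of recorded visits) for each plant–pollinator pair.
    site_id
        Site label; sites are the experimental unit of the restoration design.
    treatment
        Whether invasive plants were removed at this site (``restored``) or
        left in place (``unrestored``).
    period
        Either an ISO month label ("YYYY-MM") or a season label
        ("early" / "late").
    species_meta
        Optional map species id -> :class:`SpeciesInfo`; required by the
        vertebrate guild filter.
    """

    plant_ids: tuple[str, ...]
    pollinator_ids: tuple[str, ...]
    counts: np.ndarray
    site_id: str
    treatment: Treatment
    period: str
    species_meta: dict[str, SpeciesInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.plant_ids = tuple(str(p) for p in self.plant_ids)
        self.pollinator_ids = tuple(str(a) for a in self.pollinator_ids)
        self.treatment = Treatment(self.treatment)
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise NetworkValidationError("counts must be a 2-D matrix")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise NetworkFormatError("interaction counts must be integers")
        counts = counts.astype(np.int64, copy=True)
        if np.any(counts < 0):
            raise NetworkFormatError("interaction counts must be non-negative")
        if counts.shape != (len(self.plant_ids), len(self.pollinator_ids)):
            raise NetworkValidationError(
                f"counts shape {counts.shape} does not match id lists "
                f"({len(self.plant_ids)} plants, {len(self.pollinator_ids)} pollinators)"
            )
        all_ids = self.plant_ids + self.pollinator_ids
        if len(set(all_ids)) != len(all_ids):
            raise NetworkValidationError("duplicated species identifiers")
        self.counts = counts

    # -- basic descriptors -------------------------------------------------

    @property
    def network_id(self) -> str:
        return f"{self.site_id}_{self.period}"

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinator_ids)

    @property
    def n_species(self) -> int:
        return self.n_plants + self.n_pollinators

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def binary(self) -> np.ndarray:
        """Presence/absence incidence matrix."""
        return (self.counts > 0).astype(np.int8)

    def species_ids(self) -> tuple[str, ...]:
        return self.plant_ids + self.pollinator_ids

    def to_graph(self) -> nx.Graph:
        """Undirected bipartite graph; edge attribute ``weight`` = count."""
        g = nx.Graph()
        g.add_nodes_from(self.plant_ids, bipartite="plant")
        g.add_nodes_from(self.pollinator_ids, bipartite="pollinator")
        rows, cols = np.nonzero(self.counts)
        for i, k in zip(rows, cols):
            g.add_edge(
                self.plant_ids[i],
                self.pollinator_ids[k],
                weight=int(self.counts[i, k]),
            )
        return g

    def subnetwork(
        self, plants: Sequence[str], pollinators: Sequence[str]
    ) -> "InteractionNetwork":
        """Induced sub-network on the given species, preserving order."""
        keep_p = [p for p in self.plant_ids if p in set(plants)]
        keep_a = [a for a in self.pollinator_ids if a in set(pollinators)]
        ridx = [self.plant_ids.index(p) for p in keep_p]
        cidx = [self.pollinator_ids.index(a) for a in keep_a]
        meta = {
            s: self.species_meta[s]
            for s in (*keep_p, *keep_a)
            if s in self.species_meta
        }
        return InteractionNetwork(
            plant_ids=tuple(keep_p),
            pollinator_ids=tuple(keep_a),
            counts=self.counts[np.ix_(ridx, cidx)] if keep_p and keep_a else
            np.zeros((len(keep_p), len(keep_a)), dtype=np.int64),
            site_id=self.site_id,
            treatment=self.treatment,
            period=self.period,
            species_meta=meta,
        )


@dataclass
class StudyDataset:
    """A collection of networks at a single temporal level (month or season)."""

    networks: list[InteractionNetwork]
    level: str  # "month" or "season"

    def __post_init__(self) -> None:
        if self.level not in ("month", "season"):
            raise NetworkValidationError(f"unknown dataset level {self.level!r}")
        site_treat: dict[str, Treatment] = {}
        for net in self.networks:
            prev = site_treat.setdefault(net.site_id, net.treatment)
            if prev != net.treatment:
                raise NetworkValidationError(
                    f"site {net.site_id} has inconsistent treatment labels"
                )

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)

    def sites(self) -> list[str]:
        return sorted({net.site_id for net in self.networks})


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _month_number(period: str) -> int:
    try:
        year, month = period.split("-")
        m = int(month)
        int(year)
    except (ValueError, AttributeError) as exc:
        raise NetworkValidationError(
            f"period {period!r} is not an ISO YYYY-MM month label"
        ) from exc
    if not 1 <= m <= 12:
        raise NetworkValidationError(f"month {m} out of range in {period!r}")
    return m


def read_network(
    path: str | Path,
    format: str = "matrix_csv",
    *,
    site_id: str,
    treatment: Treatment | str,
    period: str,
    species_meta: Mapping[str, SpeciesInfo] | None = None,
) -> InteractionNetwork:
    """Read an interaction network from CSV.

    ``matrix_csv`` files carry plant ids in the first column and pollinator
    ids in the header row; ``edge_list_csv`` files have columns
    ``plant,pollinator,count`` and absent pairs are implicitly zero.
    """
    path = Path(path)
    if format == "matrix_csv":
        try:
            frame = pd.read_csv(path, index_col=0)
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise NetworkFormatError(f"cannot parse {path}: {exc}") from exc
        plant_ids = tuple(str(i) for i in frame.index)
        pollinator_ids = tuple(str(c) for c in frame.columns)
        values = frame.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise NetworkFormatError(f"non-numeric counts in {path}")
        counts = values
    elif format == "edge_list_csv":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            raise NetworkFormatError(f"cannot parse {path}: {exc}") from exc
        required = {"plant", "pollinator", "count"}
        if not required.issubset(frame.columns):
            raise NetworkFormatError(
                f"edge list {path} must have columns {sorted(required)}"
            )
        if not np.issubdtype(frame["count"].dtype, np.number):
            raise NetworkFormatError(f"non-numeric counts in {path}")
        plant_ids = tuple(dict.fromkeys(str(p) for p in frame["plant"]))
        pollinator_ids = tuple(dict.fromkeys(str(a) for a in frame["pollinator"]))
        counts = np.zeros((len(plant_ids), len(pollinator_ids)))
        pidx = {p: i for i, p in enumerate(plant_ids)}
        aidx = {a: k for k, a in enumerate(pollinator_ids)}
        for _, row in frame.iterrows():
            counts[pidx[str(row["plant"])], aidx[str(row["pollinator"])]] += row[
                "count"
            ]
    else:
        raise ValueError(f"unknown network format {format!r}")
    if np.any(np.asarray(counts, dtype=float) < 0):
        raise NetworkFormatError(f"negative counts in {path}")
    meta = dict(species_meta) if species_meta else {}
    relevant = {
        s: meta[s] for s in (*plant_ids, *pollinator_ids) if s in meta
    }
    return InteractionNetwork(
        plant_ids=plant_ids,
        pollinator_ids=pollinator_ids,
        counts=counts,
        site_id=site_id,
        treatment=treatment,
        period=period,
        species_meta=relevant,
    )


def write_network(net: InteractionNetwork, path: str | Path, format: str = "matrix_csv") -> None:
    path = Path(path)
    if format == "matrix_csv":
        frame = pd.DataFrame(
            net.counts, index=list(net.plant_ids), columns=list(net.pollinator_ids)
        )
        frame.to_csv(path)
    elif format == "edge_list_csv":
        rows, cols = np.nonzero(net.counts)
        frame = pd.DataFrame(
            {
                "plant": [net.plant_ids[i] for i in rows],
                "pollinator": [net.pollinator_ids[k] for k in cols],
                "count": [int(net.counts[i, k]) for i, k in zip(rows, cols)],
            }
        )
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_species_meta(path: str | Path) -> dict[str, SpeciesInfo]:
    """Species metadata CSV with columns id,guild,taxon_group,is_vertebrate."""
    frame = pd.read_csv(path)
    required = {"id", "guild", "taxon_group", "is_vertebrate"}
    if not required.issubset(frame.columns):
        raise NetworkFormatError(
            f"species metadata {path} must have columns {sorted(required)}"
        )
    meta = {}
    for _, row in frame.iterrows():
        meta[str(row["id"])] = SpeciesInfo(
            guild=str(row["guild"]),
            taxon_group=str(row["taxon_group"]),
            is_vertebrate=bool(row["is_vertebrate"]),
        )
    return meta


def write_species_meta(meta: Mapping[str, SpeciesInfo], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "id": list(meta),
            "guild": [m.guild for m in meta.values()],
            "taxon_group": [m.taxon_group for m in meta.values()],
            "is_vertebrate": [m.is_vertebrate for m in meta.values()],
        }
    )
    frame.to_csv(path, index=False)


def load_dataset(manifest_path: str | Path) -> StudyDataset:
    """Load a dataset from a YAML/JSON manifest.

    The manifest lists per-network entries ``{path, format, site, treatment,
    period}`` plus a dataset ``level`` and an optional ``species_meta`` CSV
    path (relative paths are resolved against the manifest's directory).
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    if manifest_path.suffix in (".yaml", ".yml"):
        manifest = yaml.safe_load(text)
    else:
        manifest = json.loads(text)
    base = manifest_path.parent
    meta: dict[str, SpeciesInfo] = {}
    if manifest.get("species_meta"):
        meta = read_species_meta(base / manifest["species_meta"])
    networks = []
    for entry in manifest["networks"]:
        networks.append(
            read_network(
                base / entry["path"],
                format=entry.get("format", "matrix_csv"),
                site_id=str(entry["site"]),
                treatment=entry["treatment"],
                period=str(entry["period"]),
                species_meta=meta,
            )
        )
    return StudyDataset(networks=networks, level=manifest.get("level", "month"))


def save_dataset(dataset: StudyDataset, outdir: str | Path, format: str = "matrix_csv") -> Path:
    """Write every network plus species metadata and a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    meta: dict[str, SpeciesInfo] = {}
    for net in dataset:
        fname = f"{net.network_id}.csv"
        write_network(net, outdir / fname, format=format)
        meta.update(net.species_meta)
        entries.append(
            {
                "path": fname,
                "format": format,
                "site": net.site_id,
                "treatment": net.treatment.value,
                "period": net.period,
            }
        )
    write_species_meta(meta, outdir / "species_meta.csv")
    manifest = {
        "level": dataset.level,
        "species_meta": "species_meta.csv",
        "networks": entries,
    }
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


# ---------------------------------------------------------------------------
# Data-preparation operations
# ---------------------------------------------------------------------------


def filter_guild(
    net: InteractionNetwork, exclude_vertebrates: bool = True
) -> InteractionNetwork:
    """Restrict the pollinator guild to invertebrates.

    Vertebrate pollinator columns are removed; plants left without any
    interaction are dropped as well.  With ``exclude_vertebrates=False`` the
    network is returned unchanged (a shallow copy).
    """
    if not exclude_vertebrates:
        return replace(net)
    keep_a = []
    for a in net.pollinator_ids:
        info = net.species_meta.get(a)
        if info is None:
            raise NetworkValidationError(
                f"missing taxon metadata for pollinator {a!r}"
            )
        if not info.is_vertebrate:
            keep_a.append(a)
    if not keep_a:
        raise NetworkValidationError(
            "guild filter removed every pollinator; network is empty"
        )
    cidx = [net.pollinator_ids.index(a) for a in keep_a]
    sub = net.counts[:, cidx]
    keep_p = [p for i, p in enumerate(net.plant_ids) if sub[i].sum() > 0]
    if not keep_p:
        raise NetworkValidationError(
            "guild filter left no interacting plants; network is empty"
        )
    return net.subnetwork(keep_p, keep_a)


def largest_component(net: InteractionNetwork) -> InteractionNetwork:
    """Keep only the connected component with the most species.

    Ties are broken by (1) larger total interaction count, then (2) the
    component containing the lexicographically smallest species id, so the
    choice is deterministic.
    """
    if net.n_plants == 0 or net.n_pollinators == 0:
        raise NetworkValidationError("cannot take largest component of empty network")
    g = net.to_graph()
    components = list(nx.connected_components(g))

    def component_total(comp: set[str]) -> int:
        return sum(
            d["weight"] for u, v, d in g.edges(comp, data=True)
        )

    top = max((len(c), component_total(c)) for c in components)
    tied = [c for c in components if (len(c), component_total(c)) == top]
    best = min(tied, key=lambda c: min(c))
    if len(best) == net.n_species:
        return replace(net)
    plants = [p for p in net.plant_ids if p in best]
    pollinators = [a for a in net.pollinator_ids if a in best]
    return net.subnetwork(plants, pollinators)


def pool_season(
    nets: Sequence[InteractionNetwork],
) -> tuple[InteractionNetwork, InteractionNetwork]:
    """Aggregate one site's monthly networks into (early, late) season networks.

    Early season = September–December, late season = January–April.  Counts
    are element-wise sums on the union of species; species never observed in
    a season's months are excluded from that season's network.
    """
    if not nets:
        raise NetworkValidationError("no networks to pool")
    site = nets[0].site_id
    treatment = nets[0].treatment
    for net in nets:
        if net.site_id != site or net.treatment != treatment:
            raise NetworkValidationError(
                "pool_season requires networks from a single site/treatment"
            )
    groups: dict[str, list[InteractionNetwork]] = {"early": [], "late": []}
    for net in nets:
        m = _month_number(net.period)
        if m in EARLY_MONTHS:
            groups["early"].append(net)
        elif m in LATE_MONTHS:
            groups["late"].append(net)
        else:
            raise NetworkValidationError(
                f"month {net.period!r} outside the September–April flowering season"
            )
    pooled = []
    for season in ("early", "late"):
        members = sorted(groups[season], key=lambda n: n.period)
        if not members:
            raise NetworkValidationError(f"no monthly networks for {season} season")
        if len(members) < 4:
            warnings.warn(
                f"{site}: only {len(members)} month(s) available for the "
                f"{season} season; pooling what exists",
                stacklevel=2,
            )
        plants = list(dict.fromkeys(p for n in members for p in n.plant_ids))
        pollinators = list(
            dict.fromkeys(a for n in members for a in n.pollinator_ids)
        )
        counts = np.zeros((len(plants), len(pollinators)), dtype=np.int64)
        pidx = {p: i for i, p in enumerate(plants)}
        aidx = {a: k for k, a in enumerate(pollinators)}
        meta: dict[str, SpeciesInfo] = {}
        for n in members:
            rows = [pidx[p] for p in n.plant_ids]
            cols = [aidx[a] for a in n.pollinator_ids]
            counts[np.ix_(rows, cols)] += n.counts
            meta.update(n.species_meta)
        keep_p = [p for p in plants if counts[pidx[p]].sum() > 0]
        keep_a = [a for a in pollinators if counts[:, aidx[a]].sum() > 0]
        ridx = [pidx[p] for p in keep_p]
        cidx = [aidx[a] for a in keep_a]
        pooled.append(
            InteractionNetwork(
                plant_ids=tuple(keep_p),
                pollinator_ids=tuple(keep_a),
                counts=counts[np.ix_(ridx, cidx)],
                site_id=site,
                treatment=treatment,
                period=season,
                species_meta={
                    s: meta[s] for s in (*keep_p, *keep_a) if s in meta
                },
            )
        )
    return pooled[0], pooled[1]


def preprocess(
    net: InteractionNetwork, exclude_vertebrates: bool = True
) -> InteractionNetwork:
    """Standard preparation: guild filter, then largest component.

    The order (filter first, component second) is fixed and recorded here so
    structure metrics and dynamics always describe the same species set.
    """
    return largest_component(filter_guild(net, exclude_vertebrates))
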