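"""Synthetic restored/unrestored study datasets.

Emulates the shape of a paired restoration experiment on tropical inselberg
plant–pollinator communities: eight sites split evenly between a "restored"
treatment (invasive plants removed) and an "unrestored" treatment, observed
monthly across one flowering season (September–April, 64 networks), poolable
into early/late season aggregates (16 networks).

The generative model produces skewed interaction-frequency distributions and
tunable nestedness via heavy-tailed species "abundance" weights: link
probability is proportional to the product of endpoint weights, so a more
skewed weight distribution concentrates links on generalist cores (higher
NODF).  Optional block structure adds modularity.  Unrestored sites
additionally contain one invasive generalist plant that flowers in every
month and is wired to a large fraction of the pollinator fauna, carrying a
fixed share of the interaction counts; restored sites omit it.  Native plant
richness declines in the late season (marked wet/dry seasonality), which
makes the ever-flowering invasive the dominant late-season resource in
unrestored sites.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .network import (
    EARLY_MONTHS,
    LATE_MONTHS,
    InteractionNetwork,
    SpeciesInfo,
    StudyDataset,
    Treatment,
    _month_number,
)

__all__ = ["SyntheticDesign", "generate_site_network", "generate_dataset"]

_DEFAULT_MONTHS = (
    "2012-09",
    "2012-10",
    "2012-11",
    "2012-12",
    "2013-01",
    "2013-02",
    "2013-03",
    "2013-04",
)

_INVERTEBRATE_TAXA = ("Hymenoptera", "Lepidoptera", "Diptera", "Coleoptera")


@dataclass(frozen=True)
class SyntheticDesign:
    """Design parameters of the synthetic study.

    Attributes
    ----------
    n_sites_per_treatment : int
        Sites per treatment arm (default 4, i.e. 8 sites in total).
    months : tuple of str
        ISO month labels spanning one flowering season; the default 8 months
        give 64 month-level networks.
    n_plants_range, n_pollinators_range : (int, int)
        Per-month native richness intervals (early season) per site.
    connectance : float
        Target fraction of realised native plant–pollinator links.
    nestedness_strength : float
        Sigma of the lognormal species-weight distribution; larger values
        mean a more skewed generalist core and higher NODF.
    module_count : int
        Number of blocks overlaid on the link probabilities (0 = none).
    invasive_generalism : float
        Fraction of the pollinators present in a month that the invasive
        plant links to (unrestored sites only).
    invasive_weight_share : float
        Fraction of each unrestored network's total interaction counts routed
        through the invasive plant.
    late_season_turnover : float
        Fraction of the native species pool replaced between the early and
        late season.
    late_plant_richness_factor : float
        Multiplier on native plant richness in late-season months; values
        below 1 emulate the late-season scarcity of flowering natives.
    count_dispersion : float
        Gamma-shape of the negative-binomial-like count distribution on
        realised links (smaller = more overdispersed).
    vertebrate_fraction : float
        Fraction of the pollinator pool tagged as vertebrates (geckos and
        birds) for exercising the guild filter; 0 by default.
    """

    n_sites_per_treatment: int = 4
    months: tuple[str, ...] = _DEFAULT_MONTHS
    n_plants_range: tuple[int, int] = (9, 13)
    n_pollinators_range: tuple[int, int] = (14, 20)
    connectance: float = 0.25
    nestedness_strength: float = 1.0
    module_count: int = 0
    invasive_generalism: float = 0.85
    invasive_weight_share: float = 0.45
    late_season_turnover: float = 0.3
    late_plant_richness_factor: float = 0.5
    count_dispersion: float = 0.6
    vertebrate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "connectance",
            "invasive_generalism",
            "invasive_weight_share",
            "late_season_turnover",
            "vertebrate_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.invasive_weight_share >= 1.0:
            raise ValueError("invasive_weight_share must be < 1")
        for name in ("n_plants_range", "n_pollinators_range"):
            lo, hi = getattr(self, name)
            if lo < 2 or hi < lo:
                raise ValueError(f"{name} must satisfy 2 <= lo <= hi")
        for month in self.months:
            if _month_number(month) not in EARLY_MONTHS | LATE_MONTHS:
                raise ValueError(
                    f"month {month!r} lies outside the September–April flowering season"
                )

    def site_labels(self) -> list[tuple[str, Treatment]]:
        sites = []
        for i in range(self.n_sites_per_treatment):
            sites.append((f"R{i + 1}", Treatment.RESTORED))
        for i in range(self.n_sites_per_treatment):
            sites.append((f"U{i + 1}", Treatment.UNRESTORED))
        return sites


# ---------------------------------------------------------------------------
# Site species pools
# ---------------------------------------------------------------------------


@dataclass
class _GuildPool:
    ids: list[str]
    weights: np.ndarray
    blocks: np.ndarray
    early: np.ndarray  # index arrays into the pool
    late: np.ndarray
    meta: dict[str, SpeciesInfo]


def _season_windows(pool_size: int, window: int, turnover: float) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping early/late index windows sharing (1 - turnover) of species."""
    shift = int(round(turnover * window))
    shift = min(shift, pool_size - window)
    early = np.arange(0, window)
    late = np.arange(shift, shift + window)
    return early, late


def _site_pools(design: SyntheticDesign, site: str) -> tuple[_GuildPool, _GuildPool]:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=design.seed, spawn_key=(zlib.crc32(site.encode()), 0))
    )
    pools = []
    for guild, (lo, hi), prefix in (
        ("plant", design.n_plants_range, "P"),
        ("pollinator", design.n_pollinators_range, "A"),
    ):
        window = int(math.ceil(1.3 * hi))
        size = window + int(math.ceil(design.late_season_turnover * window)) + 2
        ids = [f"{site}-{prefix}{i:02d}" for i in range(size)]
        weights = rng.lognormal(mean=0.0, sigma=design.nestedness_strength, size=size)
        blocks = (
            rng.integers(0, design.module_count, size=size)
            if design.module_count > 0
            else np.zeros(size, dtype=np.int64)
        )
        early, late = _season_windows(size, window, design.late_season_turnover)
        meta: dict[str, SpeciesInfo] = {}
        n_vert = (
            int(round(design.vertebrate_fraction * size))
            if guild == "pollinator"
            else 0
        )
        vertebrate_idx = set(rng.choice(size, size=n_vert, replace=False)) if n_vert else set()
        for i, sid in enumerate(ids):
            if guild == "plant":
                meta[sid] = SpeciesInfo(guild="plant", taxon_group="Angiospermae")
            elif i in vertebrate_idx:
                meta[sid] = SpeciesInfo(
                    guild="pollinator", taxon_group="Gekkonidae", is_vertebrate=True
                )
            else:
                meta[sid] = SpeciesInfo(
                    guild="pollinator",
                    taxon_group=_INVERTEBRATE_TAXA[i % len(_INVERTEBRATE_TAXA)],
                )
        pools.append(
            _GuildPool(ids=ids, weights=weights, blocks=blocks, early=early, late=late, meta=meta)
        )
    return pools[0], pools[1]


def _sample_present(
    pool: _GuildPool, season: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    candidates = pool.early if season == "early" else pool.late
    n = min(n, candidates.size)
    w = pool.weights[candidates]
    chosen = rng.choice(candidates, size=n, replace=False, p=w / w.sum())
    return np.sort(chosen)


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------


def _link_matrix(
    wp: np.ndarray,
    wa: np.ndarray,
    bp: np.ndarray,
    ba: np.ndarray,
    design: SyntheticDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli link topology with weight-product probabilities."""
    prod = np.outer(wp, wa)
    if design.module_count > 0:
        boost = np.where(bp[:, None] == ba[None, :], 4.0, 0.5)
        prod = prod * boost
    lam = design.connectance / prod.mean()
    prob = np.clip(lam * prod, 0.0, 1.0)
    links = rng.random(prob.shape) < prob
    # every present species keeps at least one link (to its strongest partner)
    for i in np.nonzero(~links.any(axis=1))[0]:
        links[i, np.argmax(wa)] = True
    for k in np.nonzero(~links.any(axis=0))[0]:
        links[np.argmax(wp), k] = True
    return links


def _draw_counts(
    links: np.ndarray,
    wp: np.ndarray,
    wa: np.ndarray,
    design: SyntheticDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Skewed per-link visit counts: 1 + negative binomial with mean tied to
    the endpoint weight product."""
    counts = np.zeros(links.shape, dtype=np.int64)
    rows, cols = np.nonzero(links)
    prod = wp[rows] * wa[cols]
    mu = 4.0 * prod / prod.mean()
    shape = design.count_dispersion
    p = shape / (shape + mu)
    counts[rows, cols] = 1 + rng.negative_binomial(shape, p)
    return counts


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    quota = total * weights / weights.sum()
    alloc = np.floor(quota).astype(np.int64)
    rem = total - int(alloc.sum())
    if rem > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:rem]] += 1
    return alloc


def generate_site_network(
    design: SyntheticDesign,
    site: str,
    treatment: Treatment | str,
    month: str,
    rng: np.random.Generator | None = None,
) -> InteractionNetwork:
    """Generate one site-month network.

    The site's species pool (identities, abundance weights, block labels) is
    derived deterministically from ``design.seed`` and the site label, so the
    same species recur across that site's months; the month-level draw
    (presence, links, counts) uses ``rng``, which defaults to a stream keyed
    by (seed, site, month).
    """
    treatment = Treatment(treatment)
    month_no = _month_number(month)
    season = "early" if month_no in EARLY_MONTHS else "late"
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=design.seed,
                spawn_key=(zlib.crc32(site.encode()), 1 + zlib.crc32(month.encode())),
            )
        )
    plant_pool, poll_pool = _site_pools(design, site)

    lo, hi = design.n_plants_range
    n_plants = int(rng.integers(lo, hi + 1))
    if season == "late":
        n_plants = max(2, int(round(n_plants * design.late_plant_richness_factor)))
    lo_a, hi_a = design.n_pollinators_range
    n_poll = int(rng.integers(lo_a, hi_a + 1))

    p_idx = _sample_present(plant_pool, season, n_plants, rng)
    a_idx = _sample_present(poll_pool, season, n_poll, rng)
    wp = plant_pool.weights[p_idx]
    wa = poll_pool.weights[a_idx]

    links = _link_matrix(
        wp, wa, plant_pool.blocks[p_idx], poll_pool.blocks[a_idx], design, rng
    )
    counts = _draw_counts(links, wp, wa, design, rng)

    plant_ids = [plant_pool.ids[i] for i in p_idx]
    poll_ids = [poll_pool.ids[k] for k in a_idx]
    meta = {sid: plant_pool.meta[sid] for sid in plant_ids}
    meta.update({sid: poll_pool.meta[sid] for sid in poll_ids})

    if treatment is Treatment.UNRESTORED:
        # One invasive generalist plant, flowering every month, linked to a
        # broad random subset of the month's pollinators and carrying a fixed
        # share of the network's interaction counts.
        inv_id = f"{site}-INV"
        n_links = max(1, int(math.ceil(design.invasive_generalism * len(poll_ids))))
        linked = np.sort(rng.choice(len(poll_ids), size=n_links, replace=False))
        native_total = int(counts.sum())
        share = design.invasive_weight_share
        inv_total = max(n_links, int(round(share / (1.0 - share) * native_total)))
        inv_counts = _largest_remainder(inv_total - n_links, wa[linked]) + 1
        inv_row = np.zeros(len(poll_ids), dtype=np.int64)
        inv_row[linked] = inv_counts
        counts = np.vstack([counts, inv_row])
        plant_ids.append(inv_id)
        meta[inv_id] = SpeciesInfo(guild="plant", taxon_group="invasive")

    return InteractionNetwork(
        plant_ids=tuple(plant_ids),
        pollinator_ids=tuple(poll_ids),
        counts=counts,
        site_id=site,
        treatment=treatment,
        period=month,
        species_meta=meta,
    )


def generate_dataset(design: SyntheticDesign) -> StudyDataset:
    """Generate the full month-level dataset (default: 8 sites x 8 months)."""
    networks = []
    for site, treatment in design.site_labels():
        for month in design.months:
            networks.append(generate_site_network(design, site, treatment, month))
    return StudyDataset(networks=networks, level="month")
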