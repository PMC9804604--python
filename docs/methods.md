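# Methods

`pollinet` estimates the long-term persistence of plants and pollinators in
bipartite interaction networks under a mutualistic population-dynamics model,
and relates persistence to network structure (nestedness, modularity) and to
species position (weighted closeness, specialisation d'). It ships a
synthetic-data generator shaped like a paired restoration experiment
(invasive-plant removal) so the entire analysis is runnable and testable
without any external dataset.

## Dynamic model

Abundance densities follow coupled Lotka–Volterra equations with a type-II
(saturating) mutualistic functional response. For plant *i*:

    dS_i^P/dt = alpha_i^P S_i^P
              - sum_{j in P} beta_ij^P S_i^P S_j^P
              + S_i^P * (sum_{k in A} gamma_ik^P S_k^A)
                      / (1 + h^P * sum_{l in A} gamma_il^P S_l^A)

and symmetrically for pollinators with the guild indices exchanged.
Assumptions baked into this form:

- **Mean-field within-guild competition.** Every within-guild pair competes
  (`beta_ij` for all j in the guild), with intraspecific competition
  (`beta_ii ~ 1.0`) strictly stronger than interspecific (`beta_ij ~ 0.23`),
  which prevents trivial single-species takeover.
- **Topology-only mutualism.** `gamma_ik` is non-zero exactly where the
  observed network records an interaction, drawn uniformly from one interval
  and *not* scaled by interaction frequency. Observed counts therefore set
  which links exist; link-specific strengths are random. The two directions
  of a link (plant benefit and animal benefit) are drawn independently.
- **Saturating benefit.** The handling-time denominator caps the per-capita
  mutualistic gain when partner abundance is high. This matters for the
  restoration contrast: an extra generalist resource changes little where
  partners are already plentiful, and a lot where they are scarce.
- **No migration, no demographic noise, no time-varying parameters.**

One literal consequence worth flagging: with all-positive growth rates,
an isolated pollinator equilibrates at `alpha/beta_ii` rather than dying
out, even though the biological reading is that pollinators depend on
plants. The equations are implemented literally; obligate dependence
enters only through competition (species with little mutualistic benefit
are competitively excluded in communities of realistic size).

### Parameters (all uniform draws unless noted)

| parameter | default interval | meaning |
|---|---|---|
| `alpha_i` | [0.85, 1.1] | intrinsic growth rate, per unit model time |
| `beta_ii` | [0.99, 1.01] | intraspecific competition |
| `beta_ij` | [0.22, 0.24] | interspecific (within-guild) competition |
| `gamma_ik` | [0.19, 0.21] | per-link mutualistic strength |
| `h` | 0.1 (fixed) | handling time of the type-II response |
| `S_i(0)` | [0, 1] | initial abundance density |
| extinction threshold | 1e-10 | final density below this counts as extinct |
| replicate runs | 1000 | per network (reducible; see problem sizes) |

### Numerical choices

- Integration uses LSODA (adaptive, stiffness-switching) with an analytic
  Jacobian, `rtol = 1e-8`, `atol = 1e-12`. The absolute tolerance sits two
  orders below the extinction threshold so threshold crossings are resolved
  signal, not solver noise.
- The model states no natural horizon; the default is `t_end = 1000` time
  units with an equilibrium check `max |dS/dt| < 1e-8`. If unmet, the
  horizon doubles (continuing from the current state) up to 4 times and the
  run is recorded as unsettled. In practice slow exponential extinctions are
  what trigger extensions, and they resolve well before the cap.
- Final abundances are clipped at zero; a species starting at exactly zero
  stays there (every term carries `S_i`).
- Each replicate run redraws *everything* — parameters and initial
  abundances. Per-run RNG streams are keyed by (seed, network id, run
  index), so results are independent of execution order and any subset of
  runs is reproducible in isolation.
- Persistence of a species = fraction of successful runs with final density
  at or above the threshold; network persistence = mean over species
  (overall and per guild). Runs that fail to integrate are dropped and
  logged; more than 5% failures aborts the estimate (in testing, failures
  have not occurred).

## Data preparation

- **Guild filter.** Vertebrate pollinators (birds, geckos, skinks) are
  removed before analysis by default — their longevity violates the model's
  assumption that pollinators track floral resources on the season's
  timescale. Plants left with no interactions are dropped with them.
- **Largest component.** Compartmentalised networks are reduced to the
  connected component with the most species. Ties (rare, small networks) are
  broken by larger total interaction count, then by the component containing
  the lexicographically smallest species id — deterministic and logged.
- **Order.** Filter first, then component. The order is a package decision
  (recorded in every run report); the alternative order can differ when a
  vertebrate is the sole bridge between compartments.
- **Season pooling.** Monthly networks aggregate by element-wise count sums
  on the union of species: early = September–December, late =
  January–April. Species not observed within a season are absent from that
  season's network. Totals are conserved by construction.

## Structure and centrality metrics

- **NODF** (0–100) on presence/absence: mean paired-overlap over all row
  pairs and column pairs, where a pair contributes `|shared partners| /
  fill(sparser)` only when fills strictly decrease, else 0. Binary NODF is
  used; weighted variants are out of scope.
- **Modularity.** Weighted Newman–Girvan Q on the bipartite graph viewed as
  a unipartite weighted graph. Module detection maximises the spin-glass
  objective at resolution 1 (where it coincides with Q) by simulated
  annealing: singleton start, single-node relabel proposals (90% adopt a
  random neighbour's label, 10% a uniform module slot so modules can split),
  Metropolis acceptance, geometric cooling (T: 1.0 -> 1e-3, factor 0.99,
  50·n proposals per temperature). The incremental dQ bookkeeping is exact
  (unit-tested against the direct double sum), the best partition seen is
  returned, and its Q is recomputed exactly at the end. On graphs of <= 10
  species the annealer matches exhaustive search over all partitions; on
  pooled synthetic networks (~40 species) it matches or exceeds igraph's
  spin-glass implementation in spot checks.
- **Weighted closeness.** Shortest-path closeness on the bipartite graph
  with edge length `1/count` — frequent interactions are short edges. For
  species *i* in a component of n species, `C(i) = (n-1) / sum_j d(i,j)`.
  "Weighted closeness" admits several constructions (one-mode projections,
  other weight transforms); this one is declared, not inferred, and values
  are max-rescaled per network (to 1) in the exported model tables.
- **Specialisation d'.** For species *i* with use proportions
  `p_ij = a_ij / A_i` and availability `q_j = A_j / m`, the raw index is the
  KL divergence `d_i = sum_j p_ij ln(p_ij / q_j)`, standardised by
  `d_max = ln(m / A_i)` and by `d_min` = divergence of the most generalised
  achievable *integer* distribution (largest-remainder allocation of `A_i`
  events proportional to availability), clamped to [0, 1]. Because `d_min`
  is an integer allocation, d' is invariant to integer rescaling of the
  whole matrix only up to discretisation (~0.01 in small matrices); `d` and
  `d_max` are exactly invariant.

Metrics are computed on exactly the same preprocessed networks as the
dynamics, so structure and persistence always describe the same species set.

## Synthetic study generator

The generator emulates the *shape* of a paired restoration experiment — it
is not fit to any real dataset. Default design: 8 sites (4 restored, 4
unrestored), 8 months (September–April), hence 64 month-level networks that
pool to 16 season-level networks.

- **Species pools.** Each site has persistent plant and pollinator pools
  with lognormal "abundance" weights (sigma = `nestedness_strength`, default
  1.0). Monthly communities sample the pool with probability proportional to
  weight; early and late season use overlapping pool windows sharing
  `1 - late_season_turnover` (default 70%) of species.
- **Topology and counts.** Links arise with probability proportional to the
  product of endpoint weights, scaled to a target connectance (default
  0.25); this weight-product rule concentrates links on a generalist core,
  so more weight skew yields higher NODF (verified as a directional test).
  Optional block structure (`module_count`) boosts within-block link odds
  for a modularity axis. Counts on realised links are 1 + negative binomial
  with mean tied to the weight product (default dispersion 0.6), giving the
  right-skewed frequency distributions typical of visitation data.
- **Seasonality.** Native plant richness in late months is multiplied by
  `late_plant_richness_factor` (default 0.5): fewer natives flower late in
  the season. Pollinator richness stays roughly constant.
- **Invasive plant.** Unrestored sites contain one invasive generalist
  plant, present in every month (emulating an invasive tree with a very
  long flowering season), linked to `invasive_generalism` (default 0.85) of
  the month's pollinators — sampled uniformly, on the view that a
  mass-flowering, open-access resource is visited broadly — and carrying
  `invasive_weight_share` (default 0.45) of the network's interaction
  counts. Restored sites omit it. Because late-season native richness drops
  while the invasive persists, the invasive becomes the dominant late-season
  resource in unrestored sites (~45% of counts), which is the mechanism
  behind the study's qualitative signature: restored sites show higher
  late-season *plant* persistence (natives freed from the extra
  competitor), unrestored sites show higher late-season *pollinator*
  persistence (the invasive props up pollinators when native resources are
  scarce), and the early-season pollinator contrast is negligible (benefit
  saturates when native resources are plentiful).

What the generator does **not** emulate: real phenology beyond monthly
presence, shared species identities across sites, vertebrate pollinators
(unless `vertebrate_fraction > 0` for testing the guild filter), abundance–
interaction feedbacks, and any quantitative property of the original
Seychelles networks. Passing tests on synthetic data therefore demonstrate
that the pipeline's mechanics and the model's comparative statics behave as
designed — not that any particular empirical effect size is reproduced.

## Statistical scope

Downstream inference (beta-error mixed models with treatment, structure and
centrality effects) is deliberately delegated: `export_model_table` writes
network- and species-level CSVs with all fixed-effect covariates (including
the squared total-species column and per-network max-scaled centrality) and
the site / species / network grouping columns for random intercepts, ready
for glmmTMB, statsmodels, or similar. Re-implementing GLMM machinery is a
non-goal.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run the full study design (8
sites, 64 monthly networks pooled to 16 season networks) at 100 replicate
runs per network, with 10–20 run configurations for determinism checks —
sizes chosen so the whole analysis re-runs in a few minutes on one CPU while
leaving Monte-Carlo error on persistence proportions near 0.01–0.03. The
library defaults remain 1000 runs per network for production use.

## Known limitations

- Persistence estimates inherit the model's mean-field competition: guild
  size strongly affects persistence, so comparisons are only meaningful
  within a design that controls richness (as the synthetic design does).
- The annealer is stochastic; on large dense networks the returned Q is a
  best-found value, not a certified optimum (the `converged` flag and
  `final_epoch_accepts` expose the chain state).
- Closeness and d' are undefined on degenerate (single-species-guild)
  networks; preprocessing normally removes these, and the pipeline excludes
  and logs networks it cannot analyse.
- With `gamma_range` near zero and all-positive growth rates, no extinction
  occurs in small communities — contrasts against a "no mutualism" baseline
  need community sizes where competitive exclusion binds.
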