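# pollinet

Persistence analysis of plant–pollinator interaction networks under habitat
restoration via invasive-plant removal.

Ecological restoration often means removing a dominant invasive plant and
hoping the native community recovers. Whether the *remaining* species then
persist is a population-dynamics question: each species' fate depends on its
competitors, its mutualistic partners, and its position in the interaction
network. `pollinet` is a toolkit for asking that question with bipartite
plant–pollinator networks, written for ecologists comparing network
persistence across experimental treatments (restored vs unrestored sites)
and seasons.

## What it computes

**Dynamics.** Species abundances follow Lotka–Volterra dynamics with
within-guild competition and a saturating (type-II) mutualistic benefit
across guilds. For plant *i*:

dS⁽ᴾ⁾ᵢ/dt = αᵢSᵢ − Σⱼ βᵢⱼ Sᵢ Sⱼ + Sᵢ · (Σₖ γᵢₖ S⁽ᴬ⁾ₖ) / (1 + h Σₗ γᵢₗ S⁽ᴬ⁾ₗ)

with the symmetric equation (guild indices exchanged) for pollinators.
Parameters are drawn uniformly per replicate run (α ∈ [0.85, 1.1],
βᵢᵢ ∈ [0.99, 1.01], βᵢⱼ ∈ [0.22, 0.24], γ ∈ [0.19, 0.21], h = 0.1 fixed,
S(0) ∈ [0, 1]); mutualistic strengths γᵢₖ are non-zero exactly where the
network records an interaction. **Persistence** of a species is the fraction
of replicate runs whose final abundance density stays above 10⁻¹⁰;
network-level persistence is the mean over species, overall and per guild.

**Structure and centrality.** NODF nestedness, weighted modularity Q with
spin-glass simulated-annealing module detection, weighted closeness
centrality (edge length = 1/count), and Blüthgen-style specialisation d′.

**Study plumbing.** Matrix/edge-list CSV I/O, vertebrate guild filtering,
largest-component extraction, month → season pooling, a synthetic generator
for the full restored/unrestored × early/late study design, and exporters
for model-ready analysis tables (downstream GLMM fitting is intentionally
left to dedicated statistics packages).

## Worked example

Generate a small synthetic study (2 sites per treatment), pool months into
seasons, run the full analysis at 100 replicate simulations per network, and
summarise the treatment × season contrast:

```python
from pollinet import (DynamicsConfig, StudyOptions, SyntheticDesign,
                      generate_dataset, pool_season, run_study,
                      summarize_contrast)
from pollinet.network import StudyDataset

design = SyntheticDesign(seed=1, n_sites_per_treatment=2)
monthly = generate_dataset(design)                     # 32 monthly networks
season_nets = []
for site in monthly.sites():
    season_nets.extend(pool_season([n for n in monthly if n.site_id == site]))
season = StudyDataset(networks=season_nets, level="season")

table = run_study(season, DynamicsConfig(seed=2, n_runs=100), StudyOptions())
cols = ["treatment", "period", "plant_persistence_mean",
        "pollinator_persistence_mean", "nodf_mean", "modularity_mean"]
print(summarize_contrast(table)[cols].round(3).to_string(index=False))
```

Output:

```
 treatment period  plant_persistence_mean  pollinator_persistence_mean  nodf_mean  modularity_mean
  restored  early                   0.750                        0.661     68.184            0.261
  restored   late                   0.833                        0.628     68.340            0.306
unrestored  early                   0.599                        0.642     74.871            0.174
unrestored   late                   0.685                        0.822     74.470            0.160
```

Reading the numbers: plants persist better where the invasive competitor
was removed (0.83 vs 0.69 in late season), while pollinators persist *better
in unrestored sites in late season* (0.82 vs 0.63) — the invasive generalist
is the dominant late-season floral resource there — and show essentially no
treatment difference in early season (0.66 vs 0.64), when native resources
are plentiful and the mutualistic benefit saturates. The unrestored
networks are also more nested and less modular, because the invasive
super-generalist pulls the network toward a single generalist core.

The same analysis is available from the shell:

```bash
pollinet synth --seed 1 --out data/
pollinet run --manifest data/manifest.yaml --seed 2 --n-runs 100 \
             --season-level --out results/
```

which writes `network_table.csv`, `species_table.csv` (with per-network
max-scaled closeness and richness covariates, ready for beta-error mixed
models), `contrast_summary.csv`, and a JSON run report with the resolved
configuration, exclusions and timings.

See `docs/methods.md` for the model's assumptions, numerical tolerances,
what the synthetic generator does and does not emulate, and known
limitations.

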