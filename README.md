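# telemeshare

Analysis toolkit for multi-species passive acoustic telemetry in coastal
bays: residency and detection indices, seasonal detection modelling,
movement-network space use with a PERMANOVA segregation test, and
hour-scale co-occurrence social networks with a node-permutation
assortativity test. It is written for movement ecologists working with
receiver-download exports (one row per detection: timestamp, transmitter,
receiver) plus receiver and tagging metadata, and ships a fully
ground-truthed synthetic generator so every stage of the pipeline can be
validated end to end without field data.

## What it computes

**Detection indices.** For an individual with `D` distinct marine
detection days,

- `DI_total = D / (days monitored)`, where the monitoring window runs from
  tagging to the earliest of study end, recapture, battery expiry, or last
  known detection outside the bay;
- `DI_bay = D / (days at liberty until the last in-bay detection)`.

Group differences are tested nonparametrically (Mann–Whitney U, or
Kruskal–Wallis with Dunn's post hoc and Benjamini–Hochberg adjustment).

**Seasonality.** Monthly detection-day counts are modelled as

```
count ~ species + f_species(month) + u_individual + offset(log days_in_month)
```

with `f_species` a cyclic cubic B-spline smooth (k = 12, periodic over the
year), `u_individual` ridge-penalized random intercepts, and a
quasi-Poisson dispersion. Smoothing parameters are chosen by grid-search
GCV; `exp(eta)` is the per-day detection probability by month.

**Space use.** Movement networks treat receivers as nodes; consecutive
detections at two receivers within 24 h add an (undirected) edge. Node
density = fraction of deployed receivers visited; edge density = fraction
of all receiver pairs realized. Spatial segregation is tested by a
sequential-SS PERMANOVA (pseudo-F, free permutation of individuals) on the
Euclidean distances between per-individual receiver-use proportion
profiles.

**Co-occurrence.** Under the gambit of the group, individuals detected at
the same receiver within the same clock hour are associated. Dyads are
weighted by the simple-ratio index `SRI = x / (x + y_AB + y_A + y_B)`, and
trait assortment uses the weighted categorical assortativity coefficient
`r = (Σ e_ii − Σ a_i b_i) / (1 − Σ a_i b_i)` with a node-permutation null
(labels shuffled over nodes, network fixed).

## Worked example

`examples/` contains one narrative script per capability. For instance,
`python examples/05_cooccurrence.py` simulates a one-year, 26-animal study
with conspecific co-assignment switched on (strength 0.4), builds the
co-occurrence network, and prints:

```
network: 24 individuals, 126 nonzero dyads, max SRI = 0.049
assortativity by species: r = 0.848, p = 0.0010 (null mean -0.045)
assortativity by life_stage: r = 0.587, p = 0.0010 (null mean -0.047)
```

Read: the 24 detected individuals form 126 associated pairs; the species
assortativity of +0.848 sits far above the node-permutation null (whose
mean is ≈ 0), so animals co-occur with conspecifics much more than random
mixing of the same network would produce — exactly the signal the
generator planted. `examples/02_residency_indices.py` similarly prints
per-species mean `DI_total`/`DI_bay`, the Kruskal–Wallis statistic, and
the BH-adjusted Dunn table.

A thin CLI mirrors the library (`telemeshare simulate | ingest |
residency | seasonality | space | social`); run any subcommand with
`--help`.

## Layout

- `src/telemeshare/` — library (`io_ingest`, `synthetic`, `residency`,
  `seasonality`, `movement`, `social`, `cli`)
- `examples/` — runnable narrative walk-throughs
- `docs/methods.md` — models, conventions, numerical choices, limitations
- `tests/` — unit, property and end-to-end validation suites
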