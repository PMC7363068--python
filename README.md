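# pollinet

Analysis pipeline for timed pollinator-visitation surveys of urban green
spaces: visitation rates, park-type community comparison, weighted
plant–pollinator interaction networks, and a per-area pollination
performance index.

Urban parks differ sharply in how much foraging habitat they offer
pollinating insects, and standardized field surveys — counting every
insect entering 1 m² of flower bed or 1 m³ of linden (*Tilia*) crown for
30 minutes — are a common way to measure it. `pollinet` is for ecologists
who run such surveys and want a reproducible path from raw observation
CSVs to the standard result set:

- **Visitation rates** `V_g = count_g × (30 / duration)` per session and
  pollinator group, summarised per park type (mean ± SD).
- **Community comparison**: Shapiro–Wilk/Levene pre-tests, Kruskal–Wallis
  across park types, Dunn post-hoc z-tests with Bonferroni–Holm
  correction and a compact letter display, plus Bray–Curtis /
  complete-linkage clustering of park types.
- **Interaction networks**: blossom visits in public beds cross-tabulated
  into a weighted bipartite matrix, normalized by per-plant replicate
  correction factors `n_ref / n_site`, analysed at three aggregation
  levels with connectance, weighted-interaction nestedness (WINE η),
  H2′ specialization, interaction evenness, mean shared partners and
  Morisita–Horn/Horn niche overlap — each implemented from its
  definition (see `docs/methods.md`).
- **Pollination estimator**: extrapolated total visitations
  `mean(ΣV_g) × spatial_total` divided by park area — visits per m² of
  park per 30 minutes, a comparable ecosystem-service performance index.

A synthetic-survey generator (`pollinet.synthetic`) reproduces the
statistical structure of such a survey — overdispersed session counts,
park-type-specific community composition, flower-constancy-driven
allocation of visits to plants — so the whole pipeline is testable and
demonstrable without field data.

## Worked example

Simulate a survey under the default study conditions and run every
analysis stage:

```sh
pollinet run --out demo --seed 1
cat demo/report/report.txt
```

```
pollinet report (292 sessions, 7103 recorded visits, 6046 blossom visits)

  cemetery           study-bed rate 13.5 ± 8.0 (n=13)
  community_garden   study-bed rate 35.1 ± 19.9 (n=27)
  prestigious        study-bed rate 24.5 ± 15.9 (n=13)
  recreational       study-bed rate 20.1 ± 13.8 (n=50)
  rural_reference    study-bed rate 37.4 ± 11.5 (n=10)

  cemetery           public_bed  estimator    0.4 visits/m² (total ≈ 47,000)
  community_garden   public_bed  estimator    6.5 visits/m² (total ≈ 8,712)
  prestigious        public_bed  estimator    7.6 visits/m² (total ≈ 54,000)
  recreational       public_bed  estimator    0.1 visits/m² (total ≈ 43,000)
  cemetery           tilia_tree  estimator    1.2 visits/m² (total ≈ 155,000)
  community_garden   tilia_tree  estimator   47.9 visits/m² (total ≈ 64,000)
  recreational       tilia_tree  estimator    9.4 visits/m² (total ≈ 2,796,000)
```

The study-bed rates are sample means over the simulated sessions (the
rural reference and community gardens are configured at 46.2 and 43.7
visits/30 min — at n = 10–27 sessions the estimates scatter accordingly).
The estimator lines read, e.g.: all public flower beds of the prestigious
park together receive ≈ 54,000 visits per 30 minutes, i.e. 7.6 visits per
m² of park area — whereas recreational parks, with only 0.4 % of their
area in flower beds, reach 0.1. The bundle also contains the rate tables,
test results (`comparison.json`), the Bray–Curtis dendrogram
(`dendrogram.nwk`), the corrected interaction matrices and their metric
JSONs at three aggregation levels, and a graph edge list for plotting.

The same stages are available individually (`simulate`, `validate`,
`rates`, `compare`, `cluster`, `network`, `performance`, `report`) and as
library functions:

```python
import pollinet as pn

ds = pn.simulate_dataset(pn.default_config(seed=1))
m = pn.apply_correction(pn.build_matrix(ds), pn.correction_factors(ds))
pn.network_metrics(m, n_null=1000, seed=0)
# NetworkMetrics(weighted_nestedness=0.192, connectance=0.631,
#                interaction_evenness=0.808, h2_prime=0.251, ...)
```

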