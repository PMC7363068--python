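# Methods

`pollinet` analyses timed pollinator-visitation surveys of urban green
spaces and reproduces a complete analysis chain: per-session visitation
rates, nonparametric park-type comparisons, community clustering, weighted
bipartite plant–pollinator networks with correction-factor normalization,
and an extrapolated per-area pollination performance index. This note
documents the models, the defaults and their provenance, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## Survey model and visitation rates

The observational unit is a 30-minute session watching one spatial unit —
1 m² of flower bed or 1 m³ of *Tilia* (linden) crown — during which every
pollinator entering the unit is counted and assigned by eye to a field
label (species where identifiable, otherwise a morphogroup). Each count is
tied to the plant approached and flagged as a *blossom visit* (landing on
and probing a flower, the precondition for pollination) or a
*reconnaissance flight* (entering the plot only). Community-level analyses
use both kinds; network analyses use blossom visits only.

The visitation rate of group *g* in a session is

    V_g = count_g × (30 / duration_min)

per spatial unit, i.e. the raw count at the reference duration of 30 min.
Sessions of other lengths are linearly rescaled; the linearity assumption
is an extrapolation — the surveyed protocol used 30-minute records only.

Labels aggregate along a fixed taxonomy: label → morphogroup → one of five
main groups (honeybee, bumblebee, hoverfly, solitary bee, other). Counts
are conserved at every level.

## Park-type comparison

Rates are non-normal overdispersed counts, so park types are compared per
group with a Kruskal–Wallis test, preceded by Shapiro–Wilk normality and
Levene (median-centered) homoscedasticity pre-tests, and followed by all
pairwise Dunn (1964) post-hoc z-tests on joint midranks with tie
correction:

    z = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − ΣT/(12(N−1))] (1/n_i + 1/n_j))

with ΣT = Σ(t³ − t) over tie groups. The pairwise family is adjusted with
the sequential Bonferroni–Holm step-down and summarised as a compact
letter display (two park types share a letter iff the adjusted p exceeds
α, default 0.05). The letter display is built greedily over park types in
name order, which makes it deterministic; letter displays are not unique
in general.

Community composition is clustered on the untransformed park-type × group
mean-rate matrix with Bray–Curtis dissimilarity, Σ|x−y| / Σ(x+y), and
complete-linkage agglomeration. Degenerate rows are defined explicitly:
two all-zero rows are identical (0), an all-zero row is maximally distant
(1) from any nonzero row. Dendrograms export as Newick; a child branch's
length is its parent's merge height minus its own.

## Interaction networks

Blossom visits in public beds are cross-tabulated into a weighted plants ×
pollinator-labels matrix. Because sites were surveyed unequally often,
each plant row is multiplied by a correction factor

    f(plant) = n_ref / n_site

where n_site is the number of public-bed sessions at the plant's site and
n_ref defaults to the replicate count of the most-surveyed site. A plant
growing at several sites takes its most-surveyed site's factor with a
warning (the emulated survey had one site per plant). Three aggregation
levels are analysed: plant species × labels, plant species × five groups,
and pollination syndromes × five groups; weighted totals are conserved.

Metrics, implemented from their definitions:

- **Connectance** C = (#cells > 0) / (rows × cols).
- **Interaction evenness** E = H2 / ln(rows × cols), where
  H2 = −Σ p_ij ln p_ij over cells. The ln(all possible cells) denominator
  makes E = 1 for uniform full matrices; the realized-links variant
  (ln #links) is available as an option.
- **H2′ specialization** = (H2max − H2) / (H2max − H2min), clipped to
  [0, 1], with the entropy extremes taken over matrices with the observed
  marginal totals. For integer matrices with total ≤ 16 and ≤ 16 cells the
  extremes are exact (dynamic enumeration); otherwise H2min uses the
  standard greedy marginal-packing heuristic and H2max the marginal outer
  product (continuous maximum, H(rows) + H(cols)). The heuristics are
  validated against exhaustive enumeration on small matrices in the test
  suite. A single-cell matrix has no degrees of freedom; H2′ is defined
  as 0 and logged.
- **Weighted-interaction nestedness (WINE)** η: positive weights are
  replaced by ranks (average ties); rows and columns are packed by
  decreasing marginal rank totals (ties broken by label order); the
  rank-weighted mean Euclidean distance d_w of filled cells to the packed
  corner is standardized as η = (d_w − d_rnd)/(d_max − d_rnd), where d_max
  comes from the maximally packed arrangement (same fill and rank
  multiset, heaviest ranks nearest the corner) and d_rnd is the mean over
  a seeded null ensemble (default 1000 matrices, same number of filled
  cells placed uniformly at random, ranks shuffled, repacked). η ≈ 1 for
  perfectly nested, ≈ 0 for random, < 0 for anti-nested matrices. The null
  consumes the rank multiset in canonical (sorted) order so that η is
  invariant under row/column permutation of the input.
- **Mean shared partners**: average over unordered pairs on one side of
  the count of opposite-side entities both interact with.
- **Niche overlap**: mean pairwise Morisita–Horn similarity
  2Σx_iy_i / [(Σx_i²/X² + Σy_i²/Y²)XY] of resource-use vectors
  (density-invariant); Horn's (1966) information-theoretic index is
  available as a variant. Zero-total vectors are excluded with a log
  entry.

Whether corrected (non-integer) weights or raw counts should enter the
nestedness null model is ambiguous in the underlying method descriptions;
the package computes on whatever weights the matrix carries (rank
transformation makes WINE insensitive to row scaling that preserves weight
order).

## Pollination performance index

Per park type and structural element (all public flower beds, or all
*Tilia* crowns):

    total_visitations = mean(Σ_g V_g) × spatial_total        (visits/30 min)
    pollination_estimator = total_visitations / park_area    (visits/30 min/m²)

where spatial_total is the summed bed surface (m²) or crown green volume
(m³) of the park type. Bed extrapolation uses public-bed rates by default
(a flag pools study beds). Estimators are reported at one decimal and
extrapolated totals above 10,000 rounded to the nearest 1,000 for
presentation — the extrapolation is a coarse order-of-magnitude index —
with full precision always retained in machine output. Park types lacking
an element (e.g. no insect-pollinated *Tilia* in the prestigious park) are
absent from the table, not zero. As an extension beyond the original
index, a nonparametric bootstrap over sessions can attach a 95 % interval.

## Synthetic survey generator

The generator produces full datasets with the statistical structure the
analysis assumes, so that every stage is testable without field data.

Per session the total count is negative binomial (the emulated survey's
printed SDs, e.g. 23.0 at mean 43.7, are far above Poisson). The size
parameter derives from the printed mean/SD pairs as size = m²/(s² − m).
The total splits multinomially over the five main groups
(park-type-specific composition), then over field labels within groups
(steep rank-abundance: one dominant representative per group), and — in
beds — over the plants present, weighted by flower-constancy preferences
of each label for each pollination syndrome. A missing constancy entry is
a structural zero; when a forager has no workable flower morphology on a
bed, its plot entries are recorded as reconnaissance flights only.
Independently of that, a configured fraction (default 0.1) of every count
is flagged as reconnaissance.

Default study conditions and their provenance:

- Study-bed totals per park type: 46.2 ± 14.6 (rural reference),
  43.7 ± 23.0 (community garden), 21.0 ± 12.6 (prestigious), 20.8 ± 15.5
  (recreational), 17.8 ± 10.1 (cemetery) — the printed survey means.
  Per-group cells use printed group means where available (e.g. solitary
  bees 20.6 rural / 19.0 community garden; hoverflies 13.9 / 13.0;
  honeybees 0.3 cemetery – 5.0 community garden; bumblebees 1.2
  prestigious – 4.5 cemetery); unprinted cells are filled so rows sum to
  the printed totals while keeping the documented community contrasts
  (wild bees and hoverflies dominate the rural reference and community
  gardens; social species are scarcer in study beds than public beds).
- Public-bed mean rates are back-derived from the printed extrapolated
  totals and bed areas (e.g. 55,000 visits / 1,130 m² ≈ 48.7 for the
  prestigious park); honeybee shares follow the printed percentages
  (33.8 / 22.9 / 44.0 / 39.2 %). Tree-crown rates are likewise
  back-derived from printed totals and green volumes.
- Session counts follow the emulated sampling table, with one deviation:
  recreational public-bed sessions are 27 over two sites (14 + 13) rather
  than 35 over three units, so that no site exceeds the 14 replicates of
  the most-surveyed public bed — the anchor of the correction factors.
- The constancy matrix is a free parameter (per-plant visit distributions
  are not printed); its defaults were chosen to reproduce the printed
  network character: structural sparsity at the fine level, near-complete
  syndrome-level coverage, and a species-level specialization H2′ near
  the printed 0.233.

What the generator does **not** emulate: weather and phenology
(environmental fields are constants), spatial autocorrelation between
neighbouring sites, site-level segregation of pollinator labels (every
label can occur in every park type, which keeps the simulated pollinator
niche overlap around 0.5 where the real survey reported 0.20), and
observer error. Consequently, passing tests demonstrate correctness of the
estimators and pipeline under a faithful sampling model — not that the
generator reproduces every empirical pattern of the real community. In
particular, the real survey's weighted nestedness declined monotonically
with aggregation (0.576 / 0.040 / −0.133), while the synthetic community
stays rank-nested at the syndrome level; reproducing that would require
the unprinted raw weight distribution.

## Numerical choices and degenerate inputs

- Blank counts in input CSVs are rejected, not coerced to zero; unknown
  columns are dropped with a logged warning.
- All-zero matrix rows/columns are dropped with a log entry at
  construction; empty matrices raise.
- All stochastic stages (simulation, WINE null ensemble, bootstrap) take
  explicit seeds; identical configurations give byte-identical outputs.
- Kruskal–Wallis on all-identical observations is reported as H = 0,
  p = 1 (no evidence) rather than an error; Shapiro–Wilk cells with n < 3
  or zero variance are flagged untestable rather than raising.
- Problem sizes in the test suite and acceptance script (e.g. 40 simulated
  surveys for the dendrogram-topology rate, 2000 replicates for the
  Kruskal–Wallis calibration, null ensembles of 100–1000) were chosen to
  keep Monte-Carlo error well below the tested tolerances.

## Known limitations

- Exact reproduction of the real survey's network metrics requires the
  deposited raw data; the corresponding test ingests it from
  `data/s5_raw/` when provided and fails with an explanatory message
  otherwise.
- H2max above the exact-enumeration limit is the continuous maximum, which
  can slightly exceed the integer-constrained maximum (H2′ marginally
  conservative on small sparse matrices).
- Dunn p-values are normal approximations; at very small group sizes
  (n ≤ 3 per group) adjacent groups cannot reach significance at
  α = 0.05 regardless of separation.
- The pollination estimator inherits the survey's extrapolation caveats:
  it scales a per-unit mean to whole park elements and should be read as
  an order-of-magnitude comparison between park types, not a measurement.
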