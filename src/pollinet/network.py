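"""Weighted bipartite plant-pollinator networks and their metrics.

The interaction matrix cross-tabulates blossom visits (reconnaissance
flights excluded — only a blossom visit is a precondition for pollination)
of pollinator groups on plant species across all public-bed sessions.
Because sites were surveyed unequally often, cells are normalized by a
per-plant correction factor: the replicate count of the most-surveyed
public bed divided by the replicate count of the bed the plant grows in.

Metrics implemented from their definitions:

* connectance — realized fraction of possible links;
* weighted-interaction nestedness (WINE) — rank-weighted distance of filled
  cells to the packed matrix corner, standardized between a random null
  ensemble (0) and the maximally packed arrangement (1);
* H2' specialization — two-dimensional Shannon entropy of the interaction
  frequencies standardized between the entropy extremes attainable with the
  observed marginal totals;
* interaction evenness — Shannon entropy over cells divided by ln(cells);
* mean number of shared partners and Morisita-Horn / Horn niche overlap on
  either side of the network.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survey_data import Dataset, filter_events, aggregate_labels

logger = logging.getLogger("pollinet")

__all__ = ["InteractionMatrix", "NetworkMetrics", "build_matrix",
           "correction_factors", "apply_correction", "aggregate_network",
           "connectance", "weighted_nestedness", "h2_prime",
           "interaction_evenness", "mean_shared_partners", "niche_overlap",
           "export_graph", "network_metrics", "WineResult"]


class EmptyMatrixError(ValueError):
    """No qualifying interactions to build a matrix from."""


@dataclass
class InteractionMatrix:
    """Weighted plants × pollinator-groups cross table.

    ``table`` rows are plants (or syndromes), columns pollinator labels (or
    main groups); weights are nonnegative. ``plant_syndrome`` and
    ``pollinator_group`` retain the mappings needed for aggregation;
    ``factors`` records any applied per-plant correction factors.
    """

    table: pd.DataFrame
    plant_level: str = "species"        # species | syndrome
    pollinator_level: str = "fine"      # fine | grouped
    plant_syndrome: dict[str, str] = field(default_factory=dict)
    pollinator_group: dict[str, str] = field(default_factory=dict)
    factors: pd.Series | None = None

    def __post_init__(self):
        if (self.table.to_numpy() < 0).any():
            raise ValueError("interaction weights must be nonnegative")

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(float)

    @property
    def total(self) -> float:
        return float(self.table.to_numpy().sum())


def _drop_empty(table: pd.DataFrame) -> pd.DataFrame:
    zero_rows = table.index[(table.sum(axis=1) == 0)]
    zero_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(zero_rows):
        logger.info("dropping all-zero plant row(s): %s", list(zero_rows))
    if len(zero_cols):
        logger.info("dropping all-zero pollinator column(s): %s",
                    list(zero_cols))
    return table.drop(index=zero_rows, columns=zero_cols)


def build_matrix(d: Dataset) -> InteractionMatrix:
    """Cross-tabulate blossom visits of public-bed sessions.

    Cell (plant, pollinator) is the total blossom-visit count over all
    public-bed sessions; rows/columns that end up all-zero are dropped with
    a log entry. Raises :class:`EmptyMatrixError` without qualifying events.
    """
    sub = filter_events(d, interaction_kind="blossom_visit",
                        element_kinds=("public_bed",))
    if not len(sub.events):
        raise EmptyMatrixError("no public-bed blossom-visit events")
    table = sub.events.pivot_table(index="plant_species",
                                   columns="pollinator_label",
                                   values="count", aggfunc="sum",
                                   fill_value=0).astype(float)
    table = _drop_empty(table.sort_index(axis=0).sort_index(axis=1))
    syndromes = dict(zip(d.plants["species"], d.plants["syndrome"]))
    groups = dict(zip(d.taxonomy["pollinator_label"],
                      d.taxonomy["main_group"]))
    return InteractionMatrix(table, "species", "fine", syndromes, groups)


# ---------------------------------------------------------------------------
# Correction factors
# ---------------------------------------------------------------------------

def correction_factors(d: Dataset, reference_n: int | None = None
                       ) -> pd.Series:
    """Per-plant replicate correction factor n_ref / n_site.

    ``n_site`` is the number of public-bed sessions at the site where the
    plant grows; ``n_ref`` defaults to the replicate count of the
    most-surveyed public-bed site. A plant recorded at several sites takes
    the factor of its most-surveyed site, with a warning.
    """
    sess = d.sessions[d.sessions["element_kind"] == "public_bed"]
    if not len(sess):
        raise EmptyMatrixError("no public-bed sessions")
    n_site = sess.groupby("site_id")["record_id"].nunique()
    n_ref = int(n_site.max()) if reference_n is None else int(reference_n)

    ev = d.events.merge(sess[["record_id", "site_id"]], on="record_id")
    factors = {}
    for plant, sites in ev.groupby("plant_species")["site_id"]:
        uniq = sorted(set(sites))
        if len(uniq) > 1:
            logger.warning("plant %r occurs at several sites %s; using its "
                           "most-surveyed site", plant, uniq)
        site = max(uniq, key=lambda s: (n_site.get(s, 0), s))
        factors[plant] = n_ref / float(n_site[site])
    return pd.Series(factors, name="correction_factor").sort_index()


def apply_correction(m: InteractionMatrix,
                     factors: pd.Series) -> InteractionMatrix:
    """Multiply each plant row by its correction factor."""
    if (factors <= 0).any():
        raise ValueError("correction factors must be > 0")
    missing = [p for p in m.table.index if p not in factors.index]
    if missing:
        raise ValueError(f"no correction factor for plant(s) {missing}")
    table = m.table.mul(factors.reindex(m.table.index), axis=0)
    return InteractionMatrix(table, m.plant_level, m.pollinator_level,
                             dict(m.plant_syndrome),
                             dict(m.pollinator_group),
                             factors.reindex(m.table.index))


# ---------------------------------------------------------------------------
# Aggregation levels
# ---------------------------------------------------------------------------

def aggregate_network(m: InteractionMatrix, plant_level: str = "species",
                      pollinator_level: str = "fine") -> InteractionMatrix:
    """Aggregate plants to pollination syndromes and/or pollinators to the
    five main groups; the weighted total is conserved."""
    table = m.table
    if plant_level not in ("species", "syndrome"):
        raise ValueError("plant_level must be 'species' or 'syndrome'")
    if pollinator_level not in ("fine", "grouped"):
        raise ValueError("pollinator_level must be 'fine' or 'grouped'")
    if plant_level == "syndrome" and m.plant_level == "species":
        unmapped = [p for p in table.index if p not in m.plant_syndrome]
        if unmapped:
            raise ValueError(f"plants without syndrome: {unmapped}")
        table = table.groupby([m.plant_syndrome[p] for p in table.index],
                              sort=True).sum()
        table.index.name = "syndrome"
    if pollinator_level == "grouped" and m.pollinator_level == "fine":
        unmapped = [c for c in table.columns if c not in m.pollinator_group]
        if unmapped:
            raise ValueError(f"pollinators without main group: {unmapped}")
        table = table.T.groupby([m.pollinator_group[c]
                                 for c in table.columns], sort=True).sum().T
        table.columns.name = "pollinator_group"
    return InteractionMatrix(_drop_empty(table), plant_level,
                             pollinator_level, dict(m.plant_syndrome),
                             dict(m.pollinator_group), None)


# ---------------------------------------------------------------------------
# Simple metrics
# ---------------------------------------------------------------------------

def connectance(m: InteractionMatrix) -> float:
    """Realized fraction of possible links: (#cells > 0) / (rows·cols)."""
    a = m.values
    if a.size == 0:
        raise EmptyMatrixError("empty matrix")
    return float((a > 0).sum() / a.size)


def _shannon(weights: np.ndarray) -> float:
    """Shannon entropy of the cell-weight distribution (natural log)."""
    w = weights[weights > 0].astype(float)
    p = w / w.sum()
    return float(-(p * np.log(p)).sum())


def interaction_evenness(m: InteractionMatrix,
                         denominator: str = "cells") -> float:
    """Shannon evenness of interaction weights: H2 / ln(rows·cols).

    ``denominator='links'`` uses ln(#realized links) instead (an optional
    variant found in network software).
    """
    a = m.values
    if a.size <= 1:
        raise ValueError("evenness undefined for a single-cell matrix")
    if a.sum() <= 0:
        raise ValueError("evenness requires a positive total")
    h2 = _shannon(a)
    n = a.size if denominator == "cells" else int((a > 0).sum())
    if denominator not in ("cells", "links"):
        raise ValueError("denominator must be 'cells' or 'links'")
    if n <= 1:
        return 0.0
    return float(h2 / np.log(n))


def mean_shared_partners(m: InteractionMatrix, axis: str) -> float:
    """Mean number of shared partners over all unordered pairs of entities
    on one side (``axis``: 'pollinators' = columns, 'plants' = rows)."""
    a = m.values > 0
    vecs = a.T if axis == "pollinators" else a
    if axis not in ("pollinators", "plants"):
        raise ValueError("axis must be 'pollinators' or 'plants'")
    if len(vecs) < 2:
        raise ValueError("need >= 2 entities to share partners")
    shared = [int(np.logical_and(x, y).sum())
              for x, y in itertools.combinations(vecs, 2)]
    return float(np.mean(shared))


def _morisita_horn(x: np.ndarray, y: np.ndarray) -> float:
    X, Y = x.sum(), y.sum()
    num = 2.0 * float((x * y).sum())
    den = (float((x * x).sum()) / X ** 2
           + float((y * y).sum()) / Y ** 2) * X * Y
    return num / den if den > 0 else 0.0


def _horn(x: np.ndarray, y: np.ndarray) -> float:
    """Horn's (1966) information-theoretic overlap (0 ln 0 = 0)."""
    def s(v):
        v = v[v > 0]
        return float((v * np.log(v)).sum())
    X, Y = float(x.sum()), float(y.sum())
    num = s(x + y) - s(x) - s(y)
    den = (X + Y) * np.log(X + Y) - X * np.log(X) - Y * np.log(Y)
    return num / den if den > 0 else 0.0


def niche_overlap(m: InteractionMatrix, axis: str,
                  variant: str = "morisita_horn") -> float:
    """Mean pairwise niche overlap of resource-use vectors on one side.

    The default is the Morisita-Horn similarity (density-invariant); the
    ``'horn'`` variant is Horn's information-theoretic index. Entities with
    zero total are excluded with a log entry.
    """
    if axis not in ("pollinators", "plants"):
        raise ValueError("axis must be 'pollinators' or 'plants'")
    sim = {"morisita_horn": _morisita_horn, "horn": _horn}[variant]
    a = m.values
    vecs = list(a.T) if axis == "pollinators" else list(a)
    keep = [v for v in vecs if v.sum() > 0]
    if len(keep) < len(vecs):
        logger.info("niche_overlap: excluded %d zero-total vector(s)",
                    len(vecs) - len(keep))
    if len(keep) < 2:
        raise ValueError("need >= 2 entities with positive totals")
    vals = [sim(x, y) for x, y in itertools.combinations(keep, 2)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Weighted-interaction nestedness (WINE)
# ---------------------------------------------------------------------------

@dataclass
class WineResult:
    """Weighted nestedness η with the quantities entering it."""

    eta: float
    d_w: float
    d_max: float
    d_rnd: float
    null_sd: float      # SD of η over the null ensemble
    n_null: int


def _packed_distance(values: np.ndarray,
                     row_labels: np.ndarray | None = None,
                     col_labels: np.ndarray | None = None
                     ) -> tuple[float, np.ndarray]:
    """Weighted mean corner distance after packing rows/columns by
    decreasing marginal rank totals (ties broken by label order where
    labels are given, else by position)."""
    def order(sums, labels):
        if labels is None:
            return np.argsort(-sums, kind="stable")
        return np.lexsort((np.asarray(labels, str), -sums))
    rows = order(values.sum(axis=1), row_labels)
    cols = order(values.sum(axis=0), col_labels)
    packed = values[np.ix_(rows, cols)]
    i, j = np.nonzero(packed)
    d = np.sqrt((i + 1.0) ** 2 + (j + 1.0) ** 2)
    w = packed[i, j]
    return float((w * d).sum() / w.sum()), packed


def weighted_nestedness(m: InteractionMatrix, n_null: int = 1000,
                        seed: int = 0) -> WineResult:
    """Weighted-interaction nestedness estimator (WINE).

    Positive weights are replaced by their ranks (average ties); the matrix
    is packed by decreasing marginal rank totals and the rank-weighted mean
    Euclidean distance d_w of filled cells to the packed corner is computed.
    The same statistic is evaluated on the maximally packed arrangement
    (d_max: the filled cells moved as close to the corner as possible, the
    largest ranks closest) and on a null ensemble (d_rnd: same number of
    filled cells placed uniformly at random, ranks shuffled, repacked).

        η = (d_w − d_rnd) / (d_max − d_rnd)

    η ≈ 1 for perfectly nested, ≈ 0 for random, < 0 for anti-nested
    matrices. The null ensemble is fixed by ``seed``.
    """
    a = m.values
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("weighted nestedness needs >= 2 rows and columns")
    pos = a > 0
    n_fill = int(pos.sum())
    if n_fill < 2:
        raise ValueError("need >= 2 filled cells")
    ranks = np.zeros_like(a)
    ranks[pos] = stats.rankdata(a[pos])

    d_w, _ = _packed_distance(ranks, m.table.index.to_numpy(),
                              m.table.columns.to_numpy())

    # maximally packed arrangement: same fill and rank multiset, cells as
    # close to the corner as possible with the heaviest ranks closest
    nr, nc = a.shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    dist_all = np.sqrt((ii + 1.0) ** 2 + (jj + 1.0) ** 2).ravel()
    closest = np.sort(dist_all)[:n_fill]
    rank_desc = np.sort(ranks[pos])[::-1]
    d_max = float((rank_desc * closest).sum() / rank_desc.sum())

    rng = np.random.default_rng(seed)
    rank_vals = np.sort(ranks[pos])  # canonical order: the null ensemble
    # must not depend on the row/column ordering of the input
    null_d = np.empty(n_null)
    flat = np.zeros(nr * nc)
    for k in range(n_null):
        flat[:] = 0.0
        cells = rng.choice(nr * nc, size=n_fill, replace=False)
        flat[cells] = rng.permutation(rank_vals)
        null_d[k], _ = _packed_distance(flat.reshape(nr, nc))
    d_rnd = float(null_d.mean())

    denom = d_max - d_rnd
    if denom == 0:
        raise ValueError("degenerate null ensemble (d_max == d_rnd)")
    eta = (d_w - d_rnd) / denom
    null_sd = float(null_d.std(ddof=1) / abs(denom)) if n_null > 1 else 0.0
    return WineResult(float(eta), d_w, d_max, d_rnd, null_sd, n_null)


# ---------------------------------------------------------------------------
# H2' specialization
# ---------------------------------------------------------------------------

def _entropy_extremes_exact(row_sums: np.ndarray, col_sums: np.ndarray
                            ) -> tuple[float, float]:
    """Exhaustive min/max Shannon entropy over nonnegative integer matrices
    with the given marginals (feasible only for small totals)."""
    nr, nc = len(row_sums), len(col_sums)
    best = [np.inf, -np.inf]

    def recurse(r, cols_left, cells):
        if r == nr:
            if all(c == 0 for c in cols_left):
                h = _shannon(np.array(cells, float))
                best[0] = min(best[0], h)
                best[1] = max(best[1], h)
            return
        # enumerate compositions of row_sums[r] bounded by cols_left
        def fill(j, remaining, row):
            if j == nc - 1:
                if remaining <= cols_left[j]:
                    recurse(r + 1,
                            [c - (row + [remaining])[k]
                             for k, c in enumerate(cols_left)],
                            cells + row + [remaining])
                return
            for v in range(min(remaining, cols_left[j]) + 1):
                fill(j + 1, remaining - v, row + [v])
        fill(0, int(row_sums[r]), [])

    recurse(0, [int(c) for c in col_sums], [])
    return best[0], best[1]


def _entropy_min_greedy(row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    """Greedy minimum-entropy (maximally specialized) filling: repeatedly
    put min(largest remaining row, largest remaining column) in one cell."""
    r = row_sums.astype(float).copy()
    c = col_sums.astype(float).copy()
    cells = []
    while r.sum() > 1e-12 and c.sum() > 1e-12:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        v = min(r[i], c[j])
        cells.append(v)
        r[i] -= v
        c[j] -= v
    return _shannon(np.array(cells))


def _entropy_max_marginal(row_sums: np.ndarray, col_sums: np.ndarray
                          ) -> float:
    """Maximum entropy given marginals: the independent outer product
    p_ij = (R_i/N)(C_j/N), whose entropy is H(rows) + H(cols)."""
    return _shannon(row_sums.astype(float)) + _shannon(col_sums.astype(float))


def h2_prime(m: InteractionMatrix, exact_limit: int = 16) -> float:
    """Network-level specialization H2'.

    H2 = −Σ p_ij ln p_ij (p_ij = weight/total) is standardized between the
    extremes attainable under the observed marginal totals:
    H2' = (H2max − H2)/(H2max − H2min), clipped to [0, 1]; 0 = maximally
    generalized, 1 = maximally specialized.

    For integer matrices with total ≤ ``exact_limit`` and at most 16 cells
    the extremes come from exhaustive enumeration; otherwise H2min uses the
    greedy marginal-packing heuristic and H2max the marginal outer product.
    A single-cell matrix has no degrees of freedom and yields 0.
    """
    a = m.values
    total = a.sum()
    if total <= 0:
        raise ValueError("H2' requires a positive total")
    if a.size == 1:
        logger.info("h2_prime: single-cell matrix, defined as 0")
        return 0.0
    h2 = _shannon(a)
    row_sums = a.sum(axis=1)
    col_sums = a.sum(axis=0)
    is_integer = np.allclose(a, np.round(a))
    if is_integer and total <= exact_limit and a.size <= 16:
        h2_min, h2_max = _entropy_extremes_exact(np.round(row_sums),
                                                 np.round(col_sums))
    else:
        h2_min = _entropy_min_greedy(row_sums, col_sums)
        h2_max = _entropy_max_marginal(row_sums, col_sums)
    if h2_max - h2_min <= 1e-12:
        return 0.0
    return float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Bundle + export
# ---------------------------------------------------------------------------

@dataclass
class NetworkMetrics:
    """The standard metric bundle for one aggregation level."""

    weighted_nestedness: float
    connectance: float
    interaction_evenness: float
    h2_prime: float
    shared_partners_pollinators: float
    shared_partners_plants: float
    niche_overlap_pollinators: float
    niche_overlap_plants: float

    def to_dict(self) -> dict[str, float]:
        return {k: round(v, 6) for k, v in self.__dict__.items()}


def network_metrics(m: InteractionMatrix, n_null: int = 1000,
                    seed: int = 0,
                    evenness_denominator: str = "cells",
                    overlap_variant: str = "morisita_horn") -> NetworkMetrics:
    """Compute the full metric bundle on one matrix."""
    return NetworkMetrics(
        weighted_nestedness=weighted_nestedness(m, n_null, seed).eta,
        connectance=connectance(m),
        interaction_evenness=interaction_evenness(m, evenness_denominator),
        h2_prime=h2_prime(m),
        shared_partners_pollinators=mean_shared_partners(m, "pollinators"),
        shared_partners_plants=mean_shared_partners(m, "plants"),
        niche_overlap_pollinators=niche_overlap(m, "pollinators",
                                                overlap_variant),
        niche_overlap_plants=niche_overlap(m, "plants", overlap_variant),
    )


def export_graph(m: InteractionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted bipartite edge list plus an annotated vertex table.

    Edges carry one row per nonzero cell; vertex weights are the marginal
    totals (suitable for sizing vertices in a circular network plot).
    """
    a = m.table
    if a.size == 0:
        raise EmptyMatrixError("empty matrix")
    edges = (a.stack().rename("weight").reset_index())
    edges.columns = ["plant", "pollinator", "weight"]
    edges = edges[edges["weight"] > 0].reset_index(drop=True)
    verts = []
    for plant, w in a.sum(axis=1).items():
        verts.append((plant, "plant", float(w),
                      m.plant_syndrome.get(plant, "")))
    for pol, w in a.sum(axis=0).items():
        verts.append((pol, "pollinator", float(w),
                      m.pollinator_group.get(pol, "")))
    vertices = pd.DataFrame(verts, columns=["vertex", "side", "weight",
                                            "annotation"])
    return edges, vertices
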