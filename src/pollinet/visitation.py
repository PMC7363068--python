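"""Visitation rates, park-type comparison statistics and community
clustering.

The visitation rate of a pollinator group is the number of individuals
recorded on one spatial unit (1 m² bed or 1 m³ tree crown) in a 30-minute
session; sessions of other lengths are linearly rescaled to the 30-minute
reference. Park types are compared per group with a Kruskal–Wallis test
followed by Dunn's post-hoc test (midranks, tie correction) under a
sequential Bonferroni–Holm familywise correction, summarised as a compact
letter display. Community composition across park types is clustered on the
untransformed mean-rate matrix with Bray–Curtis dissimilarity and
complete-linkage agglomeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .survey_data import (Dataset, INTERACTION_KINDS, REFERENCE_DURATION_MIN,
                          aggregate_labels)

__all__ = ["compute_rates", "summarize_rates", "pretest_distributions",
           "compare_park_types", "bray_curtis_cluster",
           "composition_percentages", "ComparisonResult", "holm_adjust",
           "dunn_test", "bray_curtis", "TOTAL"]

#: Pseudo-group key for the summed rate over all pollinator groups.
TOTAL = "total"


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def compute_rates(d: Dataset, level: str = "main_group",
                  interaction_filter: str | None = None) -> pd.DataFrame:
    """Per-session visitation rates (visits / 30 min / spatial unit).

    Returns a long table ``record_id, site_id, park_type, element_kind,
    group_key, rate`` containing one row per session × group observed at
    ``level`` (plus the ``total`` pseudo-group), with explicit zeros for
    sessions in which a group was not recorded. ``interaction_filter``
    restricts to ``blossom_visit`` or ``reconnaissance``; ``None`` keeps
    both (the overall community evaluation).
    """
    if interaction_filter is not None \
            and interaction_filter not in INTERACTION_KINDS:
        raise ValueError(f"unknown interaction_filter {interaction_filter!r}")
    if (d.sessions["duration_min"] <= 0).any():
        raise ValueError("session with duration_min <= 0")

    at = aggregate_labels(d, level) if level != "species" else d
    ev = at.events
    if interaction_filter is not None:
        ev = ev[ev["interaction_kind"] == interaction_filter]

    counts = (ev.groupby(["record_id", "pollinator_label"])["count"].sum()
              if len(ev) else pd.Series(dtype=float))
    groups = sorted(ev["pollinator_label"].unique()) if len(ev) else []

    sess = at.sessions.merge(at.sites[["site_id", "park_type"]], on="site_id")
    rows = []
    for _, s in sess.iterrows():
        scale = REFERENCE_DURATION_MIN / s["duration_min"]
        total = 0.0
        for g in groups:
            c = counts.get((s["record_id"], g), 0)
            rate = float(c) * scale
            total += rate
            rows.append((s["record_id"], s["site_id"], s["park_type"],
                         s["element_kind"], g, rate))
        rows.append((s["record_id"], s["site_id"], s["park_type"],
                     s["element_kind"], TOTAL, total))
    return pd.DataFrame(rows, columns=["record_id", "site_id", "park_type",
                                       "element_kind", "group_key", "rate"])


def summarize_rates(rt: pd.DataFrame,
                    by: tuple[str, ...] = ("park_type", "group_key"),
                    element_kinds: tuple[str, ...] | None = None
                    ) -> pd.DataFrame:
    """Mean, sample SD (n−1) and n of rates per grouping cell.

    With a single observation the SD is undefined and reported as NaN.
    """
    if not len(rt):
        raise ValueError("empty rate table")
    sub = rt if element_kinds is None else \
        rt[rt["element_kind"].isin(element_kinds)]
    out = (sub.groupby(list(by))["rate"]
           .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
           .reset_index())
    return out


# ---------------------------------------------------------------------------
# Pre-tests
# ---------------------------------------------------------------------------

def pretest_distributions(rt: pd.DataFrame, group: str = TOTAL
                          ) -> dict[str, pd.DataFrame | float | None]:
    """Shapiro–Wilk normality per park type and Levene (median-centered)
    homoscedasticity across park types, for one group's rates.

    Cells with fewer than 3 observations or zero variance are flagged as
    untestable (p = NaN) rather than raising.
    """
    sub = rt[rt["group_key"] == group]
    rows = []
    samples = []
    for park, vals in sub.groupby("park_type")["rate"]:
        v = vals.to_numpy(float)
        if len(v) < 3 or np.ptp(v) == 0:
            rows.append((park, len(v), np.nan, "untestable"))
        else:
            rows.append((park, len(v), float(stats.shapiro(v).pvalue), "ok"))
        if len(v) >= 2:
            samples.append(v)
    shapiro_df = pd.DataFrame(rows, columns=["park_type", "n", "shapiro_p",
                                             "status"])
    levene_p = None
    if len(samples) >= 2 and any(np.ptp(v) > 0 for v in samples):
        levene_p = float(stats.levene(*samples, center="median").pvalue)
    return {"shapiro": shapiro_df, "levene_p": levene_p}


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn + Holm + letters
# ---------------------------------------------------------------------------

def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Sequential Bonferroni–Holm step-down adjustment."""
    return multipletests(np.asarray(pvals, float), method="holm")[1]


def dunn_test(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's (1964) post-hoc z tests on joint midranks with tie correction.

    For groups i, j with mean ranks R̄ᵢ, R̄ⱼ over the pooled sample of size N:

        z = (R̄ᵢ − R̄ⱼ) / sqrt([N(N+1)/12 − ΣT/(12(N−1))] (1/nᵢ + 1/nⱼ))

    where ΣT = Σ(t³ − t) over tie groups of size t. Two-sided normal p.
    """
    names = list(samples)
    pooled = np.concatenate([samples[k] for k in names])
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(samples[k]) for k in names])
    mean_ranks = {k: ranks[offsets[i]:offsets[i + 1]].mean()
                  for i, k in enumerate(names)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))

    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(samples[a]), len(samples[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(min(p, 1.0))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])


def _letter_display(names: list[str], pairs: pd.DataFrame,
                    alpha: float) -> dict[str, str]:
    """Greedy compact letter display: two park types share a letter iff the
    Holm-adjusted pairwise p exceeds alpha. Ties broken by name order."""
    sig = {frozenset((r.group_a, r.group_b)): r.p_adj <= alpha
           for r in pairs.itertuples()}
    names = sorted(names)
    letter_sets: list[set[str]] = []
    for name in names:
        placed = False
        for group in letter_sets:
            if all(not sig.get(frozenset((name, other)), False)
                   for other in group):
                group.add(name)
                placed = True
        if not placed:
            letter_sets.append({name})
    # absorb redundant subsets
    letter_sets = [g for i, g in enumerate(letter_sets)
                   if not any(g < h for j, h in enumerate(letter_sets)
                              if i != j)]
    letters = {n: "" for n in names}
    for idx, group in enumerate(letter_sets):
        ch = chr(ord("a") + idx)
        for n in sorted(group):
            letters[n] += ch
    return letters


@dataclass
class ComparisonResult:
    """Kruskal–Wallis across park types plus Dunn/Holm pairwise results."""

    group_key: str
    kw_h: float
    kw_p: float
    pairwise: pd.DataFrame      # group_a, group_b, z, p_raw, p_adj
    letters: dict[str, str]     # park_type -> compact letter display
    alpha: float


def compare_park_types(rt: pd.DataFrame, group: str = TOTAL,
                       alpha: float = 0.05,
                       element_kinds: tuple[str, ...] | None = None
                       ) -> ComparisonResult:
    """Kruskal–Wallis on one group's rates across park types, followed by
    all pairwise Dunn tests with a Holm familywise adjustment and a compact
    letter display (shared letter ⇔ adjusted p > alpha)."""
    sub = rt[rt["group_key"] == group]
    if element_kinds is not None:
        sub = sub[sub["element_kind"].isin(element_kinds)]
    samples = {park: vals.to_numpy(float)
               for park, vals in sub.groupby("park_type")["rate"]
               if len(vals) >= 2}
    if len(samples) < 2:
        raise ValueError("need >= 2 park types with >= 2 observations each")

    arrays = [samples[k] for k in samples]
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p = 0.0, 1.0  # all observations identical: no evidence at all
    else:
        h, p = stats.kruskal(*arrays)
    pairs = dunn_test(samples)
    pairs["p_adj"] = holm_adjust(pairs["p_raw"].to_numpy())
    letters = _letter_display(list(samples), pairs, alpha)
    return ComparisonResult(group, float(h), float(p), pairs, letters, alpha)


# ---------------------------------------------------------------------------
# Bray-Curtis clustering
# ---------------------------------------------------------------------------

def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) on nonnegative vectors.

    Two all-zero vectors are defined as identical (0); an all-zero vector
    against a nonzero one is maximally dissimilar (1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    denom = float((x + y).sum())
    if denom == 0:
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_cluster(mean_matrix: pd.DataFrame
                        ) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Complete-linkage agglomeration of park types on untransformed mean
    rates.

    Parameters
    ----------
    mean_matrix
        park_type × group table of mean rates (nonnegative).

    Returns
    -------
    (dissimilarity matrix as DataFrame, scipy linkage matrix, Newick string
    with branch lengths derived from merge heights).
    """
    if len(mean_matrix) < 2:
        raise ValueError("need at least two rows to cluster")
    labels = list(mean_matrix.index)
    X = mean_matrix.to_numpy(float)
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = bray_curtis(X[i], X[j])
    link = hierarchy.linkage(squareform(dm, checks=False), method="complete")
    newick = _linkage_to_newick(link, labels)
    return pd.DataFrame(dm, index=labels, columns=labels), link, newick


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as Newick; a child branch's length is the
    parent merge height minus the child's own merge height."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            name = labels[node.id].replace(" ", "_")
            return f"{name}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def first_merge_pair(link: np.ndarray, labels: list[str]) -> frozenset:
    """The two leaves joined at the lowest merge height."""
    i, j = int(link[0, 0]), int(link[0, 1])
    return frozenset((labels[i], labels[j]))


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def composition_percentages(rt: pd.DataFrame,
                            element_kinds: tuple[str, ...] = ("study_bed",
                                                              "public_bed")
                            ) -> pd.DataFrame:
    """Percent of recorded individuals per group, per park type × bed kind.

    Percentages within a (park type, element kind) cell sum to 100; cells
    with zero total are reported as NaN (undefined), not zero.
    """
    sub = rt[(rt["element_kind"].isin(element_kinds))
             & (rt["group_key"] != TOTAL)]
    sums = (sub.groupby(["park_type", "element_kind", "group_key"])["rate"]
            .sum().reset_index())
    totals = (sums.groupby(["park_type", "element_kind"])["rate"]
              .transform("sum"))
    sums["percent"] = np.where(totals > 0, 100.0 * sums["rate"] / totals,
                               np.nan)
    return sums.drop(columns="rate")
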