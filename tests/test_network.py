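"""Interaction matrix construction, correction factors, network metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pollinet import (InteractionMatrix, aggregate_network, apply_correction,
                      build_matrix, connectance, correction_factors,
                      export_graph, h2_prime, interaction_evenness,
                      mean_shared_partners, niche_overlap,
                      weighted_nestedness)
from pollinet.network import EmptyMatrixError, _shannon
from pollinet.survey_data import filter_events

from conftest import make_dataset


def mat(values, rows=None, cols=None, **kw):
    a = np.asarray(values, float)
    rows = rows or [f"p{i}" for i in range(a.shape[0])]
    cols = cols or [f"g{j}" for j in range(a.shape[1])]
    return InteractionMatrix(pd.DataFrame(a, index=rows, columns=cols), **kw)


def _public_session(rid, site):
    return (rid, site, "public_bed", "pb1", "2016-06-01", "10:00", 30.0,
            "21", "calm", "clear")


class TestBuildMatrix:
    def test_single_event(self):
        d = make_dataset(
            sessions=[_public_session("r1", "s1")],
            events=[("r1", "Plant A", "Apis mellifera", "blossom_visit",
                     4)])
        m = build_matrix(d)
        assert m.table.shape == (1, 1)
        assert m.table.iloc[0, 0] == 4.0

    def test_additivity_and_reconnaissance_exclusion(self):
        d = make_dataset(
            sessions=[_public_session("r1", "s1"),
                      _public_session("r2", "s1")],
            events=[("r1", "Plant A", "Apis mellifera", "blossom_visit", 3),
                    ("r2", "Plant A", "Apis mellifera", "blossom_visit", 2),
                    ("r1", "Plant A", "Apis mellifera", "reconnaissance",
                     9)])
        m = build_matrix(d)
        assert m.table.loc["Plant A", "Apis mellifera"] == 5.0

    def test_conservation_against_independent_sum(self, default_dataset):
        m = build_matrix(default_dataset)
        sub = filter_events(default_dataset,
                            interaction_kind="blossom_visit",
                            element_kinds=("public_bed",))
        assert m.total == float(sub.events["count"].sum())

    def test_no_qualifying_events(self):
        d = make_dataset(sessions=[
            ("r1", "s2", "study_bed", "sb1", "2016-06-01", "10:00", 30.0,
             "21", "calm", "clear")], events=[])
        with pytest.raises(EmptyMatrixError):
            build_matrix(d)


class TestCorrectionFactors:
    def _dataset(self, n_a, n_b):
        sessions = [_public_session(f"a{i}", "s1") for i in range(n_a)]
        sessions += [(f"b{i}", "s2", "public_bed", "pb1", "2016-06-01",
                      "10:00", 30.0, "21", "calm", "clear")
                     for i in range(n_b)]
        events = [("a0", "Plant A", "Apis mellifera", "blossom_visit", 1),
                  ("b0", "Plant B", "Apis mellifera", "blossom_visit", 1)]
        return make_dataset(sessions=sessions, events=events)

    def test_most_surveyed_site_gets_unity(self):
        f = correction_factors(self._dataset(14, 8))
        assert f["Plant A"] == 1.0

    def test_quotient_14_over_8(self):
        f = correction_factors(self._dataset(14, 8))
        assert f["Plant B"] == pytest.approx(1.75)

    def test_reference_below_site_count(self):
        # a designated reference of 14 against a site with 27 replicates
        f = correction_factors(self._dataset(27, 5), reference_n=14)
        assert f["Plant A"] == pytest.approx(0.5185, abs=1e-4)

    def test_rows_scaled_by_factor(self):
        d = self._dataset(14, 7)
        m = build_matrix(d)
        corrected = apply_correction(m, correction_factors(d))
        assert corrected.table.loc["Plant B", "Apis mellifera"] == 2.0
        assert corrected.table.loc["Plant A", "Apis mellifera"] == 1.0


class TestAggregation:
    def test_identity(self):
        m = mat([[1, 2], [3, 4]])
        out = aggregate_network(m, "species", "fine")
        pd.testing.assert_frame_equal(out.table, m.table)

    def test_syndrome_sums(self):
        m = mat([[1, 2], [3, 4]], rows=["pa", "pb"],
                plant_syndrome={"pa": "generalist", "pb": "generalist"})
        out = aggregate_network(m, "syndrome", "fine")
        assert out.table.loc["generalist"].tolist() == [4.0, 6.0]

    def test_totals_conserved_at_all_levels(self, default_dataset):
        m = build_matrix(default_dataset)
        grouped = aggregate_network(m, "species", "grouped")
        syndrome = aggregate_network(m, "syndrome", "grouped")
        assert m.total == pytest.approx(grouped.total)
        assert m.total == pytest.approx(syndrome.total)


def test_connectance_counts_realized_links():
    assert connectance(mat([[1, 2], [3, 4]])) == 1.0
    assert connectance(mat([[1, 0, 2], [0, 0, 3], [4, 0, 0]])) \
        == pytest.approx(4 / 9)


def test_connectance_strictly_increases_when_cell_fills():
    a = np.array([[1.0, 0.0], [2.0, 3.0]])
    before = connectance(mat(a))
    a[0, 1] = 0.5
    assert connectance(mat(a)) > before


class TestEvenness:
    def test_uniform_matrix_is_one(self):
        assert interaction_evenness(mat([[2, 2], [2, 2]])) \
            == pytest.approx(1.0)

    def test_single_link_is_zero(self):
        assert interaction_evenness(mat([[5, 0], [0, 0]])) == 0.0

    def test_hand_computed(self):
        # p = (3,1,1,3)/8; H = 1.2555; H/ln4 = 0.9056
        assert interaction_evenness(mat([[3, 1], [1, 3]])) \
            == pytest.approx(0.9056, abs=1e-4)

    def test_links_variant(self):
        m = mat([[2, 2], [2, 0]])
        assert interaction_evenness(m, "links") == pytest.approx(1.0)


class TestSharedPartners:
    def test_identical_patterns(self):
        m = mat([[1, 2], [3, 4], [5, 6]])
        assert mean_shared_partners(m, "pollinators") == 3.0

    def test_disjoint_columns(self):
        m = mat([[1, 0], [2, 0], [0, 3]])
        assert mean_shared_partners(m, "pollinators") == 0.0

    def test_brute_force_on_4x4(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, size=(4, 4)).astype(float)
        m = mat(a)
        for axis, vecs in (("pollinators", a.T), ("plants", a)):
            pairs = [np.sum((x > 0) & (y > 0))
                     for x, y in itertools.combinations(vecs, 2)]
            assert mean_shared_partners(m, axis) \
                == pytest.approx(np.mean(pairs))


class TestNicheOverlap:
    def test_identical_and_disjoint(self):
        assert niche_overlap(mat([[1, 1], [2, 2]]), "pollinators") \
            == pytest.approx(1.0)
        assert niche_overlap(mat([[1, 0], [0, 3]]), "pollinators") == 0.0

    def test_hand_computed_morisita_horn(self):
        m = mat([[1, 1], [1, 3]])
        assert niche_overlap(m, "pollinators") == pytest.approx(8 / 9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.random((4, 3)) + 0.1
        base = niche_overlap(mat(a), "pollinators")
        a[:, 1] *= 37.0  # Morisita-Horn is density-invariant
        assert niche_overlap(mat(a), "pollinators") \
            == pytest.approx(base)


def h2_enumeration_oracle(a):
    """Brute-force H2' for small integer matrices: enumerate every matrix
    with the observed marginals and standardize between the extremes."""
    a = np.asarray(a, float)
    row_sums = a.sum(axis=1).astype(int)
    col_sums = a.sum(axis=0).astype(int)
    nr, nc = a.shape
    entropies = []

    def rows_for(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for v in range(min(total, caps[0]) + 1):
            for rest in rows_for(total - v, caps[1:]):
                yield (v,) + rest

    def walk(i, caps, cells):
        if i == nr:
            if all(c == 0 for c in caps):
                entropies.append(_shannon(np.array(cells, float)))
            return
        for row in rows_for(row_sums[i], caps):
            walk(i + 1, [c - v for c, v in zip(caps, row)],
                 cells + list(row))

    walk(0, list(col_sums), [])
    h2 = _shannon(a)
    lo, hi = min(entropies), max(entropies)
    if hi - lo < 1e-12:
        return 0.0
    return float(np.clip((hi - h2) / (hi - lo), 0.0, 1.0))


class TestH2Prime:
    def test_diagonal_is_maximally_specialized(self):
        assert h2_prime(mat([[5, 0], [0, 5]])) == pytest.approx(1.0)

    def test_outer_product_is_maximally_generalized(self):
        assert h2_prime(mat([[2, 2], [2, 2]])) == pytest.approx(0.0)

    def test_single_cell_defined_as_zero(self):
        assert h2_prime(mat([[7.0]])) == 0.0

    def test_matches_enumeration_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.integers(0, 3, size=(3, 3))
            if a.sum() < 2:
                continue
            assert h2_prime(mat(a)) \
                == pytest.approx(h2_enumeration_oracle(a), abs=1e-9)

    def test_heuristic_close_to_exact_above_limit(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 4, size=(3, 3))
        a[0, 0] += 17 - a.sum() if a.sum() < 17 else 0
        assert a.sum() > 16  # beyond the exact-enumeration limit
        approx = h2_prime(mat(a))
        exact = h2_enumeration_oracle(a)
        assert approx == pytest.approx(exact, abs=0.12)


class TestWine:
    def packed(self):
        # perfectly nested: every row's partners are a subset of the
        # previous row's, weights decreasing toward the corner
        return mat([[9, 7, 5, 3], [8, 6, 2, 0], [4, 1, 0, 0], [2, 0, 0, 0]])

    def test_packed_matrix_near_one(self):
        res = weighted_nestedness(self.packed(), n_null=300, seed=0)
        assert abs(res.eta - 1.0) <= 3 * res.null_sd

    def test_null_draws_center_on_zero(self):
        rng = np.random.default_rng(4)
        etas = []
        for _ in range(60):
            flat = np.zeros(30)
            cells = rng.choice(30, size=12, replace=False)
            flat[cells] = rng.permutation(np.arange(1.0, 13.0))
            m = mat(flat.reshape(6, 5))
            etas.append(weighted_nestedness(m, n_null=150,
                                            seed=11).eta)
        assert abs(np.mean(etas)) < 3 * np.std(etas) / np.sqrt(len(etas)) + 0.1

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            weighted_nestedness(mat([[1, 2, 3]]), n_null=10, seed=0)

    def test_seed_fixes_null_ensemble(self):
        m = self.packed()
        a = weighted_nestedness(m, n_null=100, seed=5)
        b = weighted_nestedness(m, n_null=100, seed=5)
        assert a.eta == b.eta and a.d_rnd == b.d_rnd


def test_metrics_invariant_under_joint_permutation():
    rng = np.random.default_rng(6)
    a = rng.random((5, 4)) * (rng.random((5, 4)) > 0.3)
    a += np.eye(5, 4) * 0.01  # avoid empty rows/cols
    m = mat(a)
    shuffled = m.table.iloc[rng.permutation(5), rng.permutation(4)]
    perm = InteractionMatrix(shuffled)  # labels travel with the cells
    for fn in (connectance, h2_prime, interaction_evenness,
               lambda x: mean_shared_partners(x, "plants"),
               lambda x: niche_overlap(x, "pollinators"),
               lambda x: weighted_nestedness(x, n_null=200, seed=9).eta):
        assert fn(m) == pytest.approx(fn(perm), abs=1e-9)


def test_export_graph_edges_and_vertices():
    m = mat([[4.0]], rows=["Plant A"], cols=["Apis mellifera"],
            plant_syndrome={"Plant A": "generalist"},
            pollinator_group={"Apis mellifera": "honeybee"})
    edges, verts = export_graph(m)
    assert len(edges) == 1 and edges["weight"].iloc[0] == 4.0
    assert set(verts["weight"]) == {4.0}
    assert set(verts["annotation"]) == {"generalist", "honeybee"}

    rng = np.random.default_rng(7)
    a = rng.integers(0, 3, size=(4, 3)).astype(float)
    a[0, 0] = 1.0  # keep at least one positive cell
    m2 = mat(a)
    edges2, verts2 = export_graph(m2)
    assert len(edges2) == int((a > 0).sum())
    marg = verts2.set_index("vertex")["weight"]
    for i, plant in enumerate(m2.table.index):
        assert marg[plant] == a[i].sum()
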