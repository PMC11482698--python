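import numpy as np
import pytest

import faunalregions as fr
from faunalregions import MatrixError, UndefinedAssociationError
from oracles import exact_max_phi_pvalue, pearson_phi_oracle


def _assignment(labels, k):
    return fr.ClusterAssignment(
        [f"R{i}" for i in range(len(labels))], list(labels), k=k, inertia=0.0
    )


FOUR = _assignment([1, 1, 2, 2], k=2)


# -- phi -------------------------------------------------------------------

def test_phi_perfect_fidelity():
    assert fr.phi([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)


def test_phi_independence():
    assert fr.phi([1, 0, 1, 0], [1, 1, 0, 0]) == pytest.approx(0.0)


def test_phi_matches_pearson_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(4, 16))
        p = rng.integers(0, 2, n)
        g = rng.integers(0, 2, n)
        if p.sum() in (0, n) or g.sum() in (0, n):
            continue
        assert fr.phi(p, g) == pytest.approx(pearson_phi_oracle(p, g))
        assert fr.phi(p, g) == pytest.approx(np.corrcoef(p, g)[0, 1])


def test_phi_eight_point_example():
    p = [1, 1, 1, 0, 0, 0, 0, 0]
    g = [1, 1, 0, 0, 0, 0, 0, 0]
    assert fr.phi(p, g) == pytest.approx(pearson_phi_oracle(p, g))


def test_phi_undefined_on_constant_vectors():
    with pytest.raises(UndefinedAssociationError):
        fr.phi([1, 1, 1], [1, 0, 1])
    with pytest.raises(UndefinedAssociationError):
        fr.phi([1, 0, 1], [0, 0, 0])


def test_phi_negating_group_negates_value(rng):
    for _ in range(20):
        p = rng.integers(0, 2, 10)
        g = rng.integers(0, 2, 10)
        if p.sum() in (0, 10) or g.sum() in (0, 10):
            continue
        assert fr.phi(p, 1 - g) == pytest.approx(-fr.phi(p, g))


def test_phi_invariant_under_joint_permutation(rng):
    p = np.array([1, 0, 1, 1, 0, 0, 1, 0])
    g = np.array([1, 1, 0, 1, 0, 0, 0, 1])
    for _ in range(10):
        perm = rng.permutation(8)
        assert fr.phi(p[perm], g[perm]) == pytest.approx(fr.phi(p, g))


# -- combinations ----------------------------------------------------------

def test_enumerate_combinations_counts():
    assert [c.member_clusters for c in fr.enumerate_combinations(2)] == [(1,), (2,)]
    combos5 = fr.enumerate_combinations(5)
    assert len(combos5) == 30  # 2^5 - 2
    members = [c.member_clusters for c in combos5]
    assert (1, 3, 4, 5) in members
    assert (1, 2, 3, 4, 5) not in members


def test_combinations_ordered_by_size_then_lex():
    members = [c.member_clusters for c in fr.enumerate_combinations(3)]
    assert members == [(1,), (2,), (3,), (1, 2), (1, 3), (2, 3)]


def test_combination_site_masks_follow_assignment():
    a = _assignment([1, 2, 2, 3], k=3)
    combos = {c.member_clusters: c for c in fr.enumerate_combinations(3, a)}
    assert combos[(2,)].site_mask == (False, True, True, False)
    assert combos[(1, 3)].site_mask == (True, False, False, True)


# -- best association ------------------------------------------------------

def test_best_association_perfect_indicator():
    a = _assignment([1, 1, 2, 2, 3], k=3)
    combo, val = fr.best_association([0, 0, 1, 1, 0], a)
    assert combo.member_clusters == (2,)
    assert val == pytest.approx(1.0)


def test_best_association_matches_exhaustive_loop(rng):
    a = _assignment([1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 4, 4, 5], k=5)
    combos = fr.enumerate_combinations(5, a)
    for _ in range(25):
        p = rng.integers(0, 2, 13)
        if p.sum() in (0, 13):
            continue
        best, val = fr.best_association(p, a)
        loop = [(pearson_phi_oracle(p, c.mask_array().astype(float)), c) for c in combos]
        loop_best = max(v for v, _ in loop)
        assert val == pytest.approx(loop_best)
        # first maximizer in size-then-lex order
        first = next(c for v, c in loop if v == pytest.approx(loop_best))
        assert best.member_clusters == first.member_clusters


# -- permutation p-values --------------------------------------------------

def test_pvalue_add_one_lower_bound():
    p = fr.permutation_pvalue([1, 1, 0, 0], FOUR, n_perm=999, seed=0)
    assert p >= 1 / 1000


def test_pvalue_matches_exact_enumeration_within_3_sigma():
    presence = [1, 1, 0, 0]
    masks = [np.array([1, 1, 0, 0], float), np.array([0, 0, 1, 1], float)]
    exact = exact_max_phi_pvalue(presence, [1, 1, 2, 2], masks)
    n_perm = 9999
    mc = fr.permutation_pvalue(presence, FOUR, n_perm=n_perm, seed=5)
    sigma = np.sqrt(exact * (1 - exact) / n_perm)
    assert abs(mc - exact) < 3 * sigma + 2 / (n_perm + 1)


def test_pvalue_seed_stability_mid_range(rng):
    a = _assignment([1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 4, 4, 5], k=5)
    p = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0, 1, 0])
    p1 = fr.permutation_pvalue(p, a, n_perm=999, seed=1)
    p2 = fr.permutation_pvalue(p, a, n_perm=999, seed=2)
    assert abs(p1 - p2) < 0.05


def test_pvalue_rejects_bad_nperm():
    with pytest.raises(MatrixError):
        fr.permutation_pvalue([1, 1, 0, 0], FOUR, n_perm=0)


# -- run_isa ---------------------------------------------------------------

def _matrix(vals):
    vals = np.asarray(vals, dtype=np.int8)
    return fr.PresenceAbsenceMatrix(
        vals, [f"Genus{i:03d} sp" for i in range(vals.shape[0])],
        [f"R{i}" for i in range(vals.shape[1])],
    )


def test_run_isa_deterministic_and_skips_constant_rows():
    a = _assignment([1, 1, 2, 2, 3], k=3)
    m = _matrix([[0, 0, 1, 1, 0], [1, 1, 1, 1, 1], [0, 0, 0, 0, 0], [1, 0, 1, 0, 1]])
    t1 = fr.run_isa(m, a, n_perm=199, seed=3)
    t2 = fr.run_isa(m, a, n_perm=199, seed=3)
    assert [(r.taxon_id, r.phi, r.p_value) for r in t1.results] == [
        (r.taxon_id, r.phi, r.p_value) for r in t2.results
    ]
    assert set(t1.skipped) == {"Genus001 sp", "Genus002 sp"}
    assert all(r.significant or not r.characteristic for r in t1.results)


def test_run_isa_planted_perfect_indicators_recovered():
    # deterministic limit: every taxon a perfect indicator of its combination
    m, truth = fr.generate_clustered_fauna(
        n_taxa=10, n_regions=13, k=5, p_in=1.0, p_out=0.0, seed=4
    )
    labels = [truth.planted_partition[u] for u in m.unit_ids]
    a = fr.ClusterAssignment(list(m.unit_ids), labels, k=5, inertia=0.0)
    t = fr.run_isa(m, a, seed=1)
    assert len(t.results) == 10 and not t.skipped
    for r in t.results:
        assert r.phi == pytest.approx(1.0)
        assert r.best_combination.member_clusters == truth.planted_indicators[r.taxon_id]


def test_run_isa_requires_matching_units():
    a = _assignment([1, 1, 2, 2], k=2)
    m = _matrix([[1, 0, 1, 0, 1]])
    with pytest.raises(MatrixError):
        fr.run_isa(m, a)


def test_isa_type_one_error_controlled(assignment, rng):
    # presence independent of the clusters: empirical rejection rate at
    # alpha=0.05 must not exceed 0.05 + 3 sigma (the max-over-combinations
    # selection makes the test conservative)
    n_taxa = 2000
    vals = (rng.random((n_taxa, 13)) < 0.4).astype(np.int8)
    keep = (vals.sum(axis=1) > 0) & (vals.sum(axis=1) < 13)
    vals = vals[keep]
    m = fr.PresenceAbsenceMatrix(
        vals, [f"Genus{i:04d} sp" for i in range(vals.shape[0])],
        list(assignment.unit_ids),
    )
    t = fr.run_isa(m, assignment, n_perm=199, seed=12345)
    rate = t.significant_count / len(t.results)
    sigma = np.sqrt(0.05 * 0.95 / len(t.results))
    assert rate <= 0.05 + 3 * sigma


def test_table_export_and_summary(tmp_path, assignment, iran_matrix):
    t = fr.run_isa(iran_matrix, assignment, n_perm=99, seed=0)
    out = tmp_path / "indicators.csv"
    t.to_csv(out)
    text = out.read_text()
    assert text.startswith("#") and "n_perm=99" in text
    assert "taxon_id,combination,phi,p_value,significant,characteristic" in text
    model = fr.IndicatorSpeciesAnalysis(iran_matrix, assignment, n_perm=99, seed=0)
    res = model.fit()
    assert res.significant_count == t.significant_count
    assert "Simplified indicator species analysis" in res.summary()
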