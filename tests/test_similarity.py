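import numpy as np
import pytest

import faunalregions as fr
from faunalregions import MatrixError
from conftest import random_binary_matrix
from oracles import jaccard_oracle, sorensen_oracle, upgma_cophenetic_oracle


def _m(values, units=None):
    values = np.asarray(values)
    units = units or [f"U{j}" for j in range(values.shape[1])]
    return fr.PresenceAbsenceMatrix(
        values, [f"Genus{i:03d} sp" for i in range(values.shape[0])], units
    )


# -- dissimilarities -------------------------------------------------------

def test_jaccard_hand_example():
    # columns are units: x=(1,1,0), y=(1,0,1) -> a=1,b=1,c=1 -> 2/3
    m = _m(np.array([[1, 1], [1, 0], [0, 1]]))
    d = fr.jaccard_dissimilarity(m)
    assert d[("U0", "U1")] == pytest.approx(2 / 3)


def test_sorensen_hand_example():
    m = _m(np.array([[1, 1], [1, 0], [0, 1]]))
    d = fr.sorensen_dissimilarity(m)
    assert d[("U0", "U1")] == pytest.approx(0.5)


def test_identical_units_have_zero_dissimilarity():
    m = _m(np.array([[1, 1], [1, 1], [0, 0]]))
    assert fr.jaccard_dissimilarity(m)[("U0", "U1")] == 0.0
    assert fr.sorensen_dissimilarity(m)[("U0", "U1")] == 0.0


def test_dissimilarities_match_set_oracle(rng):
    for _ in range(5):
        m = random_binary_matrix(rng, 10, 4)
        dj = fr.jaccard_dissimilarity(m)
        ds = fr.sorensen_dissimilarity(m)
        for a in range(4):
            for b in range(a + 1, 4):
                x, y = m.values[:, a], m.values[:, b]
                assert dj.values[a, b] == pytest.approx(jaccard_oracle(x, y))
                assert ds.values[a, b] == pytest.approx(sorensen_oracle(x, y))


def test_sorensen_le_jaccard(rng):
    for _ in range(10):
        m = random_binary_matrix(rng, 12, 5)
        dj = fr.jaccard_dissimilarity(m).values
        ds = fr.sorensen_dissimilarity(m).values
        assert (ds <= dj + 1e-12).all()


def test_zero_union_pair_errors_by_default():
    m = _m(np.array([[0, 0, 1], [0, 0, 1]]))
    with pytest.raises(MatrixError):
        fr.jaccard_dissimilarity(m)
    with pytest.warns(UserWarning):
        d = fr.jaccard_dissimilarity(m, zero_union="zero")
    assert d[("U0", "U1")] == 0.0


def test_distance_matrix_validation():
    with pytest.raises(MatrixError, match="symmetric"):
        fr.DistanceMatrix(["a", "b"], np.array([[0, 0.2], [0.3, 0]]))
    with pytest.raises(MatrixError, match="diagonal"):
        fr.DistanceMatrix(["a", "b"], np.array([[0.1, 0.2], [0.2, 0]]))
    with pytest.raises(MatrixError, match=r"\[0, 1\]"):
        fr.DistanceMatrix(["a", "b"], np.array([[0, 1.2], [1.2, 0]]))


# -- UPGMA -----------------------------------------------------------------

def _dm(vals, ids):
    return fr.DistanceMatrix(ids, np.asarray(vals, dtype=float))


def test_upgma_toy_average_linkage():
    d = _dm([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]], ["A", "B", "C"])
    t = fr.upgma(d)
    assert t.cophenetic_height("A", "B") == pytest.approx(0.2)
    assert t.cophenetic_height("A", "C") == pytest.approx(0.7)  # (0.6+0.8)/2
    assert t.cophenetic_height("C", "B") == pytest.approx(0.7)


def test_upgma_matches_brute_force_oracle(rng):
    for _ in range(5):
        n = 6
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        D[iu] = rng.random(len(iu[0]))
        D = np.clip(D + D.T, 0, 1)
        t = fr.upgma(fr.DistanceMatrix([f"U{i}" for i in range(n)], D))
        assert np.allclose(t.cophenetic_matrix().values, upgma_cophenetic_oracle(D))


def test_upgma_ultrametricity(rng):
    n = 7
    D = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    D[iu] = rng.random(len(iu[0]))
    D = D + D.T
    t = fr.upgma(fr.DistanceMatrix([f"U{i}" for i in range(n)], D))
    C = t.cophenetic_matrix().values
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                two_largest = sorted([C[i, j], C[i, k], C[j, k]])[1:]
                assert two_largest[0] == pytest.approx(two_largest[1])
    assert t.linkage.shape[0] == n - 1


def test_upgma_invariant_under_unit_reordering(rng):
    m = random_binary_matrix(rng, 20, 6)
    t1 = fr.upgma(fr.jaccard_dissimilarity(m))
    perm = rng.permutation(6)
    m2 = m.subset_units([m.unit_ids[i] for i in perm])
    t2 = fr.upgma(fr.jaccard_dissimilarity(m2))
    for a in range(6):
        for b in range(a + 1, 6):
            u, v = m.unit_ids[a], m.unit_ids[b]
            assert t1.cophenetic_height(u, v) == pytest.approx(t2.cophenetic_height(u, v))


def test_cophenetic_height_contract():
    d = _dm([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]], ["A", "B", "C"])
    t = fr.upgma(d)
    assert fr.cophenetic_height(t, "A", "A") == 0.0
    assert fr.cophenetic_height(t, "A", "C") == fr.cophenetic_height(t, "C", "A")
    with pytest.raises(MatrixError):
        t.cophenetic_height("A", "Q")


def test_upgma_rejects_nan_and_single_leaf():
    with pytest.raises(MatrixError):
        fr.upgma(fr.DistanceMatrix(["A"], np.zeros((1, 1))))
    d = fr.DistanceMatrix(["A", "B"], np.array([[0, 0.5], [0.5, 0]]))
    d.values[0, 1] = d.values[1, 0] = np.nan
    with pytest.raises(MatrixError):
        fr.upgma(d)


def test_planted_bipartition_recovered_at_root(rng):
    # two unit groups: within-group dissimilarity below between-group
    m, truth = fr.generate_clustered_fauna(
        n_taxa=50, n_regions=8, k=2, p_in=0.9, p_out=0.1, seed=11,
        max_combination_size=1,
    )
    t = fr.upgma(fr.jaccard_dissimilarity(m))
    h, members = max(t.clades())
    n = len(t.leaves)
    # root children = the two clades directly below the root
    clades = [mem for hh, mem in t.clades() if hh < h]
    top = sorted(clades, key=len, reverse=True)
    planted = {frozenset(u for u, c in truth.planted_partition.items() if c == g)
               for g in (1, 2)}
    root_children = {mem for mem in clades
                     if len(mem) < n and not any(mem < other for other in clades)}
    assert root_children == planted


# -- Newick ----------------------------------------------------------------

def test_newick_two_leaf_half_height():
    d = _dm([[0, 0.4], [0.4, 0]], ["A", "B"])
    assert fr.to_newick(fr.upgma(d)) == "(A:0.2,B:0.2);"


def test_newick_ends_with_semicolon(rng):
    m = random_binary_matrix(rng, 10, 5)
    assert fr.upgma(fr.jaccard_dissimilarity(m)).to_newick().endswith(";")


def test_newick_round_trip_reproduces_cophenetic(rng):
    dendropy = pytest.importorskip("dendropy")
    m = random_binary_matrix(rng, 15, 6)
    t = fr.upgma(fr.jaccard_dissimilarity(m))
    tree = dendropy.Tree.get(data=t.to_newick(), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in tree.taxon_namespace}
    for a in range(6):
        for b in range(a + 1, 6):
            u, v = m.unit_ids[a], m.unit_ids[b]
            # path length between leaves equals the cophenetic height
            assert pdm.distance(taxa[u], taxa[v]) == pytest.approx(
                t.cophenetic_height(u, v), abs=1e-9
            )


# -- model facade ----------------------------------------------------------

def test_faunal_similarity_genus_equals_manual_aggregation(checklist):
    res = fr.FaunalSimilarity(checklist, metric="jaccard", level="genus").fit()
    manual = fr.jaccard_dissimilarity(checklist.aggregate_to_genus())
    assert np.allclose(res.distance.values, manual.values)
    assert "genus" in res.summary()


def test_faunal_similarity_rejects_unknown_options(checklist):
    with pytest.raises(ValueError):
        fr.FaunalSimilarity(checklist, metric="euclidean")
    with pytest.raises(ValueError):
        fr.FaunalSimilarity(checklist, level="family")
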