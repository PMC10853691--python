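import io

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.ordination import pcoa as skbio_pcoa

from fmtgraft.diversity import (
    DistanceMatrix,
    bray_curtis,
    pairwise_distances,
    pcoa,
    shannon,
    unweighted_unifrac,
    weighted_unifrac,
)
from fmtgraft.profile_io import FeatureTable, ValidationError, read_newick
from fmtgraft.simulate import simulate_tree


# -- independent oracles -------------------------------------------------------


def branch_tip_sets(tree):
    """(length, descendant tip set) for every non-root edge, by traversal."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        out.append((node.length, tips))
    return out


def unifrac_unweighted_bruteforce(x, y, tree):
    shared = unique = 0.0
    for length, tips in branch_tip_sets(tree):
        in_x, in_y = bool(tips & x), bool(tips & y)
        if in_x or in_y:
            if in_x and in_y:
                shared += length
            else:
                unique += length
    return unique / (unique + shared)


def unifrac_weighted_bruteforce(px, py, tree, normalized):
    num = den = 0.0
    for length, tips in branch_tip_sets(tree):
        pbx = sum(px.get(t, 0.0) for t in tips)
        pby = sum(py.get(t, 0.0) for t in tips)
        num += length * abs(pbx - pby)
        den += length * (pbx + pby)
    return num / den if normalized else num


# -- shannon -------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,base,expected",
    [
        ((10, 0, 0), 2, 0.0),
        ((5, 5, 5, 5), 2, 2.0),
        ((2, 1, 1), 2, 1.5),
        ((1, 1, 1), np.e, np.log(3)),
    ],
)
def test_shannon_values(counts, base, expected):
    assert shannon(counts, log_base=base) == pytest.approx(expected)


def test_shannon_empty_sample_undefined():
    with pytest.raises(ValidationError):
        shannon((0, 0, 0))


# -- bray-curtis ---------------------------------------------------------------


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ((3, 1, 2), (3, 1, 2), 0.0),
        ((5, 0, 0), (0, 2, 7), 1.0),
        ((6, 2), (2, 2), 1 / 3),
    ],
)
def test_bray_curtis_values(x, y, expected):
    assert bray_curtis(x, y) == pytest.approx(expected)


def test_bray_curtis_both_empty_is_error():
    with pytest.raises(ValidationError):
        bray_curtis((0, 0), (0, 0))


def test_bray_curtis_symmetric_and_bounded():
    rng = np.random.default_rng(0)
    for _ in range(50):
        x = rng.integers(0, 20, size=6)
        y = rng.integers(0, 20, size=6)
        if x.sum() == 0 and y.sum() == 0:
            continue
        d = bray_curtis(x, y)
        assert 0 <= d <= 1
        assert d == pytest.approx(bray_curtis(y, x))


# -- unifrac -------------------------------------------------------------------


def test_unweighted_identical_sets_zero(toy_tree):
    assert unweighted_unifrac({"A", "B"}, {"A", "B"}, toy_tree) == pytest.approx(0.0)


def test_unweighted_fully_disjoint_cherry():
    tree = read_newick(io.StringIO("(A:1,B:1);"))
    assert unweighted_unifrac({"A"}, {"B"}, tree) == pytest.approx(1.0)


def test_unweighted_partial_overlap(toy_tree):
    # unique branches B(1) + C(2) over observed total 5
    assert unweighted_unifrac({"A", "B"}, {"A", "C"}, toy_tree) == pytest.approx(0.6)


def test_weighted_proportional_samples_zero(toy_tree):
    ids = ["A", "B", "C"]
    assert weighted_unifrac([2, 4, 6], [1, 2, 3], toy_tree, ids) == pytest.approx(0.0)


def test_weighted_cherry_raw_and_normalized():
    tree = read_newick(io.StringIO("(A:1,B:1);"))
    assert weighted_unifrac([10, 0], [0, 10], tree, ["A", "B"]) == pytest.approx(2.0)
    assert weighted_unifrac(
        [10, 0], [0, 10], tree, ["A", "B"], normalized=True
    ) == pytest.approx(1.0)


def test_star_tree_unweighted_equals_jaccard(star_tree):
    tips = ["A", "B", "C", "D", "E"]
    rng = np.random.default_rng(1)
    for _ in range(20):
        x = {t for t in tips if rng.random() < 0.6} or {"A"}
        y = {t for t in tips if rng.random() < 0.6} or {"B"}
        jaccard = 1 - len(x & y) / len(x | y)
        assert unweighted_unifrac(x, y, star_tree, tips) == pytest.approx(jaccard)


@pytest.mark.parametrize("n_tips", [3, 5, 8])
def test_unifrac_matches_bruteforce_enumeration(n_tips):
    """Both UniFrac variants agree with explicit per-branch summation."""
    rng = np.random.default_rng(n_tips)
    tree = simulate_tree(n_tips, seed=n_tips)
    tips = sorted(t.name for t in tree.tips())
    for trial in range(15):
        xc = rng.integers(0, 10, size=n_tips)
        yc = rng.integers(0, 10, size=n_tips)
        if xc.sum() == 0:
            xc[0] = 1
        if yc.sum() == 0:
            yc[-1] = 1
        x = {t for t, c in zip(tips, xc) if c}
        y = {t for t, c in zip(tips, yc) if c}
        got_u = unweighted_unifrac(xc, yc, tree, tips)
        assert got_u == pytest.approx(unifrac_unweighted_bruteforce(x, y, tree))
        px = dict(zip(tips, xc / xc.sum()))
        py = dict(zip(tips, yc / yc.sum()))
        for normalized in (False, True):
            got_w = weighted_unifrac(xc, yc, tree, tips, normalized=normalized)
            assert got_w == pytest.approx(
                unifrac_weighted_bruteforce(px, py, tree, normalized)
            )


# -- pairwise matrices ---------------------------------------------------------


def test_single_sample_matrix_is_zero():
    table = FeatureTable(("f1",), ("S1",), np.array([[4]]))
    dm = pairwise_distances(table, "bray_curtis")
    assert dm.values.shape == (1, 1) and dm.values[0, 0] == 0


def test_duplicated_sample_has_zero_distance(toy_tree):
    table = FeatureTable(
        ("A", "B", "C"), ("S1", "S2"), np.array([[3, 3], [1, 1], [0, 0]])
    )
    for metric in ("bray_curtis", "unweighted_unifrac", "weighted_unifrac"):
        dm = pairwise_distances(table, metric, tree=toy_tree)
        assert dm.values[0, 1] == pytest.approx(0.0)


def test_matrix_matches_scalar_recomputation(toy_tree):
    rng = np.random.default_rng(2)
    counts = rng.integers(1, 30, size=(3, 4))
    table = FeatureTable(
        ("A", "B", "C"), tuple(f"S{i}" for i in range(4)), counts
    )
    tips = list(table.feature_ids)
    dm_bc = pairwise_distances(table, "bray_curtis")
    dm_uu = pairwise_distances(table, "unweighted_unifrac", tree=toy_tree)
    dm_wu = pairwise_distances(table, "weighted_unifrac", tree=toy_tree)
    for i, si in enumerate(table.sample_ids):
        for j, sj in enumerate(table.sample_ids):
            xi, xj = counts[:, i], counts[:, j]
            assert dm_bc.values[i, j] == pytest.approx(bray_curtis(xi, xj))
            assert dm_uu.values[i, j] == pytest.approx(
                unweighted_unifrac(xi, xj, toy_tree, tips)
            )
            assert dm_wu.values[i, j] == pytest.approx(
                weighted_unifrac(xi, xj, toy_tree, tips)
            )


def test_unifrac_without_tree_is_error(small_table):
    with pytest.raises(ValidationError):
        pairwise_distances(small_table, "unweighted_unifrac")


# -- pcoa ----------------------------------------------------------------------


def test_two_samples_embed_at_plus_minus_half_distance():
    dm = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]), "toy")
    ord_res = pcoa(dm)
    coords = sorted(ord_res.coordinates[:, 0])
    assert coords == pytest.approx([-1.5, 1.5])


def test_all_zero_matrix_gives_no_positive_axes():
    dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)), "toy")
    ord_res = pcoa(dm)
    assert ord_res.eigenvalues.size == 0
    assert ord_res.coordinates.shape == (3, 0)


def test_equilateral_triangle_embedding():
    d = np.ones((3, 3)) - np.eye(3)
    ord_res = pcoa(DistanceMatrix(("a", "b", "c"), d, "toy"))
    assert ord_res.eigenvalues.size == 2
    assert ord_res.eigenvalues[0] == pytest.approx(ord_res.eigenvalues[1])
    coords = ord_res.coordinates
    for i in range(3):
        for j in range(i + 1, 3):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0)


def test_euclidean_matrix_reconstructed_exactly():
    rng = np.random.default_rng(4)
    points = rng.normal(size=(6, 3))
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    dm = DistanceMatrix(tuple(f"s{i}" for i in range(6)), d, "euclidean")
    coords = pcoa(dm).coordinates
    recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    assert np.allclose(recon, d, atol=1e-8)


def test_matches_skbio_pcoa_eigenvalues():
    rng = np.random.default_rng(8)
    points = rng.normal(size=(5, 4))
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    dm = DistanceMatrix(tuple(f"s{i}" for i in range(5)), d, "euclidean")
    mine = pcoa(dm)
    theirs = skbio_pcoa(SkbioDM(d, ids=list(dm.sample_ids)))
    ref = np.asarray(theirs.eigvals)
    ref = ref[ref > 1e-9]
    assert np.allclose(np.sort(mine.eigenvalues), np.sort(ref), atol=1e-8)


def test_truncation_warns_when_axes_exceed_rank():
    dm = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]), "toy")
    with pytest.warns(UserWarning, match="positive"):
        ord_res = pcoa(dm, n_axes=5)
    assert ord_res.coordinates.shape[1] == 1
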