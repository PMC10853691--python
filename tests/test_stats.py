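import itertools

import numpy as np
import pytest
import scipy.stats
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova

from fmtgraft.diversity import DistanceMatrix
from fmtgraft.profile_io import SampleRecord, ValidationError
from fmtgraft.stats import distance_from_baseline, permanova, permdisp, welch_t


def euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or tuple(f"s{i}" for i in range(len(points)))
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    return DistanceMatrix(tuple(ids), d, "euclidean")


def pseudo_f_oracle(d, labels):
    """Direct evaluation of the PERMANOVA pseudo-F from its definition."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (len(groups) - 1)) / (ss_within / (n - len(groups)))


class TestPermanova:
    def test_mirrored_groups_show_no_effect(self):
        pts = [[0, 0], [1, 0], [0, 1]]
        dm = euclidean_dm(pts + pts)
        res = permanova(dm, ["a", "a", "a", "b", "b", "b"], n_perm=499, seed=0)
        assert res.r_squared < 0.05
        assert res.p_value > 0.5

    def test_exhaustive_p_matches_enumeration(self):
        """Exhaustive p equals the tail probability over all 20 label splits."""
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 2))
        pts[:3] += 1.5
        dm = euclidean_dm(pts)
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova(dm, labels, n_perm="exhaustive")
        f_obs = pseudo_f_oracle(dm.values, labels)
        assert res.statistic == pytest.approx(f_obs)
        # enumerate the C(6,3)=20 distinct assignments independently
        f_all = []
        for combo in itertools.combinations(range(6), 3):
            lab = ["b"] * 6
            for i in combo:
                lab[i] = "a"
            f_all.append(pseudo_f_oracle(dm.values, lab))
        expected_p = np.mean([f >= f_obs - 1e-12 for f in f_all])
        assert res.p_value == pytest.approx(expected_p)

    def test_separated_clusters_reach_minimum_p(self):
        # groups of 10 so a random permutation essentially never recreates
        # the separating split (which would tie the observed F)
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.01, (10, 2)), rng.normal(50, 0.01, (10, 2))])
        dm = euclidean_dm(pts)
        res = permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=2)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_invariant_to_reordering_and_renaming(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        dm = euclidean_dm(pts)
        labels = ["x"] * 4 + ["y"] * 4
        base = permanova(dm, labels, n_perm=99, seed=5)
        perm = rng.permutation(8)
        ids = [dm.sample_ids[i] for i in perm]
        shuffled = dm.filter(ids)
        res2 = permanova(shuffled, {s: labels[dm.sample_ids.index(s)] for s in ids},
                         n_perm=99, seed=5)
        assert res2.statistic == pytest.approx(base.statistic)
        renamed = permanova(dm, ["g1" if l == "x" else "g2" for l in labels],
                            n_perm=99, seed=5)
        assert renamed.statistic == pytest.approx(base.statistic)

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        dm = euclidean_dm(rng.normal(size=(10, 2)))
        labels = ["a"] * 5 + ["b"] * 5
        p1 = permanova(dm, labels, n_perm=199, seed=11).p_value
        p2 = permanova(dm, labels, n_perm=199, seed=11).p_value
        assert p1 == p2

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(9, 3))
        pts[:4] += 0.8
        dm = euclidean_dm(pts)
        labels = ["a"] * 4 + ["b"] * 5
        mine = permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio_permanova(
            SkbioDM(dm.values, ids=list(dm.sample_ids)), list(labels), permutations=99
        )
        assert mine.statistic == pytest.approx(theirs["test statistic"])

    def test_single_group_rejected(self):
        dm = euclidean_dm(np.eye(3))
        with pytest.raises(ValidationError):
            permanova(dm, ["a", "a", "a"], n_perm=9, seed=0)

    def test_p_value_floor(self):
        # p >= 1/(n_perm+1) by construction
        rng = np.random.default_rng(8)
        dm = euclidean_dm(rng.normal(size=(6, 2)))
        res = permanova(dm, ["a"] * 3 + ["b"] * 3, n_perm=49, seed=1)
        assert res.p_value >= 1 / 50


class TestPermdisp:
    def test_identical_group_geometry_gives_null(self):
        # same within-group point configuration, far apart: the dispersion
        # multisets coincide, so between-group variance (and F) vanish
        shape = [[0, 0], [1, 0], [3, 0], [0, 2]]
        far = [[1000 + x, y] for x, y in shape]
        dm = euclidean_dm(shape + far)
        res = permdisp(dm, ["a"] * 4 + ["b"] * 4, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.5

    def test_tight_vs_diffuse_cluster_detected(self):
        rng = np.random.default_rng(2)
        tight = rng.normal(0, 0.01, size=(8, 2))
        diffuse = rng.normal(0, 5.0, size=(8, 2))
        dm = euclidean_dm(np.vstack([tight, diffuse]))
        res = permdisp(dm, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=3)
        assert res.p_value < 0.05

    def test_exhaustive_p_matches_enumeration(self):
        """Dispersion F tail probability over all label permutations."""
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        pts[3:] *= 3
        dm = euclidean_dm(pts)
        labels = ["a"] * 3 + ["b"] * 3
        res = permdisp(dm, labels, n_perm="exhaustive")

        def disp_f(lab):
            groups = sorted(set(lab))
            z = np.empty(len(lab))
            for g in groups:
                idx = [i for i, l in enumerate(lab) if l == g]
                centroid = pts[idx].mean(axis=0)
                z[idx] = np.linalg.norm(pts[idx] - centroid, axis=1)
            return scipy.stats.f_oneway(*[z[[i for i, l in enumerate(lab) if l == g]]
                                          for g in groups]).statistic

        # embedding of a Euclidean matrix is rigid-motion equivalent to pts,
        # so dispersions computed from pts are an independent oracle
        f_obs = disp_f(labels)
        assert res.statistic == pytest.approx(f_obs)
        f_all = [
            disp_f([labels[i] for i in perm])
            for perm in itertools.permutations(range(6))
        ]
        expected_p = np.mean([f >= f_obs - 1e-12 for f in f_all])
        assert res.p_value == pytest.approx(expected_p)

    def test_dispersions_reported_per_sample(self):
        dm = euclidean_dm([[0, 0], [2, 0], [0, 0], [4, 0]])
        res = permdisp(dm, ["a", "a", "b", "b"], n_perm=49, seed=0)
        assert res.dispersions is not None
        assert res.dispersions.loc["s0"] == pytest.approx(1.0)  # centroid at (1,0)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_detected(self):
        res = welch_t([1, 2, 3], [101, 102, 103])
        assert abs(res.t_statistic) > 50
        assert res.p_value < 1e-4

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 7)
        y = rng.normal(0.5, 2, 5)
        res = welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * scipy.stats.t.sf(abs(t), df)
        assert res.t_statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])


class TestDistanceFromBaseline:
    @staticmethod
    def records_for(animal, n_post=3):
        recs = [
            SampleRecord(f"{animal}_B0", animal, "recipient", "baseline", 0, 0),
            SampleRecord(f"{animal}_B1", animal, "recipient", "baseline", 1, 1),
        ]
        recs += [
            SampleRecord(f"{animal}_P{k}", animal, "recipient", "post_fmt", k, 1 + k)
            for k in range(1, n_post + 1)
        ]
        return recs

    def test_identical_samples_give_zero_series(self):
        ids = ("X_B0", "X_B1", "X_P1", "X_P2", "X_P3")
        dm = DistanceMatrix(ids, np.zeros((5, 5)), "toy")
        series = distance_from_baseline(dm, self.records_for("X"))
        assert list(series["X"]) == [0.0, 0.0, 0.0]

    def test_series_equal_direct_lookups(self):
        recs = self.records_for("X", n_post=2) + self.records_for("Y", n_post=2)
        ids = tuple(r.sample_id for r in recs)
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(len(ids), 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(ids, d, "toy")
        series = distance_from_baseline(dm, recs)
        # default anchor is the last baseline sample (timepoint 1 here)
        for animal in ("X", "Y"):
            for k in (1, 2):
                assert series[animal].loc[k] == pytest.approx(
                    dm[f"{animal}_P{k}", f"{animal}_B1"]
                )

    def test_first_baseline_anchor(self):
        recs = self.records_for("X", n_post=1)
        ids = tuple(r.sample_id for r in recs)
        d = np.array(
            [[0, 1, 2], [1, 0, 5], [2, 5, 0]], dtype=float
        )
        dm = DistanceMatrix(ids, d, "toy")
        series = distance_from_baseline(dm, recs, baseline="first")
        assert series["X"].loc[1] == pytest.approx(2.0)

    def test_animal_without_baseline_skipped_with_warning(self):
        recs = [
            SampleRecord("Z_P1", "Z", "recipient", "post_fmt", 1, 0),
            *self.records_for("X", n_post=1),
        ]
        ids = tuple(r.sample_id for r in recs)
        dm = DistanceMatrix(ids, np.ones((4, 4)) - np.eye(4), "toy")
        with pytest.warns(UserWarning, match="no baseline"):
            series = distance_from_baseline(dm, recs)
        assert "Z" not in series and "X" in series
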