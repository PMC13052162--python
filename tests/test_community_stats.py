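"""Richness, Jaccard, PCoA and permutation tests, cross-checked against scikit-bio."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import mantel as skbio_mantel

from edna_divide import community_stats as cs
from edna_divide.asv_filtering import ASVRecord, CommunityMatrix

from conftest import random_distance_frame


def presence_frame(rows, basins=None):
    arr = np.asarray(rows, dtype=bool)
    basins = basins or [f"b{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=basins,
                        columns=[f"a{j}" for j in range(arr.shape[1])])


class TestJaccard:
    @pytest.mark.parametrize("rows,expect", [
        ([[1, 1, 0], [1, 1, 0]], 0.0),            # identical sets
        ([[1, 1, 0, 0], [0, 0, 1, 1]], 1.0),      # disjoint sets
        ([[1, 1, 1, 0], [0, 1, 1, 1]], 0.5),      # {a,b,c} vs {b,c,d}
    ])
    def test_worked_examples(self, rows, expect):
        D = cs.jaccard(presence_frame(rows))
        assert D.iloc[0, 1] == pytest.approx(expect)

    def test_empty_pair_defined_as_zero(self):
        D = cs.jaccard(presence_frame([[0, 0], [0, 0]]))
        assert D.iloc[0, 1] == 0.0

    def test_triangle_inequality_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            D = cs.jaccard(presence_frame(rng.random((3, 12)) < 0.5)).to_numpy()
            assert D[0, 2] <= D[0, 1] + D[1, 2] + 1e-12


class TestPcoa:
    def test_recovers_right_triangle_embedding(self):
        D = pd.DataFrame([[0, 3, 5], [3, 0, 4], [5, 4, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        res = cs.pcoa(D)
        C = res.coordinates.to_numpy()
        rec = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, D.to_numpy(), atol=1e-8)

    def test_duplicate_points_coincide(self):
        D = pd.DataFrame([[0, 0, 2], [0, 0, 2], [2, 2, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        res = cs.pcoa(D)
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["b"])

    def test_euclidean_input_has_no_negative_axes(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            pts = rng.normal(size=(7, 3))
            D = pd.DataFrame(
                np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)),
                index=range(7), columns=range(7))
            res = cs.pcoa(D)
            if len(res.negative_eigenvalues):
                assert np.abs(res.negative_eigenvalues).max() < 1e-8
            C = res.coordinates.to_numpy()
            rec = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
            assert np.allclose(rec, D.to_numpy(), atol=1e-8)

    def test_all_zero_matrix_is_zero_dimensional(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        assert cs.pcoa(D).coordinates.shape[1] == 0


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        n = 6
        D = np.full((n, n), 10.0)
        D[:3, :3] = 1.0
        D[3:, 3:] = 1.0
        np.fill_diagonal(D, 0)
        Df = pd.DataFrame(D, index=list("abcdef"), columns=list("abcdef"))
        res = cs.anosim(Df, ["x"] * 3 + ["y"] * 3, 99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_brute_force_rank_computation(self):
        rng = np.random.default_rng(2)
        D = random_distance_frame(rng, 6)
        groups = ["x", "x", "x", "y", "y", "y"]
        res = cs.anosim(D, groups, 9, seed=0)
        iu, ju = np.triu_indices(6, k=1)
        ranks = stats.rankdata(D.to_numpy()[iu, ju])
        within = np.array([groups[i] == groups[j] for i, j in zip(iu, ju)])
        expect = (ranks[~within].mean() - ranks[within].mean()) / (len(ranks) / 2)
        assert res.statistic == pytest.approx(expect, abs=1e-12)

    def test_statistic_agrees_with_skbio(self):
        rng = np.random.default_rng(3)
        M = random_distance_frame(rng, 8).to_numpy()
        labels = list("abcdefgh")
        groups = ["x"] * 4 + ["y"] * 4
        mine = cs.anosim(pd.DataFrame(M, index=labels, columns=labels),
                         dict(zip(labels, groups)), 99, seed=0)
        theirs = skbio_anosim(SkbioDM(M, labels),
                              pd.DataFrame({"g": groups}, index=labels),
                              column="g", permutations=0)
        assert mine.statistic == pytest.approx(theirs["test statistic"])

    def test_r_bounded_and_p_convention(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            D = random_distance_frame(rng, 8)
            res = cs.anosim(D, ["x"] * 4 + ["y"] * 4, 99, seed=seed)
            assert -1 <= res.statistic <= 1
            assert 0 < res.p_value <= 1
            assert round(res.p_value * 100) == res.p_value * 100  # k+1 over 100

    def test_degenerate_grouping_rejected(self):
        D = random_distance_frame(np.random.default_rng(0), 4)
        with pytest.raises(ValueError):
            cs.anosim(D, ["x", "x", "x", "x"], 99)
        with pytest.raises(ValueError):
            cs.anosim(D, ["x", "x", "x", "y"], 99)


class TestMantel:
    def test_self_correlation_is_exactly_one(self):
        D = random_distance_frame(np.random.default_rng(5), 6)
        assert cs.mantel(D, D, 99, seed=0).statistic == pytest.approx(1.0)

    def test_invariant_to_positive_affine_transform(self):
        D = random_distance_frame(np.random.default_rng(6), 6)
        D2 = 3.0 * D + 1.0
        for f in (D2,):
            f.values[np.diag_indices(6)] = 0
        assert cs.mantel(D, D2, 99, seed=0).statistic == pytest.approx(1.0)

    def test_statistic_agrees_with_skbio(self):
        rng = np.random.default_rng(7)
        labels = list("abcdefgh")
        D1 = random_distance_frame(rng, 8, labels=labels)
        D2 = random_distance_frame(rng, 8, labels=labels)
        mine = cs.mantel(D1, D2, 99, seed=0).statistic
        r, _, _ = skbio_mantel(SkbioDM(D1.to_numpy(), labels),
                               SkbioDM(D2.to_numpy(), labels),
                               method="pearson", permutations=0)
        assert mine == pytest.approx(r)

    def test_zero_variance_rejected(self):
        labels = list("abcd")
        D1 = random_distance_frame(np.random.default_rng(8), 4, labels=labels)
        flat = pd.DataFrame(1.0, index=labels, columns=labels)
        flat.values[np.diag_indices(4)] = 0  # constant off-diagonal
        with pytest.raises(ValueError, match="variance"):
            cs.mantel(D1, flat, 99)


class TestRichness:
    def make(self, west, east):
        rows = []
        for v in west + east:
            rows.append([1] * v + [0] * (max(west + east) - v))
        # give each basin its own distinct ASVs so richness equals the vector
        n = len(rows)
        width = max(west + east)
        P = np.zeros((n, n * width), dtype=bool)
        for i, v in enumerate(west + east):
            P[i, i * width:i * width + v] = True
        basins = [f"b{i}" for i in range(n)]
        side = pd.Series(["w"] * len(west) + ["e"] * len(east), index=basins)
        return pd.DataFrame(P, index=basins), side

    def test_identical_sides_give_p_one(self):
        P, side = self.make([2, 3, 4], [2, 3, 4])
        assert cs.richness_by_side(P, side).p_value == pytest.approx(1.0)

    def test_fully_separated_small_sides_exact_p(self):
        P, side = self.make([1, 2, 3], [10, 11, 12])
        res = cs.richness_by_side(P, side)
        assert res.p_value == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_statistic_equals_brute_force_u_count(self):
        rng = np.random.default_rng(9)
        west = list(rng.integers(1, 20, 5))
        east = list(rng.integers(1, 20, 6))
        P, side = self.make(west, east)
        res = cs.richness_by_side(P, side)
        x, y = sorted(("e", "w"))
        a = [v for v, s in zip(west + east, side) if s == x]
        b = [v for v, s in zip(west + east, side) if s == y]
        u = sum((1.0 if i > j else 0.5 if i == j else 0.0) for i in a for j in b)
        assert res.statistic == pytest.approx(u)

    def test_one_empty_side_rejected(self):
        P, side = self.make([1, 2], [3])
        side[:] = "w"
        with pytest.raises(ValueError):
            cs.richness_by_side(P, side)


class TestTaxonCollapse:
    def test_highest_assigned_taxon_rules(self):
        deep = ASVRecord("a", "A", taxon_path=("Actinopterygii", "o", "f", "g", "sp1"))
        fam = ASVRecord("b", "A", taxon_path=("Actinopterygii", "o", "f", "", ""))
        shallow = ASVRecord("c", "A", taxon_path=("Actinopterygii", "o", "", "", ""))
        assert cs.highest_assigned_taxon(deep) == "sp1"
        assert cs.highest_assigned_taxon(fam) == "f"
        assert cs.highest_assigned_taxon(shallow) is None

    def test_taxon_presence_merges_asvs_of_one_taxon(self):
        P = presence_frame([[1, 0], [0, 1]])
        comm = CommunityMatrix(presence=P,
                               side_of_divide=pd.Series("w", index=P.index))
        recs = [
            ASVRecord("a0", "A", taxon_path=("Actinopterygii", "o", "f", "g", "sp")),
            ASVRecord("a1", "A", taxon_path=("Actinopterygii", "o", "f", "g", "sp")),
        ]
        tp = cs.taxon_presence(comm, recs)
        assert list(tp.columns) == ["sp"]
        assert tp["sp"].all()
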