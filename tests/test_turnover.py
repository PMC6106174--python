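import math

import numpy as np
import pytest

from betadrift.traits import DistanceMatrix
from betadrift.turnover import (CommunityPair, beta_rao_pair,
                                beta_sim, community_pair, delta, mfd_pair,
                                neighborhood_turnover, nfn_pair)
from conftest import make_atlas, random_distance_matrix


def brute_beta_rao(c1, c2, d, jost=True, proportional=False):
    """Double-loop pooled/within Rao decomposition, independent of the
    vectorized implementation."""
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    if c1.sum() == 0 or c2.sum() == 0:
        return float("nan")
    p1 = c1 / c1.sum()
    p2 = c2 / c2.sum()
    pool = (p1 + p2) / 2.0
    n = len(c1)

    def q(p):
        return sum(p[i] * p[j] * d[i, j] for i in range(n) for j in range(n))

    qa = (q(p1) + q(p2)) / 2.0
    qg = q(pool)
    if jost:
        qa = 1.0 / (1.0 - qa)
        qg = 1.0 / (1.0 - qg)
    return (qg - qa) / qg if proportional else qg - qa


class TestBetaSim:
    def test_identical_and_nested_give_zero(self):
        assert beta_sim(CommunityPair(3, 0, 0)) == 0.0
        assert beta_sim(CommunityPair(2, 5, 0)) == 0.0

    def test_printed_formula(self):
        assert beta_sim(CommunityPair(2, 1, 1)) == pytest.approx(1.0 / 3.0)

    def test_empty_community_is_nan(self):
        assert math.isnan(beta_sim(CommunityPair(0, 3, 0)))

    def test_set_arithmetic_oracle_500_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(500):
            n = int(rng.integers(1, 40))
            f = rng.integers(0, 2, n).astype(bool)
            g = rng.integers(0, 2, n).astype(bool)
            fs = set(np.flatnonzero(f))
            gs = set(np.flatnonzero(g))
            a = len(fs & gs)
            b = len(gs - fs)
            c = len(fs - gs)
            if a + b + c == 0:
                continue
            got = beta_sim(community_pair(f, g))
            if a == 0 and min(b, c) == 0:
                assert math.isnan(got)
            else:
                assert got == min(b, c) / (min(b, c) + a)

    def test_adding_shared_species_strictly_decreases(self):
        for a, b, c in [(1, 2, 3), (4, 1, 1), (2, 5, 2)]:
            assert beta_sim(CommunityPair(a + 1, b, c)) < \
                beta_sim(CommunityPair(a, b, c))


class TestBetaRao:
    def test_identical_communities_zero(self):
        dm = random_distance_matrix(np.random.default_rng(0), 5)
        c = np.array([1, 0, 1, 1, 0])
        assert beta_rao_pair(c, c, dm) == pytest.approx(0.0, abs=1e-15)

    def test_two_singletons_raw_additive(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 0.4], [0.4, 0]]))
        got = beta_rao_pair([1, 0], [0, 1], dm, jost=False)
        assert got == pytest.approx(0.2)

    def test_symmetric_in_communities(self):
        rng = np.random.default_rng(2)
        dm = random_distance_matrix(rng, 7)
        c1 = rng.integers(0, 2, 7)
        c2 = rng.integers(0, 2, 7)
        c1[0] = c2[1] = 1
        assert beta_rao_pair(c1, c2, dm) == pytest.approx(
            beta_rao_pair(c2, c1, dm), abs=1e-15)

    @pytest.mark.parametrize("jost,proportional", [(True, False), (False, False),
                                                   (True, True)])
    def test_matches_double_loop_oracle(self, jost, proportional):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 10))
            dm = random_distance_matrix(rng, n)
            c1 = rng.integers(0, 2, n)
            c2 = rng.integers(0, 2, n)
            if c1.sum() == 0:
                c1[0] = 1
            if c2.sum() == 0:
                c2[-1] = 1
            got = beta_rao_pair(c1, c2, dm, jost=jost,
                                proportional=proportional)
            want = brute_beta_rao(c1, c2, dm.d, jost=jost,
                                  proportional=proportional)
            assert got == pytest.approx(want, abs=1e-12)


class TestNfnMfd:
    def test_identical_singletons_zero(self):
        dm = random_distance_matrix(np.random.default_rng(0), 3)
        c = np.array([1, 0, 0])
        assert nfn_pair(c, c, dm) == 0.0
        assert mfd_pair(c, c, dm) == 0.0

    def test_single_pair_case(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 0.4], [0.4, 0]]))
        assert nfn_pair([1, 0], [0, 1], dm) == pytest.approx(0.4)
        assert mfd_pair([1, 0], [0, 1], dm) == pytest.approx(0.4)

    def test_mean_at_least_nearest_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            dm = random_distance_matrix(rng, n)
            c1 = rng.integers(0, 2, n)
            c2 = rng.integers(0, 2, n)
            if c1.sum() == 0 or c2.sum() == 0:
                continue
            assert mfd_pair(c1, c2, dm) >= nfn_pair(c1, c2, dm) - 1e-12

    def test_brute_force_cross_pair_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            dm = random_distance_matrix(rng, n)
            c1 = rng.integers(0, 2, n)
            c2 = rng.integers(0, 2, n)
            i = [k for k in range(n) if c1[k]]
            j = [k for k in range(n) if c2[k]]
            if not i or not j:
                continue
            mfd_want = np.mean([dm.d[a, b] for a in i for b in j])
            nfn_want = (np.mean([min(dm.d[a, b] for b in j) for a in i])
                        + np.mean([min(dm.d[a, b] for a in i) for b in j])) / 2
            assert mfd_pair(c1, c2, dm) == pytest.approx(mfd_want, abs=1e-12)
            assert nfn_pair(c1, c2, dm) == pytest.approx(nfn_want, abs=1e-12)


class TestNeighborhoodTurnover:
    def test_constant_atlas_turnover_vanishes(self):
        # identical communities everywhere: replacement-type measures are 0;
        # MFD (mean cross-pair distance) equals the constant within-community
        # mean pairwise distance rather than 0, by construction
        presence = np.tile(np.array([1, 0, 1, 1, 0], dtype=np.uint8), (16, 1))
        atlas = make_atlas(presence)
        dm = random_distance_matrix(np.random.default_rng(0), 5)
        for measure in ("sim", "rao", "nfn"):
            field = neighborhood_turnover(atlas, dm, measure)
            np.testing.assert_allclose(field.values, 0.0, atol=1e-14)
        idx = np.array([0, 2, 3])
        within = dm.d[np.ix_(idx, idx)].mean()
        mfd = neighborhood_turnover(atlas, dm, "mfd")
        np.testing.assert_allclose(mfd.values, within, atol=1e-12)

    def test_checkerboard_of_disjoint_communities(self):
        # alternate cells host two disjoint equal-richness communities
        presence = np.zeros((16, 4), dtype=np.uint8)
        for idx in range(16):
            r, c = divmod(idx, 4)
            if (r + c) % 2 == 0:
                presence[idx, :2] = 1
            else:
                presence[idx, 2:] = 1
        atlas = make_atlas(presence)
        field = neighborhood_turnover(atlas, None, "sim")
        # diagonal neighbors share the community; orthogonal ones are disjoint
        assert np.nanmax(field.values) <= 1.0
        interior = field.values[5]  # has 8 neighbors, 4 disjoint + 4 identical
        assert interior == pytest.approx(0.5)

    def test_mean_over_available_neighbors(self):
        # 2x2 grid: every cell has 3 Moore neighbors.  Focal {s0,s1} against
        # identical, half-shared and disjoint neighbors -> mean(0, 0.5, 1).
        presence = np.array([[1, 1, 0, 0],   # focal
                             [1, 1, 0, 0],   # identical -> 0
                             [0, 0, 1, 1],   # disjoint -> 1
                             [1, 0, 1, 0]],  # a=1,b=1,c=1 -> 0.5
                            dtype=np.uint8)
        atlas = make_atlas(presence)
        field = neighborhood_turnover(atlas, None, "sim")
        assert field.values[0] == pytest.approx(0.5)

    def test_empty_neighbor_pairs_dropped(self):
        presence = np.ones((9, 3), dtype=np.uint8)
        presence[0] = 0  # empty corner community
        atlas = make_atlas(presence)
        field = neighborhood_turnover(atlas, None, "sim")
        assert math.isnan(field.values[0])  # all its pairs are empty-sided
        assert field.values[4] == 0.0       # center ignores the empty pair


class TestDelta:
    def test_subtraction_and_sign_convention(self):
        atlas = make_atlas(np.ones((9, 2)))
        t1 = neighborhood_turnover(atlas, None, "sim")
        t1.values = np.full(9, 0.6)
        t2 = neighborhood_turnover(atlas, None, "sim")
        t2.values = np.full(9, 0.4)
        d = delta(t1, t2)
        np.testing.assert_allclose(d.delta, -0.2)  # negative = homogenization

    def test_identical_fields_zero_and_nan_propagates(self):
        atlas = make_atlas(np.ones((9, 2)))
        t1 = neighborhood_turnover(atlas, None, "sim")
        t2 = neighborhood_turnover(atlas, None, "sim")
        t1.values = t1.values.copy()
        t1.values[0] = np.nan
        d = delta(t1, t2)
        assert math.isnan(d.delta[0])
        np.testing.assert_allclose(d.delta[1:], 0.0)

    def test_measure_mismatch_rejected(self):
        atlas = make_atlas(np.ones((9, 2)))
        t1 = neighborhood_turnover(atlas, None, "sim")
        t2 = neighborhood_turnover(atlas, random_distance_matrix(
            np.random.default_rng(0), 2), "mfd")
        with pytest.raises(ValueError, match="different measures"):
            delta(t1, t2)
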