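"""Alignment scoring, the affine-gap DP against brute force, distances."""

from itertools import combinations

import numpy as np
import pytest

from helpers import onehot_record, oracle_align_score, random_record
from padist.align import (
    AlignmentParams,
    SCORE_FLOOR,
    distance_matrix,
    global_align,
    normalized_to_distance,
    pair_score,
    score_matrix,
    sd_distance,
    self_score,
)
from padist.profile import FeatureProfile, build_profile
from padist.records import ConsistencyError, PadistError


class TestParams:
    def test_positive_gap_rejected(self):
        with pytest.raises(PadistError):
            AlignmentParams(gap_open=0.5)

    def test_extend_cannot_exceed_open(self):
        with pytest.raises(PadistError):
            AlignmentParams(gap_open=-0.5, gap_extend=-1.0)

    def test_weights_outside_range_warn(self):
        with pytest.warns(UserWarning, match="omega1"):
            AlignmentParams(omega1=3.0)


class TestPairScore:
    def test_identical_onehot_sites_with_bonuses(self, rng):
        rec = onehot_record(rng, 5)
        prof = build_profile(rec)
        params = AlignmentParams(omega1=1.5, omega2=1.5)
        # dot product of a site with itself is 2 (two one-hot unit blocks)
        assert pair_score(prof, 2, prof, 2, params) == pytest.approx(5.0)

    def test_orthogonal_sites_score_zero(self):
        vec_a = np.zeros((2, 640))
        vec_a[:, 0] = vec_a[:, 400] = 1.0
        vec_b = np.zeros((2, 640))
        vec_b[:, 21] = vec_b[:, 421] = 1.0
        pa = FeatureProfile("a", vec_a, "HH", "BB")
        pb = FeatureProfile("b", vec_b, "CC", "EE")
        assert pair_score(pa, 0, pb, 0, AlignmentParams()) == 0.0

    def test_uniform_sites_closed_form(self, rng):
        probs = np.full((2, 20), 0.05)
        from helpers import make_record

        rec = make_record("u", [0, 0], probs, "HH", "BB")
        prof = build_profile(rec)
        params = AlignmentParams(omega1=1.0, omega2=1.0)
        # 400 * 0.0025^2 + 20 * 0.05^2 = 0.0525; same SS and acc add 2
        assert pair_score(prof, 0, prof, 0, params) == pytest.approx(2.0525)

    def test_bounded_by_two_plus_weights(self, rng):
        params = AlignmentParams()
        pa = build_profile(random_record(rng, 10, "a"))
        pb = build_profile(random_record(rng, 10, "b"))
        S = score_matrix(pa, pb, params)
        assert np.all(S >= 0)
        assert np.all(S <= 2 + params.omega1 + params.omega2 + 1e-9)

    def test_out_of_range_index(self, rng):
        prof = build_profile(random_record(rng, 5))
        with pytest.raises(IndexError):
            pair_score(prof, 5, prof, 0, AlignmentParams())


class TestGlobalAlign:
    def test_self_alignment_is_the_diagonal(self, rng):
        prof = build_profile(random_record(rng, 12))
        params = AlignmentParams()
        res = global_align(prof, prof, params)
        assert res.aligned_pairs == [(i, i) for i in range(12)]
        assert res.score == pytest.approx(self_score(prof, params))
        assert res.gaps == []

    def test_hand_enumerated_one_vs_two(self):
        # site A1 scores 5 against B2 and 0 against B1; with d=-1 the
        # optimal alignment gaps B1 and matches (A1, B2): 5 - 1 = 4.
        e0 = np.zeros(640)
        e0[0] = 1.0
        va = np.sqrt(5.0) * e0[None, :]
        vb = np.vstack([np.roll(e0, 7), np.sqrt(5.0) * e0])
        pa = FeatureProfile("a", va, "H", "B")
        pb = FeatureProfile("b", vb, "CC", "EE")
        res = global_align(pa, pb, AlignmentParams(gap_open=-1.0,
                                                   gap_extend=-0.2))
        assert res.score == pytest.approx(4.0)
        assert res.aligned_pairs == [(0, 1)]
        assert res.gaps == [("B", 0, 1)]

    @pytest.mark.parametrize("d,e", [(-1.0, -0.2), (-0.5, -0.5), (-2.0, -0.1)])
    def test_dp_equals_enumeration_on_small_profiles(self, rng, d, e):
        params = AlignmentParams(gap_open=d, gap_extend=e)
        profs = [
            build_profile(onehot_record(rng, L, f"o{L}{k}"))
            for L in (2, 3, 4)
            for k in range(2)
        ] + [build_profile(random_record(rng, 3, "rr"))]
        for pa, pb in combinations(profs, 2):
            S = score_matrix(pa, pb, params)
            expected = oracle_align_score(S, d, e)
            assert global_align(pa, pb, params).score == pytest.approx(
                expected, abs=1e-9
            )

    def test_aligned_pairs_strictly_increasing_and_score_consistent(self, rng):
        from helpers import gap_cost

        params = AlignmentParams()
        pa = build_profile(random_record(rng, 9, "a"))
        pb = build_profile(random_record(rng, 14, "b"))
        res = global_align(pa, pb, params)
        S = score_matrix(pa, pb, params)
        iis = [p[0] for p in res.aligned_pairs]
        jjs = [p[1] for p in res.aligned_pairs]
        assert iis == sorted(set(iis)) and jjs == sorted(set(jjs))
        # reconstruct the score from the reported path
        s = sum(S[i, j] for i, j in res.aligned_pairs)
        pa_i = pb_j = -1
        d, e = params.gap_open, params.gap_extend
        for i, j in res.aligned_pairs:
            s += gap_cost(i - pa_i - 1, d, e) + gap_cost(j - pb_j - 1, d, e)
            pa_i, pb_j = i, j
        s += gap_cost(len(pa) - 1 - pa_i, d, e)
        s += gap_cost(len(pb) - 1 - pb_j, d, e)
        assert res.score == pytest.approx(s, abs=1e-9)


class TestDistance:
    @pytest.mark.parametrize(
        "norm,expected", [(1.0, 0.0), (0.25, 0.5), (SCORE_FLOOR, 49.5)]
    )
    def test_distance_map_spot_values(self, norm, expected):
        assert normalized_to_distance(norm) == pytest.approx(expected)

    def test_identical_profiles_distance_zero(self, rng):
        prof = build_profile(random_record(rng, 20))
        res = sd_distance(prof, prof, AlignmentParams())
        assert res.normalized_score == 1.0
        assert res.distance == 0.0

    def test_symmetric(self, rng):
        pa = build_profile(random_record(rng, 10, "a"))
        pb = build_profile(random_record(rng, 15, "b"))
        params = AlignmentParams()
        assert sd_distance(pa, pb, params).distance == pytest.approx(
            sd_distance(pb, pa, params).distance, abs=1e-12
        )

    def test_unalignable_profiles_saturate_at_cap(self):
        vec_a = np.zeros((3, 640))
        vec_a[:, 0] = vec_a[:, 400] = 1.0
        vec_b = np.zeros((3, 640))
        vec_b[:, 25] = vec_b[:, 425] = 1.0
        pa = FeatureProfile("a", vec_a, "HHH", "BBB")
        pb = FeatureProfile("b", vec_b, "CCC", "EEE")
        res = sd_distance(pa, pb, AlignmentParams())
        assert res.normalized_score == SCORE_FLOOR
        assert res.distance == pytest.approx(49.5)

    def test_distance_bounds(self, rng):
        params = AlignmentParams()
        for _ in range(5):
            pa = build_profile(random_record(rng, 8, "a"))
            pb = build_profile(random_record(rng, 11, "b"))
            dist = sd_distance(pa, pb, params).distance
            assert 0.0 <= dist <= 49.5


class TestDistanceMatrix:
    def test_two_identical_records_give_zero_matrix(self, rng):
        rec = random_record(rng, 15, "a")
        rec2 = random_record(np.random.default_rng(20240917), 15, "b")
        dm = distance_matrix([rec, rec2])
        np.testing.assert_array_equal(dm.values, np.zeros((2, 2)))

    def test_duplicate_ids_rejected(self, rng):
        recs = [random_record(rng, 10, "same"), random_record(rng, 10, "same")]
        with pytest.raises(ConsistencyError, match="duplicate"):
            distance_matrix(recs)

    def test_permutation_invariance(self, rng):
        recs = [random_record(rng, 10, f"r{i}") for i in range(4)]
        dm = distance_matrix(recs)
        perm = [2, 0, 3, 1]
        dm2 = distance_matrix([recs[i] for i in perm])
        np.testing.assert_allclose(
            dm2.values, dm.submatrix(dm2.ids).values, atol=1e-12
        )

    def test_distances_grow_with_substitution_load(self):
        # average distance from a common ancestor is non-decreasing in the
        # number of point substitutions applied (stochastic trend, fixed seed)
        from padist.simulate import _mutate, _pseudo_pssm
        from helpers import make_record

        rng = np.random.default_rng(5)
        L = 80
        ancestor = rng.integers(0, 20, L)
        ss = "H" * L
        acc = "B" * L
        base = make_record("anc", ancestor, _pseudo_pssm(ancestor, 4.0), ss, acc)
        params = AlignmentParams()
        base_prof = build_profile(base)
        means = []
        for rate in (0.05, 0.2, 0.4, 0.7):
            dists = []
            for rep in range(6):
                idx = _mutate(ancestor, rate, rng)
                rec = make_record(f"m{rate}{rep}", idx,
                                  _pseudo_pssm(idx, 4.0), ss, acc)
                dists.append(
                    sd_distance(base_prof, build_profile(rec), params).distance
                )
            means.append(np.mean(dists))
        assert all(a < b for a, b in zip(means, means[1:]))
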