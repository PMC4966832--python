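"""Anchor superposition and DTW distance: oracles, symmetry, invariances."""

import itertools

import numpy as np
import pytest

from cdrclust.similarity import (
    DegenerateGeometryError,
    build_anchor_frame,
    closest_partner_analysis,
    dtw_score,
    insertion_site_agreement,
    kabsch,
    pairwise_matrix,
    superpose_all,
    superpose_to_frame,
)
from cdrclust.synthetic import FamilySpec, generate_loop_family

from conftest import make_loop_from_coords, random_rigid_transform


def _random_loop(rng, length, source="RAND_A", sequence=None):
    loop = rng.normal(0, 3.0, (length, 4, 3))
    anchors = rng.normal(0, 5.0, (10, 4, 3))
    return make_loop_from_coords(loop, anchors, source=source, sequence=sequence)


def _brute_force_dtw(cost):
    """Enumerate every monotone boundary-matched path; return (total, path)."""
    n, m = cost.shape
    best = (np.inf, None)
    stack = [((0, 0), cost[0, 0], [(0, 0)])]
    while stack:
        (i, j), total, path = stack.pop()
        if (i, j) == (n - 1, m - 1):
            if total < best[0]:
                best = (total, path)
            continue
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                stack.append(((ni, nj), total + cost[ni, nj], path + [(ni, nj)]))
    return best


class TestSuperposition:
    def test_identity_transform_when_already_in_frame(self, three_family_loops):
        loops, _ = three_family_loops
        frame = build_anchor_frame([loops[0]], mode="first")
        moved, rmsd = superpose_to_frame(loops[0], frame)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(moved.loop_coords(), loops[0].loop_coords(), atol=1e-9)

    def test_known_rotation_recovered(self, three_family_loops):
        loops, _ = three_family_loops
        rng = np.random.default_rng(11)
        R, t = random_rigid_transform(rng)
        moved = loops[0].transformed(R, t)
        frame = build_anchor_frame([loops[0]], mode="first")
        back, rmsd = superpose_to_frame(moved, frame)
        assert rmsd < 1e-6
        assert np.allclose(back.loop_coords(), loops[0].loop_coords(), atol=1e-6)

    def test_single_loop_frame_is_its_own_anchors(self, three_family_loops):
        loops, _ = three_family_loops
        frame = build_anchor_frame([loops[0]], mode="medoid")
        assert np.allclose(frame.coords, loops[0].anchor_coords().reshape(40, 3))

    def test_frame_from_rigid_transforms_is_congruent(self, three_family_loops):
        loops, _ = three_family_loops
        rng = np.random.default_rng(5)
        copies = []
        for k in range(3):
            R, t = random_rigid_transform(rng)
            c = loops[0].transformed(R, t)
            c.source = f"CPY{k}_A"
            copies.append(c)
        frame = build_anchor_frame(copies, mode="medoid")
        for c in copies:
            _, rmsd = superpose_to_frame(c, frame)
            assert rmsd < 1e-6

    def test_mean_mode_is_coordinate_average(self, three_family_loops):
        loops, _ = three_family_loops
        a = loops[0].anchor_coords().reshape(40, 3)
        b = loops[1].anchor_coords().reshape(40, 3)
        frame = build_anchor_frame(loops[:2], mode="mean")
        assert np.allclose(frame.coords, (a + b) / 2)

    def test_collinear_anchors_raise(self):
        line = np.zeros((10, 4, 3))
        line[:, :, 0] = np.arange(40).reshape(10, 4)
        loop = make_loop_from_coords(np.random.default_rng(0).normal(size=(5, 4, 3)),
                                     line)
        with pytest.raises(DegenerateGeometryError):
            kabsch(loop.anchor_coords().reshape(40, 3), np.ones((40, 3)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_anchor_frame([], mode="medoid")


class TestDTW:
    def test_self_distance_zero_diagonal_path(self, three_family_loops):
        loops, _ = three_family_loops
        fitted, _, _ = superpose_all(loops[:2])
        r = dtw_score(fitted[0], fitted[0])
        assert r.score == 0.0
        assert r.pairs == [(i, i) for i in range(len(fitted[0]))]
        assert r.same_length_shortcut

    def test_equal_length_equals_plain_rmsd(self):
        rng = np.random.default_rng(3)
        anchors = rng.normal(0, 5.0, (10, 4, 3))
        a = make_loop_from_coords(rng.normal(0, 3, (7, 4, 3)), anchors, "AAAA_A")
        b = make_loop_from_coords(rng.normal(0, 3, (7, 4, 3)), anchors, "BBBB_A")
        r = dtw_score(a, b, check_frame=False)
        flat_a = a.loop_coords().reshape(-1, 3)
        flat_b = b.loop_coords().reshape(-1, 3)
        rmsd = np.sqrt(np.mean(np.sum((flat_a - flat_b) ** 2, axis=1)))
        assert r.score == pytest.approx(rmsd, abs=1e-12)

    @pytest.mark.parametrize("la,lb", [(3, 4), (4, 3), (5, 3), (4, 5), (5, 4)])
    def test_dp_matches_exhaustive_enumeration(self, la, lb):
        rng = np.random.default_rng(la * 10 + lb)
        anchors = rng.normal(0, 5.0, (10, 4, 3))
        a = make_loop_from_coords(rng.normal(0, 2, (la, 4, 3)), anchors, "ENUA_A")
        b = make_loop_from_coords(rng.normal(0, 2, (lb, 4, 3)), anchors, "ENUB_A")
        r = dtw_score(a, b, check_frame=False)
        diff = a.loop_coords()[:, None] - b.loop_coords()[None, :]
        cost = np.sum(diff ** 2, axis=(2, 3))
        total, path = _brute_force_dtw(cost)
        assert sum(cost[i, j] for i, j in r.pairs) == pytest.approx(total)
        assert r.score == pytest.approx(np.sqrt(total / (4 * len(path))), rel=1e-9)

    def test_path_invariants_random_lengths(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=25, deadline=None)
        @given(la=st.integers(2, 8), lb=st.integers(2, 8), seed=st.integers(0, 100))
        def check(la, lb, seed):
            rng = np.random.default_rng(seed)
            anchors = rng.normal(0, 5.0, (10, 4, 3))
            a = make_loop_from_coords(rng.normal(0, 2, (la, 4, 3)), anchors, "HYPA_A")
            b = make_loop_from_coords(rng.normal(0, 2, (lb, 4, 3)), anchors, "HYPB_A")
            r = dtw_score(a, b, check_frame=False)
            assert r.pairs[0] == (0, 0) and r.pairs[-1] == (la - 1, lb - 1)
            iis = [i for i, _ in r.pairs]
            jjs = [j for _, j in r.pairs]
            assert iis == sorted(iis) and jjs == sorted(jjs)
            assert set(iis) == set(range(la)) and set(jjs) == set(range(lb))
            assert r.score >= 0
            assert r.score == pytest.approx(
                dtw_score(b, a, check_frame=False).score, abs=1e-9)

        check()

    def test_path_invariants(self):
        rng = np.random.default_rng(8)
        anchors = rng.normal(0, 5.0, (10, 4, 3))
        a = make_loop_from_coords(rng.normal(0, 2, (9, 4, 3)), anchors, "PTHA_A")
        b = make_loop_from_coords(rng.normal(0, 2, (12, 4, 3)), anchors, "PTHB_A")
        r = dtw_score(a, b, check_frame=False)
        assert r.pairs[0] == (0, 0) and r.pairs[-1] == (8, 11)
        iis = [i for i, _ in r.pairs]
        jjs = [j for _, j in r.pairs]
        assert iis == sorted(iis) and jjs == sorted(jjs)
        assert set(iis) == set(range(9)) and set(jjs) == set(range(12))
        assert r.score >= 0

    def test_symmetry(self, three_family_loops):
        loops, _ = three_family_loops
        fitted, _, _ = superpose_all(loops)
        rng = np.random.default_rng(0)
        for _ in range(10):
            i, j = rng.integers(0, len(fitted), 2)
            assert dtw_score(fitted[i], fitted[j]).score == pytest.approx(
                dtw_score(fitted[j], fitted[i]).score, abs=1e-9)

    def test_frame_mismatch_rejected(self, three_family_loops):
        loops, _ = three_family_loops
        fitted, _, _ = superpose_all(loops[:3])
        with pytest.raises(ValueError, match="frame"):
            dtw_score(fitted[0], loops[1])

    def test_frame_invariance_under_rigid_pretransforms(self, three_family_loops):
        loops, _ = three_family_loops
        subset = loops[:6]
        fitted, _, _ = superpose_all(subset)
        reference = pairwise_matrix(fitted).values
        rng = np.random.default_rng(21)
        jumbled = []
        for lp in subset:
            R, t = random_rigid_transform(rng)
            jumbled.append(lp.transformed(R, t))
        fitted2, _, _ = superpose_all(jumbled)
        moved = pairwise_matrix(fitted2).values
        assert np.allclose(moved, reference, atol=1e-6)

    def test_score_grows_with_noise(self):
        spec = FamilySpec(base_length=9, n_members=1, coordinate_noise_sd=0.0, seed=0)
        base, _ = generate_loop_family(spec)
        rng = np.random.default_rng(9)
        means = []
        for sd in (0.1, 0.3, 1.0):
            scores = []
            for _ in range(10):
                noisy = base[0].copy()
                for res in noisy.loop_residues:
                    res.backbone_atoms = res.backbone_atoms + rng.normal(0, sd, (4, 3))
                scores.append(dtw_score(base[0], noisy, check_frame=False).score)
            means.append(np.mean(scores))
        assert means[0] < means[1] < means[2]


class TestPairwiseMatrix:
    def test_two_identical_loops(self, three_family_loops):
        loops, _ = three_family_loops
        twin = loops[0].copy()
        twin.source = "TWIN_A"
        fitted, _, _ = superpose_all([loops[0], twin])
        m = pairwise_matrix(fitted)
        assert np.allclose(m.values, 0.0, atol=1e-6)

    def test_matches_independent_dtw_calls(self, three_family_loops):
        loops, _ = three_family_loops
        fitted, _, _ = superpose_all(loops[:5])
        m = pairwise_matrix(fitted)
        for i in range(5):
            for j in range(i + 1, 5):
                assert m.values[i, j] == pytest.approx(
                    dtw_score(fitted[i], fitted[j]).score)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_permutation_equivariance(self, three_family_loops):
        loops, _ = three_family_loops
        fitted, _, _ = superpose_all(loops[:5])
        m = pairwise_matrix(fitted)
        perm = [3, 1, 4, 0, 2]
        m2 = pairwise_matrix([fitted[i] for i in perm])
        assert np.allclose(m2.values, m.values[np.ix_(perm, perm)])


class TestClosestPartner:
    def test_same_length_set_has_zero_fraction(self):
        rng = np.random.default_rng(2)
        anchors = rng.normal(0, 5.0, (10, 4, 3))
        loops = [make_loop_from_coords(rng.normal(0, 3, (7, 4, 3)), anchors,
                                       f"SEQ{i}_A", sequence="ACDEFGH"[:7][::1])
                 for i in range(3)]
        for i, lp in enumerate(loops):  # make sequences distinct
            lp.loop_residues[0].amino_acid = "ACD"[i]
        m = pairwise_matrix(loops, check_frame=False)
        seqs = {lp.source: lp.sequence for lp in loops}
        summary = closest_partner_analysis(m, seqs)
        assert summary.n_unique_sequences == 3
        assert summary.fraction_different_length == 0.0

    def test_planted_cross_length_partner(self):
        spec13 = FamilySpec(base_length=13, n_members=3, coordinate_noise_sd=0.05,
                            motif="ASTDYGNSWLKPQ", seed=4)
        fam13, _ = generate_loop_family(spec13, family_index=0)
        # a 12-residue loop drawn from the same arc: closest partner must be
        # one of the length-13 loops, not the distant length-12 family
        spec12_same = FamilySpec(base_length=12, n_members=1,
                                 coordinate_noise_sd=0.05,
                                 motif="ASTDYGNSWLKP", seed=5,
                                 arc_height=5.0, arc_angle_deg=0.0)
        probe, _ = generate_loop_family(spec12_same, family_index=0)
        spec12_far = FamilySpec(base_length=12, n_members=3,
                                coordinate_noise_sd=0.05,
                                motif="GYTFTNYGMNWV", seed=6)
        far, _ = generate_loop_family(spec12_far, family_index=2)
        probe[0].source = "PRBE_A"
        loops = fam13 + probe + far
        fitted, _, _ = superpose_all(loops)
        m = pairwise_matrix(fitted)
        seqs = {lp.source: lp.sequence for lp in loops}
        summary = closest_partner_analysis(m, seqs)
        rec = [r for r in summary.records if "PRBE_A" in r.own_sources][0]
        assert rec.own_length == 12 and rec.partner_length == 13
        assert rec.different_length

    def test_two_singletons_are_mutual_partners(self):
        rng = np.random.default_rng(7)
        anchors = rng.normal(0, 5.0, (10, 4, 3))
        a = make_loop_from_coords(rng.normal(0, 3, (6, 4, 3)), anchors, "AONE_A",
                                  sequence="AAAAAA")
        b = make_loop_from_coords(rng.normal(0, 3, (6, 4, 3)), anchors, "BTWO_A",
                                  sequence="CCCCCC")
        m = pairwise_matrix([a, b], check_frame=False)
        summary = closest_partner_analysis(m, {"AONE_A": "AAAAAA", "BTWO_A": "CCCCCC"})
        partners = {r.sequence: r.partner_source for r in summary.records}
        assert partners == {"AAAAAA": "BTWO_A", "CCCCCC": "AONE_A"}

    def test_single_sequence_rejected(self):
        rng = np.random.default_rng(7)
        anchors = rng.normal(0, 5.0, (10, 4, 3))
        loops = [make_loop_from_coords(rng.normal(0, 3, (6, 4, 3)), anchors,
                                       f"ONE{i}_A", sequence="AAAAAA")
                 for i in range(2)]
        m = pairwise_matrix(loops, check_frame=False)
        with pytest.raises(ValueError):
            closest_partner_analysis(m, {lp.source: "AAAAAA" for lp in loops})


class TestInsertionSite:
    def test_equal_length_not_applicable(self, three_family_loops):
        loops, truth = three_family_loops
        same = [lp for lp in loops if len(lp) == 11][:2]
        fitted, _, _ = superpose_all(same)
        assert insertion_site_agreement(dtw_score(*fitted), [5]) is None

    def test_planted_duplication_found_at_site(self):
        spec = FamilySpec(base_length=11, n_members=4, coordinate_noise_sd=0.05,
                          length_variant_fraction=0.5, insertion_index=5, seed=12)
        loops, truth = generate_loop_family(spec)
        fitted, _, _ = superpose_all(loops)
        base = [lp for lp in fitted if truth.insertion_sites[lp.source] is None]
        longer = [lp for lp in fitted if truth.insertion_sites[lp.source] == 5]
        r = dtw_score(longer[0], base[0])
        assert insertion_site_agreement(r, [5]) == 0

    def test_declared_site_two_residues_off(self):
        spec = FamilySpec(base_length=11, n_members=4, coordinate_noise_sd=0.05,
                          length_variant_fraction=0.5, insertion_index=5, seed=12)
        loops, truth = generate_loop_family(spec)
        fitted, _, _ = superpose_all(loops)
        base = [lp for lp in fitted if truth.insertion_sites[lp.source] is None]
        longer = [lp for lp in fitted if truth.insertion_sites[lp.source] == 5]
        r = dtw_score(longer[0], base[0])
        offset = insertion_site_agreement(r, [8])  # mislabelled by 2-3
        assert offset is not None and offset >= 2
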