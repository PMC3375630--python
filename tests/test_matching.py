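import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketzd import matching as M
from pocketzd.structure import Pocket, SurfacePatch


def toy_patch(anchor, desc, weights=None):
    """Patch with fabricated descriptors; desc maps channel -> array."""
    n = 1
    p = SurfacePatch(
        anchor_atom=anchor, anchor_name=f"C{anchor}",
        point_indices=np.arange(n), points=np.zeros((n, 3)),
        normals=np.zeros((n, 3)),
    )
    p.descriptors = {ch: np.asarray(v, float) for ch, v in desc.items()}
    if weights is not None:
        p.weights = np.asarray(weights, float)
    return p


def toy_pocket(source_id, ligand, vectors, weights=None):
    """One patch per row of ``vectors``; all four channels share the row."""
    patches = [
        toy_patch(i, {ch: row for ch in M.CHANNELS}, weights)
        for i, row in enumerate(vectors)
    ]
    return Pocket(source_id=source_id, ligand_code=ligand, patches=patches)


class TestWeights:
    def test_symmetric_gives_uniform(self):
        w = M.weights_from_stats(np.ones(4), np.zeros(4))
        np.testing.assert_allclose(w.values, 0.25)

    def test_hand_computed_case(self):
        w = M.weights_from_stats(np.array([1.0, 1, 1, 1]),
                                 np.array([0.0, 0, 0, 0.5]))
        np.testing.assert_allclose(w.values, [2 / 7, 2 / 7, 2 / 7, 1 / 7])

    @given(
        st.lists(st.floats(min_value=0.01, max_value=10), min_size=4, max_size=4),
        st.lists(st.floats(min_value=0.0, max_value=10), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_always_sum_to_one(self, avg, std):
        w = M.weights_from_stats(np.array(avg), np.array(std))
        assert abs(w.values.sum() - 1.0) < 1e-9

    def test_degenerate_group_floored_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            w = M.weights_from_stats(np.array([0.0, 1, 1, 1]), np.zeros(4))
        assert w.values[0] > 0.99

    def test_single_patch_group_uniform_fallback(self):
        p = toy_patch(0, {ch: np.ones(4) for ch in M.CHANNELS})
        w = M.compute_weights([p])
        np.testing.assert_allclose(w.values, 0.25)

    def test_compute_weights_matches_direct_stats(self):
        rng = np.random.default_rng(0)
        group = [toy_patch(i, {ch: rng.random(6) for ch in M.CHANNELS})
                 for i in range(4)]
        w = M.compute_weights(group)
        avg, std = np.empty(4), np.empty(4)
        for t, ch in enumerate(M.CHANNELS):
            ds = []
            for a, b in itertools.combinations(group, 2):
                va = a.descriptors[ch] / np.linalg.norm(a.descriptors[ch])
                vb = b.descriptors[ch] / np.linalg.norm(b.descriptors[ch])
                ds.append(np.linalg.norm(va - vb))
            avg[t], std[t] = np.mean(ds), np.std(ds)
        np.testing.assert_allclose(
            w.values, M.weights_from_stats(avg, std).values)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            M.PatchWeights(values=np.array([0.5, 0.5, 0.5, 0.5]))


class TestPatchDistance:
    def test_identical_patches_zero(self):
        a = toy_patch(0, {ch: np.arange(1.0, 5) for ch in M.CHANNELS})
        assert M.patch_distance(a, a) == 0.0

    def test_shape_only_weights(self):
        a = toy_patch(0, {ch: np.array([1.0, 0]) for ch in M.CHANNELS})
        b = toy_patch(0, {ch: np.array([0.0, 1]) for ch in M.CHANNELS})
        d = M.patch_distance(a, b, weights=[1, 0, 0, 0])
        assert d == pytest.approx(np.sqrt(2))

    def test_hand_computed_weighted_sum(self):
        # channels already unit-length; shape L2 = sqrt(2), ele L2 = 2
        desc_a = {"shape": [1.0, 0], "ele": [1.0, 0],
                  "hyd": [1.0, 0], "conc": [1.0, 0]}
        desc_b = {"shape": [0.0, 1], "ele": [-1.0, 0],
                  "hyd": [1.0, 0], "conc": [0.0, 1]}
        a, b = toy_patch(0, desc_a), toy_patch(0, desc_b)
        d = M.patch_distance(a, b, weights=[0.5, 0.5, 0, 0])
        assert d == pytest.approx(0.5 * np.sqrt(2) + 0.5 * 2.0)

    def test_default_weights_from_db_patch(self):
        a = toy_patch(0, {ch: np.array([1.0, 0]) for ch in M.CHANNELS})
        b = toy_patch(0, {ch: np.array([0.0, 1]) for ch in M.CHANNELS},
                      weights=[1, 0, 0, 0])
        assert M.patch_distance(a, b) == pytest.approx(np.sqrt(2))

    def test_length_mismatch_rejected(self):
        a = toy_patch(0, {ch: np.ones(3) for ch in M.CHANNELS})
        b = toy_patch(0, {ch: np.ones(4) for ch in M.CHANNELS})
        with pytest.raises(ValueError, match="mismatch"):
            M.patch_distance(a, b, weights=[0.25] * 4)


def brute_force_assignment(cost, threshold=None):
    """Permutation-enumeration oracle: maximize pairs, then minimize cost."""
    nq, nt = cost.shape
    best = (0, 0.0, [])
    small, large = (nq, nt) if nq <= nt else (nt, nq)
    for combo in itertools.permutations(range(max(nq, nt)), min(nq, nt)):
        pairs = []
        for i, j in enumerate(combo):
            q, t = (i, j) if nq <= nt else (j, i)
            d = cost[q, t]
            if threshold is None or d <= threshold:
                pairs.append((q, t, d))
        key = (len(pairs), -sum(p[2] for p in pairs))
        if key > (best[0], -best[1]):
            best = (len(pairs), sum(p[2] for p in pairs), pairs)
    return best[0], best[1]


class TestMatching:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("shape", [(3, 3), (4, 6), (6, 5)])
    def test_equals_permutation_enumeration(self, seed, shape):
        rng = np.random.default_rng(seed)
        cost = rng.random(shape)
        got = M.match_cost_matrix(cost)
        n, total = brute_force_assignment(cost)
        assert got.n_pairs == n
        assert got.total_distance == pytest.approx(total)

    @pytest.mark.parametrize("seed", range(4))
    def test_thresholded_equals_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        cost = rng.random((5, 5))
        thr = 0.5
        got = M.match_cost_matrix(cost, threshold=thr)
        n, total = brute_force_assignment(cost, threshold=thr)
        assert got.n_pairs == n
        assert got.total_distance == pytest.approx(total)
        assert all(d <= thr for _, _, d in got.pairs)

    def test_threshold_below_minimum_empty(self):
        cost = np.full((3, 4), 0.9)
        got = M.match_cost_matrix(cost, threshold=0.1)
        assert got.n_pairs == 0
        assert got.unmatched_query == [0, 1, 2]
        assert got.unmatched_target == [0, 1, 2, 3]

    def test_infinite_threshold_equals_none(self):
        rng = np.random.default_rng(7)
        cost = rng.random((4, 5))
        a = M.match_cost_matrix(cost, threshold=None)
        b = M.match_cost_matrix(cost, threshold=np.inf)
        assert a.pairs == b.pairs

    def test_pair_count_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        cost = rng.random((5, 5))
        counts = [M.match_cost_matrix(cost, threshold=t).n_pairs
                  for t in np.linspace(0, 1.5, 12)]
        assert counts == sorted(counts)

    def test_pocket_vs_itself(self):
        rng = np.random.default_rng(1)
        pocket = toy_pocket("p", "LIG", rng.random((4, 6)),
                            weights=[0.25] * 4)
        m = M.match_patches(pocket, pocket)
        assert m.n_pairs == 4
        assert m.total_distance == pytest.approx(0.0)
        assert all(q == t for q, t, _ in m.pairs)

    def test_one_to_one(self):
        rng = np.random.default_rng(2)
        a = toy_pocket("a", "LIG", rng.random((5, 6)), weights=[0.25] * 4)
        b = toy_pocket("b", "LIG", rng.random((3, 6)), weights=[0.25] * 4)
        m = M.match_patches(a, b)
        assert len({q for q, _, _ in m.pairs}) == m.n_pairs
        assert len({t for _, t, _ in m.pairs}) == m.n_pairs
        assert m.n_pairs == 3  # smaller pocket fully matched


class TestPocketScore:
    def test_self_score_zero(self):
        rng = np.random.default_rng(3)
        p = toy_pocket("p", "LIG", rng.random((4, 6)), weights=[0.25] * 4)
        m = M.match_patches(p, p)
        assert M.pocket_score(m, p, p) == pytest.approx(0.0)

    def test_mean_distance_term(self):
        m = M.PatchMatching(pairs=[(0, 0, 0.1), (1, 1, 0.3)],
                            unmatched_query=[], unmatched_target=[])
        p = toy_pocket("p", "LIG", np.eye(2), weights=[0.25] * 4)
        s = M.pocket_score(m, p, p, term_weights=(1.0, 0.0, 0.0))
        assert s == pytest.approx(0.2)

    def test_unmatchable_patch_increases_score(self):
        rng = np.random.default_rng(4)
        base = rng.random((3, 6))
        target = toy_pocket("t", "LIG", base, weights=[0.25] * 4)
        q1 = toy_pocket("q1", "LIG", base)
        q2 = toy_pocket("q2", "LIG", np.vstack([base, -base[0]]))
        thr = 1e-6
        s1 = M.pocket_score(M.match_patches(q1, target, thr), q1, target,
                            threshold=thr)
        s2 = M.pocket_score(M.match_patches(q2, target, thr), q2, target,
                            threshold=thr)
        assert s2 > s1

    def test_empty_matching_ranks_last(self):
        rng = np.random.default_rng(5)
        a = toy_pocket("a", "LIG", rng.random((2, 6)))
        b = toy_pocket("b", "LIG", rng.random((2, 6)), weights=[0.25] * 4)
        empty = M.PatchMatching(pairs=[], unmatched_query=[0, 1],
                                unmatched_target=[0, 1])
        full = M.match_patches(a, b)
        assert M.pocket_score(empty, a, b, threshold=0.2) > M.pocket_score(
            full, a, b, threshold=0.2)


class TestSearchAndPredict:
    @pytest.fixture()
    def toy_db(self):
        from pocketzd.database import PocketDatabase

        rng = np.random.default_rng(6)
        entries = []
        for fam, code in enumerate(["AAA", "BBB"]):
            center = np.zeros(6)
            center[fam] = 5.0
            for m in range(3):
                vecs = center + 0.05 * rng.random((3, 6)) + 1.0
                entries.append(toy_pocket(f"{code.lower()}{m}", code, vecs,
                                          weights=[0.25] * 4))
        return PocketDatabase(entries=entries, metadata={})

    def test_query_in_db_ranks_first_with_zero(self, toy_db):
        q = toy_db.entries[2]
        res = M.search_database(q, toy_db)
        assert res.entries[0][0] == q.source_id
        assert res.entries[0][2] == pytest.approx(0.0)

    def test_family_separation(self, toy_db):
        q = toy_db.entries[0]  # AAA family
        res = M.search_database(q, toy_db)
        top3 = [code for _, code, _ in res.entries[:3]]
        assert top3 == ["AAA", "AAA", "AAA"]

    def test_shape_only_ignores_other_channels(self):
        from pocketzd.database import PocketDatabase

        rng = np.random.default_rng(7)
        shape_vec = rng.random(6)
        entries = []
        for code, ele_shift in [("AAA", 0.0), ("BBB", 3.0)]:
            p = toy_patch(0, {
                "shape": shape_vec, "conc": shape_vec,
                "ele": shape_vec + ele_shift, "hyd": shape_vec,
            }, weights=[0.25] * 4)
            entries.append(Pocket(source_id=code.lower(), ligand_code=code,
                                  patches=[p]))
        db = PocketDatabase(entries=entries, metadata={})
        q = entries[0]
        res = M.search_database(q, db, properties="shape")
        scores = [s for _, _, s in res.entries]
        assert scores[0] == pytest.approx(scores[1])
        res_all = M.search_database(q, db, properties="all")
        assert res_all.entries[0][1] == "AAA"
        assert res_all.entries[0][2] < res_all.entries[1][2]

    def test_empty_db_rejected(self):
        from pocketzd.database import PocketDatabase

        q = toy_pocket("q", "AAA", np.eye(2))
        with pytest.raises(ValueError, match="empty"):
            M.search_database(q, PocketDatabase(entries=[], metadata={}))

    def test_predict_hand_case(self):
        res = M.RetrievalResult(query_id="q", entries=[
            ("p1", "HEM", 0.1), ("p2", "ATP", 0.2), ("p3", "HEM", 0.3)])
        ranked = M.predict_ligand(res, k=3)
        assert ranked[0] == ("HEM", pytest.approx(1 + 1 / 3))
        assert ranked[1] == ("ATP", pytest.approx(0.5))

    def test_predict_k1_top_entry(self):
        res = M.RetrievalResult(query_id="q", entries=[
            ("p1", "ATP", 0.1), ("p2", "HEM", 0.2)])
        assert M.predict_ligand(res, k=1)[0][0] == "ATP"

    def test_predict_k_clamped_with_warning(self):
        res = M.RetrievalResult(query_id="q", entries=[("p1", "ATP", 0.1)])
        with pytest.warns(UserWarning, match="clamp"):
            ranked = M.predict_ligand(res, k=10)
        assert ranked[0][0] == "ATP"
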