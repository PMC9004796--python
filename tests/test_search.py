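"""Candidate pools, the stochastic search, and the Legacy baseline."""

from itertools import permutations

import numpy as np
import pytest

from resetlib import (
    CandidateSet,
    SearchConfig,
    TStatTable,
    build_candidate_set,
    cell_type_centroids,
    finalize_library,
    legacy_library,
    loo_dsc_contributions,
    modified_dsc,
    one_vs_rest_tstats,
    reset_search,
    sample_library,
    synth_reference,
    update_probabilities,
)
from resetlib.exceptions import InsufficientPoolError, NumericError, ValidationError

from conftest import make_matrix


def tstat_oracle(x1, x2):
    n1, n2 = len(x1), len(x2)
    sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / (n1 + n2 - 2)
    return (np.mean(x1) - np.mean(x2)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestTStats:
    def test_matches_textbook_formula(self):
        m, ann = make_matrix(200, {"a": 5, "b": 6, "c": 4}, seed=0)
        t = one_vs_rest_tstats(m, ann)
        lab = dict(zip(ann.sample_ids, ann.labels))
        for k, ct in enumerate(t.cell_types):
            in_k = np.array([lab[s] == ct for s in m.sample_ids])
            for j in (0, 17, 199):
                expected = tstat_oracle(m.values[j, in_k], m.values[j, ~in_k])
                assert t.tstat[j, k] == pytest.approx(expected, rel=1e-10)

    def test_constant_cpg_gets_zero(self):
        m, ann = make_matrix(10, {"a": 3, "b": 3}, seed=1)
        m.values[4, :] = 0.5
        t = one_vs_rest_tstats(m, ann)
        np.testing.assert_array_equal(t.tstat[4], 0.0)

    def test_perfect_separation_sign(self):
        m, ann = make_matrix(5, {"a": 4, "b": 4}, seed=2)
        m.values[0] = [1, 1, 1, 1, 0, 0, 0, 0]
        m.values[0] += np.random.default_rng(0).normal(0, 1e-6, 8)
        t = one_vs_rest_tstats(m, ann)
        k_a = t.cell_types.index("a")
        assert t.tstat[0, k_a] > 100  # hypermethylated in a -> large positive


class TestLegacyLibrary:
    def make_table(self, J, K, seed):
        rng = np.random.default_rng(seed)
        return TStatTable(
            np.array([f"cg{j:03d}" for j in range(J)], object),
            [f"t{k}" for k in range(K)],
            rng.normal(size=(J, K)),
        )

    def test_extremes_k2(self):
        t = self.make_table(20, 2, 0)
        lib = legacy_library(t, per_type=1)
        expected = set()
        for k in range(2):
            expected.add(t.cpg_ids[np.argmax(t.tstat[:, k])])
            expected.add(t.cpg_ids[np.argmin(t.tstat[:, k])])
        assert set(lib) == expected

    def test_size_bound_and_sort_oracle(self):
        t = self.make_table(500, 6, 1)
        lib = legacy_library(t, per_type=6)
        assert len(lib) <= 72
        expected = set()
        for k in range(6):
            order = np.argsort(t.tstat[:, k])
            expected.update(t.cpg_ids[order[:6]])
            expected.update(t.cpg_ids[order[-6:]])
        assert set(lib) == expected

    def test_insufficient_pool(self):
        t = self.make_table(10, 3, 2)
        with pytest.raises(InsufficientPoolError):
            legacy_library(t, per_type=2)  # needs 12 > 10


class TestCandidateSet:
    def test_uniform_init_and_membership(self):
        rng = np.random.default_rng(3)
        t = TStatTable(
            np.array([f"cg{j}" for j in range(100)], object),
            ["a", "b", "c"],
            rng.normal(size=(100, 3)),
        )
        q = build_candidate_set(t, L=10)
        assert q.P <= 30
        np.testing.assert_allclose(q.probs, 1.0 / q.P)
        expected = set()
        for k in range(3):
            order = np.argsort(t.tstat[:, k])
            expected.update(t.cpg_ids[order[:5]])
            expected.update(t.cpg_ids[order[-5:]])
        assert set(q.cpg_ids) == expected

    def test_duplicate_winner_merged_once(self):
        # one CpG is the top scorer for both cell types
        tt = np.array([[9.0, 9.0], [1.0, -1.0], [-5.0, 2.0], [0.5, -3.0]])
        t = TStatTable(np.array(["w", "x", "y", "z"], object), ["a", "b"], tt)
        q = build_candidate_set(t, L=2)
        assert sorted(q.cpg_ids) == ["w", "y", "z"]  # 'w' only once -> P < LK
        np.testing.assert_allclose(q.probs, 1.0 / 3)

    def test_odd_L_rejected(self):
        t = TStatTable(np.array(["a", "b"], object), ["x"], np.zeros((2, 1)))
        with pytest.raises(ValidationError):
            build_candidate_set(t, L=3)


def uniform_candidates(P, L=2):
    return CandidateSet(
        np.array([f"cg{j}" for j in range(P)], object),
        np.full(P, 1.0 / P),
        L,
        np.array(["a:hyper"] * P, object),
    )


class TestSampleLibrary:
    def test_exhaustive_draw_returns_all(self):
        q = uniform_candidates(8)
        lib = sample_library(q, 8, np.random.default_rng(0))
        assert sorted(lib) == sorted(q.cpg_ids)

    def test_degenerate_weights(self):
        probs = np.full(5, 1e-12)
        probs[2] = 1 - probs.sum() + 1e-12
        q = CandidateSet(np.array(list("abcde"), object), probs / probs.sum(), 2,
                         np.array(["x"] * 5, object))
        rng = np.random.default_rng(1)
        draws = [sample_library(q, 1, rng)[0] for _ in range(200)]
        assert draws.count("c") == 200

    def test_inclusion_matches_sequential_enumeration_oracle(self):
        """Empirical inclusion frequencies vs exact sequential-draw probabilities.

        The oracle enumerates every ordered sequence of 3 distinct draws from
        P=6 items under successive renormalized weighted sampling.
        """
        rng0 = np.random.default_rng(5)
        probs = rng0.dirichlet(np.arange(1, 7).astype(float))
        q = CandidateSet(np.array(list("abcdef"), object), probs, 2,
                         np.array(["x"] * 6, object))
        incl = np.zeros(6)
        for seq in permutations(range(6), 3):
            p, remaining = 1.0, 1.0
            for item in seq:
                p *= probs[item] / remaining
                remaining -= probs[item]
            for item in seq:
                incl[item] += p
        rng = np.random.default_rng(6)
        counts = np.zeros(6)
        n_draws = 20000
        for _ in range(n_draws):
            for c in sample_library(q, 3, rng):
                counts[list("abcdef").index(c)] += 1
        freq = counts / n_draws
        np.testing.assert_allclose(freq, incl, atol=0.02)

    def test_oversize_request_errors(self):
        with pytest.raises(ValidationError):
            sample_library(uniform_candidates(4), 5, np.random.default_rng(0))


class TestUpdateProbabilities:
    def test_multiplicative_formula(self):
        q = uniform_candidates(4)
        loo = np.array([1.6, 2.0])
        out = update_probabilities(q, ["cg0", "cg1"], mdsc=2.0, loo=loo)
        # pre-rescale factors: 1.25 and 1.0 on members, 1.0 on the rest
        raw = np.array([0.25 * 1.25, 0.25, 0.25, 0.25])
        np.testing.assert_allclose(out.probs, raw / raw.sum(), atol=1e-12)
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_neutral_cpg_unchanged_relative_rank(self):
        q = uniform_candidates(5)
        out = update_probabilities(q, ["cg0", "cg1", "cg2"], 1.5, np.array([1.5, 1.2, 1.8]))
        # cg0 neutral (r=1); cg1 helpful (r>1); cg2 harmful (r<1)
        assert out.probs[1] > out.probs[0] > out.probs[2]

    def test_nonpositive_values_rejected(self):
        q = uniform_candidates(3)
        with pytest.raises(NumericError):
            update_probabilities(q, ["cg0"], 0.0, np.array([1.0]))
        with pytest.raises(NumericError):
            update_probabilities(q, ["cg0"], 1.0, np.array([-1.0]))


@pytest.fixture(scope="module")
def planted():
    ref, ann, truth = synth_reference(
        n_cpgs=300, K=3, n_per=5, n_dml_per_type=8, effect=0.35, phi=60, seed=21
    )
    q = build_candidate_set(one_vs_rest_tstats(ref, ann), L=30)
    return ref, ann, q, truth


class TestResetSearch:
    def test_zero_iterations_noop(self, planted):
        ref, ann, q, _ = planted
        st = reset_search(ref, ann, q, SearchConfig(iterations=0, j_star=10, seed=0))
        assert len(st.trace) == 0 and st.best_library == []

    def test_deterministic_given_seed(self, planted):
        ref, ann, q, _ = planted
        cfg = SearchConfig(iterations=50, j_star=15, seed=42)
        a = reset_search(ref, ann, q, cfg)
        b = reset_search(ref, ann, q, cfg)
        assert a.best_library == b.best_library
        assert a.trace.equals(b.trace)
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_trace_running_max_and_prob_simplex(self, planted):
        ref, ann, q, _ = planted
        st = reset_search(ref, ann, q, SearchConfig(iterations=200, j_star=15, seed=7))
        bm = st.trace.best_mdsc.to_numpy()
        assert np.all(np.diff(bm) >= -1e-12)
        assert st.best_mdsc == pytest.approx(np.nanmax(st.trace.mdsc.to_numpy()))
        assert st.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(st.probs >= 0)

    def test_signal_enrichment_in_probabilities(self, planted):
        ref, ann, q, truth = planted
        st = reset_search(ref, ann, q, SearchConfig(iterations=2000, j_star=12, seed=3))
        planted_mask = np.isin(q.cpg_ids.astype(str), truth.cpg_id.astype(str).to_numpy())
        assert planted_mask.any() and (~planted_mask).any()
        assert st.probs[planted_mask].mean() > st.probs[~planted_mask].mean()

    def test_random_size_mode_respects_bounds(self, planted):
        ref, ann, q, _ = planted
        cfg = SearchConfig(iterations=60, size_mode="random", j_min=5, j_max=20, seed=9)
        st = reset_search(ref, ann, q, cfg)
        sizes = st.trace["size"].to_numpy()
        assert sizes.min() >= 5 and sizes.max() <= 20 and len(set(sizes)) > 1


class TestFinalizeLibrary:
    def test_full_library_equals_centroids(self):
        m, ann = make_matrix(12, {"a": 3, "b": 4}, seed=30)
        lib = finalize_library(m, ann, list(m.cpg_ids))
        np.testing.assert_allclose(
            lib.mean_matrix, cell_type_centroids(m, ann).to_numpy(), atol=1e-12
        )

    def test_subset_matches_loop_oracle(self):
        m, ann = make_matrix(12, {"a": 3, "b": 4}, seed=31)
        chosen = [m.cpg_ids[i] for i in (7, 2, 9)]
        lib = finalize_library(m, ann, chosen)
        lab = dict(zip(ann.sample_ids, ann.labels))
        for k, t in enumerate(lib.cell_types):
            cols = [i for i, s in enumerate(m.sample_ids) if lab[s] == t]
            for r, c in enumerate((7, 2, 9)):
                assert lib.mean_matrix[r, k] == pytest.approx(
                    np.mean([m.values[c, i] for i in cols])
                )

    def test_unknown_cpg_errors(self):
        m, ann = make_matrix(5, {"a": 2, "b": 2}, seed=32)
        with pytest.raises(ValidationError):
            finalize_library(m, ann, ["nope"])
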