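import itertools

import numpy as np
import pytest

from msatpop.ancestry import (AncestryError, align_runs, dic, dic_table,
                              dominant_ancestor, run_chain, structure_r2,
                              write_q_matrix, _g_similarity, _loglik, _encode)

from conftest import make_table


def two_cluster_fixed_difference(n_per=30, n_loci=6, seed=0, het_frac=0.0):
    """Two groups fixed for different alleles at every locus; the cleanest
    possible K=2 signal."""
    rng = np.random.default_rng(seed)
    genos = []
    for g, base in ((0, 10), (1, 20)):
        for _ in range(n_per):
            row = []
            for _ in range(n_loci):
                a = base + int(rng.integers(0, 2))
                b = a if rng.random() >= het_frac \
                    else base + int(rng.integers(0, 2))
                row.append(tuple(sorted((a, b))))
            genos.append(row)
    truth = np.repeat([0, 1], n_per)
    return make_table(genos), truth


def selfing_table(s, n=120, n_loci=8, seed=1):
    """Single-cluster genotypes generated exactly under the model: with
    probability s the two allele copies are one IBD draw."""
    rng = np.random.default_rng(seed)
    alleles = np.array([10, 11, 12, 13])
    genos = []
    for _ in range(n):
        row = []
        for _ in range(n_loci):
            if rng.random() < s:
                a = int(rng.choice(alleles))
                row.append((a, a))
            else:
                row.append(tuple(sorted(rng.choice(alleles, size=2))))
        genos.append(row)
    return make_table(genos)


class TestRunChain:
    def test_k1_membership_is_trivially_one(self):
        t, _ = two_cluster_fixed_difference(n_per=5, n_loci=3)
        chain = run_chain(t, K=1, n_burnin=20, n_iter=30, seed=0)
        assert np.allclose(chain.Q, 1.0)
        assert np.isfinite(dic(chain))

    def test_q_rows_sum_to_one(self):
        t, _ = two_cluster_fixed_difference(n_per=8, n_loci=4)
        chain = run_chain(t, K=3, n_burnin=30, n_iter=50, seed=1)
        assert np.allclose(chain.Q.sum(axis=1), 1.0)
        for Pj in chain.P:
            assert np.allclose(Pj.sum(axis=1), 1.0)

    def test_two_cluster_structure_recovered(self):
        t, truth = two_cluster_fixed_difference(n_per=25, n_loci=6, seed=2)
        chain = run_chain(t, K=2, n_burnin=200, n_iter=400, seed=3)
        assigned = np.argmax(chain.Q, axis=1)
        # label switching: accept either labelling
        agree = max((assigned == truth).mean(), (assigned != truth).mean())
        assert agree == 1.0
        assert chain.Q.max(axis=1).min() > 0.9

    def test_fix_s_zero_is_standard_admixture(self):
        t, _ = two_cluster_fixed_difference(n_per=6, n_loci=3)
        chain = run_chain(t, K=2, n_burnin=20, n_iter=30, seed=4, fix_s=0.0)
        assert chain.s == 0.0

    def test_inbreeding_rate_recovered(self):
        # data drawn exactly under the model at s = 0.6
        t = selfing_table(s=0.6, seed=5)
        chain = run_chain(t, K=1, n_burnin=200, n_iter=400, seed=6)
        assert chain.s == pytest.approx(0.6, abs=0.12)

    def test_near_zero_selfing_estimated_low(self):
        t = selfing_table(s=0.0, seed=7)
        chain = run_chain(t, K=1, n_burnin=200, n_iter=400, seed=8)
        assert chain.s < 0.25

    def test_same_seed_reproducible(self):
        t, _ = two_cluster_fixed_difference(n_per=6, n_loci=3)
        c1 = run_chain(t, K=2, n_burnin=30, n_iter=40, seed=9)
        c2 = run_chain(t, K=2, n_burnin=30, n_iter=40, seed=9)
        assert np.array_equal(c1.Q, c2.Q)
        assert np.array_equal(c1.deviance, c2.deviance)

    def test_missing_loci_tolerated(self):
        genos = [[(10, 10), None], [(10, 10), (5, 5)], [(20, 20), (9, 9)],
                 [(20, 20), None]]
        t = make_table(genos)
        chain = run_chain(t, K=2, n_burnin=20, n_iter=30, seed=10)
        assert np.isfinite(chain.deviance).all()

    def test_k_above_mlg_count_warns(self, caplog):
        t = make_table([[(10, 10)], [(10, 10)], [(20, 20)]])
        with caplog.at_level("WARNING"):
            run_chain(t, K=3, n_burnin=5, n_iter=5, seed=0)
        assert "distinct MLGs" in caplog.text

    def test_invalid_k_rejected(self):
        t = make_table([[(10, 10)], [(20, 20)]])
        with pytest.raises(AncestryError):
            run_chain(t, K=0, n_burnin=5, n_iter=5)


class TestLoglik:
    def test_cluster_relabelling_invariance(self):
        t, _ = two_cluster_fixed_difference(n_per=5, n_loci=4)
        ca, cb, vals = _encode(t)
        rng = np.random.default_rng(11)
        K = 3
        Q = rng.dirichlet(np.ones(K), size=len(t))
        P = [rng.dirichlet(np.ones(len(v)), size=K) for v in vals]
        base = _loglik(ca, cb, Q, P, 0.7)
        perm = np.array([2, 0, 1])
        swapped = _loglik(ca, cb, Q[:, perm], [p[perm] for p in P], 0.7)
        assert swapped == pytest.approx(base, rel=1e-12)

    def test_perfect_model_beats_wrong_model(self):
        t, truth = two_cluster_fixed_difference(n_per=10, n_loci=4)
        ca, cb, vals = _encode(t)
        Q_true = np.eye(2)[truth]
        # true per-cluster frequencies: uniform over that cluster's alleles
        P_true = []
        for v in vals:
            p = np.zeros((2, len(v)))
            for k, base in enumerate((10, 20)):
                m = (v >= base) & (v < base + 2)
                p[k, m] = 1.0 / m.sum()
            P_true.append(p)
        Q_flat = np.full((len(t), 2), 0.5)
        assert _loglik(ca, cb, Q_true, P_true, 0.9) > \
            _loglik(ca, cb, Q_flat, P_true, 0.9)


class TestDic:
    def test_k2_beats_k1_on_structured_data(self):
        t, _ = two_cluster_fixed_difference(n_per=20, n_loci=6, seed=12)
        c1 = run_chain(t, K=1, n_burnin=150, n_iter=300, seed=13)
        c2 = run_chain(t, K=2, n_burnin=150, n_iter=300, seed=14)
        assert dic(c2) < dic(c1)

    def test_dic_table_plateau_flag(self):
        t, _ = two_cluster_fixed_difference(n_per=15, n_loci=5, seed=15)
        runs = {k: [run_chain(t, K=k, n_burnin=100, n_iter=200,
                              seed=20 + k)] for k in (1, 2, 3)}
        df = dic_table(runs)
        assert set(df.columns) == {"K", "chain", "DIC", "plateau_at_K"}
        best = df.groupby("K")["DIC"].min()
        assert best[2] < best[1]  # real structure found
        # adding a third cluster gives no comparable improvement
        assert best[2] - best[3] < best[1] - best[2]


class TestAlignRuns:
    def _random_q(self, n=20, K=3, seed=0):
        return np.random.default_rng(seed).dirichlet(np.ones(K), size=n)

    def test_permuted_copies_align_exactly(self):
        Q = self._random_q()
        perms = [np.array(p) for p in itertools.permutations(range(3))]
        runs = [Q[:, p] for p in perms[:4]]
        aligned, consensus, H = align_runs(runs, n_random_orders=5, seed=0)
        assert H == pytest.approx(1.0)
        for A in aligned:
            assert np.allclose(A, aligned[0])
        assert np.allclose(consensus, aligned[0])

    def test_noisy_runs_similarity_below_one(self):
        rng = np.random.default_rng(1)
        Q = self._random_q(seed=2)
        noisy = Q + rng.normal(scale=0.3, size=Q.shape)
        noisy = np.abs(noisy)
        noisy /= noisy.sum(axis=1, keepdims=True)
        _, _, H = align_runs([Q, noisy], n_random_orders=3, seed=3)
        assert H < 0.99

    def test_alignment_never_decreases_similarity(self):
        rng = np.random.default_rng(4)
        Q = self._random_q(seed=5)
        runs = []
        for _ in range(4):
            noisy = np.abs(Q + rng.normal(scale=0.05, size=Q.shape))
            noisy /= noisy.sum(axis=1, keepdims=True)
            runs.append(noisy[:, rng.permutation(3)])
        raw_H = np.mean([_g_similarity(runs[i], runs[j])
                         for i in range(4) for j in range(i + 1, 4)])
        _, _, H = align_runs(runs, n_random_orders=10, seed=6)
        assert H >= raw_H - 1e-12

    def test_single_run_similarity_one(self):
        Q = self._random_q()
        aligned, consensus, H = align_runs([Q])
        assert H == 1.0 and np.allclose(consensus, Q)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(AncestryError):
            align_runs([self._random_q(K=2), self._random_q(K=3)])

    def test_similarity_bounds(self):
        # G of a matrix with itself is 1; of maximally different
        # memberships (everyone flipped) it is 0
        A = np.repeat([[1.0, 0.0]], 10, axis=0)
        B = np.repeat([[0.0, 1.0]], 10, axis=0)
        assert _g_similarity(A, A) == pytest.approx(1.0)
        assert _g_similarity(A, B) == pytest.approx(0.0)


class TestDominantAncestor:
    def test_clear_dominant(self):
        assert dominant_ancestor(np.array([[0.979, 0.011, 0.010]])) == [0]

    def test_admixed_profile_has_none(self):
        q = np.array([[0.596, 0.110, 0.260, 0.034]])
        assert dominant_ancestor(q) == [None]

    def test_cutoff_is_inclusive(self):
        assert dominant_ancestor(np.array([[0.75, 0.25]])) == [0]
        assert dominant_ancestor(np.array([[0.7499, 0.2501]])) == [None]

    def test_custom_cutoff(self):
        q = np.array([[0.6, 0.4]])
        assert dominant_ancestor(q, cutoff=0.5) == [0]


class TestStructureR2:
    def test_perfectly_separated_pops_r2_one(self):
        Q = np.vstack([np.repeat([[1.0, 0.0]], 4, axis=0),
                       np.repeat([[0.0, 1.0]], 4, axis=0)])
        r2, p, contrib = structure_r2(Q, ["a"] * 4 + ["b"] * 4,
                                      n_perm=99, seed=0)
        assert r2 == pytest.approx(1.0)
        assert p <= 0.05

    def test_r2_matches_hand_formula(self):
        rng = np.random.default_rng(7)
        Q = rng.dirichlet(np.ones(3), size=9)
        pops = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        r2, _, _ = structure_r2(Q, pops, n_perm=9, seed=0)
        grand = Q.mean(axis=0)
        sst = ((Q - grand) ** 2).sum()
        ssw = sum(((Q[pops == u] - Q[pops == u].mean(axis=0)) ** 2).sum()
                  for u in "abc")
        assert r2 == pytest.approx(1 - ssw / sst)

    def test_p_value_against_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        Q = rng.dirichlet(np.ones(2), size=6)
        pops = np.array(["a"] * 3 + ["b"] * 3)

        def r2_of(labels):
            labels = np.asarray(labels)
            grand = Q.mean(axis=0)
            sst = ((Q - grand) ** 2).sum()
            ssw = sum(((Q[labels == u] - Q[labels == u].mean(axis=0)) ** 2)
                      .sum() for u in ("a", "b"))
            return 1 - ssw / sst

        obs = r2_of(pops)
        perms = list(itertools.permutations(pops))
        exact = sum(r2_of(np.array(p)) >= obs - 1e-12
                    for p in perms) / len(perms)
        _, p, _ = structure_r2(Q, pops, n_perm=1999, seed=9)
        assert p == pytest.approx(exact, abs=0.05)

    def test_leave_one_out_contributions(self):
        Q = np.vstack([np.repeat([[1.0, 0.0]], 3, axis=0),
                       np.repeat([[0.0, 1.0]], 3, axis=0),
                       np.repeat([[0.5, 0.5]], 3, axis=0)])
        pops = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        r2, _, contrib = structure_r2(Q, pops, n_perm=9, seed=0)
        assert set(contrib) == {"a", "b", "c"}
        # dropping the intermediate pop leaves perfect separation
        assert r2 - contrib["c"] == pytest.approx(1.0)

    def test_single_population_rejected(self):
        Q = np.full((4, 2), 0.5)
        with pytest.raises(AncestryError):
            structure_r2(Q, ["a"] * 4, n_perm=9)


def test_write_q_matrix_layout(tmp_path):
    Q = np.array([[0.9, 0.1], [0.2, 0.8]])
    path = tmp_path / "q.txt"
    write_q_matrix(Q, ["i1", "i2"], ["V2", "V8"], path)
    lines = path.read_text().splitlines()
    assert lines[0] == "i1 V2 : 0.9000 0.1000"
    assert lines[1] == "i2 V8 : 0.2000 0.8000"
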