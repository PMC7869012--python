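"""CNC network construction against formula, permutation and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncnet.cnc import build_cnc, correlation_test, select_top_lncrnas
from lncnet.io import ExpressionMatrix
from lncnet.simulate import cnc_module_config, lnc_id, mrna_id, simulate_expression

from conftest import de_frame, make_matrix


class TestSelectTopLncrnas:
    def test_returns_all_when_fewer_than_k(self):
        table = de_frame([("a", 3.0, 0.001), ("b", -2.5, 0.002), ("c", 2.1, 0.003)])
        assert len(select_top_lncrnas(table, k=50)) == 3

    def test_ranks_by_absolute_fold_change(self):
        table = de_frame([("a", 2.4, 0.001), ("b", -6.5, 0.002), ("c", 2.9, 0.003)])
        assert select_top_lncrnas(table, k=2) == ["b", "c"]

    def test_p_cut_is_strict(self):
        table = de_frame([("a", 9.0, 0.01), ("b", 2.1, 0.005)])
        assert select_top_lncrnas(table, k=5, p_cut=0.01) == ["b"]

    def test_empty_eligible_set(self):
        table = de_frame([("a", 9.0, 0.5)])
        assert select_top_lncrnas(table) == []

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_invariant_under_shuffling_vs_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 30))
        table = de_frame(
            [(f"f{i}", float(np.round(r.choice([-1, 1]) * r.uniform(1, 8), 2)),
              float(np.round(r.uniform(0, 0.05), 4))) for i in range(n)]
        )
        k = int(r.integers(1, 10))
        expected = [
            fid for fid, _, _ in sorted(
                [(t.feature_id, t.fold_change, t.p_value)
                 for t in table.itertuples() if t.p_value < 0.01],
                key=lambda rec: (-abs(rec[1]), rec[2], rec[0]),
            )
        ][:k]
        shuffled = table.sample(frac=1, random_state=int(seed % 2**31)).reset_index(drop=True)
        assert select_top_lncrnas(shuffled, k=k) == expected


class TestCorrelationTest:
    def test_perfect_linearity(self):
        x = np.arange(8.0)
        r, p = correlation_test(x, 2 * x + 1)
        assert (r, p) == (1.0, 0.0)

    def test_constructed_orthogonality_gives_p_one(self):
        x = np.array([1, 0, -1, 0, 1, 0, -1, 0], float)
        y = np.array([0, 1, 0, -1, 0, 1, 0, -1], float)
        r, p = correlation_test(x, y)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_matches_t_formula_and_scipy(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(size=8)
            r, p = correlation_test(x, y)
            t = r * np.sqrt(6) / np.sqrt(1 - r * r)
            assert p == pytest.approx(2 * stats.t.sf(abs(t), 6), abs=1e-12)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_consistent_with_exhaustive_permutation_tail(self):
        r0 = np.random.default_rng(5)
        x, y = r0.normal(size=8), r0.normal(size=8)
        r, p = correlation_test(x, y)
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        robs = abs(np.dot(xc, yc) / 8)
        count = 0
        total = 0
        for perm in itertools.permutations(range(8)):
            rp = abs(np.dot(xc, yc[list(perm)]) / 8)
            count += rp >= robs - 1e-12
            total += 1
        assert abs(p - count / total) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_test(np.ones(8), np.arange(8.0))

    def test_high_correlation_implies_significance_at_n8(self):
        # threshold interplay: any |r| > 0.9 at n = 8 has p < 0.05
        for r in np.linspace(0.9, 0.999999, 50):
            t = r * np.sqrt(6) / np.sqrt(1 - r * r)
            assert 2 * stats.t.sf(abs(t), 6) < 0.05


def _edges_by_hand(matrix, lncs, mrnas, pcc_thr=0.9, p_thr=0.05, fdr_thr=1.0):
    """Independent all-pairs scan: scalar pearsonr + hand step-up BH."""
    rows = []
    for l in lncs:
        for m in mrnas:
            r, p = stats.pearsonr(matrix.values.loc[l], matrix.values.loc[m])
            rows.append((l, m, r, p))
    df = pd.DataFrame(rows, columns=["lncRNA", "mRNA", "pcc", "p_value"])
    m = len(df)
    order = np.argsort(df["p_value"].to_numpy(), kind="mergesort")
    q = np.minimum.accumulate(
        (m * df["p_value"].to_numpy()[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(q, 1.0)
    df["fdr"] = fdr
    keep = (df["pcc"].abs() > pcc_thr) & (df["p_value"] < p_thr) & (df["fdr"] < fdr_thr)
    return df[keep].sort_values(["lncRNA", "mRNA"]).reset_index(drop=True)


class TestBuildCnc:
    def test_null_matrix_matches_direct_post_check(self, rng):
        vals = rng.normal(8, 1, size=(50, 8))
        ids = [f"L{i}" for i in range(20)] + [f"M{i}" for i in range(30)]
        matrix = make_matrix(vals, feature_ids=ids)
        lncs, mrnas = ids[:20], ids[20:]
        net = build_cnc(matrix, lncs, mrnas)
        by_hand = _edges_by_hand(matrix, lncs, mrnas)
        assert net.n_edges == len(by_hand)
        if net.n_edges:
            pd.testing.assert_frame_equal(
                net.edges[["lncRNA", "mRNA"]], by_hand[["lncRNA", "mRNA"]]
            )
        assert net.n_candidates == 600

    def test_planted_module_recovered_exactly_at_zero_noise(self):
        cfg = cnc_module_config(seed=3, noise_sd=0.0,
                                sign_pattern=tuple([1] * 5 + [1] * 15 + [-1] * 5))
        matrix, truth = simulate_expression(cfg)
        lncs = [lnc_id(i) for i in range(5)]
        mrnas = [mrna_id(i) for i in range(20)]
        net = build_cnc(matrix, lncs, mrnas)
        got = set(map(tuple, net.edges[["lncRNA", "mRNA"]].to_numpy()))
        want = set(map(tuple, truth.module_edges[["lncRNA", "mRNA"]].to_numpy()))
        assert got == want
        signs = dict(zip(map(tuple, net.edges[["lncRNA", "mRNA"]].to_numpy()),
                         net.edges["sign"]))
        for rec in truth.module_edges.itertuples(index=False):
            assert signs[(rec.lncRNA, rec.mRNA)] == rec.sign

    def test_edges_respect_all_thresholds(self, rng):
        cfg = cnc_module_config(seed=9, noise_sd=0.2)
        matrix, _ = simulate_expression(cfg)
        net = build_cnc(matrix, [lnc_id(i) for i in range(35)],
                        [mrna_id(i) for i in range(70)])
        assert (net.edges["pcc"].abs() > 0.9).all()
        assert (net.edges["p_value"] < 0.05).all()
        assert (net.edges["fdr"] < 1.0).all()
        assert set(net.lnc_nodes) == set(net.edges["lncRNA"])
        assert set(net.mrna_nodes) == set(net.edges["mRNA"])

    def test_raising_pcc_threshold_never_adds_edges(self, rng):
        vals = rng.normal(8, 1, size=(30, 8))
        vals[:10] += rng.normal(size=8) * 0.9  # a shared factor
        ids = [f"L{i}" for i in range(10)] + [f"M{i}" for i in range(20)]
        matrix = make_matrix(vals, feature_ids=ids)
        prev = None
        for thr in (0.5, 0.7, 0.9, 0.95, 0.99):
            net = build_cnc(matrix, ids[:10], ids[10:], pcc_threshold=thr)
            pairs = set(map(tuple, net.edges[["lncRNA", "mRNA"]].to_numpy()))
            if prev is not None:
                assert pairs <= prev
            prev = pairs

    def test_invariant_to_affine_rescaling_of_one_feature(self, rng):
        cfg = cnc_module_config(seed=11, noise_sd=0.1)
        matrix, _ = simulate_expression(cfg)
        lncs = [lnc_id(i) for i in range(35)]
        mrnas = [mrna_id(i) for i in range(70)]
        net1 = build_cnc(matrix, lncs, mrnas)
        rescaled = ExpressionMatrix(matrix.values.copy(), matrix.groups)
        rescaled.values.loc[lnc_id(0)] = 3.5 * rescaled.values.loc[lnc_id(0)] + 100.0
        net2 = build_cnc(rescaled, lncs, mrnas)
        pd.testing.assert_frame_equal(
            net1.edges[["lncRNA", "mRNA", "sign"]], net2.edges[["lncRNA", "mRNA", "sign"]]
        )
        assert np.allclose(net1.edges["pcc"], net2.edges["pcc"])

    def test_bipartite_and_empty_candidates(self, rng):
        matrix = make_matrix(rng.normal(8, 1, size=(4, 8)))
        net = build_cnc(matrix, [], ["F0000"])
        assert net.n_edges == 0 and net.lnc_nodes == [] and net.mrna_nodes == []

    def test_to_networkx_bipartite(self, rng):
        cfg = cnc_module_config(seed=3, noise_sd=0.05, n_distractor_lnc=0,
                                n_distractor_mrna=0)
        matrix, _ = simulate_expression(cfg)
        net = build_cnc(matrix, [lnc_id(i) for i in range(5)],
                        [mrna_id(i) for i in range(20)])
        g = net.to_networkx()
        assert g.number_of_edges() == net.n_edges
        for u, v in g.edges():
            kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
            assert kinds == {"lncRNA", "mRNA"}
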