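"""Marker selection and risk-score checks: greedy LD pruning against an
exhaustive verifier, P thresholding semantics, hand-computed scores, the
selection-index linear system, and the four weighting scenarios."""

import inspect

import numpy as np
import pandas as pd
import pytest

from mtgrs import (
    build_scenario,
    index_weights,
    ld_prune,
    mt_adjust_effects,
    mt_grs,
    p_threshold,
    st_grs,
)
from mtgrs.gwas import SUMSTAT_COLUMNS, SummaryStats
from mtgrs.ldsc import adjusted_r2
from mtgrs.scoring import DEFAULT_M, MT_P_GRID, ST_P_GRID

from conftest import make_genotypes


def _stats(ids, beta, p, af=0.3, trait="t"):
    m = len(ids)
    tab = pd.DataFrame({
        "id": ids, "chrom": "1", "pos": np.arange(1, m + 1) * 100,
        "effect_allele": "A", "other_allele": "G",
        "af": af, "beta": beta, "se": 0.1, "p": p, "n": 100, "valid": True,
    })
    return SummaryStats(table=tab[SUMSTAT_COLUMNS], trait=trait)


def _stats_for(G, beta, p, trait="t"):
    tab = G.markers[["id", "chrom", "pos", "effect_allele", "other_allele", "af"]].copy()
    tab["beta"] = beta
    tab["se"] = 0.1
    tab["p"] = p
    tab["n"] = G.n
    tab["valid"] = True
    return SummaryStats(table=tab[SUMSTAT_COLUMNS], trait=trait)


class TestLDPrune:
    def test_threshold_of_one_keeps_everything(self, random_genotypes):
        rng = np.random.default_rng(0)
        ss = _stats_for(random_genotypes, rng.normal(size=30), rng.uniform(size=30))
        kept = ld_prune(random_genotypes, ss, r2_max=1.0, window=7)
        assert len(kept) == 30

    def test_duplicate_marker_keeps_smaller_p(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.4, 80).astype(np.float32)
        G = make_genotypes(np.column_stack([col, col]))
        ss = _stats_for(G, [0.1, 0.2], [0.5, 0.01])
        kept = ld_prune(G, ss, r2_max=0.9, window=7)
        assert kept == ["m2"]  # the better-P copy survives

    def test_exhaustive_verification_oracle(self, random_genotypes):
        """Kept set: pairwise clean within window, and every dropped marker
        conflicts with a better-P kept marker."""
        G = random_genotypes
        rng = np.random.default_rng(2)
        pvals = rng.uniform(size=30)
        ss = _stats_for(G, rng.normal(size=30), pvals)
        r2_max, window = 0.2, 11
        kept = ld_prune(G, ss, r2_max=r2_max, window=window)
        pos = {mid: j for j, mid in enumerate(G.markers["id"])}
        X = np.asarray(G.counts, dtype=float)
        half = window // 2
        kept_idx = [pos[mid] for mid in kept]
        for a in kept_idx:
            for b in kept_idx:
                if a < b and b - a <= half:
                    assert adjusted_r2(X[:, a], X[:, b]) < r2_max
        p_by_idx = {pos[m]: p for m, p in zip(ss.table["id"], pvals)}
        dropped = set(range(30)) - set(kept_idx)
        for d in dropped:
            conflicts = [
                k for k in kept_idx
                if abs(k - d) <= half
                and p_by_idx[k] <= p_by_idx[d]
                and adjusted_r2(X[:, k], X[:, d]) >= r2_max
            ]
            assert conflicts, f"marker {d} was dropped without a blocking kept marker"

    def test_invalid_threshold_rejected(self, random_genotypes):
        ss = _stats_for(random_genotypes, np.ones(30), np.full(30, 0.5))
        with pytest.raises(ValueError):
            ld_prune(random_genotypes, ss, r2_max=0.0)


class TestPThreshold:
    def test_strict_inequality_at_boundary(self):
        ss = _stats(["a", "b", "c"], [0.1] * 3, [0.01, 0.05, 0.2])
        assert p_threshold(ss, 0.05) == ["a"]
        assert p_threshold(ss, 0.051) == ["a", "b"]
        assert p_threshold(ss, 1.0) == ["a", "b", "c"]

    def test_hand_enumerated_subset(self):
        p = [0.001, 0.2, 0.04, 0.9, 0.03, 0.07, 0.5, 0.049, 0.6, 0.99]
        ss = _stats([f"v{i}" for i in range(10)], [0.1] * 10, p)
        assert len(p_threshold(ss, 0.05)) == 4

    def test_default_grids_match_printed_sets(self):
        assert ST_P_GRID == (0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9, 0.99)
        assert MT_P_GRID == (0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 0.75, 0.99)


class TestSTGRS:
    def test_zero_effects_zero_scores(self, random_genotypes):
        ss = _stats_for(random_genotypes, np.zeros(30), np.full(30, 0.5))
        sc = st_grs(random_genotypes, ss, [f"m{j}" for j in (1, 5, 9)])
        np.testing.assert_allclose(sc.score, 0.0)

    def test_single_unit_effect_returns_allele_count(self, random_genotypes):
        beta = np.zeros(30)
        beta[0] = 1.0
        ss = _stats_for(random_genotypes, beta, np.full(30, 0.5))
        sc = st_grs(random_genotypes, ss, ["m1"])
        np.testing.assert_allclose(sc.score, random_genotypes.counts[:, 0])

    def test_matches_hand_matrix_product(self):
        rng = np.random.default_rng(3)
        counts = rng.binomial(2, 0.5, size=(5, 8)).astype(np.float32)
        G = make_genotypes(counts)
        beta = rng.normal(size=8)
        ss = _stats_for(G, beta, np.full(8, 0.5))
        sc = st_grs(G, ss, list(G.markers["id"]))
        np.testing.assert_allclose(sc.score, counts.astype(float) @ beta, rtol=1e-6)

    def test_missing_genotypes_imputed_to_training_frequency(self):
        counts = np.array([[0.0], [1.0], [np.nan]], dtype=np.float32)
        G = make_genotypes(counts)
        ss = _stats_for(G, [1.0], [0.5])
        af = ss.table["af"][0]
        sc = st_grs(G, ss, ["m1"])
        assert sc.score[2] == pytest.approx(2 * af)

    def test_empty_subset_rejected(self, random_genotypes):
        ss = _stats_for(random_genotypes, np.ones(30), np.full(30, 0.5))
        with pytest.raises(ValueError):
            st_grs(random_genotypes, ss, [])


class TestIndexWeights:
    def test_scalar_case_forced_by_arithmetic(self):
        iw = index_weights([0.3], np.eye(1), [200_000.0], M=60_000)
        assert iw.w[0] == pytest.approx(0.5, rel=1e-12)

    def test_default_segment_count(self):
        assert DEFAULT_M == 60_000
        assert inspect.signature(index_weights).parameters["M"].default == 60_000

    def test_uncorrelated_information_traits_get_zero_weight(self):
        rg = np.eye(3)
        iw = index_weights([0.3, 0.5, 0.4], rg, [1e5, 1e5, 1e5], M=60_000)
        assert iw.w[1] == 0.0 and iw.w[2] == 0.0
        assert iw.w[0] > 0

    def test_two_trait_explicit_inverse_oracle(self):
        h2 = np.array([0.5, 0.5])
        rg = np.array([[1.0, 0.5], [0.5, 1.0]])
        N = np.array([10_000.0, 10_000.0])
        M = 60_000.0
        iw = index_weights(h2, rg, N, M=M)
        # independent 2x2 inversion
        h = np.sqrt(h2)
        a = h2[0] / M + 1 / N[0]
        d = h2[1] / M + 1 / N[1]
        b = 0.5 * h[0] * h[1] / M
        det = a * d - b * b
        Vinv = np.array([[d, -b], [-b, a]]) / det
        C = np.array([h2[0] / M, 0.5 * h[0] * h[1] / M])
        np.testing.assert_allclose(iw.w, Vinv @ C, rtol=1e-12)

    def test_solution_satisfies_linear_system(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            k = 5
            A = rng.normal(size=(k, k))
            R = np.corrcoef(A @ A.T + np.eye(k))
            h2 = rng.uniform(0.05, 0.6, k)
            N = rng.uniform(1e3, 1e5, k)
            iw = index_weights(h2, R, N, M=50_000)
            assert iw.residual() < 1e-10

    def test_weight_ordering_tracks_rg_and_power(self):
        """The best-correlated, well-powered information trait dominates."""
        h2 = [0.07, 0.4, 0.4, 0.4]
        rg = np.array([
            [1.0, 0.58, 0.30, 0.10],
            [0.58, 1.0, 0.20, 0.20],
            [0.30, 0.20, 1.0, 0.20],
            [0.10, 0.20, 0.20, 1.0],
        ])
        N = [20_000.0, 300_000.0, 300_000.0, 300_000.0]
        iw = index_weights(h2, rg, N, M=60_000)
        info = np.abs(iw.w[1:])
        assert info[0] == info.max()

    def test_ill_conditioned_system_names_the_pair(self):
        h2 = [0.5, 0.5]
        rg = np.array([[1.0, 0.99], [0.99, 1.0]])
        with pytest.raises(ValueError, match="tA / tB"):
            index_weights(h2, rg, [1e4, 1e4], M=60_000,
                          traits=["tA", "tB"], cond_max=1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            index_weights([0.5], np.eye(1), [0.0])
        with pytest.raises(ValueError):
            index_weights([0.5], np.eye(1), [100.0], M=0)


class TestMTAdjust:
    @staticmethod
    def _trio(betas):
        ids = [f"v{i}" for i in range(len(betas[0]))]
        return [_stats(ids, b, [0.5] * len(b), trait=f"t{k}") for k, b in enumerate(betas)]

    def test_identity_weights_reproduce_focal(self):
        stats = self._trio([[0.1, 0.2, -0.3], [1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        iw = index_weights(np.full(3, 0.3), np.eye(3), np.full(3, 1e4))
        iw.w = np.array([1.0, 0.0, 0.0])
        out = mt_adjust_effects(stats, iw)
        np.testing.assert_allclose(out.table["beta"], [0.1, 0.2, -0.3])

    def test_equal_vectors_under_convex_weights(self):
        stats = self._trio([[0.3, -0.1], [0.3, -0.1]])
        iw = index_weights(np.full(2, 0.3), np.eye(2), np.full(2, 1e4))
        iw.w = np.array([0.5, 0.5])
        out = mt_adjust_effects(stats, iw)
        np.testing.assert_allclose(out.table["beta"], [0.3, -0.1])

    def test_hand_computed_weighted_sums(self):
        betas = [[0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                 [1.0, -1.0, 0.5, 0.0, 2.0, -0.5],
                 [0.0, 0.1, -0.1, 0.2, -0.2, 0.3]]
        stats = self._trio(betas)
        iw = index_weights(np.full(3, 0.3), np.eye(3), np.full(3, 1e4))
        iw.w = np.array([0.5, 0.2, -0.1])
        out = mt_adjust_effects(stats, iw)
        expected = (0.5 * np.array(betas[0]) + 0.2 * np.array(betas[1])
                    - 0.1 * np.array(betas[2]))
        np.testing.assert_allclose(out.table["beta"], expected, rtol=1e-12)

    def test_mismatched_marker_sets_rejected(self):
        a = _stats(["x", "y"], [0.1, 0.2], [0.5, 0.5])
        b = _stats(["x", "z"], [0.1, 0.2], [0.5, 0.5])
        iw = index_weights(np.full(2, 0.3), np.eye(2), np.full(2, 1e4))
        with pytest.raises(ValueError):
            mt_adjust_effects([a, b], iw)


class TestMTGRS:
    def test_identity_weights_reduce_to_single_trait(self, random_genotypes):
        G = random_genotypes
        rng = np.random.default_rng(5)
        focal = _stats_for(G, rng.normal(size=30), rng.uniform(size=30))
        other = _stats_for(G, rng.normal(size=30), rng.uniform(size=30), trait="o")
        iw = index_weights(np.full(2, 0.3), np.eye(2), np.full(2, 1e4))
        iw.w = np.array([1.0, 0.0])
        adjusted = mt_adjust_effects([focal, other], iw)
        markers = list(G.markers["id"][:10])
        st = st_grs(G, focal, markers)
        mt = mt_grs(G, adjusted, markers)
        np.testing.assert_array_equal(st.score, mt.score)

    def test_scaled_weights_scale_scores(self, random_genotypes):
        G = random_genotypes
        rng = np.random.default_rng(6)
        focal = _stats_for(G, rng.normal(size=30), rng.uniform(size=30))
        other = _stats_for(G, rng.normal(size=30), rng.uniform(size=30), trait="o")
        iw = index_weights(np.full(2, 0.3), np.eye(2), np.full(2, 1e4))
        iw.w = np.array([2.5, 0.0])
        adjusted = mt_adjust_effects([focal, other], iw)
        markers = list(G.markers["id"])
        st = st_grs(G, focal, markers)
        mt = mt_grs(G, adjusted, markers)
        np.testing.assert_allclose(mt.score, 2.5 * st.score, rtol=1e-10)


class TestScenarios:
    @staticmethod
    def _labelled(n, prefix):
        return [_stats(["a", "b"], [0.1, 0.2], [0.5, 0.5], trait=f"{prefix}{i}")
                for i in range(n)]

    def test_scenario_sizes(self):
        focal = self._labelled(1, "focal")[0]
        info = self._labelled(7, "info")
        ext = self._labelled(2, "ext")
        assert build_scenario("S1", focal=focal, info=info).k == 8
        assert build_scenario("S2", focal=focal, info=info, external=ext).k == 8
        assert build_scenario("S3", focal=focal, info=info, external=ext).k == 9
        assert build_scenario("S4", focal=focal, info=info, external=ext).k == 10

    def test_focal_comes_first(self):
        focal = self._labelled(1, "focal")[0]
        info = self._labelled(2, "info")
        sset = build_scenario("S1", focal=focal, info=info)
        assert sset.labels[0] == "focal0"

    def test_missing_external_stats_informative_error(self):
        focal = self._labelled(1, "focal")[0]
        info = self._labelled(2, "info")
        with pytest.raises(ValueError, match="external"):
            build_scenario("S2", focal=focal, info=info, external=[])

    def test_unknown_scenario_rejected(self):
        focal = self._labelled(1, "f")[0]
        with pytest.raises(ValueError):
            build_scenario("S9", focal=focal, info=self._labelled(1, "i"))
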