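import itertools

import numpy as np
import pandas as pd
import pytest

from phenoclust.criteria import (cdf_delta_auc, consensus_score,
                                 contrast_criterion, core_probabilities,
                                 dunn_index, improver_flags, pac,
                                 pairwise_cluster_tests, pcc,
                                 point_biserial_index, select_optimal,
                                 standard_indices)
from phenoclust.io import CATEGORICAL, CONTINUOUS, CohortTable, VariableMeta
from tests.conftest import ideal_block_matrix


# ---------------------------------------------------------------------------
# naive double-loop oracles
# ---------------------------------------------------------------------------

def naive_cc(M, labels):
    ids = sorted(set(labels))
    N = len(labels)
    contrasts = []
    for k in ids:
        members = [n for n in range(N) if labels[n] == k]
        others = [n for n in range(N) if labels[n] != k]
        Nk = len(members)
        within = 0.0
        if Nk > 1:
            s = sum(M[n][q] for n in members for q in members if q != n)
            within = s / (Nk * (Nk - 1))
        between = 0.0
        if others:
            s = sum(M[n][q] for n in members for q in others)
            between = s / (Nk * (N - Nk))
        contrasts.append(within - between)
    return sum(contrasts) / len(contrasts)


def naive_pi(M, labels):
    ids = sorted(set(labels))
    N = len(labels)
    pi = np.zeros((N, len(ids)))
    for n in range(N):
        for i, k in enumerate(ids):
            members = [q for q in range(N) if labels[q] == k]
            if labels[n] == k:
                if len(members) == 1:
                    pi[n, i] = np.nan
                    continue
                pi[n, i] = sum(M[n][q] for q in members if q != n) / (len(members) - 1)
            else:
                pi[n, i] = sum(M[n][q] for q in members) / len(members)
    return pi


def naive_pcc(M, labels):
    ids = sorted(set(labels))
    pi = naive_pi(M, labels)
    per = []
    for i, k in enumerate(ids):
        members = [n for n in range(len(labels)) if labels[n] == k]
        core = sum(1 for n in members if pi[n, i] > 0.5)
        per.append(core / len(members))
    return per, sum(per) / len(per)


def naive_pac(M, lower=0.1, upper=0.9):
    N = len(M)
    vals = [M[i][j] for i in range(N) for j in range(N) if i != j]
    return sum(1 for v in vals if lower < v < upper) / len(vals)


def naive_cs(M, labels):
    ids = sorted(set(labels))
    terms = []
    for k in ids:
        members = [n for n in range(len(labels)) if labels[n] == k]
        Nk = len(members)
        if Nk > 1:
            s = sum(M[n][q] for n in members for q in members if q != n)
            terms.append(s / (Nk * (Nk - 1)))
        else:
            terms.append(0.0)
    return sum(terms) / len(terms)


def set_partitions(items, k):
    """All set partitions of ``items`` into exactly k nonempty blocks."""
    if k == 1:
        yield [list(items)]
        return
    if len(items) == k:
        yield [[x] for x in items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest, k - 1):
        yield [[first]] + part
    for part in set_partitions(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]


def partition_to_labels(part, n):
    lab = np.empty(n, dtype=int)
    for k, block in enumerate(part, start=1):
        for x in block:
            lab[x] = k
    return lab


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

class TestContrastCriterion:
    def test_ideal_blocks_reach_one(self, blocks_3x4):
        M, labels = blocks_3x4
        cc, per = contrast_criterion(M, labels)
        assert cc == pytest.approx(1.0)
        np.testing.assert_allclose(per, 1.0)

    def test_constant_matrix_gives_zero(self):
        for K in (2, 3, 4):
            M = np.full((12, 12), 1.0 / K)
            np.fill_diagonal(M, 1.0)
            labels = np.repeat(np.arange(1, K + 1), 12 // K)
            cc, _ = contrast_criterion(M, labels)
            assert cc == pytest.approx(0.0, abs=1e-12)

    def test_hand_example_four_subjects(self):
        M = np.array([
            [1.0, 0.9, 0.2, 0.2],
            [0.9, 1.0, 0.2, 0.2],
            [0.2, 0.2, 1.0, 0.9],
            [0.2, 0.2, 0.9, 1.0],
        ])
        cc, per = contrast_criterion(M, [1, 1, 2, 2])
        np.testing.assert_allclose(per, 0.7)
        assert cc == pytest.approx(0.7)

    def test_permutation_invariance(self, rng):
        M = rng.random((9, 9))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        cc, _ = contrast_criterion(M, labels)
        perm = rng.permutation(9)
        cc_p, _ = contrast_criterion(M[np.ix_(perm, perm)], labels[perm])
        assert cc_p == pytest.approx(cc, abs=1e-12)

    def test_edge_conventions(self, rng):
        M = rng.random((5, 5))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        assert contrast_criterion(M, np.ones(5, dtype=int))[0] == 0.0
        off = ~np.eye(5, dtype=bool)
        assert contrast_criterion(M, np.arange(1, 6))[0] == pytest.approx(-M[off].mean())

    def test_range_on_unit_interval_matrices(self, rng):
        for _ in range(20):
            M = rng.random((8, 8))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 1.0)
            labels = rng.integers(1, 4, 8)
            cc, _ = contrast_criterion(M, labels)
            assert -1.0 <= cc <= 1.0


class TestCorePCC:
    def test_ideal_blocks(self, blocks_3x4):
        M, labels = blocks_3x4
        pi = core_probabilities(M, labels)
        own = pi[np.arange(12), labels - 1]
        np.testing.assert_allclose(own, 1.0)
        per, overall = pcc(pi, labels)
        np.testing.assert_allclose(per, 1.0)
        assert overall == 1.0

    def test_constant_matrix_no_core(self):
        K = 3
        M = np.full((12, 12), 1.0 / K)
        np.fill_diagonal(M, 1.0)
        labels = np.repeat([1, 2, 3], 4)
        pi = core_probabilities(M, labels)
        per, overall = pcc(pi, labels)
        assert overall == 0.0
        np.testing.assert_allclose(pi[np.arange(12), labels - 1], 1.0 / K)

    def test_hand_example(self):
        M = np.array([
            [1.0, 0.9, 0.2, 0.2],
            [0.9, 1.0, 0.2, 0.2],
            [0.2, 0.2, 1.0, 0.9],
            [0.2, 0.2, 0.9, 1.0],
        ])
        labels = np.array([1, 1, 2, 2])
        pi = core_probabilities(M, labels)
        np.testing.assert_allclose(pi[np.arange(4), labels - 1], 0.9)
        _, overall = pcc(pi, labels)
        assert overall == 1.0

    def test_singleton_counts_non_core(self):
        M = np.full((3, 3), 0.8)
        np.fill_diagonal(M, 1.0)
        labels = np.array([1, 1, 2])
        pi = core_probabilities(M, labels)
        assert np.isnan(pi[2, 1])
        per, _ = pcc(pi, labels)
        assert per[1] == 0.0


class TestOracleEquivalence:
    def test_exhaustive_partitions_match_naive_oracles(self):
        """Vectorized CC, pi, PCC, PAC and CS agree with naive double-loop
        oracles to 1e-12 over 100 random small matrices and every set
        partition into 2 or 3 clusters."""
        rng = np.random.default_rng(2024)
        for rep in range(100):
            n = int(rng.integers(6, 9))
            M = rng.random((n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 1.0)
            assert pac(M) == pytest.approx(naive_pac(M), abs=1e-12)
            for K in (2, 3):
                for part in set_partitions(list(range(n)), K):
                    labels = partition_to_labels(part, n)
                    cc, _ = contrast_criterion(M, labels)
                    assert cc == pytest.approx(naive_cc(M, labels), abs=1e-12)
                    pi = core_probabilities(M, labels)
                    np.testing.assert_allclose(pi, naive_pi(M, labels),
                                               atol=1e-12, equal_nan=True)
                    per, overall = pcc(pi, labels)
                    n_per, n_overall = naive_pcc(M, labels)
                    np.testing.assert_allclose(per, n_per, atol=1e-12)
                    assert overall == pytest.approx(n_overall, abs=1e-12)
                    assert consensus_score(M, labels) == pytest.approx(
                        naive_cs(M, labels), abs=1e-12)

    def test_cs_equals_mean_of_cc_within_terms(self, rng):
        """CS is exactly the unweighted mean of the contrast criterion's
        within-cluster terms: CC = CS - mean(between-terms)."""
        M = rng.random((10, 10))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        labels = np.array([1] * 4 + [2] * 3 + [3] * 3)
        cs = consensus_score(M, labels)
        cc, per = contrast_criterion(M, labels)
        between = []
        for k in (1, 2, 3):
            mask = labels == k
            between.append(M[np.ix_(mask, ~mask)].mean())
        assert cs == pytest.approx(cc + np.mean(between), abs=1e-12)


class TestPacCs:
    def test_ideal_blocks(self, blocks_3x4):
        M, labels = blocks_3x4
        assert pac(M) == 0.0
        assert consensus_score(M, labels) == 1.0

    def test_all_ambiguous(self):
        M = np.full((6, 6), 0.5)
        np.fill_diagonal(M, 1.0)
        assert pac(M) == 1.0

    def test_constant_matrix_cs_is_one_over_k(self):
        for K in (2, 4):
            M = np.full((8, 8), 1.0 / K)
            np.fill_diagonal(M, 1.0)
            labels = np.repeat(np.arange(1, K + 1), 8 // K)
            assert consensus_score(M, labels) == pytest.approx(1.0 / K)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            pac(np.eye(3), lower=0.9, upper=0.1)

    def test_cdf_delta_auc_flags_true_k(self):
        """The CDF area stops growing once K reaches the true block count."""
        M3, _ = ideal_block_matrix([5, 5, 5])
        noisy = {}
        rng = np.random.default_rng(0)
        for K in (2, 3, 4):
            jitter = rng.normal(0, 0.02, M3.shape)
            jitter = (jitter + jitter.T) / 2
            base = M3 if K >= 3 else np.where(M3 > 0, 1.0, 0.45)
            noisy[K] = np.clip(base + jitter, 0, 1)
        deltas = cdf_delta_auc(noisy)
        assert deltas.loc[3] > deltas.loc[4]


class TestSelectOptimal:
    def test_argmax_with_tiebreaks(self):
        grid = pd.DataFrame({
            "K": [2, 3, 4, 3],
            "rho": [0.1, 0.1, 0.1, 0.2],
            "CC": [0.5, 0.8, 0.8, 0.3],
            "PCC": [0.9, 0.7, 0.8, 0.2],
            "PAC": [0.1] * 4,
            "CS": [0.5] * 4,
        })
        sel = select_optimal(grid)
        # CC tie between (K=3, PCC=0.7) and (K=4, PCC=0.8): larger PCC wins
        assert (sel.selected_K, sel.selected_rho) == (4, 0.1)

    def test_single_row_grid(self):
        grid = pd.DataFrame({"K": [3], "rho": [0.3], "CC": [0.4], "PCC": [0.5],
                             "PAC": [0.2], "CS": [0.6]})
        sel = select_optimal(grid)
        assert (sel.selected_K, sel.selected_rho) == (3, 0.3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_optimal(pd.DataFrame(columns=["K", "rho", "CC", "PCC"]))


class TestStandardIndices:
    def test_separated_blobs_limits(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(50, 0.1, (20, 2))])
        labels = np.repeat([1, 2], 20)
        idx = standard_indices(labels, X=X)
        assert idx["silhouette"] > 0.95
        assert idx["dunn"] > 10
        assert idx["calinski_harabasz"] > 1000
        assert idx["davies_bouldin"] < 0.1
        assert idx["point_biserial"] < -0.9

    def test_calinski_harabasz_hand_computed(self):
        # four 1-d points, two clusters {0, 2}, {10, 12}
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        labels = np.array([1, 1, 2, 2])
        # centroids 1 and 11, grand mean 6: B = 2*25+2*25 = 100, W = 4*1 = 4
        # CH = (B/(K-1)) / (W/(N-K)) = 100 / 2 = 50
        idx = standard_indices(labels, X=X)
        assert idx["calinski_harabasz"] == pytest.approx(50.0)

    def test_duplicate_points_no_crash(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        idx = standard_indices(np.array([1, 1, 2, 2]), X=X)
        assert np.isfinite(idx["davies_bouldin"])

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            standard_indices(np.ones(4, dtype=int), X=np.arange(8.0).reshape(4, 2))

    def test_distance_only_route(self, rng):
        M, labels = ideal_block_matrix([5, 5])
        D = 1.0 - M
        np.fill_diagonal(D, 0.0)
        idx = standard_indices(labels, D=D)
        assert idx["silhouette"] == pytest.approx(1.0)
        assert "calinski_harabasz" not in idx


class TestPairwiseClusterTests:
    @staticmethod
    def _cohort(rng, shift=0.0, n=60):
        half = n // 2
        cont = np.concatenate([rng.normal(0, 1, half), rng.normal(shift, 1, half)])
        binary = rng.integers(0, 2, n).astype(float)
        df = pd.DataFrame({"score": cont, "flag": binary},
                          index=[f"s{i}" for i in range(n)])
        meta = [VariableMeta("score", CONTINUOUS, control_mean=0, control_sd=1),
                VariableMeta("flag", CATEGORICAL, control_freq=0.5)]
        labels = np.repeat([1, 2], half)
        return CohortTable(df, meta), labels

    def test_planted_shift_detected(self, rng):
        t, labels = self._cohort(rng, shift=2.0, n=200)
        long, summary = pairwise_cluster_tests(t, labels)
        row = long[long.variable == "score"].iloc[0]
        assert row.q < 0.05 and row.significant
        assert 0 <= summary.loc[1, 2] <= 1

    def test_chi_square_and_fisher_routes(self, rng):
        n = 40
        flag = np.array([1] * 18 + [0] * 2 + [0] * 18 + [1] * 2, dtype=float)
        rare = np.array([1] * 2 + [0] * 18 + [0] * 20, dtype=float)
        df = pd.DataFrame({"common": flag, "rare": rare},
                          index=[f"s{i}" for i in range(n)])
        meta = [VariableMeta("common", CATEGORICAL), VariableMeta("rare", CATEGORICAL)]
        long, _ = pairwise_cluster_tests(CohortTable(df, meta), np.repeat([1, 2], 20))
        assert set(long.test) <= {"chi2", "fisher"}
        assert "fisher" in set(long.test)  # small expected counts fall back

    def test_constant_variable_skipped_with_warning(self, rng, caplog):
        t, labels = self._cohort(rng, shift=1.0)
        vals = t.values.copy()
        vals["score"] = 1.0
        with caplog.at_level("WARNING", logger="phenoclust"):
            long, _ = pairwise_cluster_tests(CohortTable(vals, t.meta), labels)
        assert "constant variable" in caplog.text
        assert "score" not in set(long.variable)

    def test_tiny_cluster_skipped(self, rng, caplog):
        t, _ = self._cohort(rng)
        labels = np.array([1, 1, 2] + [3] * 57)
        with caplog.at_level("WARNING", logger="phenoclust"):
            long, _ = pairwise_cluster_tests(t, labels)
        assert "n < 3" in caplog.text

    def test_single_cluster_rejected(self, rng):
        t, _ = self._cohort(rng)
        with pytest.raises(ValueError):
            pairwise_cluster_tests(t, np.ones(60, dtype=int))


class TestImproverFlags:
    def test_boundary_inclusive_and_directions(self):
        base = np.array([8.0, 10.0, 12.0])      # SD exactly 2
        assert np.std(base, ddof=1) == 2.0
        follow = np.array([7.0, 10.0, 13.0])    # improve by exactly 0.5 SD / none / worse
        flags = improver_flags(base, follow)
        assert flags.tolist() == [True, False, False]

    def test_zero_baseline_sd_rejected(self):
        with pytest.raises(ValueError):
            improver_flags([5.0, 5.0, 5.0], [4.0, 4.0, 4.0])
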