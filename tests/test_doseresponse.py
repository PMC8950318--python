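"""Selection gates, clustering, Davies-Bouldin and group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from catechoflux import (
    SelectionThresholds,
    SimulationConfig,
    UndefinedCorrelationError,
    ValidationError,
    cluster_profiles,
    davies_bouldin,
    encode_dose,
    log2_fold_change,
    mann_whitney_u,
    optimal_partition,
    pearson_r,
    responder_profiles,
    select_responders,
    simulate_feature_table,
    wald_slope_test,
)
from conftest import make_table


class TestEncodeDose:
    @pytest.mark.parametrize(
        "doses, expected",
        [((0, 0.5, 5, 50), (0, 1, 2, 3)), ((0, 0.5), (0, 1)), ((0, 50, 0.5), (0, 2, 1))],
    )
    def test_ordinal(self, doses, expected):
        np.testing.assert_array_equal(encode_dose(doses), expected)

    def test_raw_is_identity(self):
        np.testing.assert_array_equal(encode_dose([0, 0.5, 5], "raw"), [0, 0.5, 5])

    def test_log10_uses_delta_offset(self):
        out = encode_dose([0.0, 0.5], "log10", delta=0.05)
        np.testing.assert_allclose(out, np.log10([0.05, 0.55]))

    def test_unknown_encoding_rejected(self):
        with pytest.raises(ValidationError):
            encode_dose([0, 1], "quadratic")


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(4.0)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_from_definition_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 2.0, 4.0])
        # oracle: plain covariance over product of standard deviations
        r_oracle = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        t = r_oracle * math.sqrt(2) / math.sqrt(1 - r_oracle**2)
        p_oracle = 2 * scipy.stats.t.sf(abs(t), df=2)
        r, p = pearson_r(x, y)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWaldSlope:
    def test_constant_response_slope_zero_p_one(self):
        slope, p = wald_slope_test([0.0, 1.0, 2.0, 3.0], [5.0, 5.0, 5.0, 5.0])
        assert slope == 0.0
        assert p == pytest.approx(1.0)

    def test_exact_line_p_collapses(self):
        _, p = wald_slope_test([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert p < 1e-9

    def test_matches_closed_form_ols_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 2.0, 4.0])
        sxx = ((x - x.mean()) ** 2).sum()
        slope_o = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - (y.mean() + slope_o * (x - x.mean()))
        se = math.sqrt((resid**2).sum() / (len(x) - 2) / sxx)
        p_o = 2 * scipy.stats.t.sf(abs(slope_o / se), df=len(x) - 2)
        slope, p = wald_slope_test(x, y)
        assert slope == pytest.approx(slope_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)


def _exact_mw_p_less(a, b):
    """Enumerate all group assignments of the pooled sample (oracle).

    U counts pairs where the first group exceeds the second; the one-sided
    'less' p is the fraction of assignments with U at or below the observed.
    """

    def u_stat(grp_a, grp_b):
        return sum(1 for x in grp_a for y in grp_b if x > y) + 0.5 * sum(
            1 for x in grp_a for y in grp_b if x == y
        )

    pooled = list(a) + list(b)
    u_obs = u_stat(a, b)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), len(a)):
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if u_stat([pooled[i] for i in combo], rest) <= u_obs:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_groups_exact_twentieth(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0
        assert p == pytest.approx(1 / 20)

    def test_matches_enumeration_oracle(self):
        a, b = [1.2, 3.4, 2.2, 5.0], [4.1, 6.3, 7.0]
        _, p = mann_whitney_u(a, b, alternative="less")
        assert p == pytest.approx(_exact_mw_p_less(a, b))

    def test_identical_groups_u_half(self):
        u, _ = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n1*n2/2

    def test_swapping_groups_reflects_u(self):
        a, b = [1.0, 5.0, 2.0], [3.0, 8.0, 9.0, 4.0]
        u_ab, p_ab = mann_whitney_u(a, b)
        u_ba, p_ba = mann_whitney_u(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


def _ramp_table(lfc_by_dose, time=24.0):
    """One feature whose log2 response follows lfc_by_dose exactly."""
    doses, lfcs = zip(*lfc_by_dose.items())
    rows, d, t, donors = [], [], [], []
    for dose, lfc in lfc_by_dose.items():
        for donor in ("d1", "d2", "d3"):
            rows.append([100.0 * 2**lfc])
            d.append(dose)
            t.append(time)
            donors.append(donor)
    # a matching reference time point is required at 4 h as well
    for dose in doses:
        for donor in ("d1", "d2", "d3"):
            rows.append([100.0])
            d.append(dose)
            t.append(4.0)
            donors.append(donor)
    return make_table(rows, d, t, donors)


class TestSelectResponders:
    def test_flat_table_selects_nothing(self):
        table = _ramp_table({0.0: 0, 0.5: 0, 5.0: 0, 50.0: 0})
        fc = log2_fold_change(table, pseudo=0.0)
        res = select_responders(fc, table, pseudo=0.0)
        assert len(res.selected) == 0

    def test_planted_ordinal_ramp_selected_with_unit_gates(self):
        # lfc (0, 1, 2, 3) across ordinal doses at T24, zero noise:
        # |lfc| = 3 > 1, r = 1 > 0.8, p < 0.05 at T24 only
        table = _ramp_table({0.0: 0, 0.5: 1, 5.0: 2, 50.0: 3})
        fc = log2_fold_change(table, pseudo=0.0)
        res = select_responders(fc, table, pseudo=0.0)
        assert list(res.selected) == ["F0"]
        assert bool(res.stats.loc["F0", "selected_t24"])
        assert not bool(res.stats.loc["F0", "selected_t4"])
        assert res.stats.loc["F0", "max_abs_lfc_t24"] == pytest.approx(3.0)
        assert res.stats.loc["F0", "r_t24"] == pytest.approx(1.0)

    def test_decreasing_responder_selected_via_absolute_r(self):
        table = _ramp_table({0.0: 0, 0.5: -1, 5.0: -2, 50.0: -3})
        fc = log2_fold_change(table, pseudo=0.0)
        res = select_responders(fc, table, pseudo=0.0)
        assert list(res.selected) == ["F0"]
        assert res.stats.loc["F0", "r_t24"] == pytest.approx(-1.0)

    def test_selection_monotone_in_thresholds(self):
        cfg = SimulationConfig(n_features=80, n_responders=15, seed=11)
        table, _ = simulate_feature_table(cfg)
        fc = log2_fold_change(table)
        strict = select_responders(fc, table, SelectionThresholds(lfc=1.2, r=0.9))
        loose = select_responders(fc, table, SelectionThresholds(lfc=0.8, r=0.7))
        assert set(strict.selected) <= set(loose.selected)

    def test_null_data_false_positive_rate_below_alpha(self):
        rates = []
        for seed in range(5):
            cfg = SimulationConfig(n_features=120, n_responders=0, seed=seed)
            table, _ = simulate_feature_table(cfg)
            fc = log2_fold_change(table)
            res = select_responders(fc, table)
            rates.append(len(res.selected) / cfg.n_features)
        assert np.mean(rates) < 0.05


def _brute_force_complete_linkage(profiles):
    """Agglomerate by hand: merge the pair with smallest max cosine distance."""

    def cosd(u, v):
        return 1 - np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))

    clusters = [frozenset([i]) for i in range(len(profiles))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = max(cosd(profiles[i], profiles[j]) for i in a for j in b)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append((a | b, d))
    return merges


class TestClustering:
    def test_parallel_profiles_merge_first_at_zero_distance(self):
        profiles = np.array([[1.0, 2.0], [2.0, 4.0], [5.0, -1.0], [0.0, 3.0]])
        Z = cluster_profiles(profiles)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_profiles_distance_one(self):
        Z = cluster_profiles(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert Z[0, 2] == pytest.approx(1.0)

    def test_merge_order_matches_brute_force_oracle(self):
        profiles = np.array(
            [[1.0, 0.1], [0.9, 0.3], [-0.2, 1.0], [-1.0, -0.4]], dtype=float
        )
        Z = cluster_profiles(profiles)
        oracle = _brute_force_complete_linkage(profiles)
        # translate the scipy linkage into merged member-sets
        members = {i: frozenset([i]) for i in range(4)}
        for row_i, row in enumerate(Z):
            a, b = int(row[0]), int(row[1])
            merged = members[a] | members[b]
            members[4 + row_i] = merged
            assert merged == oracle[row_i][0]
            assert row[2] == pytest.approx(oracle[row_i][1], abs=1e-12)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            cluster_profiles(np.array([[0.0, 0.0], [1.0, 2.0]]))

    def test_permutation_equivariant_labels(self):
        cfg = SimulationConfig(n_features=21, n_responders=21, seed=3)
        table, truth = simulate_feature_table(cfg)
        fc = log2_fold_change(table)
        profiles = responder_profiles(fc, truth.responder_ids)
        part = optimal_partition(profiles, range(2, 8))
        perm = np.random.default_rng(0).permutation(len(profiles))
        part_p = optimal_partition(profiles.iloc[perm], range(2, 8))
        # same features end up together regardless of row order
        def partition_sets(labels):
            return {frozenset(labels.index[labels == c]) for c in labels.unique()}

        assert partition_sets(part.labels) == partition_sets(part_p.labels)


class TestDaviesBouldin:
    def test_hand_computed_two_cluster_value(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert davies_bouldin(pts, [0, 0, 1, 1]) == pytest.approx(0.1)

    def test_coincident_clusters_diverge(self):
        pts = np.array([[0.0], [1.0], [0.0], [1.0]])
        with pytest.warns(UserWarning, match="coincident"):
            assert davies_bouldin(pts, [0, 0, 1, 1]) == np.inf

    def test_duplicating_points_leaves_index_unchanged(self, rng):
        pts = rng.normal(size=(12, 3))
        labels = np.repeat([0, 1, 2], 4)
        doubled = davies_bouldin(np.vstack([pts, pts]), np.concatenate([labels, labels]))
        assert doubled == pytest.approx(davies_bouldin(pts, labels))

    def test_matches_definition_and_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import davies_bouldin_score

        for _ in range(10):
            n = int(rng.integers(6, 20))
            pts = rng.normal(size=(n, 2))
            labels = rng.integers(0, 3, size=n)
            if np.unique(labels).size < 2:
                continue
            # from-definition recomputation, written independently
            uniq = np.unique(labels)
            cents = {u: pts[labels == u].mean(0) for u in uniq}
            scat = {
                u: np.mean([np.linalg.norm(p - cents[u]) for p in pts[labels == u]])
                for u in uniq
            }
            db_terms = []
            for u in uniq:
                db_terms.append(
                    max(
                        (scat[u] + scat[v]) / np.linalg.norm(cents[u] - cents[v])
                        for v in uniq
                        if v != u
                    )
                )
            expected = float(np.mean(db_terms))
            got = davies_bouldin(pts, labels)
            assert got == pytest.approx(expected, abs=1e-9)
            assert got == pytest.approx(davies_bouldin_score(pts, labels), abs=1e-9)

    def test_singleton_partition_rejected(self):
        with pytest.raises(ValidationError):
            davies_bouldin(np.zeros((3, 2)), [0, 0, 0])


class TestOptimalPartition:
    def test_three_separated_groups_zero_noise(self):
        base = np.array([[4.0, 0.0], [0.0, 4.0], [-4.0, -4.0]])
        profiles = np.repeat(base, 4, axis=0) + np.tile(
            np.linspace(-0.01, 0.01, 4)[:, None], (3, 2)
        )
        part = optimal_partition(profiles, range(2, 8))
        assert part.k == 3

    def test_single_candidate_k_returned(self):
        profiles = np.random.default_rng(1).normal(size=(10, 3))
        part = optimal_partition(profiles, [2])
        assert part.k == 2

    def test_empty_k_range_rejected(self):
        with pytest.raises(ValidationError):
            optimal_partition(np.eye(5), [])

    def test_planted_seven_archetypes_recovered(self):
        cfg = SimulationConfig(
            n_features=49,
            n_responders=49,
            noise_sd=0.1,
            seed=2,
            archetype_weights=tuple([1 / 7] * 7),
        )
        table, truth = simulate_feature_table(cfg)
        fc = log2_fold_change(table)
        part = optimal_partition(responder_profiles(fc, truth.responder_ids), range(2, 13))
        assert part.k == 7
        # clusters coincide with the planted archetypes
        arch = pd.Series(truth.archetype_of)
        crosstab = pd.crosstab(arch, part.labels[arch.index])
        assert (crosstab.gt(0).sum(axis=1) == 1).all()
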