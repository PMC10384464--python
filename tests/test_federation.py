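"""Server-side federation: aggregation, node selection, feature ranking, loop."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fdqp import (
    AttributeFate,
    AttributeMeasures,
    CohortSpec,
    FederationConfig,
    FederationError,
    QualityDimension,
    aggregate_profiles,
    build_edge_profile,
    combine_ranks,
    corrupt_node,
    decide_attribute_fate,
    federated_feature_selection,
    generate_cohort,
    make_baseline_profile,
    missing_value_vector,
    run_federation,
    select_nodes,
    standard_corrupted_scenario,
)
from fdqp.federation import _permutation_rank


def _edge_profile(node_id, rows, per_attr_missing, baseline):
    p = baseline.copy()
    from fdqp import ProfileRole

    p.role = ProfileRole.EDGE
    p.node_id = node_id
    p.row_count = rows
    p.measures = {
        name: AttributeMeasures(
            observed_min=float(i), observed_max=float(i + 10), mode=float(i),
            skewness=0.0, missing_fraction=mf, completeness=1.0 - mf,
            unique_fraction=0.5, outlier_fraction=0.01, cv=0.2,
        )
        for i, (name, mf) in enumerate(per_attr_missing.items())
    }
    return p


class TestMissingValueVector:
    @pytest.mark.parametrize("mf,expected", [(0.10, 1), (0.40, 0), (0.70, 0)])
    def test_indicator_against_30pct_missing_ceiling(
        self, three_attr_profile, mf, expected
    ):
        # completeness tolerance 0.70 -> missing-fraction ceiling 0.30
        p = _edge_profile(
            "n", 100,
            {"heart_rate": mf, "variability": 0.0, "accelerations": 0.0},
            three_attr_profile,
        )
        v = missing_value_vector(p)
        assert v.mv["heart_rate"] == mf
        assert v.indicator["heart_rate"] == expected


class TestAggregation:
    def test_single_edge_aggregates_to_itself(self, three_attr_profile):
        e = _edge_profile(
            "n1", 100,
            {"heart_rate": 0.1, "variability": 0.2, "accelerations": 0.0},
            three_attr_profile,
        )
        fed = aggregate_profiles([e])
        for name in ("heart_rate", "variability", "accelerations"):
            assert fed.measures[name] == e.measures[name]
        assert fed.row_count == 100

    def test_min_max_and_weighted_mean_fields(self, three_attr_profile):
        attrs = ("heart_rate", "variability", "accelerations")
        e1 = _edge_profile("n1", 100, {a: 0.1 for a in attrs}, three_attr_profile)
        e2 = _edge_profile("n2", 300, {a: 0.3 for a in attrs}, three_attr_profile)
        e1.measures["heart_rate"].observed_min = 3.0
        e1.measures["heart_rate"].observed_max = 9.0
        e2.measures["heart_rate"].observed_min = 5.0
        e2.measures["heart_rate"].observed_max = 7.0
        fed = aggregate_profiles([e1, e2])
        m = fed.measures["heart_rate"]
        assert m.observed_min == 3.0 and m.observed_max == 9.0
        # (100*0.1 + 300*0.3) / 400
        assert m.missing_fraction == pytest.approx(0.25)
        assert m.completeness == pytest.approx(0.75)

    def test_permutation_invariant_in_edge_order(self, three_attr_profile):
        attrs = ("heart_rate", "variability", "accelerations")
        edges = [
            _edge_profile(f"n{i}", 50 * (i + 1), {a: 0.05 * i for a in attrs},
                          three_attr_profile)
            for i in range(4)
        ]
        a = aggregate_profiles(edges)
        b = aggregate_profiles(edges[::-1])
        assert a.measures == b.measures
        assert a.row_count == b.row_count

    def test_mismatched_attributes_rejected(self, three_attr_profile):
        e1 = _edge_profile("n1", 10, {"heart_rate": 0, "variability": 0,
                                      "accelerations": 0}, three_attr_profile)
        e2 = e1.copy()
        e2.attributes = e2.attributes[:2]
        with pytest.raises(FederationError):
            aggregate_profiles([e1, e2])
        with pytest.raises(FederationError):
            aggregate_profiles([])


class TestAttributeFate:
    @pytest.mark.parametrize(
        "indicator,weight,fate",
        [
            (0, 0.6, AttributeFate.FORCE_IMPUTE),
            (0, 0.05, AttributeFate.DROP),
            (1, 0.05, AttributeFate.RETAIN),
            (1, 0.3, AttributeFate.RETAIN),
        ],
    )
    def test_weight_tolerance_arbitration(self, indicator, weight, fate):
        assert decide_attribute_fate(indicator, weight, FederationConfig()) is fate


class TestNodeSelection:
    def test_corrupted_node_eliminated_exactly(self):
        corrupted, _, manifest = standard_corrupted_scenario(3)
        baseline = make_baseline_profile(list(corrupted[0].table.columns))
        profiles = [build_edge_profile(e, baseline) for e in corrupted]
        selected, eliminated, _ = select_nodes(profiles)
        assert [p.node_id for p in eliminated] == [manifest.corrupted_node]
        assert len(selected) == 4

    def test_all_clean_nodes_survive(self):
        clean = generate_cohort(CohortSpec(seed=5, rows_per_edge=120))
        baseline = make_baseline_profile(list(clean[0].table.columns))
        selected, eliminated, _ = select_nodes(
            [build_edge_profile(e, baseline) for e in clean]
        )
        assert eliminated == []

    def test_elimination_flips_once_across_severity_sweep(self):
        edge = generate_cohort(CohortSpec(seed=6, rows_per_edge=200, n_edges=1))[0]
        baseline = make_baseline_profile(list(edge.table.columns))
        outcomes = []
        for severity in (0.05, 0.15, 0.25, 0.35, 0.5, 0.7):
            damaged = corrupt_node(edge, severity, seed=6)
            report_pass = build_edge_profile(damaged, baseline)
            from fdqp import check_dimension_tolerances

            outcomes.append(check_dimension_tolerances(report_pass).overall_pass)
        flips = sum(
            outcomes[i] != outcomes[i + 1] for i in range(len(outcomes) - 1)
        )
        assert outcomes[0] and not outcomes[-1] and flips == 1

    def test_worsening_never_rescues(self, three_attr_profile):
        attrs = ("heart_rate", "variability", "accelerations")
        bad = _edge_profile("bad", 100, {a: 0.45 for a in attrs},
                            three_attr_profile)
        worse = _edge_profile("bad", 100, {a: 0.60 for a in attrs},
                              three_attr_profile)
        ok = _edge_profile("ok", 100, {a: 0.05 for a in attrs},
                           three_attr_profile)
        _, elim1, _ = select_nodes([ok, bad])
        _, elim2, _ = select_nodes([ok, worse])
        assert [p.node_id for p in elim1] == ["bad"]
        assert [p.node_id for p in elim2] == ["bad"]

    def test_all_eliminated_raises(self, three_attr_profile):
        attrs = ("heart_rate", "variability", "accelerations")
        bad = _edge_profile("bad", 100, {a: 0.8 for a in attrs},
                            three_attr_profile)
        with pytest.raises(FederationError):
            select_nodes([bad])


class TestFeatureSelection:
    def test_printed_rank_table_example(self):
        # the worked rank-aggregation example: per-criterion ranks for
        # features A-E already aggregated across nodes
        ranks = pd.DataFrame(
            {
                "value_rank": [3, 5, 9, 1, 7],
                "outlier_rank": [1, 4, 8, 2, 23],
                "missing_rank": [8, 7, 2, 5, 13],
            },
            index=list("ABCDE"),
        )
        table = combine_ranks(ranks)
        assert table.table["federated_rank"].tolist() == [12, 16, 19, 8, 43]
        assert table.ordering == ["D", "A", "B", "C", "E"]
        assert table.ordering[0] == "D" and table.ordering[-1] == "E"

    def test_single_feature_gets_rank_three(self):
        stats = pd.DataFrame(
            {"feature_value": [4.2], "outlier_pct": [0.1], "missing_pct": [0.0]},
            index=["only"],
        )
        table = federated_feature_selection([stats], feature_tol=1)
        assert table.table.loc["only", ["value_rank", "outlier_rank",
                                        "missing_rank"]].tolist() == [1, 1, 1]
        assert table.table.loc["only", "federated_rank"] == 3
        assert table.selected == ["only"]

    def test_matches_brute_force_rank_sum_oracle(self):
        rng = np.random.default_rng(17)
        features = [f"g{i}" for i in range(20)]
        per_node = []
        for _ in range(4):
            per_node.append(
                pd.DataFrame(
                    {
                        "feature_value": rng.integers(0, 5, 20).astype(float),
                        "outlier_pct": rng.integers(0, 3, 20) / 10,
                        "missing_pct": rng.integers(0, 3, 20) / 10,
                    },
                    index=features,
                )
            )  # coarse grids force rank ties
        table = federated_feature_selection(per_node, feature_tol=10)
        agg = sum(df for df in per_node)
        # independent oracle: scipy ordinal ranking equals stable-sort ranks
        expect_value = sps.rankdata(-agg["feature_value"], method="ordinal")
        expect_out = sps.rankdata(agg["outlier_pct"], method="ordinal")
        expect_miss = sps.rankdata(agg["missing_pct"], method="ordinal")
        assert table.table["value_rank"].tolist() == expect_value.tolist()
        assert table.table["outlier_rank"].tolist() == expect_out.tolist()
        assert table.table["missing_rank"].tolist() == expect_miss.tolist()
        fed = expect_value + expect_out + expect_miss
        assert table.table["federated_rank"].tolist() == fed.tolist()
        expected_order = sorted(
            range(20),
            key=lambda i: (fed[i], expect_value[i], expect_out[i],
                           expect_miss[i], i),
        )
        assert table.ordering == [features[i] for i in expected_order]
        assert table.selected == table.ordering[:10]

    def test_rank_columns_are_permutations(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 4, 30).astype(float)
        ranks = _permutation_rank(values, ascending=True)
        assert sorted(ranks) == list(range(1, 31))

    def test_inconsistent_feature_sets_rejected(self):
        a = pd.DataFrame(
            {"feature_value": [1.0], "outlier_pct": [0.0], "missing_pct": [0.0]},
            index=["x"],
        )
        b = a.rename(index={"x": "y"})
        with pytest.raises(FederationError):
            federated_feature_selection([a, b], feature_tol=1)


class TestFederationLoop:
    def _run(self, seed, **kwargs):
        corrupted, _, _ = standard_corrupted_scenario(
            seed, CohortSpec(seed=seed, rows_per_edge=150)
        )
        baseline = make_baseline_profile(list(corrupted[0].table.columns))
        config = FederationConfig(seed=seed, **kwargs)
        return run_federation(corrupted, baseline, config)

    def test_zero_target_stops_after_one_round(self):
        result = self._run(2, q_tol=0.0, max_rounds=5)
        assert len(result.history) == 1
        assert result.profile.version == 1

    def test_versions_increment_per_round(self):
        result = self._run(2, q_tol=1.0, max_rounds=3)
        assert [r.version for r in result.history] == [1, 2, 3]

    def test_deterministic_under_seed(self):
        a = self._run(4, q_tol=1.0, max_rounds=2)
        b = self._run(4, q_tol=1.0, max_rounds=2)
        assert [r.federated_accuracy for r in a.history] == [
            r.federated_accuracy for r in b.history
        ]
        assert [r.selected_features for r in a.history] == [
            r.selected_features for r in b.history
        ]
        assert a.profile == b.profile

    def test_corrupted_node_absent_from_every_round(self):
        result = self._run(3, q_tol=1.0, max_rounds=3)
        assert result.history[0].eliminated == ["node3"]
        for record in result.history:
            assert "node3" not in record.per_edge_accuracy
        assert all(e.node_id != "node3" for e in result.enriched)

    def test_delta_exchange_after_first_round(self):
        result = self._run(5, q_tol=1.0, max_rounds=3)
        assert result.history[0].delta_fields is None
        assert all(r.delta_fields is not None for r in result.history[1:])

    def test_too_few_edges_rejected(self, three_attr_profile):
        with pytest.raises(FederationError):
            run_federation([], three_attr_profile)


class TestScalingShape:
    def test_aggregation_grows_subquadratically_in_edges(self, three_attr_profile):
        import time

        attrs = ("heart_rate", "variability", "accelerations")

        def timed(n_edges):
            edges = [
                _edge_profile(f"n{i}", 100, {a: 0.1 for a in attrs},
                              three_attr_profile)
                for i in range(n_edges)
            ]
            best = np.inf
            for _ in range(3):
                t0 = time.perf_counter()
                for _ in range(5):
                    aggregate_profiles(edges)
                best = min(best, time.perf_counter() - t0)
            return best

        t_small, t_big = timed(4), timed(32)
        # 8x the edges: linear predicts 8x, quadratic 64x
        assert t_big / t_small < 32

    def test_ranking_grows_subquadratically_in_features(self):
        import time

        rng = np.random.default_rng(0)

        def timed(n):
            stats = pd.DataFrame(
                {
                    "feature_value": rng.random(n),
                    "outlier_pct": rng.random(n),
                    "missing_pct": rng.random(n),
                },
                index=[f"f{i}" for i in range(n)],
            )
            best = np.inf
            for _ in range(3):
                t0 = time.perf_counter()
                federated_feature_selection([stats], feature_tol=n)
                best = min(best, time.perf_counter() - t0)
            return best

        t_small, t_big = timed(500), timed(8000)
        # 16x the features: N log N predicts ~21x, quadratic 256x
        assert t_big / t_small < 100
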