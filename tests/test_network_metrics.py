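"""Person-days aggregation, composition, and relation-class summaries."""

import numpy as np
import pytest

from egosupport.data_model import Dataset, build_networks
from egosupport.network_metrics import (aggregate_support,
                                        alter_interconnectedness,
                                        composition_proportions,
                                        dataset_summaries, ego_support_summary,
                                        money_received, relation_summary_graph,
                                        relation_type_summary)

from conftest import make_alter, make_ego


def one_ego_network(alters):
    ds = Dataset([make_ego("e1")], alters, [])
    return build_networks(ds)[0]


class TestAggregateSupport:
    def test_material_sum_of_mapped_days(self):
        nw = one_ego_network([
            make_alter("e1", 1, provides_material=True, material_freq="once_week"),
            make_alter("e1", 2, provides_material=True,
                       material_freq="few_times_month"),
        ])
        assert aggregate_support(nw, "material") == 6.0   # 4 + 2

    def test_no_provider_gives_zero(self):
        nw = one_ego_network([make_alter("e1", 1), make_alter("e1", 2)])
        assert aggregate_support(nw, "material") == 0.0

    def test_contact_three_daily_alters(self):
        nw = one_ego_network([make_alter("e1", i) for i in (1, 2, 3)])
        assert aggregate_support(nw, "contact") == 90.0   # 3 x 30

    def test_nonmaterial_pools_emotional_and_informational(self):
        nw = one_ego_network([
            make_alter("e1", 1, emotional_freq="once_week",
                       provides_informational=True,
                       informational_freq="few_times_month"),
            make_alter("e1", 2),
        ])
        assert aggregate_support(nw, "nonmaterial") == 4 + 2 + 1

    def test_unknown_kind_rejected(self):
        nw = one_ego_network([make_alter("e1", 1), make_alter("e1", 2)])
        with pytest.raises(ValueError, match="kind"):
            aggregate_support(nw, "spiritual")

    def test_additive_under_alter_split(self):
        """Splitting one alter's support across two fictitious alters leaves
        the ego total unchanged."""
        whole = one_ego_network([
            make_alter("e1", 1, provides_material=True, material_freq="once_week",
                       emotional_freq="few_times_month"),
            make_alter("e1", 2),
        ])
        split = one_ego_network([
            make_alter("e1", 1, provides_material=True, material_freq="once_week",
                       provides_emotional=False, emotional_freq=None),
            make_alter("e1", 2, emotional_freq="few_times_month"),
            make_alter("e1", 3),   # carries the original once_month emotional tie
        ])
        for kind in ("nonmaterial", "material"):
            assert aggregate_support(whole, kind) == aggregate_support(split, kind)


class TestStructure:
    def test_complete_graph_density_one(self):
        nw = one_ego_network([make_alter("e1", i) for i in (1, 2, 3)])
        assert alter_interconnectedness(nw) == 1.0

    def test_one_missing_edge(self, tiny_dataset):
        nw = build_networks(tiny_dataset)[0]
        assert alter_interconnectedness(nw) == pytest.approx(2 / 3)

    def test_composition_first_degree(self):
        nw = one_ego_network([
            make_alter("e1", 1), make_alter("e1", 2),
            make_alter("e1", 3, relation="significant_other"),
        ])
        assert composition_proportions(nw)["first_degree"] == 1.0

    def test_composition_mixed(self):
        nw = one_ego_network([make_alter("e1", 1),
                              make_alter("e1", 2, relation="neighbour")])
        props = composition_proportions(nw)
        assert props == {"first_degree": 0.5, "other_family": 0.0, "other": 0.5}
        assert sum(props.values()) == pytest.approx(1.0)

    def test_dataset_medians_match_recount(self, survey_100):
        nws = build_networks(survey_100)
        med = np.median([composition_proportions(nw)["first_degree"]
                         for nw in nws])
        recount = np.median([
            np.mean([a.relation in ("child", "parent", "significant_other")
                     for a in nw.alters]) for nw in nws])
        assert med == recount


class TestMoney:
    def test_total_and_purposes(self):
        nw = one_ego_network([
            make_alter("e1", 1, provides_material=True, material_freq="once_week",
                       material_kinds=frozenset({"money"}), money_amount=50000,
                       money_purposes=frozenset({"clinic_pharmacy_fees",
                                                 "transport_fare"})),
            make_alter("e1", 2, provides_material=True,
                       material_freq="once_month",
                       material_kinds=frozenset({"money"}), money_amount=47620,
                       money_purposes=frozenset({"transport_fare"})),
        ])
        total, purposes = money_received(nw)
        assert total == 97620
        assert purposes == {"clinic_pharmacy_fees": 1, "transport_fare": 2,
                            "other": 0}

    def test_no_money_gives_zero(self):
        nw = one_ego_network([make_alter("e1", 1), make_alter("e1", 2)])
        assert money_received(nw) == (0, {"clinic_pharmacy_fees": 0,
                                          "transport_fare": 0, "other": 0})


class TestEgoSummary:
    def test_monthly_flags_consistent(self, survey_100):
        for s in dataset_summaries(survey_100):
            assert s.monthly_nonmaterial == (s.nonmaterial_days >= 1)
            assert s.monthly_material == (s.material_days >= 1)
            assert s.nonmaterial_days >= 0 and s.material_days >= 0
            assert 0 <= s.prop_first_degree <= 1
            assert 0 <= s.alter_density <= 1

    def test_summary_fields(self, tiny_dataset):
        nw = build_networks(tiny_dataset)[0]
        s = ego_support_summary(nw)
        assert s.n_alters == 3
        assert s.money_total == 50000
        assert s.material_days == 4.0
        assert s.monthly_material


class TestRelationSummary:
    def test_single_class_forced_mapping(self):
        alters = [make_alter("e1", i, provides_material=True,
                             material_freq="once_week",
                             provides_emotional=False, emotional_freq=None)
                  for i in (1, 2)]
        ds = Dataset([make_ego("e1")], alters, [])
        summ = relation_type_summary(ds)
        assert len(summ) == 1
        s = summ[0]
        assert s.relation == "child"
        assert s.prevalence == 1.0
        assert s.prop_material == 1.0
        assert s.mean_material_days == 4.0

    def test_absent_class_omitted_and_prevalences_sum(self, survey_100):
        summ = relation_type_summary(survey_100)
        present = {a.relation for a in survey_100.alters}
        assert {s.relation for s in summ} == present
        assert sum(s.prevalence for s in summ) == pytest.approx(1.0)
        n_total = len(survey_100.alters)
        total = sum(round(s.prevalence * n_total) for s in summ)
        assert total == n_total

    def test_star_graph_export(self, survey_100):
        summ = relation_type_summary(survey_100)
        g = relation_summary_graph(summ)
        assert g.number_of_nodes() == len(summ) + 1
        assert g.degree["ego"] == len(summ)
        for s in summ:
            assert g.nodes[s.relation]["size"] == pytest.approx(s.prevalence)
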