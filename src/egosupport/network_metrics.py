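"""Ego-level and dataset-level network composition and support summaries.

Support frequencies are aggregated at the ego level as *person-days* of
contact or support received per month: the sum over alters of the recoded
event-days.  Composition statistics follow the kin grouping used throughout
the analysis: first-degree relatives (children, parents, significant
others), other family, and other ties (friends, neighbours, others).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_model import Dataset, EgoNetwork, RELATIONS, build_networks
from .recoding import dichotomize_monthly, frequency_to_days, pool_nonmaterial

__all__ = ["EgoSupportSummary", "RelationTypeSummary", "alter_support_days",
           "aggregate_support", "alter_interconnectedness",
           "composition_proportions", "money_received", "ego_support_summary",
           "relation_type_summary", "relation_summary_graph"]

FIRST_DEGREE = frozenset({"child", "parent", "significant_other"})
OTHER_FAMILY = frozenset({"other_family"})
SUPPORT_KINDS = ("nonmaterial", "material", "contact")


@dataclass
class EgoSupportSummary:
    """Per-ego aggregation of contact/support person-days and structure."""

    ego_id: str
    contact_days: float
    nonmaterial_days: float
    material_days: float
    monthly_nonmaterial: bool
    monthly_material: bool
    money_total: int
    n_alters: int
    prop_first_degree: float
    alter_density: float


@dataclass
class RelationTypeSummary:
    """Dataset-level profile of one alter relation class."""

    relation: str
    prevalence: float
    prop_nonmaterial: float
    prop_material: float
    mean_support_events: float
    mean_nonmaterial_days: float
    mean_material_days: float


def alter_support_days(alter, kind: str, frequency_map=None) -> float:
    """Event-days per month one alter contributes for the requested kind."""
    def days(freq):
        return 0.0 if freq is None else frequency_to_days(freq, frequency_map)

    if kind == "contact":
        return frequency_to_days(alter.contact_freq, frequency_map)
    if kind == "nonmaterial":
        return pool_nonmaterial(days(alter.emotional_freq),
                                days(alter.informational_freq))
    if kind == "material":
        return days(alter.material_freq)
    raise ValueError(f"unknown support kind {kind!r}; expected one of {SUPPORT_KINDS}")


def aggregate_support(network: EgoNetwork, kind: str,
                      frequency_map=None) -> float:
    """Person-days per month of the requested kind, summed over alters."""
    return float(sum(alter_support_days(a, kind, frequency_map)
                     for a in network.alters))


def alter_interconnectedness(network: EgoNetwork) -> float:
    """Fraction of alter pairs acquainted with each other (density of the
    alter–alter graph)."""
    n = network.n_alters
    if n < 2:
        raise ValueError("interconnectedness needs at least 2 alters")
    pairs = n * (n - 1) // 2
    known = sum(network.adjacency[i][j]
                for i in range(n) for j in range(i + 1, n))
    return known / pairs


def composition_proportions(network: EgoNetwork) -> dict:
    """Fractions of alters who are first-degree kin, other family, other."""
    n = network.n_alters
    if n == 0:
        raise ValueError("ego network has no alters")
    first = sum(a.relation in FIRST_DEGREE for a in network.alters)
    fam = sum(a.relation in OTHER_FAMILY for a in network.alters)
    return {"first_degree": first / n, "other_family": fam / n,
            "other": (n - first - fam) / n}


def money_received(network: EgoNetwork) -> tuple:
    """Total TSH received from the network and counts per money purpose."""
    total = 0
    purposes = {"clinic_pharmacy_fees": 0, "transport_fare": 0, "other": 0}
    for a in network.alters:
        if a.money_amount is not None:
            total += a.money_amount
        for p in a.money_purposes:
            purposes[p] += 1
    return total, purposes


def ego_support_summary(network: EgoNetwork,
                        frequency_map=None) -> EgoSupportSummary:
    nm = aggregate_support(network, "nonmaterial", frequency_map)
    mat = aggregate_support(network, "material", frequency_map)
    total, _ = money_received(network)
    return EgoSupportSummary(
        ego_id=network.ego.ego_id,
        contact_days=aggregate_support(network, "contact", frequency_map),
        nonmaterial_days=nm,
        material_days=mat,
        monthly_nonmaterial=dichotomize_monthly(nm),
        monthly_material=dichotomize_monthly(mat),
        money_total=total,
        n_alters=network.n_alters,
        prop_first_degree=composition_proportions(network)["first_degree"],
        alter_density=alter_interconnectedness(network)
        if network.n_alters >= 2 else 1.0,
    )


def relation_type_summary(dataset: Dataset, frequency_map=None) -> list:
    """Per-relation-class prevalence and support profile over all alters.

    Classes absent from the data are omitted; prevalences sum to 1.
    """
    if not dataset.alters:
        raise ValueError("empty dataset")
    n_total = len(dataset.alters)
    out = []
    for rel in RELATIONS:
        members = [a for a in dataset.alters if a.relation == rel]
        if not members:
            continue
        nm_days = [alter_support_days(a, "nonmaterial", frequency_map)
                   for a in members]
        mat_days = [alter_support_days(a, "material", frequency_map)
                    for a in members]
        out.append(RelationTypeSummary(
            relation=rel,
            prevalence=len(members) / n_total,
            prop_nonmaterial=float(np.mean(
                [a.provides_emotional or a.provides_informational
                 for a in members])),
            prop_material=float(np.mean([a.provides_material for a in members])),
            mean_support_events=float(np.mean(nm_days) + np.mean(mat_days)),
            mean_nonmaterial_days=float(np.mean(nm_days)),
            mean_material_days=float(np.mean(mat_days)),
        ))
    return out


def relation_summary_graph(summaries) -> nx.Graph:
    """Average-cluster star graph: an ego node plus one node per relation
    class, node ``size`` = prevalence, edges carrying mean support events."""
    g = nx.Graph()
    g.add_node("ego", kind="ego")
    for s in summaries:
        g.add_node(s.relation, kind="relation_class", size=s.prevalence,
                   prop_nonmaterial=s.prop_nonmaterial,
                   prop_material=s.prop_material)
        g.add_edge("ego", s.relation, mean_support_events=s.mean_support_events)
    return g


def dataset_summaries(dataset: Dataset, frequency_map=None) -> list:
    """Ego support summaries for every ego in the dataset."""
    return [ego_support_summary(nw, frequency_map)
            for nw in build_networks(dataset)]
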