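"""Shared fixtures: handcrafted micro-datasets and generated survey data."""

import pytest

from egosupport.data_model import (AlterAlterTie, AlterRecord, Dataset,
                                   EgoRecord, write_dataset)
from egosupport.synthetic_data import default_config, generate_dataset


def make_ego(ego_id="e1", **kw):
    base = dict(age=63, gender="woman", marital_status="married",
                education="primary", household_size=4,
                occupation="subsistence_farmer", ncd_prevents_work="never",
                insured=True, conditions=frozenset({"hypertension"}),
                adherent_7d=True)
    base.update(kw)
    return EgoRecord(ego_id=ego_id, **base)


def make_alter(ego_id="e1", alter_index=1, **kw):
    base = dict(relation="child", alter_gender="woman",
                alter_age_bracket="20_30", proximity="same_household",
                time_known="over_10y", contact_freq="every_day",
                provides_emotional=True, emotional_freq="once_month",
                provides_informational=False, provides_material=False,
                reciprocated_by_ego=True, satisfaction="very_satisfied",
                support_trend_12m="unchanged")
    base.update(kw)
    return AlterRecord(ego_id=ego_id, alter_index=alter_index, **base)


@pytest.fixture
def tiny_dataset():
    """Two egos, five alters, one recorded unacquainted pair."""
    egos = [make_ego("e1"), make_ego("e2", gender="man", adherent_7d=False)]
    alters = [
        make_alter("e1", 1),
        make_alter("e1", 2, relation="significant_other",
                   alter_gender="man", provides_material=True,
                   material_freq="once_week",
                   material_kinds=frozenset({"money"}), money_amount=50000,
                   money_purposes=frozenset({"transport_fare"})),
        make_alter("e1", 3, relation="neighbour", proximity="same_village"),
        make_alter("e2", 1, provides_informational=True,
                   informational_freq="few_times_month"),
        make_alter("e2", 2, relation="other_family",
                   contact_freq="less_than_monthly",
                   provides_emotional=False, emotional_freq=None),
    ]
    ties = [AlterAlterTie("e1", 1, 3, acquainted=False)]
    for e in egos:
        e.validate()
    for a in alters:
        a.validate()
    return Dataset(egos=egos, alters=alters, ties=ties)


@pytest.fixture
def tiny_paths(tiny_dataset, tmp_path):
    paths = (tmp_path / "egos.csv", tmp_path / "alters.csv",
             tmp_path / "alter_ties.csv")
    write_dataset(tiny_dataset, *paths)
    return paths


@pytest.fixture(scope="session")
def survey_100():
    """Default-configuration synthetic survey of 100 egos."""
    return generate_dataset(default_config(), seed=20260901)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()
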