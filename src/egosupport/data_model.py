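"""Domain types and I/O for egocentric support-network survey microdata.

The survey design is a three-table relational layout:

* an *ego* table — one row per index participant (the surveyed NCD patient),
* an *alter* table — one row per named social tie, carrying both alter
  attributes (relation, gender, age bracket) and tie attributes (contact and
  support frequencies, money amounts),
* an *alter–alter tie* table — acquaintance between pairs of an ego's alters.

All categorical fields use closed snake_case vocabularies; validation is
total: every raw row is either accepted or listed in the drop report with a
reason.  Alter–alter acquaintance defaults to ``True`` when unrecorded (the
tie table stores exceptions), reflecting the near-complete interconnection
typical of these small kin-dominated networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import pandas as pd

__all__ = [
    "GENDERS", "MARITAL_STATUSES", "EDUCATION_LEVELS", "OCCUPATIONS",
    "NCD_PREVENTS_WORK_LEVELS", "CONDITIONS", "RELATIONS", "AGE_BRACKETS",
    "AGE_BRACKET_BOUNDS", "PROXIMITIES", "TIME_KNOWN_LEVELS",
    "FREQUENCY_CATEGORIES", "SATISFACTION_LEVELS", "SUPPORT_TRENDS",
    "MATERIAL_KINDS", "MONEY_PURPOSES",
    "EgoRecord", "AlterRecord", "AlterAlterTie", "EgoNetwork", "Dataset",
    "ValidationReport", "SchemaError", "ReferentialError",
    "read_dataset", "write_dataset", "build_networks", "write_graphml",
]

# ---------------------------------------------------------------------------
# Closed vocabularies (order matters for the ordered categoricals)

GENDERS = ("woman", "man")
MARITAL_STATUSES = ("married", "widowed", "divorced", "living_with_partner",
                    "never_married", "separated")
EDUCATION_LEVELS = ("none", "some_primary", "primary", "some_secondary",
                    "secondary", "college")
OCCUPATIONS = ("subsistence_farmer", "self_employed", "public_servant",
               "retired", "caring_for_home", "private_formal_sector")
NCD_PREVENTS_WORK_LEVELS = ("never", "sometimes", "completely")
CONDITIONS = ("hypertension", "diabetes", "asthma", "epilepsy", "other")
RELATIONS = ("child", "significant_other", "parent", "friend", "neighbour",
             "other_family", "other")
AGE_BRACKETS = ("under_20", "20_30", "30_40", "40_50", "50_60", "over_60")
#: Half-open interval [lower, upper) for each alter age bracket, in years.
AGE_BRACKET_BOUNDS = {
    "under_20": (0.0, 20.0),
    "20_30": (20.0, 30.0),
    "30_40": (30.0, 40.0),
    "40_50": (40.0, 50.0),
    "50_60": (50.0, 60.0),
    "over_60": (60.0, math.inf),
}
PROXIMITIES = ("same_household", "same_village", "same_district",
               "other_district_in_region", "other_region", "other_country")
TIME_KNOWN_LEVELS = ("under_1y", "1_5y", "5_10y", "over_10y")
#: Contact/support frequency scale, ordered most to least frequent.
FREQUENCY_CATEGORIES = ("every_day", "few_times_week", "once_week",
                        "few_times_month", "once_month", "less_than_monthly")
SATISFACTION_LEVELS = ("very_dissatisfied", "dissatisfied", "neutral",
                       "satisfied", "very_satisfied")
SUPPORT_TRENDS = ("decreased", "unchanged", "increased")
MATERIAL_KINDS = ("money", "transport", "other")
MONEY_PURPOSES = ("clinic_pharmacy_fees", "transport_fare", "other")

MIN_ALTERS = 2
MAX_ALTERS = 10


class SchemaError(ValueError):
    """A raw table is missing a required column or is otherwise unreadable."""


class ReferentialError(ValueError):
    """A record references an ego or alter that does not exist."""


# ---------------------------------------------------------------------------
# Records


@dataclass
class EgoRecord:
    """One surveyed participant (ego): demographics, insurance, conditions,
    and the binary 7-day medication-adherence outcome."""

    ego_id: str
    age: int
    gender: str
    marital_status: str
    education: str
    household_size: int
    occupation: str
    ncd_prevents_work: str
    insured: bool
    conditions: frozenset
    adherent_7d: bool
    systolic: float | None = None
    diastolic: float | None = None
    random_glucose: float | None = None

    @property
    def multimorbid(self) -> bool:
        return len(self.conditions) >= 2

    def validate(self) -> None:
        if not self.ego_id:
            raise ValueError("empty ego_id")
        if self.age < 18:
            raise ValueError(f"ego age {self.age} < 18")
        _check_vocab("gender", self.gender, GENDERS)
        _check_vocab("marital_status", self.marital_status, MARITAL_STATUSES)
        _check_vocab("education", self.education, EDUCATION_LEVELS)
        _check_vocab("occupation", self.occupation, OCCUPATIONS)
        _check_vocab("ncd_prevents_work", self.ncd_prevents_work,
                     NCD_PREVENTS_WORK_LEVELS)
        if self.household_size < 1:
            raise ValueError(f"household_size {self.household_size} < 1")
        if not self.conditions:
            raise ValueError("ego has no chronic condition")
        for c in self.conditions:
            _check_vocab("conditions", c, CONDITIONS)
        for name in ("systolic", "diastolic", "random_glucose"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class AlterRecord:
    """One named social tie: alter attributes plus every ego–alter tie
    attribute (contact, support provision and frequency, money)."""

    ego_id: str
    alter_index: int
    relation: str
    alter_gender: str
    alter_age_bracket: str
    proximity: str
    time_known: str
    contact_freq: str
    provides_emotional: bool
    provides_informational: bool
    provides_material: bool
    reciprocated_by_ego: bool
    satisfaction: str
    support_trend_12m: str
    emotional_freq: str | None = None
    informational_freq: str | None = None
    material_freq: str | None = None
    material_kinds: frozenset = field(default_factory=frozenset)
    money_amount: int | None = None
    money_purposes: frozenset = field(default_factory=frozenset)

    def validate(self) -> None:
        if not (1 <= self.alter_index <= MAX_ALTERS):
            raise ValueError(f"alter_index {self.alter_index} outside 1..{MAX_ALTERS}")
        _check_vocab("relation", self.relation, RELATIONS)
        _check_vocab("alter_gender", self.alter_gender, GENDERS)
        _check_vocab("alter_age_bracket", self.alter_age_bracket, AGE_BRACKETS)
        _check_vocab("proximity", self.proximity, PROXIMITIES)
        _check_vocab("time_known", self.time_known, TIME_KNOWN_LEVELS)
        _check_vocab("contact_freq", self.contact_freq, FREQUENCY_CATEGORIES)
        _check_vocab("satisfaction", self.satisfaction, SATISFACTION_LEVELS)
        _check_vocab("support_trend_12m", self.support_trend_12m, SUPPORT_TRENDS)
        for kind, flag, freq in (
            ("emotional", self.provides_emotional, self.emotional_freq),
            ("informational", self.provides_informational, self.informational_freq),
            ("material", self.provides_material, self.material_freq),
        ):
            if flag and freq is None:
                raise ValueError(f"provides_{kind} is true but {kind}_freq missing")
            if not flag and freq is not None:
                raise ValueError(f"{kind}_freq present but provides_{kind} is false")
            if freq is not None:
                _check_vocab(f"{kind}_freq", freq, FREQUENCY_CATEGORIES)
        for k in self.material_kinds:
            _check_vocab("material_kinds", k, MATERIAL_KINDS)
        for p in self.money_purposes:
            _check_vocab("money_purposes", p, MONEY_PURPOSES)
        if self.material_kinds and not self.provides_material:
            raise ValueError("material_kinds present but provides_material is false")
        if self.money_amount is not None:
            if self.money_amount < 0:
                raise ValueError(f"negative money_amount {self.money_amount}")
            if "money" not in self.material_kinds:
                raise ValueError("money_amount present but money not in material_kinds")
        if "money" in self.material_kinds and self.money_amount is None:
            raise ValueError("money in material_kinds but money_amount missing")


@dataclass
class AlterAlterTie:
    """Recorded acquaintance status for one unordered pair of an ego's alters."""

    ego_id: str
    alter_index_a: int
    alter_index_b: int
    acquainted: bool

    def validate(self) -> None:
        if self.alter_index_a == self.alter_index_b:
            raise ValueError("self-tie: alter_index_a == alter_index_b")
        for i in (self.alter_index_a, self.alter_index_b):
            if not (1 <= i <= MAX_ALTERS):
                raise ValueError(f"alter index {i} outside 1..{MAX_ALTERS}")


@dataclass
class EgoNetwork:
    """An ego, its alters (sorted by alter_index), and the symmetric boolean
    alter–alter acquaintance matrix (diagonal False)."""

    ego: EgoRecord
    alters: list
    adjacency: list  # list of list of bool, n x n

    @property
    def n_alters(self) -> int:
        return len(self.alters)


@dataclass
class Dataset:
    egos: list
    alters: list
    ties: list

    def alters_of(self, ego_id: str) -> list:
        return sorted((a for a in self.alters if a.ego_id == ego_id),
                      key=lambda a: a.alter_index)


@dataclass
class ValidationReport:
    """Counts of rows read and dropped per table, with per-row reasons."""

    n_read: dict = field(default_factory=dict)
    n_accepted: dict = field(default_factory=dict)
    drops: list = field(default_factory=list)  # (table, row_number, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.drops)

    def to_dict(self) -> dict:
        return {
            "n_read": dict(self.n_read),
            "n_accepted": dict(self.n_accepted),
            "n_dropped": self.n_dropped,
            "drops": [
                {"table": t, "row": r, "reason": why} for t, r, why in self.drops
            ],
        }


def _check_vocab(name, value, vocab) -> None:
    if value not in vocab:
        raise ValueError(f"unknown category {value!r} for {name}")


# ---------------------------------------------------------------------------
# CSV parsing helpers.  Files are UTF-8, comma-delimited, header row; empty
# string encodes a missing optional; set-valued fields are ';'-joined.

EGO_COLUMNS = ["ego_id", "age", "gender", "marital_status", "education",
               "household_size", "occupation", "ncd_prevents_work", "insured",
               "conditions", "adherent_7d", "systolic", "diastolic",
               "random_glucose"]
ALTER_COLUMNS = ["ego_id", "alter_index", "relation", "alter_gender",
                 "alter_age_bracket", "proximity", "time_known",
                 "contact_freq", "provides_emotional", "emotional_freq",
                 "provides_informational", "informational_freq",
                 "provides_material", "material_freq", "reciprocated_by_ego",
                 "satisfaction", "support_trend_12m", "material_kinds",
                 "money_amount", "money_purposes"]
TIE_COLUMNS = ["ego_id", "alter_index_a", "alter_index_b", "acquainted"]


def _parse_bool(s: str) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise ValueError(f"expected 'true' or 'false', got {s!r}")


def _parse_set(s: str) -> frozenset:
    return frozenset(p for p in s.split(";") if p) if s else frozenset()


def _opt(s: str):
    return s if s != "" else None


def _read_table(path, columns, table_name) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # unreadable file is a schema-level failure
        raise SchemaError(f"cannot read {table_name} table at {path}: {exc}") from exc
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{table_name} table missing required column {col!r}")
    return df


def _ego_from_row(row) -> EgoRecord:
    rec = EgoRecord(
        ego_id=row["ego_id"],
        age=int(row["age"]),
        gender=row["gender"],
        marital_status=row["marital_status"],
        education=row["education"],
        household_size=int(row["household_size"]),
        occupation=row["occupation"],
        ncd_prevents_work=row["ncd_prevents_work"],
        insured=_parse_bool(row["insured"]),
        conditions=_parse_set(row["conditions"]),
        adherent_7d=_parse_bool(row["adherent_7d"]),
        systolic=float(row["systolic"]) if row["systolic"] else None,
        diastolic=float(row["diastolic"]) if row["diastolic"] else None,
        random_glucose=float(row["random_glucose"]) if row["random_glucose"] else None,
    )
    rec.validate()
    return rec


def _alter_from_row(row) -> AlterRecord:
    rec = AlterRecord(
        ego_id=row["ego_id"],
        alter_index=int(row["alter_index"]),
        relation=row["relation"],
        alter_gender=row["alter_gender"],
        alter_age_bracket=row["alter_age_bracket"],
        proximity=row["proximity"],
        time_known=row["time_known"],
        contact_freq=row["contact_freq"],
        provides_emotional=_parse_bool(row["provides_emotional"]),
        provides_informational=_parse_bool(row["provides_informational"]),
        provides_material=_parse_bool(row["provides_material"]),
        reciprocated_by_ego=_parse_bool(row["reciprocated_by_ego"]),
        satisfaction=row["satisfaction"],
        support_trend_12m=row["support_trend_12m"],
        emotional_freq=_opt(row["emotional_freq"]),
        informational_freq=_opt(row["informational_freq"]),
        material_freq=_opt(row["material_freq"]),
        material_kinds=_parse_set(row["material_kinds"]),
        money_amount=int(row["money_amount"]) if row["money_amount"] else None,
        money_purposes=_parse_set(row["money_purposes"]),
    )
    rec.validate()
    return rec


def _tie_from_row(row) -> AlterAlterTie:
    rec = AlterAlterTie(
        ego_id=row["ego_id"],
        alter_index_a=int(row["alter_index_a"]),
        alter_index_b=int(row["alter_index_b"]),
        acquainted=_parse_bool(row["acquainted"]),
    )
    rec.validate()
    return rec


def read_dataset(ego_path, alter_path, tie_path):
    """Read and validate the three survey tables.

    Returns ``(Dataset, ValidationReport)``.  Row-level problems (unknown
    category, broken invariant, orphan reference) drop the row into the
    report; structural problems (missing column) raise :class:`SchemaError`.
    """
    report = ValidationReport()
    ego_df = _read_table(ego_path, EGO_COLUMNS, "ego")
    alter_df = _read_table(alter_path, ALTER_COLUMNS, "alter")
    tie_df = _read_table(tie_path, TIE_COLUMNS, "alter_tie")
    report.n_read = {"egos": len(ego_df), "alters": len(alter_df),
                     "alter_ties": len(tie_df)}

    egos, seen_ids = [], set()
    for i, row in enumerate(ego_df.to_dict("records")):
        try:
            rec = _ego_from_row(row)
            if rec.ego_id in seen_ids:
                raise ValueError(f"duplicate ego_id {rec.ego_id!r}")
            seen_ids.add(rec.ego_id)
            egos.append(rec)
        except (ValueError, KeyError) as exc:
            report.drops.append(("egos", i + 2, str(exc)))  # +2: header + 1-based

    alters, seen_alter_keys = [], set()
    for i, row in enumerate(alter_df.to_dict("records")):
        try:
            rec = _alter_from_row(row)
            if rec.ego_id not in seen_ids:
                raise ValueError(f"orphan alter: ego_id {rec.ego_id!r} not in ego table")
            key = (rec.ego_id, rec.alter_index)
            if key in seen_alter_keys:
                raise ValueError(f"duplicate alter_index {rec.alter_index} for ego {rec.ego_id!r}")
            seen_alter_keys.add(key)
            alters.append(rec)
        except (ValueError, KeyError) as exc:
            report.drops.append(("alters", i + 2, str(exc)))

    # enforce 2..10 alters per ego; an ego with too few valid ties is dropped
    counts: dict = {}
    for a in alters:
        counts[a.ego_id] = counts.get(a.ego_id, 0) + 1
    keep_ids = {e.ego_id for e in egos if MIN_ALTERS <= counts.get(e.ego_id, 0)}
    for e in egos:
        if e.ego_id not in keep_ids:
            report.drops.append(("egos", None,
                                 f"ego {e.ego_id!r} has fewer than {MIN_ALTERS} valid alters"))
    egos = [e for e in egos if e.ego_id in keep_ids]
    dropped_alters = [a for a in alters if a.ego_id not in keep_ids]
    for a in dropped_alters:
        report.drops.append(("alters", None,
                             f"alter {a.alter_index} of dropped ego {a.ego_id!r}"))
    alters = [a for a in alters if a.ego_id in keep_ids]

    ties, seen_pairs = [], set()
    for i, row in enumerate(tie_df.to_dict("records")):
        try:
            rec = _tie_from_row(row)
            if rec.ego_id not in keep_ids:
                raise ValueError(f"orphan tie: ego_id {rec.ego_id!r} not in ego table")
            for idx in (rec.alter_index_a, rec.alter_index_b):
                if (rec.ego_id, idx) not in seen_alter_keys:
                    raise ValueError(f"tie references nonexistent alter {idx} of ego {rec.ego_id!r}")
            pair = (rec.ego_id, *sorted((rec.alter_index_a, rec.alter_index_b)))
            if pair in seen_pairs:
                raise ValueError(f"duplicate alter pair {pair[1:]} for ego {rec.ego_id!r}")
            seen_pairs.add(pair)
            ties.append(rec)
        except (ValueError, KeyError) as exc:
            report.drops.append(("alter_ties", i + 2, str(exc)))

    report.n_accepted = {"egos": len(egos), "alters": len(alters),
                         "alter_ties": len(ties)}
    return Dataset(egos=egos, alters=alters, ties=ties), report


# ---------------------------------------------------------------------------
# Writing


def _fmt_opt(v) -> str:
    return "" if v is None else str(v)


def _fmt_bool(v: bool) -> str:
    return "true" if v else "false"


def _fmt_set(s) -> str:
    return ";".join(sorted(s))


def write_dataset(dataset: Dataset, ego_path, alter_path, tie_path) -> None:
    """Write the three tables in the canonical CSV dialect (round-trips
    bit-for-bit through :func:`read_dataset` for all categorical and integer
    fields)."""
    ego_rows = []
    for e in dataset.egos:
        d = asdict(e)
        d["insured"] = _fmt_bool(e.insured)
        d["adherent_7d"] = _fmt_bool(e.adherent_7d)
        d["conditions"] = _fmt_set(e.conditions)
        for k in ("systolic", "diastolic", "random_glucose"):
            d[k] = _fmt_opt(d[k])
        ego_rows.append(d)
    pd.DataFrame(ego_rows, columns=EGO_COLUMNS).to_csv(ego_path, index=False)

    alter_rows = []
    for a in dataset.alters:
        d = asdict(a)
        for k in ("provides_emotional", "provides_informational",
                  "provides_material", "reciprocated_by_ego"):
            d[k] = _fmt_bool(d[k])
        for k in ("emotional_freq", "informational_freq", "material_freq",
                  "money_amount"):
            d[k] = _fmt_opt(d[k])
        d["material_kinds"] = _fmt_set(a.material_kinds)
        d["money_purposes"] = _fmt_set(a.money_purposes)
        alter_rows.append(d)
    pd.DataFrame(alter_rows, columns=ALTER_COLUMNS).to_csv(alter_path, index=False)

    tie_rows = [{**asdict(t), "acquainted": _fmt_bool(t.acquainted)}
                for t in dataset.ties]
    pd.DataFrame(tie_rows, columns=TIE_COLUMNS).to_csv(tie_path, index=False)


# ---------------------------------------------------------------------------
# Network assembly and export


def build_networks(dataset: Dataset) -> list:
    """Assemble one :class:`EgoNetwork` per ego.

    Alter pairs absent from the tie table default to acquainted; the tie
    table records exceptions (and explicit confirmations).
    """
    ties_by_ego: dict = {}
    for t in dataset.ties:
        ties_by_ego.setdefault(t.ego_id, []).append(t)
    alters_by_ego: dict = {}
    for a in dataset.alters:
        alters_by_ego.setdefault(a.ego_id, []).append(a)

    networks = []
    for ego in dataset.egos:
        alters = sorted(alters_by_ego.get(ego.ego_id, []),
                        key=lambda a: a.alter_index)
        index_pos = {a.alter_index: k for k, a in enumerate(alters)}
        n = len(alters)
        adj = [[i != j for j in range(n)] for i in range(n)]
        for t in ties_by_ego.get(ego.ego_id, []):
            for idx in (t.alter_index_a, t.alter_index_b):
                if idx not in index_pos:
                    raise ReferentialError(
                        f"tie references nonexistent alter {idx} of ego {ego.ego_id!r}")
            i, j = index_pos[t.alter_index_a], index_pos[t.alter_index_b]
            adj[i][j] = adj[j][i] = t.acquainted
        networks.append(EgoNetwork(ego=ego, alters=alters, adjacency=adj))
    return networks


def to_graph(network: EgoNetwork, weights=None) -> nx.Graph:
    """Ego-centred star plus alter–alter acquaintance edges as a networkx
    graph; ego–alter edges carry the tie weight when given."""
    n = network.n_alters
    if weights is not None:
        if len(weights) != n:
            raise ValueError(f"got {len(weights)} weights for {n} alters")
        for w in weights:
            if not (0.0 <= float(w) <= 1.0):
                raise ValueError(f"tie weight {w} outside [0, 1]")
    g = nx.Graph()
    g.add_node("ego", kind="ego", gender=network.ego.gender)
    for k, a in enumerate(network.alters):
        node = f"alter_{a.alter_index}"
        g.add_node(node, kind="alter", relation=a.relation, gender=a.alter_gender)
        if weights is not None:
            g.add_edge("ego", node, weight=float(weights[k]))
        else:
            g.add_edge("ego", node)
    for i in range(n):
        for j in range(i + 1, n):
            if network.adjacency[i][j]:
                g.add_edge(f"alter_{network.alters[i].alter_index}",
                           f"alter_{network.alters[j].alter_index}")
    return g


def write_graphml(network: EgoNetwork, weights, path) -> None:
    """Export one ego network (with per-tie weights in [0, 1]) as GraphML."""
    nx.write_graphml(to_graph(network, weights), path)
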