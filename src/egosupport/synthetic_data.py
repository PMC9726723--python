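"""Synthetic survey generator emulating the study's design and margins.

The generator draws complete three-table datasets (egos, alters, alter–alter
ties) whose *marginal* distributions reproduce the descriptive tables of the
Ifakara NCD outpatient survey: ~100 egos (mean age 62.8, 68% women, 87%
insured), 2–10 named alters per ego (mean 3.0, SD ~1.0), a relation mix
dominated by children and partners, six-level contact/support frequency
scales, support-provision rates (emotional 85%, informational 73%, material
41% of ties), log-normal money amounts (mean ~Tsh 50,861, SD ~64,163), and
near-complete alter–alter acquaintance.  The 7-day medication-adherence
outcome is drawn from a logistic model on each ego's *realised* monthly
support indicators, so the support→adherence odds ratio is a configurable
generative parameter the analysis pipeline can be asked to recover.

Joint structure beyond the configured margins (e.g. gender × marital
status) is not modelled: attributes are sampled independently.  A single
integer seed drives one root `SeedSequence`; per-ego substreams are spawned
from it, so the first k egos are identical for any ``n_egos >= k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import (AGE_BRACKETS, AlterAlterTie, AlterRecord, CONDITIONS,
                         Dataset, EDUCATION_LEVELS, EgoRecord,
                         FREQUENCY_CATEGORIES, MARITAL_STATUSES,
                         MATERIAL_KINDS, MONEY_PURPOSES, OCCUPATIONS,
                         NCD_PREVENTS_WORK_LEVELS, PROXIMITIES,
                         SATISFACTION_LEVELS, SUPPORT_TRENDS,
                         TIME_KNOWN_LEVELS)
from .network_metrics import alter_support_days
from .recoding import dichotomize_monthly
from .association_stats import TwoByTwoTable, odds_ratio_cornfield

__all__ = ["GeneratorConfig", "default_config", "generate_dataset",
           "recover_parameters", "lognormal_params"]


def lognormal_params(mean: float, sd: float) -> tuple:
    """Method-of-moments (mu, sigma) of a log-normal with given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass
class GeneratorConfig:
    """All sampling distributions of the synthetic survey.

    Probability vectors are dicts over the corresponding vocabulary and must
    sum to 1; independent flags are single Bernoulli probabilities.
    """

    n_egos: int = 100
    seed: int = 0

    # --- ego level -------------------------------------------------------
    age_mean: float = 62.8
    age_sd: float = 8.2
    age_bounds: tuple = (30.0, 95.0)
    p_woman: float = 0.68
    marital_probs: dict = field(default_factory=dict)
    education_probs: dict = field(default_factory=dict)
    occupation_probs: dict = field(default_factory=dict)
    prevents_work_probs: dict = field(default_factory=dict)
    household_extra_mean: float = 3.7   # household size = 1 + Poisson(mean)
    p_insured: float = 0.87
    condition_probs: dict = field(default_factory=dict)  # independent flags

    # --- alters and ties -------------------------------------------------
    alter_count_weights: dict = field(default_factory=dict)  # on 2..10
    relation_probs: dict = field(default_factory=dict)
    p_alter_woman: float = 0.447
    age_bracket_probs: dict = field(default_factory=dict)
    proximity_probs: dict = field(default_factory=dict)
    time_known_probs: dict = field(default_factory=dict)
    contact_freq_probs: dict = field(default_factory=dict)
    satisfaction_probs: dict = field(default_factory=dict)
    support_trend_probs: dict = field(default_factory=dict)
    p_emotional: float = 0.849
    p_informational: float = 0.734
    p_material: float = 0.411
    emotional_freq_probs: dict = field(default_factory=dict)
    informational_freq_probs: dict = field(default_factory=dict)
    material_freq_probs: dict = field(default_factory=dict)
    p_reciprocated: float = 0.80
    material_kind_probs: dict = field(default_factory=dict)  # independent flags
    money_mean: float = 50861.3
    money_sd: float = 64163.1
    money_purpose_probs: dict = field(default_factory=dict)  # independent flags
    p_unacquainted_pair: float = 0.007

    # --- adherence model -------------------------------------------------
    adherence_baseline_log_odds: float = -1.0
    adherence_log_or_nonmaterial: float = math.log(8.0)
    adherence_log_or_material: float = math.log(6.0)

    def validate(self) -> None:
        if self.n_egos < 1:
            raise ValueError("n_egos must be >= 1")
        for name, probs, vocab in [
            ("marital_probs", self.marital_probs, MARITAL_STATUSES),
            ("education_probs", self.education_probs, EDUCATION_LEVELS),
            ("occupation_probs", self.occupation_probs, OCCUPATIONS),
            ("prevents_work_probs", self.prevents_work_probs, NCD_PREVENTS_WORK_LEVELS),
            ("relation_probs", self.relation_probs, None),
            ("age_bracket_probs", self.age_bracket_probs, AGE_BRACKETS),
            ("proximity_probs", self.proximity_probs, PROXIMITIES),
            ("time_known_probs", self.time_known_probs, TIME_KNOWN_LEVELS),
            ("contact_freq_probs", self.contact_freq_probs, FREQUENCY_CATEGORIES),
            ("satisfaction_probs", self.satisfaction_probs, SATISFACTION_LEVELS),
            ("support_trend_probs", self.support_trend_probs, SUPPORT_TRENDS),
            ("emotional_freq_probs", self.emotional_freq_probs, FREQUENCY_CATEGORIES),
            ("informational_freq_probs", self.informational_freq_probs, FREQUENCY_CATEGORIES),
            ("material_freq_probs", self.material_freq_probs, FREQUENCY_CATEGORIES),
            ("alter_count_weights", self.alter_count_weights, None),
        ]:
            if not probs:
                raise ValueError(f"{name} is empty")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has a negative probability")
            if vocab is not None and not set(probs) <= set(vocab):
                raise ValueError(f"{name} contains labels outside the vocabulary")
        if not set(self.alter_count_weights) <= set(range(2, 11)):
            raise ValueError("alter_count_weights keys must lie in 2..10")
        for name in ("p_woman", "p_insured", "p_alter_woman", "p_emotional",
                     "p_informational", "p_material", "p_reciprocated",
                     "p_unacquainted_pair"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name, probs in [("condition_probs", self.condition_probs),
                            ("material_kind_probs", self.material_kind_probs),
                            ("money_purpose_probs", self.money_purpose_probs)]:
            if any(not (0.0 <= p <= 1.0) for p in probs.values()):
                raise ValueError(f"{name} has a probability outside [0, 1]")
        if not any(p > 0 for p in self.condition_probs.values()):
            raise ValueError("at least one condition probability must be positive")
        if self.money_mean <= 0 or self.money_sd <= 0:
            raise ValueError("money amount mean and sd must be positive")
        if not (self.age_bounds[0] < self.age_mean < self.age_bounds[1]):
            raise ValueError("age mean outside truncation bounds")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_bounds"] = list(self.age_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "age_bounds" in d:
            d["age_bounds"] = tuple(d["age_bounds"])
        if "alter_count_weights" in d:
            d["alter_count_weights"] = {int(k): v for k, v
                                        in d["alter_count_weights"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


def default_config() -> GeneratorConfig:
    """Configuration whose marginals emulate the study's descriptive tables."""
    cfg = GeneratorConfig(
        marital_probs={"married": 0.57, "widowed": 0.39, "divorced": 0.01,
                       "living_with_partner": 0.01, "never_married": 0.01,
                       "separated": 0.01},
        education_probs={"none": 0.01, "some_primary": 0.12, "primary": 0.56,
                         "some_secondary": 0.04, "secondary": 0.21,
                         "college": 0.06},
        occupation_probs={"subsistence_farmer": 0.68, "self_employed": 0.10,
                          "public_servant": 0.07, "retired": 0.07,
                          "caring_for_home": 0.05,
                          "private_formal_sector": 0.03},
        prevents_work_probs={"never": 0.59, "sometimes": 0.37,
                             "completely": 0.04},
        condition_probs={"hypertension": 0.92, "diabetes": 0.24,
                         "asthma": 0.02, "epilepsy": 0.01, "other": 0.12},
        # mean 3.0, SD ~1.0 named alters
        alter_count_weights={2: 0.37, 3: 0.38, 4: 0.165, 5: 0.055,
                             6: 0.025, 7: 0.005},
        relation_probs={"child": 0.641, "significant_other": 0.171,
                        "parent": 0.013, "friend": 0.007, "neighbour": 0.056,
                        "other_family": 0.109, "other": 0.003},
        age_bracket_probs={"under_20": 0.010, "20_30": 0.283, "30_40": 0.280,
                           "40_50": 0.201, "50_60": 0.138, "over_60": 0.088},
        proximity_probs={"same_household": 0.559, "same_village": 0.168,
                         "same_district": 0.053,
                         "other_district_in_region": 0.039,
                         "other_region": 0.178, "other_country": 0.003},
        time_known_probs={"under_1y": 0.023, "1_5y": 0.194, "5_10y": 0.099,
                          "over_10y": 0.684},
        contact_freq_probs={"every_day": 0.701, "few_times_week": 0.155,
                            "once_week": 0.118, "few_times_month": 0.016,
                            "once_month": 0.007, "less_than_monthly": 0.003},
        satisfaction_probs={"very_dissatisfied": 0.0, "dissatisfied": 0.0,
                            "neutral": 0.013, "satisfied": 0.336,
                            "very_satisfied": 0.651},
        support_trend_probs={"decreased": 0.016, "unchanged": 0.908,
                             "increased": 0.076},
        emotional_freq_probs={"every_day": 0.012, "few_times_week": 0.008,
                              "once_week": 0.008, "few_times_month": 0.143,
                              "once_month": 0.297,
                              "less_than_monthly": 0.532},
        informational_freq_probs={"every_day": 0.0, "few_times_week": 0.009,
                                  "once_week": 0.049,
                                  "few_times_month": 0.147,
                                  "once_month": 0.362,
                                  "less_than_monthly": 0.433},
        material_freq_probs={"every_day": 0.056, "few_times_week": 0.262,
                             "once_week": 0.095, "few_times_month": 0.214,
                             "once_month": 0.119,
                             "less_than_monthly": 0.254},
        material_kind_probs={"money": 0.944, "transport": 0.336,
                             "other": 0.064},
        money_purpose_probs={"clinic_pharmacy_fees": 0.254,
                             "transport_fare": 0.496, "other": 0.683},
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Sampling


def _categorical(rng, probs: dict) -> str:
    labels = list(probs.keys())
    p = np.array([probs[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=p / p.sum())]


def _truncnorm(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(min(max(mean, lo), hi))


def _sample_ego(rng, cfg: GeneratorConfig, ego_id: str):
    age = int(round(_truncnorm(rng, cfg.age_mean, cfg.age_sd, *cfg.age_bounds)))
    conditions = frozenset(c for c in CONDITIONS
                           if rng.random() < cfg.condition_probs.get(c, 0.0))
    if not conditions:
        # every participant has at least one diagnosed condition; redraw
        while not conditions:
            conditions = frozenset(c for c in CONDITIONS
                                   if rng.random() < cfg.condition_probs.get(c, 0.0))
    return EgoRecord(
        ego_id=ego_id,
        age=max(age, 18),
        gender="woman" if rng.random() < cfg.p_woman else "man",
        marital_status=_categorical(rng, cfg.marital_probs),
        education=_categorical(rng, cfg.education_probs),
        household_size=1 + int(rng.poisson(cfg.household_extra_mean)),
        occupation=_categorical(rng, cfg.occupation_probs),
        ncd_prevents_work=_categorical(rng, cfg.prevents_work_probs),
        insured=rng.random() < cfg.p_insured,
        conditions=conditions,
        adherent_7d=False,  # filled in after alters are drawn
        systolic=round(_truncnorm(rng, 143.2, 18.5, 80.0, 250.0), 1),
        diastolic=round(_truncnorm(rng, 92.8, 13.5, 50.0, 160.0), 1),
        random_glucose=round(_truncnorm(rng, 6.1, 2.7, 2.0, 30.0), 1),
    )


def _sample_alter(rng, cfg: GeneratorConfig, ego_id: str, index: int):
    provides = {
        "emotional": rng.random() < cfg.p_emotional,
        "informational": rng.random() < cfg.p_informational,
        "material": rng.random() < cfg.p_material,
    }
    freqs = {
        "emotional": _categorical(rng, cfg.emotional_freq_probs)
        if provides["emotional"] else None,
        "informational": _categorical(rng, cfg.informational_freq_probs)
        if provides["informational"] else None,
        "material": _categorical(rng, cfg.material_freq_probs)
        if provides["material"] else None,
    }
    kinds = frozenset()
    money_amount = None
    purposes = frozenset()
    if provides["material"]:
        kinds = frozenset(k for k in MATERIAL_KINDS
                          if rng.random() < cfg.material_kind_probs.get(k, 0.0))
        if "money" in kinds:
            mu, sigma = lognormal_params(cfg.money_mean, cfg.money_sd)
            money_amount = int(round(rng.lognormal(mu, sigma) / 100.0) * 100)
            purposes = frozenset(p for p in MONEY_PURPOSES
                                 if rng.random() < cfg.money_purpose_probs.get(p, 0.0))
    return AlterRecord(
        ego_id=ego_id,
        alter_index=index,
        relation=_categorical(rng, cfg.relation_probs),
        alter_gender="woman" if rng.random() < cfg.p_alter_woman else "man",
        alter_age_bracket=_categorical(rng, cfg.age_bracket_probs),
        proximity=_categorical(rng, cfg.proximity_probs),
        time_known=_categorical(rng, cfg.time_known_probs),
        contact_freq=_categorical(rng, cfg.contact_freq_probs),
        provides_emotional=provides["emotional"],
        provides_informational=provides["informational"],
        provides_material=provides["material"],
        reciprocated_by_ego=rng.random() < cfg.p_reciprocated,
        satisfaction=_categorical(rng, cfg.satisfaction_probs),
        support_trend_12m=_categorical(rng, cfg.support_trend_probs),
        emotional_freq=freqs["emotional"],
        informational_freq=freqs["informational"],
        material_freq=freqs["material"],
        material_kinds=kinds,
        money_amount=money_amount,
        money_purposes=purposes,
    )


def generate_dataset(config: GeneratorConfig, seed: int | None = None) -> Dataset:
    """Draw one complete synthetic dataset.

    Reproducible given (config, seed); ``seed`` overrides ``config.seed``.
    Every generated record passes the data-model validator.  Adherence is
    drawn last, from the logistic model applied to the ego's realised
    monthly-support indicators.
    """
    config.validate()
    root_seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(root_seed).spawn(config.n_egos)
    width = max(4, len(str(config.n_egos)))

    egos, alters, ties = [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        ego_id = f"ego_{i + 1:0{width}d}"
        ego = _sample_ego(rng, config, ego_id)
        counts = config.alter_count_weights
        n_alters = int(_categorical(rng, {str(k): v for k, v in counts.items()}))
        my_alters = [_sample_alter(rng, config, ego_id, j + 1)
                     for j in range(n_alters)]

        # acquaintance exceptions only
        for aidx in range(1, n_alters + 1):
            for bidx in range(aidx + 1, n_alters + 1):
                if rng.random() < config.p_unacquainted_pair:
                    ties.append(AlterAlterTie(ego_id=ego_id, alter_index_a=aidx,
                                              alter_index_b=bidx,
                                              acquainted=False))

        nm_days = sum(alter_support_days(a, "nonmaterial") for a in my_alters)
        mat_days = sum(alter_support_days(a, "material") for a in my_alters)
        logit = (config.adherence_baseline_log_odds
                 + config.adherence_log_or_nonmaterial * dichotomize_monthly(nm_days)
                 + config.adherence_log_or_material * dichotomize_monthly(mat_days))
        ego.adherent_7d = rng.random() < 1.0 / (1.0 + math.exp(-logit))

        ego.validate()
        for a in my_alters:
            a.validate()
        egos.append(ego)
        alters.extend(my_alters)

    return Dataset(egos=egos, alters=alters, ties=ties)


def recover_parameters(dataset: Dataset, alpha: float = 0.05) -> dict:
    """Run the support→adherence pipeline and estimate both crude odds
    ratios (monthly non-material and monthly material vs 7-day adherence).

    Validation harness for the generator: on data generated with a single
    active effect, the returned OR is a consistent estimate of the
    configured one.
    """
    from .network_metrics import dataset_summaries
    summaries = dataset_summaries(dataset)
    adherent = {e.ego_id: e.adherent_7d for e in dataset.egos}
    out = {}
    for kind, flag in (("nonmaterial", "monthly_nonmaterial"),
                       ("material", "monthly_material")):
        a = b = c = d = 0
        for s in summaries:
            exposed = getattr(s, flag)
            outcome = adherent[s.ego_id]
            if exposed and outcome:
                a += 1
            elif exposed:
                b += 1
            elif outcome:
                c += 1
            else:
                d += 1
        out[kind] = odds_ratio_cornfield(TwoByTwoTable(a, b, c, d), alpha=alpha)
    return out
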