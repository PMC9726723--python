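"""Generator configuration, determinism, degenerate limits, and recovery."""

import math

import numpy as np
import pytest

from egosupport.data_model import read_dataset, write_dataset
from egosupport.network_metrics import dataset_summaries
from egosupport.synthetic_data import (GeneratorConfig, default_config,
                                       generate_dataset, lognormal_params,
                                       recover_parameters)


class TestDefaultConfig:
    def test_probability_vectors_sum_to_one(self, default_cfg):
        for probs in (default_cfg.marital_probs, default_cfg.education_probs,
                      default_cfg.occupation_probs,
                      default_cfg.prevents_work_probs,
                      default_cfg.relation_probs,
                      default_cfg.age_bracket_probs,
                      default_cfg.proximity_probs,
                      default_cfg.time_known_probs,
                      default_cfg.contact_freq_probs,
                      default_cfg.satisfaction_probs,
                      default_cfg.support_trend_probs,
                      default_cfg.emotional_freq_probs,
                      default_cfg.informational_freq_probs,
                      default_cfg.material_freq_probs,
                      default_cfg.alter_count_weights):
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_relation_weights_match_survey_margins(self, default_cfg):
        assert default_cfg.relation_probs["child"] == pytest.approx(0.641)
        assert default_cfg.relation_probs["significant_other"] == pytest.approx(0.171)
        assert default_cfg.relation_probs["other_family"] == pytest.approx(0.109)
        assert default_cfg.p_material == pytest.approx(0.411)

    def test_lognormal_method_of_moments(self, default_cfg):
        mu, sigma = lognormal_params(default_cfg.money_mean,
                                     default_cfg.money_sd)
        mean = math.exp(mu + sigma ** 2 / 2)
        sd = math.sqrt((math.exp(sigma ** 2) - 1) * math.exp(2 * mu + sigma ** 2))
        assert mean == pytest.approx(default_cfg.money_mean)
        assert sd == pytest.approx(default_cfg.money_sd)

    def test_invalid_configs_rejected_before_sampling(self, default_cfg):
        bad = GeneratorConfig.from_dict(default_cfg.to_dict())
        bad.relation_probs = {"child": 0.9}
        with pytest.raises(ValueError, match="relation_probs"):
            generate_dataset(bad, seed=1)
        bad2 = GeneratorConfig.from_dict(default_cfg.to_dict())
        bad2.p_material = 1.5
        with pytest.raises(ValueError, match="p_material"):
            bad2.validate()


class TestGeneration:
    def test_same_seed_byte_identical_tables(self, default_cfg, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        d1.mkdir(), d2.mkdir()
        for d in (d1, d2):
            ds = generate_dataset(default_cfg, seed=99)
            write_dataset(ds, d / "e.csv", d / "a.csv", d / "t.csv")
        for name in ("e.csv", "a.csv", "t.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_prefix_stable_under_n_egos(self, default_cfg):
        small = generate_dataset(
            GeneratorConfig.from_dict({**default_cfg.to_dict(), "n_egos": 20}),
            seed=4)
        big = generate_dataset(
            GeneratorConfig.from_dict({**default_cfg.to_dict(), "n_egos": 60}),
            seed=4)
        strip = lambda e: {k: v for k, v in vars(e).items() if k != "ego_id"}
        for a, b in zip(small.egos, big.egos[:20]):
            assert strip(a) == strip(b)

    def test_no_material_provision_limit(self, default_cfg):
        cfg = GeneratorConfig.from_dict({**default_cfg.to_dict(),
                                         "p_material": 0.0})
        ds = generate_dataset(cfg, seed=8)
        assert all(not a.provides_material for a in ds.alters)
        for s in dataset_summaries(ds):
            assert s.material_days == 0.0
            assert s.money_total == 0

    def test_validation_closure(self, survey_100, tmp_path):
        write_dataset(survey_100, tmp_path / "e.csv", tmp_path / "a.csv",
                      tmp_path / "t.csv")
        _, report = read_dataset(tmp_path / "e.csv", tmp_path / "a.csv",
                                 tmp_path / "t.csv")
        assert report.n_dropped == 0

    def test_alter_count_mean_matches_configured_distribution(self, default_cfg):
        cfg = GeneratorConfig.from_dict({**default_cfg.to_dict(),
                                         "n_egos": 5000})
        ds = generate_dataset(cfg, seed=17)
        assert len(ds.alters) / 5000 == pytest.approx(3.0, abs=0.05)

    def test_unacquainted_pairs_rare_and_recorded(self, survey_100):
        # with per-pair prob 0.007 and ~3 pairs per ego, most egos are complete
        assert len(survey_100.ties) < 15
        assert all(not t.acquainted for t in survey_100.ties)


class TestAdherenceModel:
    @staticmethod
    def analytic_adherence(cfg):
        """Closed-form overall adherence implied by the configuration."""
        p_em = cfg.p_emotional * (1 - cfg.emotional_freq_probs["less_than_monthly"])
        p_inf = cfg.p_informational * (
            1 - cfg.informational_freq_probs["less_than_monthly"])
        r_nm = 1 - (1 - p_em) * (1 - p_inf)
        r_mat = cfg.p_material * (1 - cfg.material_freq_probs["less_than_monthly"])
        expit = lambda x: 1 / (1 + math.exp(-x))
        total = 0.0
        for n, w in cfg.alter_count_weights.items():
            p_nm = 1 - (1 - r_nm) ** n
            p_mat = 1 - (1 - r_mat) ** n
            for znm, pz1 in ((1, p_nm), (0, 1 - p_nm)):
                for zm, pz2 in ((1, p_mat), (0, 1 - p_mat)):
                    total += w * pz1 * pz2 * expit(
                        cfg.adherence_baseline_log_odds
                        + cfg.adherence_log_or_nonmaterial * znm
                        + cfg.adherence_log_or_material * zm)
        return total

    def test_overall_adherence_near_analytic_value(self, default_cfg):
        cfg = GeneratorConfig.from_dict({**default_cfg.to_dict(),
                                         "n_egos": 4000})
        ds = generate_dataset(cfg, seed=12)
        observed = np.mean([e.adherent_7d for e in ds.egos])
        expected = self.analytic_adherence(cfg)
        se = math.sqrt(expected * (1 - expected) / 4000)
        assert abs(observed - expected) < 3 * se
        assert 0.80 < expected < 0.90   # emulates the ~85% adherence margin

    def test_null_model_recovers_unit_odds_ratio(self, default_cfg):
        cfg = GeneratorConfig.from_dict({
            **default_cfg.to_dict(), "n_egos": 2000,
            "adherence_baseline_log_odds": math.log(0.85 / 0.15),
            "adherence_log_or_nonmaterial": 0.0,
            "adherence_log_or_material": 0.0})
        ds = generate_dataset(cfg, seed=21)
        est = recover_parameters(ds)["material"].estimate
        assert 0.8 <= est <= 1.25
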