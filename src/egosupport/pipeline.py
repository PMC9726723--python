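"""End-to-end analysis pipeline: validate → recode → score → aggregate →
associate → report.

``run_analysis`` consumes either the three raw survey tables or a generator
configuration, and writes a reproducible report bundle:

* ``ego_descriptives.csv`` — ego-level summary by ego gender with
  chi-square/Fisher (categorical) or Welch (continuous) p-values,
* ``alter_descriptives.csv`` — alter/tie-level summary by alter gender,
* ``support_predictors.csv`` — bivariate predictors of monthly support
  event-days (ego-level rows via Welch tests, alter-level rows via
  ego-cluster-robust regression),
* ``adherence_2x2.csv`` — monthly non-material / material support vs 7-day
  adherence panels with Katz risk ratios and Cornfield odds ratios,
* ``relation_summary.csv`` + GraphML exports (relation-class star graph and
  the first few individual sociograms),
* ``tie_weights.csv`` / ``ego_summaries.csv`` — per-tie composite weights
  and classes, per-ego aggregates,
* ``manifest.json`` — config hash, seed, package versions, row counts.

Every stage failure aborts the run with the stage name; partially written
outputs are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association_stats import (TwoByTwoTable, cluster_robust_ols,
                                odds_ratio_cornfield, pearson_chi_square,
                                risk_ratio_katz, welch_t_test)
from .data_model import (Dataset, build_networks, read_dataset, write_dataset,
                         to_graph)
from .network_metrics import (alter_support_days, dataset_summaries,
                              relation_summary_graph, relation_type_summary)
from .recoding import DEFAULT_FREQUENCY_DAYS, classify_alter_age
from .synthetic_data import GeneratorConfig, generate_dataset
from .tie_strength import (components_from_record, ego_mean_tie_weight,
                           kmeans_1d, tie_weight)

__all__ = ["RunConfig", "PipelineError", "run_analysis", "twobytwo_results"]

logger = logging.getLogger("egosupport")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One analysis run: exactly one of input paths or a generator config."""

    out_dir: str
    input_paths: tuple | None = None          # (egos, alters, ties)
    generator: GeneratorConfig | None = None
    seed: int = 0
    alpha: float = 0.05
    frequency_map: dict | None = None
    satisfaction_levels: int = 5
    fisher_fallback: bool = True
    n_network_exports: int = 10
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_paths is None) == (self.generator is None):
            raise ValueError("exactly one of input_paths or generator must be set")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.frequency_map is not None:
            missing = set(DEFAULT_FREQUENCY_DAYS) - set(self.frequency_map)
            if missing:
                raise ValueError(f"frequency_map missing categories {sorted(missing)}")


def _config_hash(run_config: RunConfig) -> str:
    payload = {
        "input_paths": list(run_config.input_paths) if run_config.input_paths else None,
        "generator": run_config.generator.to_dict() if run_config.generator else None,
        "seed": run_config.seed,
        "alpha": run_config.alpha,
        "frequency_map": run_config.frequency_map,
        "satisfaction_levels": run_config.satisfaction_levels,
        "fisher_fallback": run_config.fisher_fallback,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Report tables


def _result_row(variable, level, res, extra=None):
    row = {"variable": variable, "level": level, "estimate": res.estimate,
           "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
           "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
           "method": res.method, "n": res.n}
    if extra:
        row.update(extra)
    return row


def _ego_descriptives(dataset: Dataset, alpha, fisher) -> pd.DataFrame:
    rows = []
    egos = dataset.egos
    women = [e for e in egos if e.gender == "woman"]
    men = [e for e in egos if e.gender == "man"]

    def cat_row(variable, level, selector):
        counts = [[sum(selector(e) for e in g),
                   sum(not selector(e) for e in g)] for g in (women, men)]
        table = np.array(counts).T
        try:
            p = pearson_chi_square(table, fisher_fallback=fisher, alpha=alpha)
            pv, method = p.p_value, p.method
        except ValueError:
            pv, method = math.nan, "degenerate"
        rows.append({
            "variable": variable, "level": level,
            "overall_pct": 100.0 * np.mean([selector(e) for e in egos]),
            "women_pct": 100.0 * np.mean([selector(e) for e in women]) if women else math.nan,
            "men_pct": 100.0 * np.mean([selector(e) for e in men]) if men else math.nan,
            "p_value": pv, "method": method,
        })

    def cont_row(variable, getter):
        vals_w = [getter(e) for e in women if getter(e) is not None]
        vals_m = [getter(e) for e in men if getter(e) is not None]
        allv = vals_w + vals_m
        try:
            res = welch_t_test(vals_w, vals_m, alpha=alpha)
            pv, method = res.p_value, res.method
        except ValueError:
            pv, method = math.nan, "degenerate"
        rows.append({
            "variable": variable, "level": "mean",
            "overall_pct": float(np.mean(allv)) if allv else math.nan,
            "women_pct": float(np.mean(vals_w)) if vals_w else math.nan,
            "men_pct": float(np.mean(vals_m)) if vals_m else math.nan,
            "p_value": pv, "method": method,
        })

    cont_row("age", lambda e: e.age)
    from .data_model import (MARITAL_STATUSES, EDUCATION_LEVELS, OCCUPATIONS,
                             NCD_PREVENTS_WORK_LEVELS, CONDITIONS)
    for lv in MARITAL_STATUSES:
        cat_row("marital_status", lv, lambda e, lv=lv: e.marital_status == lv)
    for lv in EDUCATION_LEVELS:
        cat_row("education", lv, lambda e, lv=lv: e.education == lv)
    cont_row("household_size", lambda e: e.household_size)
    for lv in OCCUPATIONS:
        cat_row("occupation", lv, lambda e, lv=lv: e.occupation == lv)
    for lv in NCD_PREVENTS_WORK_LEVELS:
        cat_row("ncd_prevents_work", lv, lambda e, lv=lv: e.ncd_prevents_work == lv)
    cat_row("insured", "yes", lambda e: e.insured)
    for c in CONDITIONS:
        cat_row("condition", c, lambda e, c=c: c in e.conditions)
    cat_row("multimorbid", "yes", lambda e: e.multimorbid)
    cat_row("adherent_7d", "yes", lambda e: e.adherent_7d)
    cont_row("systolic", lambda e: e.systolic)
    cont_row("diastolic", lambda e: e.diastolic)
    cont_row("random_glucose", lambda e: e.random_glucose)
    n_alters = {e.ego_id: 0 for e in egos}
    for a in dataset.alters:
        n_alters[a.ego_id] += 1
    cont_row("n_alters", lambda e: n_alters[e.ego_id])
    return pd.DataFrame(rows)


def _alter_descriptives(dataset: Dataset, alpha, fisher) -> pd.DataFrame:
    rows = []
    alters = dataset.alters
    women = [a for a in alters if a.alter_gender == "woman"]
    men = [a for a in alters if a.alter_gender == "man"]

    def cat_row(variable, level, selector):
        table = np.array([[sum(selector(a) for a in g),
                           sum(not selector(a) for a in g)]
                          for g in (women, men)]).T
        try:
            p = pearson_chi_square(table, fisher_fallback=fisher, alpha=alpha)
            pv, method = p.p_value, p.method
        except ValueError:
            pv, method = math.nan, "degenerate"
        rows.append({
            "variable": variable, "level": level,
            "overall_pct": 100.0 * np.mean([selector(a) for a in alters]),
            "women_pct": 100.0 * np.mean([selector(a) for a in women]) if women else math.nan,
            "men_pct": 100.0 * np.mean([selector(a) for a in men]) if men else math.nan,
            "p_value": pv, "method": method,
        })

    from .data_model import (RELATIONS, AGE_BRACKETS, PROXIMITIES,
                             TIME_KNOWN_LEVELS, FREQUENCY_CATEGORIES,
                             SATISFACTION_LEVELS)
    from .recoding import homophily_gender
    egos_by_id = {e.ego_id: e for e in dataset.egos}
    for lv in RELATIONS:
        cat_row("relation", lv, lambda a, lv=lv: a.relation == lv)
    cat_row("homophily_gender", "yes",
            lambda a: homophily_gender(egos_by_id[a.ego_id].gender, a.alter_gender))
    for lv in AGE_BRACKETS:
        cat_row("alter_age_bracket", lv, lambda a, lv=lv: a.alter_age_bracket == lv)
    for lv in PROXIMITIES:
        cat_row("proximity", lv, lambda a, lv=lv: a.proximity == lv)
    for lv in TIME_KNOWN_LEVELS:
        cat_row("time_known", lv, lambda a, lv=lv: a.time_known == lv)
    for lv in FREQUENCY_CATEGORIES:
        cat_row("contact_freq", lv, lambda a, lv=lv: a.contact_freq == lv)
    for lv in SATISFACTION_LEVELS:
        cat_row("satisfaction", lv, lambda a, lv=lv: a.satisfaction == lv)
    cat_row("provides_emotional", "yes", lambda a: a.provides_emotional)
    cat_row("provides_informational", "yes", lambda a: a.provides_informational)
    cat_row("provides_material", "yes", lambda a: a.provides_material)
    amounts_w = [a.money_amount for a in women if a.money_amount is not None]
    amounts_m = [a.money_amount for a in men if a.money_amount is not None]
    try:
        res = welch_t_test(amounts_w, amounts_m, alpha=alpha)
        pv, method = res.p_value, res.method
    except ValueError:
        pv, method = math.nan, "degenerate"
    allv = amounts_w + amounts_m
    rows.append({"variable": "money_amount", "level": "mean",
                 "overall_pct": float(np.mean(allv)) if allv else math.nan,
                 "women_pct": float(np.mean(amounts_w)) if amounts_w else math.nan,
                 "men_pct": float(np.mean(amounts_m)) if amounts_m else math.nan,
                 "p_value": pv, "method": method})
    return pd.DataFrame(rows)


def _support_predictors(dataset: Dataset, summaries, alpha,
                        frequency_map) -> pd.DataFrame:
    """Bivariate predictors of monthly support event-days (Welch at the ego
    level, cluster-robust OLS at the tie level), for both support kinds."""
    rows = []
    by_id = {s.ego_id: s for s in summaries}
    egos = dataset.egos

    def welch_row(variable, lev1, lev0, split):
        g1 = [e for e in egos if split(e)]
        g0 = [e for e in egos if not split(e)]
        for kind, attr in (("nonmaterial", "nonmaterial_days"),
                           ("material", "material_days")):
            try:
                res = welch_t_test([getattr(by_id[e.ego_id], attr) for e in g1],
                                   [getattr(by_id[e.ego_id], attr) for e in g0],
                                   alpha=alpha)
                rows.append(_result_row(variable, f"{lev1} vs {lev0}", res,
                                        {"outcome": kind, "level_kind": "ego"}))
            except ValueError as exc:
                logger.debug("skipping %s (%s): %s", variable, kind, exc)

    median_age = float(np.median([e.age for e in egos]))
    welch_row("ego_gender", "woman", "man", lambda e: e.gender == "woman")
    welch_row("ego_age", f"<{median_age:g}", f">={median_age:g}",
              lambda e: e.age < median_age)
    welch_row("marital", "widowed_or_single", "partnered",
              lambda e: e.marital_status not in ("married", "living_with_partner"))
    welch_row("ncd_prevents_work", "ever", "never",
              lambda e: e.ncd_prevents_work != "never")
    welch_row("multimorbid", "yes", "no", lambda e: e.multimorbid)

    # tie-level regressions with ego clustering
    alters = dataset.alters
    egos_by_id = {e.ego_id: e for e in dataset.egos}
    cluster = [a.ego_id for a in alters]
    for kind in ("nonmaterial", "material"):
        y = [alter_support_days(a, kind, frequency_map) for a in alters]

        def reg(variable, X, names):
            try:
                res = cluster_robust_ols(y, X, cluster, names=names, alpha=alpha)
            except ValueError as exc:
                logger.debug("skipping %s (%s): %s", variable, kind, exc)
                return
            for r, nm in zip(res[1:], names):  # skip intercept
                rows.append(_result_row(variable, nm, r,
                                        {"outcome": kind, "level_kind": "alter"}))

        reg("alter_gender",
            np.array([[a.alter_gender == "man" for a in alters]], dtype=float).T,
            ["man_vs_woman"])
        reg("alter_age",
            np.array([[classify_alter_age(egos_by_id[a.ego_id].age,
                                          a.alter_age_bracket) == "same_or_older"
                       for a in alters]], dtype=float).T,
            ["same_or_older_vs_younger"])
        reg("daily_contact",
            np.array([[a.contact_freq == "every_day" for a in alters]],
                     dtype=float).T,
            ["daily_vs_less"])
        rel_levels = ["significant_other", "other_family", "friend",
                      "neighbour", "parent", "other"]
        present = [lv for lv in rel_levels
                   if any(a.relation == lv for a in alters)]
        if present and any(a.relation == "child" for a in alters):
            X = np.array([[a.relation == lv for a in alters]
                          for lv in present], dtype=float).T
            reg("relation_vs_child", X, [f"{lv}_vs_child" for lv in present])
        reg("same_household",
            np.array([[a.proximity == "same_household" for a in alters]],
                     dtype=float).T,
            ["same_household_vs_other"])
    return pd.DataFrame(rows)


def _adherence_panels(dataset: Dataset, summaries, alpha) -> pd.DataFrame:
    adherent = {e.ego_id: e.adherent_7d for e in dataset.egos}
    rows = []
    for kind, flag in (("nonmaterial", "monthly_nonmaterial"),
                       ("material", "monthly_material")):
        a = b = c = d = 0
        for s in summaries:
            exp_, out_ = getattr(s, flag), adherent[s.ego_id]
            a += exp_ and out_
            b += exp_ and not out_
            c += (not exp_) and out_
            d += (not exp_) and not out_
        t = TwoByTwoTable(int(a), int(b), int(c), int(d))
        base = {"panel": kind, "a": t.a, "b": t.b, "c": t.c, "d": t.d}
        try:
            rr = risk_ratio_katz(t, alpha=alpha)
            rows.append({**base, **_result_row("monthly_" + kind, "rr", rr)})
        except ValueError as exc:
            logger.debug("risk ratio unavailable for %s: %s", kind, exc)
        try:
            orr = odds_ratio_cornfield(t, alpha=alpha)
            rows.append({**base, **_result_row("monthly_" + kind, "or", orr)})
        except (ValueError, RuntimeError) as exc:
            logger.debug("odds ratio unavailable for %s: %s", kind, exc)
    return pd.DataFrame(rows)


def twobytwo_results(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> dict:
    """Katz RR and Cornfield OR for raw 2x2 cell counts (exposure rows)."""
    t = TwoByTwoTable(a, b, c, d)
    return {"table": t, "risk_ratio": risk_ratio_katz(t, alpha=alpha),
            "odds_ratio": odds_ratio_cornfield(t, alpha=alpha),
            "chi_square": pearson_chi_square([[a, b], [c, d]], alpha=alpha)}


# ---------------------------------------------------------------------------
# Orchestration


def run_analysis(run_config: RunConfig) -> dict:
    """Execute the full pipeline; returns a manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    run_config.validate()
    logging.basicConfig(level=run_config.log_level)
    out = Path(run_config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list = []

    def emit_csv(name, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(df))
        return path

    stage = "load"
    try:
        if run_config.generator is not None:
            stage = "simulate"
            dataset = generate_dataset(run_config.generator, run_config.seed)
            for p, n in zip(("egos.csv", "alters.csv", "alter_ties.csv"),
                            ("egos", "alters", "ties")):
                written.append(out / p)
            write_dataset(dataset, out / "egos.csv", out / "alters.csv",
                          out / "alter_ties.csv")
            report = None
        else:
            stage = "validate"
            dataset, report = read_dataset(*run_config.input_paths)
            if not dataset.egos:
                raise PipelineError(stage, "no valid egos after validation")
            (out / "validation_report.json").write_text(
                json.dumps(report.to_dict(), indent=2))
            written.append(out / "validation_report.json")
        logger.info("stage %s: %d egos, %d alters, %d tie rows", stage,
                    len(dataset.egos), len(dataset.alters), len(dataset.ties))

        stage = "score"
        networks = build_networks(dataset)
        tie_rows, ego_weights = [], []
        for nw in networks:
            for a in nw.alters:
                w = tie_weight(components_from_record(
                    a, run_config.satisfaction_levels))
                tie_rows.append({"ego_id": a.ego_id,
                                 "alter_index": a.alter_index, "weight": w})
            ego_weights.append(ego_mean_tie_weight(
                nw, run_config.satisfaction_levels))
        # three-class split needs at least three values; tiny datasets stay unclassified
        from .tie_strength import TieClassAssignment
        def classify(values):
            if len(values) >= 3:
                return kmeans_1d(values, k=3)
            return TieClassAssignment(labels=["unclassified"] * len(values),
                                      centers=[], sse=float("nan"))
        assignment = classify(ego_weights)
        tie_assignment = classify([r["weight"] for r in tie_rows])
        for r, cls in zip(tie_rows, tie_assignment.labels):
            r["tie_class"] = cls
        emit_csv("tie_weights.csv", pd.DataFrame(tie_rows))

        stage = "aggregate"
        summaries = dataset_summaries(dataset, run_config.frequency_map)
        ego_df = pd.DataFrame([vars(s) for s in summaries])
        ego_df["mean_tie_weight"] = ego_weights
        ego_df["tie_class"] = assignment.labels
        emit_csv("ego_summaries.csv", ego_df)

        stage = "describe"
        emit_csv("ego_descriptives.csv",
                 _ego_descriptives(dataset, run_config.alpha,
                                   run_config.fisher_fallback))
        emit_csv("alter_descriptives.csv",
                 _alter_descriptives(dataset, run_config.alpha,
                                     run_config.fisher_fallback))

        stage = "associate"
        emit_csv("support_predictors.csv",
                 _support_predictors(dataset, summaries, run_config.alpha,
                                     run_config.frequency_map))
        emit_csv("adherence_2x2.csv",
                 _adherence_panels(dataset, summaries, run_config.alpha))

        stage = "graphs"
        rel = relation_type_summary(dataset, run_config.frequency_map)
        emit_csv("relation_summary.csv", pd.DataFrame([vars(r) for r in rel]))
        import networkx as nx
        nx.write_graphml(relation_summary_graph(rel),
                         out / "relation_summary.graphml")
        written.append(out / "relation_summary.graphml")
        weights_by_ego: dict = {}
        for r in tie_rows:
            weights_by_ego.setdefault(r["ego_id"], []).append(r["weight"])
        for nw in networks[:run_config.n_network_exports]:
            path = out / f"network_{nw.ego.ego_id}.graphml"
            nx.write_graphml(to_graph(nw, weights_by_ego[nw.ego.ego_id]), path)
            written.append(path)

        stage = "manifest"
        manifest = {
            "config_hash": _config_hash(run_config),
            "seed": run_config.seed,
            "alpha": run_config.alpha,
            "package_version": __version__,
            "frequency_map": run_config.frequency_map or DEFAULT_FREQUENCY_DAYS,
            "n_egos": len(dataset.egos),
            "n_alters": len(dataset.alters),
            "n_tie_rows": len(dataset.ties),
            "validation": report.to_dict() if report is not None else None,
            "tie_class_centers": assignment.centers,
            "tie_class_counts": {lab: assignment.labels.count(lab)
                                 for lab in ("weak", "medium", "strong")},
            "mean_tie_weight": float(np.mean(ego_weights)),
            "artifacts": sorted(p.name for p in written),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc
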