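"""Composite tie-strength scoring and the weak/medium/strong classification.

Each ego–alter tie gets a relationship-strength score in [0, 1]: the
arithmetic mean of eight components — residential proximity, relationship
duration, contact frequency, support frequency, reciprocity, provision of
non-material support, provision of material support, and the ego's
satisfaction with the alter's support.  Non-binary components are first
scaled linearly to the unit interval.  Components that are genuinely
unobserved (e.g. support frequency for an alter providing no support) are
dropped and the mean renormalised over the rest, so "unknown" is never
conflated with "weakest possible".

Egos are then classified into weak/medium/strong average-tie classes with a
*globally optimal* one-dimensional k-means (dynamic programming over sorted
values) — no random initialisation, hence a fully reproducible split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .data_model import (AlterRecord, EgoNetwork, FREQUENCY_CATEGORIES,
                         PROXIMITIES, SATISFACTION_LEVELS, TIME_KNOWN_LEVELS)
from .recoding import scale_ordinal

__all__ = ["TieComponents", "TieClassAssignment", "components_from_record",
           "tie_weight", "ego_mean_tie_weight", "kmeans_1d"]

CLASS_LABELS = ("weak", "medium", "strong")


@dataclass
class TieComponents:
    """The eight unit-interval components of the composite tie weight.

    ``None`` marks a component as missing (excluded, mean renormalised).
    """

    proximity_score: float | None
    duration_score: float | None
    contact_freq_score: float | None
    support_freq_score: float | None
    reciprocity: float | None
    provides_nonmaterial: float | None
    provides_material: float | None
    satisfaction_score: float | None

    def values(self):
        return [getattr(self, f.name) for f in fields(self)]


def _reversed_scale(value: str, vocab) -> float:
    # vocab ordered strongest-first (closest / most frequent = rank 0)
    return 1.0 - scale_ordinal(vocab.index(value), len(vocab))


def components_from_record(alter: AlterRecord,
                           satisfaction_levels: int = 5) -> TieComponents:
    """Derive the eight tie components from a validated alter record.

    Support frequency is the strongest (most frequent) of the sub-type
    frequencies the alter actually provides, or missing when the alter
    provides no support at all.  Satisfaction is scaled over the
    instrument's declared level count (default 5-level Likert), not over the
    levels observed in any one sample.
    """
    freq_scores = [
        _reversed_scale(f, FREQUENCY_CATEGORIES)
        for f in (alter.emotional_freq, alter.informational_freq,
                  alter.material_freq) if f is not None
    ]
    return TieComponents(
        proximity_score=_reversed_scale(alter.proximity, PROXIMITIES),
        duration_score=scale_ordinal(TIME_KNOWN_LEVELS.index(alter.time_known),
                                     len(TIME_KNOWN_LEVELS)),
        contact_freq_score=_reversed_scale(alter.contact_freq, FREQUENCY_CATEGORIES),
        support_freq_score=max(freq_scores) if freq_scores else None,
        reciprocity=float(alter.reciprocated_by_ego),
        provides_nonmaterial=float(alter.provides_emotional
                                   or alter.provides_informational),
        provides_material=float(alter.provides_material),
        satisfaction_score=scale_ordinal(
            SATISFACTION_LEVELS.index(alter.satisfaction), satisfaction_levels),
    )


def tie_weight(components: TieComponents) -> float:
    """Composite tie strength: mean of the available components, in [0, 1]."""
    vals = [v for v in components.values() if v is not None]
    if not vals:
        raise ValueError("all eight tie components missing; weight undefined")
    for v in vals:
        if not (0.0 <= v <= 1.0) or not math.isfinite(v):
            raise ValueError(f"tie component {v} outside [0, 1]")
    return float(sum(vals) / len(vals))


def ego_mean_tie_weight(network: EgoNetwork,
                        satisfaction_levels: int = 5) -> float:
    """Mean composite tie weight over an ego's alters."""
    if network.n_alters == 0:
        raise ValueError("ego network has no alters")
    weights = [tie_weight(components_from_record(a, satisfaction_levels))
               for a in network.alters]
    return float(np.mean(weights))


# ---------------------------------------------------------------------------
# Exact 1-D k-means


@dataclass
class TieClassAssignment:
    """Result of the 1-D k-means split: per-value labels and sorted centers."""

    labels: list           # per input value, in input order
    centers: list          # ascending cluster means
    sse: float             # within-cluster sum of squares


def kmeans_1d(values, k: int = 3) -> TieClassAssignment:
    """Globally optimal one-dimensional k-means by dynamic programming.

    An optimal 1-D partition is contiguous in sorted order, so the DP over
    sorted values attains the minimum within-cluster sum of squares exactly
    and deterministically — no random initialisation.  For k = 3 the labels
    are ``weak < medium < strong`` by ascending center; for other k they are
    ``class_0 .. class_{k-1}``.  Boundary ties break toward the lower
    cluster, so equal values always share a label.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    if k < 1:
        raise ValueError("k must be positive")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1 = np.concatenate(([0.0], np.cumsum(xs)))
    s2 = np.concatenate(([0.0], np.cumsum(xs * xs)))

    def seg_cost(i: int, j: int) -> float:
        # SSE of xs[i..j] inclusive
        m = j - i + 1
        s = s1[j + 1] - s1[i]
        return max(0.0, (s2[j + 1] - s2[i]) - s * s / m)

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    dp[0][0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, best_i = INF, m - 1
            for i in range(m - 1, j):
                c = dp[m - 1][i] + seg_cost(i, j - 1)
                if c <= best:  # <=: prefer the latest split -> boundary ties fall low
                    best, best_i = c, i
            dp[m][j] = best
            split[m][j] = best_i

    # recover cluster boundaries
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = split[m][j]
        bounds.append(j)
    bounds.reverse()  # [0, b1, ..., n]

    sorted_labels = np.empty(n, dtype=int)
    for c in range(k):
        sorted_labels[bounds[c]:bounds[c + 1]] = c
    # pull equal values across a boundary into the lower cluster
    for i in range(1, n):
        if xs[i] == xs[i - 1] and sorted_labels[i] != sorted_labels[i - 1]:
            sorted_labels[i] = sorted_labels[i - 1]
    centers = [float(xs[sorted_labels == c].mean())
               if np.any(sorted_labels == c) else float("nan")
               for c in range(k)]

    labels_int = np.empty(n, dtype=int)
    labels_int[order] = sorted_labels
    names = CLASS_LABELS if k == 3 else tuple(f"class_{i}" for i in range(k))
    return TieClassAssignment(labels=[names[i] for i in labels_int],
                              centers=centers, sse=float(dp[k][n]))
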