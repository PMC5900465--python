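"""Bootstrap-stability coping classification.

The classifier assumes per-animal average defeat latencies are drawn
from a bimodal distribution: a short-latency (passive-coping,
vulnerable) and a long-latency (active-coping, resilient) component.
It clusters the averages with PAM (k = 2), then quantifies the
uncertainty of each animal's assignment by resampling:

1. draw ``n`` latencies with replacement from the original averages;
2. refit PAM on the resample;
3. classify every original average by its nearest medoid of that fit,
   calling the higher-medoid cluster "active";
4. after ``B`` iterations (default 10,000), each animal's active-coping
   probability ``p_active`` is the fraction of iterations in which it
   was classified active.

Animals consistently classified have ``p_active`` 0.0 or 1.0.  Animals
with ``p_active`` strictly between the thresholds (defaults 0.1 and
0.9) changed classification in more than 10% of resamples and are
excluded as ambiguous; the boundary values themselves are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pam import pam_k2_batch

__all__ = [
    "BootstrapConfig",
    "CohortClassification",
    "ClassificationError",
    "average_latency",
    "average_latencies",
    "bootstrap_probabilities",
    "classify_cohort",
]

#: Redraw budget for degenerate resamples, as a multiple of n_iterations.
MAX_REDRAW_FACTOR = 10


class ClassificationError(ValueError):
    """Raised on inputs the classifier cannot work with."""


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap-stability settings.

    ``n_iterations`` resamples (B); animals with active-coping
    probability in the open interval (``lower_threshold``,
    ``upper_threshold``) are excluded. ``k`` is fixed at 2 — one cluster
    per coping style.
    """

    n_iterations: int = 10_000
    lower_threshold: float = 0.1
    upper_threshold: float = 0.9
    seed: int = 0
    k: int = 2

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ClassificationError("n_iterations must be >= 1")
        if not (0.0 <= self.lower_threshold < self.upper_threshold <= 1.0):
            raise ClassificationError(
                "need 0 <= lower_threshold < upper_threshold <= 1, got "
                f"({self.lower_threshold}, {self.upper_threshold})"
            )
        if self.k != 2:
            raise ClassificationError("the coping pipeline supports k = 2 only")


@dataclass(frozen=True)
class CohortClassification:
    """Classification of one cohort.

    ``table`` has one row per animal: ``animal_id, avg_latency_s,
    p_active, label`` with label in {passive, active, excluded}.
    """

    table: pd.DataFrame
    n_excluded: int
    exclusion_fraction: float
    n_degenerate_redraws: int
    config: BootstrapConfig


def average_latency(latencies, day_range: tuple[int, int] | None = None) -> float:
    """Arithmetic mean defeat latency for one animal.

    ``latencies`` is either a sequence of per-day latencies (seconds;
    censored encounters enter at the cap value) or a DataFrame with
    ``day`` and ``latency_s`` columns. ``day_range`` restricts to an
    inclusive day window — the phenotyping window is days 1–7 when
    defeat runs a full week, days 1–5 when drug treatment starts on
    day 6.
    """
    if isinstance(latencies, pd.DataFrame):
        sub = latencies
        if day_range is not None:
            sub = sub[sub["day"].between(*day_range)]
        values = sub["latency_s"].to_numpy(dtype=float)
    else:
        values = np.asarray(latencies, dtype=float)
        if day_range is not None:
            values = values[day_range[0] - 1 : day_range[1]]
    if values.size == 0:
        raise ClassificationError("no latencies in the requested day window")
    return float(values.mean())


def average_latencies(
    latency_table: pd.DataFrame, day_range: tuple[int, int] | None = None
) -> pd.Series:
    """Per-animal average latency over a day window, indexed by animal_id."""
    sub = latency_table
    if day_range is not None:
        sub = sub[sub["day"].between(*day_range)]
    if sub.empty:
        raise ClassificationError("no latencies in the requested day window")
    missing = set(latency_table["animal_id"]) - set(sub["animal_id"])
    if missing:
        raise ClassificationError(
            f"animals with no latencies in day window: {sorted(missing)[:5]}"
        )
    avg = sub.groupby("animal_id", sort=False)["latency_s"].mean()
    avg.name = "avg_latency_s"
    return avg


def _resample_indices(
    rng: np.random.Generator, x: np.ndarray, n_iterations: int
) -> tuple[np.ndarray, int]:
    """Index matrix (B, n) of bootstrap resamples; degenerate rows redrawn.

    A resample with fewer than two distinct values cannot be split into
    two clusters; such rows are redrawn from the same stream, with a
    hard budget of ``MAX_REDRAW_FACTOR * B`` redraws.
    """
    n = x.size
    idx = rng.integers(0, n, size=(n_iterations, n))
    redraws = 0
    budget = MAX_REDRAW_FACTOR * n_iterations
    bad = np.flatnonzero(np.ptp(x[idx], axis=1) == 0)
    while bad.size:
        redraws += bad.size
        if redraws > budget:
            raise ClassificationError(
                "too many degenerate bootstrap resamples; cohort latencies "
                "are nearly constant"
            )
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
        bad = bad[np.ptp(x[idx[bad]], axis=1) == 0]
    return idx, redraws


def bootstrap_probabilities(
    avg_latencies, config: BootstrapConfig
) -> tuple[np.ndarray, int]:
    """Active-coping probability for each animal.

    For each of B iterations, resample the averages with replacement,
    fit PAM (k = 2), and classify every original average by its nearest
    medoid (the higher-medoid cluster is active; an exact midpoint tie
    goes to the lower, passive medoid). Deterministic given
    ``config.seed``.

    Returns
    -------
    (p_active, n_redraws)
        ``p_active[i]`` is the fraction of iterations classifying
        animal i active, an exact multiple of 1/B; ``n_redraws`` counts
        degenerate resamples that were redrawn.
    """
    config.validate()
    x = np.asarray(avg_latencies, dtype=float)
    if x.ndim != 1:
        raise ClassificationError("avg_latencies must be one-dimensional")
    if np.unique(x).size < 2:
        raise ClassificationError(
            "need at least 2 distinct average latencies to classify"
        )
    rng = np.random.default_rng(config.seed)
    idx, redraws = _resample_indices(rng, x, config.n_iterations)
    m_low, m_high, _ = pam_k2_batch(x[idx])
    midpoint = 0.5 * (m_low + m_high)
    # strict > : a value exactly equidistant assigns to the lower medoid
    active_counts = (x[None, :] > midpoint[:, None]).sum(axis=0)
    return active_counts / config.n_iterations, redraws


def label_from_probability(p_active: float, config: BootstrapConfig) -> str:
    """Threshold rule: active at/above upper, passive at/below lower,
    excluded strictly between (the boundary values are retained)."""
    if p_active >= config.upper_threshold:
        return "active"
    if p_active <= config.lower_threshold:
        return "passive"
    return "excluded"


def classify_cohort(avg_latencies, config: BootstrapConfig) -> CohortClassification:
    """Classify a cohort's average latencies as passive / active / excluded.

    ``avg_latencies`` is a mapping or Series indexed by animal id, or a
    plain sequence (ids then default to positions). Labels: active if
    ``p_active >= upper_threshold``, passive if ``<= lower_threshold``,
    excluded otherwise (ambiguous under resampling).
    """
    if isinstance(avg_latencies, dict):
        avg_latencies = pd.Series(avg_latencies)
    if isinstance(avg_latencies, pd.Series):
        ids = avg_latencies.index.to_numpy()
        values = avg_latencies.to_numpy(dtype=float)
    else:
        values = np.asarray(avg_latencies, dtype=float)
        ids = np.arange(values.size)
    if values.size == 0:
        raise ClassificationError("empty cohort: no average latencies")

    p_active, redraws = bootstrap_probabilities(values, config)
    label = np.where(
        p_active >= config.upper_threshold,
        "active",
        np.where(p_active <= config.lower_threshold, "passive", "excluded"),
    )
    table = pd.DataFrame(
        {
            "animal_id": ids,
            "avg_latency_s": values,
            "p_active": p_active,
            "label": label,
        }
    )
    n_excluded = int((label == "excluded").sum())
    return CohortClassification(
        table=table,
        n_excluded=n_excluded,
        exclusion_fraction=n_excluded / values.size,
        n_degenerate_redraws=redraws,
        config=config,
    )
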