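"""Synthetic social-defeat cohorts.

Emulates the data structure of a resident–intruder social-defeat study:
each defeated animal carries a latent coping phenotype (passive =
short defeat latency, vulnerable; active = long latency, resilient),
its per-day defeat latencies are the phenotype's true mean plus
day-to-day noise, right-censored at the encounter cap (900 s = 15 min),
hypothalamic prepro-orexin expression decreases linearly with average
latency, and post-defeat behavioral endpoints (social interaction,
forced swim test) are drawn per stress-by-drug cell.

The generator exists so the classification and statistics stages can be
exercised end to end with known ground truth: the hidden phenotype of
every animal is returned in a separate truth table that downstream
stages never see.

Model summary
-------------
* phenotype ~ Bernoulli(pi_active); true mean latency ~ truncated
  normal per component on [floor, cap] (components 182 s / 419 s by
  default, matching the passive/active cluster means the pipeline is
  expected to recover);
* daily latency = true mean + N(0, sigma_within), clipped to
  [floor, cap]; a latency at the cap is flagged censored (no defeat
  within 15 min);
* expression_i = beta0 + beta1 * avg_latency_i + N(0, sigma_expr) for
  defeated animals (beta1 < 0); controls draw from their own
  mean/SD since they have no defeat latencies;
* each behavioral endpoint is drawn N(mean, SD) from its
  stress-by-drug cell; forced-swim percentages (immobile/swim/climb)
  are renormalized to sum to 100 within each animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CohortModelParams",
    "Cohort",
    "ParameterError",
    "CohortDataError",
    "DEFAULT_BEHAVIOR_CELLS",
    "FST_ENDPOINTS",
    "generate_latencies",
    "generate_expression",
    "generate_behavior",
    "generate_cohort",
]

STRESS_LEVELS = ("control", "passive", "active")
DRUG_LEVELS = ("vehicle", "CNO")

#: Forced-swim endpoints whose percentages must sum to 100 per animal.
FST_ENDPOINTS = ("fst_pct_immobile", "fst_pct_swim", "fst_pct_climb")

BEHAVIOR_ENDPOINTS = (
    "interaction_time_s",
    "interaction_latency_s",
    "distance_cm",
) + FST_ENDPOINTS


class ParameterError(ValueError):
    """A cohort parameter violates an invariant (message names it)."""


class CohortDataError(ValueError):
    """Input table is missing data the generator needs."""


def _cells(means: Mapping[tuple[str, str], float], sd: float):
    return {cell: (m, sd) for cell, m in means.items()}


#: Default stress-by-drug cell means/SDs, ordered to reproduce the
#: qualitative study findings: vehicle-treated passive copers interact
#: less than active copers and are more immobile than controls; CNO
#: (orexin-neuron inhibition during the last defeats) normalizes both in
#: passive copers, raises immobility in controls, and leaves active
#: copers unchanged.
DEFAULT_BEHAVIOR_CELLS: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "interaction_time_s": _cells(
        {
            ("control", "vehicle"): 100.0,
            ("control", "CNO"): 100.0,
            ("passive", "vehicle"): 55.0,
            ("passive", "CNO"): 105.0,
            ("active", "vehicle"): 105.0,
            ("active", "CNO"): 105.0,
        },
        25.0,
    ),
    "interaction_latency_s": _cells(
        {(s, d): 18.0 for s in STRESS_LEVELS for d in DRUG_LEVELS}, 10.0
    ),
    "distance_cm": _cells(
        {(s, d): 22000.0 for s in STRESS_LEVELS for d in DRUG_LEVELS}, 5000.0
    ),
    "fst_pct_immobile": _cells(
        {
            ("control", "vehicle"): 21.0,
            ("control", "CNO"): 36.0,
            ("passive", "vehicle"): 38.0,
            ("passive", "CNO"): 25.0,
            ("active", "vehicle"): 23.0,
            ("active", "CNO"): 23.0,
        },
        8.0,
    ),
    "fst_pct_swim": _cells(
        {
            ("control", "vehicle"): 52.0,
            ("control", "CNO"): 40.0,
            ("passive", "vehicle"): 38.0,
            ("passive", "CNO"): 45.0,
            ("active", "vehicle"): 50.0,
            ("active", "CNO"): 50.0,
        },
        8.0,
    ),
    # climb completes each cell to 100 so that FST cell means are already a
    # percentage composition; per-animal draws are renormalized to 100
    "fst_pct_climb": _cells(
        {
            ("control", "vehicle"): 27.0,
            ("control", "CNO"): 24.0,
            ("passive", "vehicle"): 24.0,
            ("passive", "CNO"): 30.0,
            ("active", "vehicle"): 27.0,
            ("active", "CNO"): 27.0,
        },
        6.0,
    ),
}


@dataclass(frozen=True)
class CohortModelParams:
    """All generative parameters of a synthetic cohort.

    Latency units are seconds; expression units are arbitrary
    densitometry units. ``sigma_between_*`` are between-animal SDs of
    the true mean latency; ``sigma_within`` is the day-to-day SD around
    an animal's true mean.  Defaults put the passive and active average
    latency clusters on either side of 300 s.
    """

    n_control: int = 16
    n_defeated: int = 32
    days: int = 7
    pi_active: float = 0.5
    mu_passive: float = 182.0
    mu_active: float = 419.0
    sigma_between_passive: float = 45.0
    sigma_between_active: float = 60.0
    sigma_within: float = 60.0
    latency_floor: float = 3.0
    latency_cap: float = 900.0
    beta0: float = 2000.0
    beta1: float = -2.0
    sigma_expr: float = 430.0
    control_expr_mean: float = 1650.0
    control_expr_sd: float = 430.0
    behavior_cells: dict[str, dict[tuple[str, str], tuple[float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_BEHAVIOR_CELLS.items()
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 0 or self.n_defeated < 0:
            raise ParameterError("animal counts must be >= 0")
        if self.days < 1:
            raise ParameterError("days must be >= 1")
        if not 0.0 <= self.pi_active <= 1.0:
            raise ParameterError("pi_active must lie in [0, 1]")
        if not self.mu_passive < self.mu_active:
            raise ParameterError(
                f"mu_passive ({self.mu_passive}) must be < mu_active ({self.mu_active})"
            )
        if not self.latency_floor < self.latency_cap:
            raise ParameterError("latency_floor must be < latency_cap")
        if min(
            self.sigma_between_passive,
            self.sigma_between_active,
            self.sigma_within,
            self.sigma_expr,
            self.control_expr_sd,
        ) < 0:
            raise ParameterError("standard deviations must be >= 0")
        if self.beta1 >= 0:
            raise ParameterError(
                f"beta1 must be < 0 (expression decreases with latency), got {self.beta1}"
            )
        for endpoint, cells in self.behavior_cells.items():
            for s in STRESS_LEVELS:
                for d in DRUG_LEVELS:
                    if (s, d) not in cells:
                        raise ParameterError(
                            f"behavior_cells[{endpoint!r}] missing cell {(s, d)}"
                        )

    def with_updates(self, **kwargs) -> "CohortModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Cohort:
    """All tables of one generated cohort.

    ``truth`` holds the hidden per-animal phenotype and true mean
    latency; it is written to its own clearly named file and is never an
    input to the classification or statistics stages.
    """

    latencies: pd.DataFrame
    truth: pd.DataFrame
    expression: pd.DataFrame
    behavior: pd.DataFrame
    params: CohortModelParams


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams derived deterministically from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_true_means(
    rng: np.random.Generator, n: int, mu: float, sigma: float, lo: float, hi: float
) -> np.ndarray:
    """Truncated-normal true means; sigma = 0 degenerates to a clipped constant."""
    if n == 0:
        return np.empty(0)
    if sigma == 0:
        return np.full(n, np.clip(mu, lo, hi))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def generate_latencies(
    params: CohortModelParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the daily latency table and the hidden truth table.

    Returns
    -------
    (latencies, truth)
        ``latencies`` has one row per defeated animal per day with
        columns ``animal_id, group, drug, day, latency_s, censored``.
        Control animals experience no defeat and carry no latency rows;
        they appear only in ``truth`` (phenotype ``control``, true mean
        marked not-applicable). ``truth`` also records each defeated
        animal's latent phenotype and true mean latency.
    """
    params.validate()
    rng_pheno, rng_mean, rng_day, rng_drug = _streams(params.seed, 4)

    n_c, n_d = params.n_control, params.n_defeated
    ids = np.array(
        [f"C{i + 1:03d}" for i in range(n_c)] + [f"D{i + 1:03d}" for i in range(n_d)]
    )
    group = np.array(["control"] * n_c + ["defeated"] * n_d)

    is_active = rng_pheno.random(n_d) < params.pi_active
    phenotype = np.concatenate(
        [
            np.array(["control"] * n_c),
            np.where(is_active, "active", "passive"),
        ]
    )

    true_mean = np.full(n_c + n_d, np.nan)
    lo, hi = params.latency_floor, params.latency_cap
    n_act = int(is_active.sum())
    # Draw per phenotype; fixed draw order keeps streams reproducible.
    passive_means = _draw_true_means(
        rng_mean, n_d - n_act, params.mu_passive, params.sigma_between_passive, lo, hi
    )
    active_means = _draw_true_means(
        rng_mean, n_act, params.mu_active, params.sigma_between_active, lo, hi
    )
    defeated_means = np.empty(n_d)
    defeated_means[~is_active] = passive_means
    defeated_means[is_active] = active_means
    true_mean[n_c:] = defeated_means

    # Balanced vehicle/CNO assignment within each phenotype stratum.
    drug = np.empty(n_c + n_d, dtype=object)
    for pheno in STRESS_LEVELS:
        idx = np.flatnonzero(phenotype == pheno)
        half = [DRUG_LEVELS[i % 2] for i in range(idx.size)]
        drug[idx[rng_drug.permutation(idx.size)]] = half

    truth = pd.DataFrame(
        {
            "animal_id": ids,
            "group": group,
            "drug": drug.astype(str),
            "phenotype": phenotype,
            "true_mean_latency_s": true_mean,
        }
    )

    if n_d == 0:
        latencies = pd.DataFrame(
            columns=["animal_id", "group", "drug", "day", "latency_s", "censored"]
        )
        return latencies, truth

    noise = rng_day.normal(0.0, params.sigma_within, size=(n_d, params.days))
    raw = defeated_means[:, None] + noise
    clipped = np.clip(raw, lo, hi)
    censored = clipped >= hi

    day = np.tile(np.arange(1, params.days + 1), n_d)
    latencies = pd.DataFrame(
        {
            "animal_id": np.repeat(ids[n_c:], params.days),
            "group": "defeated",
            "drug": np.repeat(drug[n_c:].astype(str), params.days),
            "day": day,
            "latency_s": clipped.ravel(),
            "censored": censored.ravel(),
        }
    )
    return latencies, truth


def generate_expression(
    latencies: pd.DataFrame,
    truth: pd.DataFrame,
    params: CohortModelParams,
    day_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-animal prepro-orexin expression (arbitrary densitometry units).

    Defeated animals: ``beta0 + beta1 * avg_latency + N(0, sigma_expr)``
    — expression decreases with average defeat latency, so active copers
    (long latencies) express less. Controls draw from their own
    distribution since they have no latencies. Defaults are calibrated
    so the latency-expression squared correlation in a default cohort
    falls in the 0.2–0.35 range.
    """
    params.validate()
    rng = _streams(params.seed, 6)[4]
    defeated = truth.loc[truth["group"] == "defeated", "animal_id"]
    if day_range is not None:
        lat = latencies[latencies["day"].between(*day_range)]
    else:
        lat = latencies
    avg = lat.groupby("animal_id")["latency_s"].mean()
    missing = set(defeated) - set(avg.index)
    if missing:
        raise CohortDataError(
            f"defeated animals without latencies: {sorted(missing)[:5]}"
        )

    rows = []
    ctrl = truth.loc[truth["group"] == "control", "animal_id"]
    ctrl_vals = rng.normal(params.control_expr_mean, params.control_expr_sd, len(ctrl))
    for aid, v in zip(ctrl, ctrl_vals):
        rows.append((aid, "control", np.nan, v))
    noise = rng.normal(0.0, params.sigma_expr, len(defeated))
    for aid, e in zip(defeated, noise):
        a = avg[aid]
        rows.append((aid, "defeated", a, params.beta0 + params.beta1 * a + e))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "avg_latency_s", "expression"]
    )


def generate_behavior(truth: pd.DataFrame, params: CohortModelParams) -> pd.DataFrame:
    """Per-animal behavioral endpoints drawn from stress-by-drug cells.

    ``truth`` supplies each animal's stress level (control / passive /
    active, the latter two from the hidden phenotype — the study assigns
    behavior by the animal's actual coping style) and drug. Forced-swim
    percentages are clipped at zero and renormalized to sum to 100.
    """
    params.validate()
    rng = _streams(params.seed, 6)[5]
    out = pd.DataFrame(
        {
            "animal_id": truth["animal_id"],
            "stress": truth["phenotype"],
            "drug": truth["drug"],
        }
    )
    n = len(out)
    for endpoint in BEHAVIOR_ENDPOINTS:
        cells = params.behavior_cells.get(endpoint)
        if cells is None:
            raise ParameterError(f"behavior_cells missing endpoint {endpoint!r}")
        mean = np.empty(n)
        sd = np.empty(n)
        for i, (s, d) in enumerate(zip(out["stress"], out["drug"])):
            try:
                mean[i], sd[i] = cells[(s, d)]
            except KeyError:
                raise ParameterError(
                    f"behavior_cells[{endpoint!r}] missing cell {(s, d)}"
                ) from None
        out[endpoint] = mean + sd * rng.standard_normal(n)

    fst = out.loc[:, list(FST_ENDPOINTS)].to_numpy().clip(min=0.0)
    total = fst.sum(axis=1)
    if np.any(total <= 0):
        raise ParameterError("forced-swim cell means must give positive totals")
    out.loc[:, list(FST_ENDPOINTS)] = 100.0 * fst / total[:, None]
    return out


def generate_cohort(params: CohortModelParams) -> Cohort:
    """Generate all tables of one cohort from a single master seed."""
    latencies, truth = generate_latencies(params)
    expression = generate_expression(latencies, truth, params)
    behavior = generate_behavior(truth, params)
    return Cohort(
        latencies=latencies,
        truth=truth,
        expression=expression,
        behavior=behavior,
        params=params,
    )
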