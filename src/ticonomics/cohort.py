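"""Synthetic survey cohorts for the utility-mapping stage.

Generates patient-level records (demographics, YGTSS motor/vocal/total tic
scores, EQ-5D-Y utility index) with a known linear utility-vs-severity truth
and a censoring ceiling at utility 1, so regression-based mapping code can be
exercised and validated without access to real survey data.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PatientRecord",
    "CohortConfig",
    "ConfigurationError",
    "CohortParseError",
    "generate_cohort",
    "summarize_cohort",
    "write_cohort",
    "read_cohort",
    "toy_value_set_utility",
]

YGTSS_SUBSCALE_MAX = 25

COHORT_COLUMNS = [
    "id",
    "sex",
    "age",
    "height",
    "weight",
    "ygtss_motor",
    "ygtss_vocal",
    "ygtss_total",
    "eq5dy_utility",
]


class ConfigurationError(ValueError):
    """Raised for invalid cohort-generation settings."""


class CohortParseError(ValueError):
    """Raised when a cohort CSV violates the schema or record invariants."""


@dataclass(frozen=True)
class PatientRecord:
    """One surveyed child: demographics, tic scores and observed utility.

    ``sex`` is coded 0 for females and 1 for males. ``height``/``weight``
    may be ``None`` (item non-response). Utility is censored above at 1.
    """

    id: str
    sex: int
    age: float
    height: float | None
    weight: float | None
    ygtss_motor: int
    ygtss_vocal: int
    ygtss_total: int
    eq5dy_utility: float

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex!r}")
        for name in ("ygtss_motor", "ygtss_vocal"):
            value = getattr(self, name)
            if not 0 <= value <= YGTSS_SUBSCALE_MAX:
                raise ValueError(
                    f"{name} must be in [0, {YGTSS_SUBSCALE_MAX}], got {value}"
                )
        if self.ygtss_total != self.ygtss_motor + self.ygtss_vocal:
            raise ValueError(
                "ygtss_total must equal ygtss_motor + ygtss_vocal "
                f"({self.ygtss_motor} + {self.ygtss_vocal} != {self.ygtss_total})"
            )
        if self.eq5dy_utility > 1.0:
            raise ValueError(
                f"eq5dy_utility must not exceed 1, got {self.eq5dy_utility}"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Settings for :func:`generate_cohort`.

    Score means/SDs describe the *target* marginal moments: motor and vocal
    subscores are drawn from truncated normals on ``[0, 25]`` whose parent
    parameters are moment-matched so the truncated draws hit the requested
    mean and SD, then rounded to integers. The total score is the per-record
    sum. Utility follows ``intercept + slope * total (+ sex_effect * sex) +
    Gaussian noise``, censored above at ``1`` and floored at
    ``utility_floor``. ``ceiling_prob_at_zero`` adds an extra point mass at
    exactly 1 with probability decaying linearly from its value at a total
    score of 0 to zero at the score maximum (stress-testing hook).
    """

    n: int = 144
    seed: int = 0
    male_fraction: float = 0.8699
    age_mean: float = 9.01
    age_sd: float = 2.47
    height_mean: float = 139.05
    height_sd: float = 14.50
    weight_mean: float = 34.49
    weight_sd: float = 11.92
    motor_mean: float = 11.28
    motor_sd: float = 5.07
    vocal_mean: float = 4.95
    vocal_sd: float = 6.36
    utility_intercept: float = 0.9881
    utility_slope: float = -0.0035
    sex_effect: float = 0.0
    # residual utility noise; default chosen so the marginal utility SD is
    # close to the 0.083 a ceiling-censored cohort of this severity shows
    noise_sd: float = 0.075
    ceiling_prob_at_zero: float = 0.0
    utility_floor: float = 0.0
    height_missing_rate: float = 0.0
    weight_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        problems = []
        if self.n < 10:
            problems.append(f"n must be >= 10, got {self.n}")
        for name in ("age_sd", "height_sd", "weight_sd", "motor_sd", "vocal_sd"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0, got {getattr(self, name)}")
        for name in (
            "male_fraction",
            "ceiling_prob_at_zero",
            "height_missing_rate",
            "weight_missing_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {value}")
        if self.noise_sd < 0:
            problems.append(f"noise_sd must be >= 0, got {self.noise_sd}")
        if problems:
            raise ConfigurationError("; ".join(problems))


def _clipped_normal_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean and SD of ``clip(N(mu, sigma), lo, hi)`` in closed form."""
    alpha, beta = (lo - mu) / sigma, (hi - mu) / sigma
    phi_a, phi_b = stats.norm.pdf(alpha), stats.norm.pdf(beta)
    cdf_a, cdf_b = stats.norm.cdf(alpha), stats.norm.cdf(beta)
    mid = cdf_b - cdf_a
    mean = lo * cdf_a + hi * (1 - cdf_b) + mu * mid + sigma * (phi_a - phi_b)
    second = (
        lo**2 * cdf_a
        + hi**2 * (1 - cdf_b)
        + mu**2 * mid
        + 2 * mu * sigma * (phi_a - phi_b)
        + sigma**2 * (mid - beta * phi_b + alpha * phi_a)
    )
    return mean, float(np.sqrt(max(second - mean**2, 0.0)))


@lru_cache(maxsize=64)
def _matched_clipnorm(target_mean: float, target_sd: float,
                      lo: float = 0.0, hi: float = float(YGTSS_SUBSCALE_MAX)):
    """Parent (mu, sigma) whose [lo, hi]-clipped normal has the target moments.

    Clipping (censoring at the bounds) rather than truncation: the printed
    score SDs can exceed the truncated-normal feasibility bound, while a
    censored normal with boundary point masses reaches them.
    """

    def residuals(x):
        mu, log_sigma = x
        m, s = _clipped_normal_moments(mu, float(np.exp(log_sigma)), lo, hi)
        return [m - target_mean, s - target_sd]

    sol = optimize.root(residuals, [target_mean, np.log(target_sd)], method="hybr")
    if not sol.success or not np.allclose(residuals(sol.x), 0.0, atol=1e-6):
        raise ConfigurationError(
            f"cannot match a clipped normal on [{lo}, {hi}] to "
            f"mean={target_mean}, sd={target_sd}"
        )
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _draw_scores(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    mu, sigma = _matched_clipnorm(mean, sd)
    raw = rng.normal(mu, sigma, n)
    return np.clip(np.rint(raw), 0, YGTSS_SUBSCALE_MAX).astype(int)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort under ``config``.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    sex = (rng.random(n) < config.male_fraction).astype(int)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 1.0, 17.0)
    height = rng.normal(config.height_mean, config.height_sd, n)
    weight = rng.normal(config.weight_mean, config.weight_sd, n)
    motor = _draw_scores(rng, n, config.motor_mean, config.motor_sd)
    vocal = _draw_scores(rng, n, config.vocal_mean, config.vocal_sd)
    total = motor + vocal

    utility = (
        config.utility_intercept
        + config.utility_slope * total
        + config.sex_effect * sex
        + rng.normal(0.0, config.noise_sd, n)
    )
    if config.ceiling_prob_at_zero > 0:
        p_mass = config.ceiling_prob_at_zero * np.clip(
            1.0 - total / (2 * YGTSS_SUBSCALE_MAX), 0.0, 1.0
        )
        utility[rng.random(n) < p_mass] = 1.0
    utility = np.minimum(utility, 1.0)
    utility = np.maximum(utility, config.utility_floor)

    height_missing = rng.random(n) < config.height_missing_rate
    weight_missing = rng.random(n) < config.weight_missing_rate

    width = max(4, len(str(n)))
    return [
        PatientRecord(
            id=f"P{i + 1:0{width}d}",
            sex=int(sex[i]),
            age=float(age[i]),
            height=None if height_missing[i] else float(height[i]),
            weight=None if weight_missing[i] else float(weight[i]),
            ygtss_motor=int(motor[i]),
            ygtss_vocal=int(vocal[i]),
            ygtss_total=int(total[i]),
            eq5dy_utility=float(utility[i]),
        )
        for i in range(n)
    ]


def summarize_cohort(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-variable n/mean/SD plus sex counts and ratio, indexed by parameter."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty cohort")

    n_male = sum(r.sex == 1 for r in records)
    n_total = len(records)
    rows: list[dict] = [
        {
            "parameter": "sex_male",
            "n": n_male,
            "ratio_pct": 100.0 * n_male / n_total,
            "mean": np.nan,
            "sd": np.nan,
        },
        {
            "parameter": "sex_female",
            "n": n_total - n_male,
            "ratio_pct": 100.0 * (n_total - n_male) / n_total,
            "mean": np.nan,
            "sd": np.nan,
        },
    ]
    for name in ("age", "height", "weight", "ygtss_total", "ygtss_motor",
                 "ygtss_vocal", "eq5dy_utility"):
        values = np.array(
            [getattr(r, name) for r in records if getattr(r, name) is not None],
            dtype=float,
        )
        rows.append(
            {
                "parameter": name,
                "n": values.size,
                "ratio_pct": np.nan,
                "mean": float(values.mean()) if values.size else np.nan,
                "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records as UTF-8 CSV (dot decimal separator, '' for missing)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(COHORT_COLUMNS)
        for record in records:
            writer.writerow(
                [_format_value(getattr(record, column)) for column in COHORT_COLUMNS]
            )


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort`.

    Raises :class:`CohortParseError` naming the offending row for malformed
    values, missing columns or invariant violations.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise CohortParseError(f"{path}: empty file, expected a header row")
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortParseError(
                f"{path}: missing columns: {', '.join(sorted(missing))}"
            )
        records = []
        for index, row in enumerate(reader):
            try:
                records.append(
                    PatientRecord(
                        id=row["id"],
                        sex=int(row["sex"]),
                        age=float(row["age"]),
                        height=float(row["height"]) if row["height"] else None,
                        weight=float(row["weight"]) if row["weight"] else None,
                        ygtss_motor=int(row["ygtss_motor"]),
                        ygtss_vocal=int(row["ygtss_vocal"]),
                        ygtss_total=int(row["ygtss_total"]),
                        eq5dy_utility=float(row["eq5dy_utility"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise CohortParseError(f"{path}: row {index}: {exc}") from exc
    return records


# Interface-testing stand-in for a real country value set: equal additive
# decrements per dimension level on a 5-dimension / 3-level descriptive state.
_TOY_LEVEL_DECREMENT = 0.08


def toy_value_set_utility(state: str) -> float:
    """Score a 5-digit descriptive health state with a toy additive tariff.

    ``'11111'`` maps to 1.0 and each level above 1 on any dimension
    subtracts a flat decrement. Not a real value set.
    """
    if len(state) != 5 or not state.isdigit():
        raise ValueError(f"expected a 5-digit state string, got {state!r}")
    levels = [int(c) for c in state]
    if any(not 1 <= lv <= 3 for lv in levels):
        raise ValueError(f"levels must be 1-3, got {state!r}")
    return 1.0 - _TOY_LEVEL_DECREMENT * sum(lv - 1 for lv in levels)
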