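"""52-week decision-tree cost-utility model for two oral dosing strategies.

Each strategy arm branches on adverse-event (AE) driven discontinuation and,
among continuers, on a three-way response split (post hoc / partial /
non-response, conditional on continuing). Costs combine a weekly direct
medical cost accrued by every patient with a per-day drug cost accrued over
the full drug-year (52 x 7 = 364 days) by continuers and over a short
treatment window by AE-discontinuers. Utilities are held constant within the
horizon, so QALYs are branch utilities weighted by branch probabilities and
the horizon length in years.

The utility assigned to the AE-discontinuation branch is not uniquely
pinned down by the reference inputs, so three explicit conventions are
implemented and surfaced everywhere a QALY is computed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .mapping import REFERENCE_INTERCEPT, REFERENCE_SLOPE

__all__ = [
    "AE_CONVENTIONS",
    "ArmParameters",
    "EconomicParameters",
    "UtilityParameters",
    "ArmResult",
    "IncrementalResult",
    "CEAParameters",
    "DEFAULT_WTP",
    "default_parameters",
    "disutility_from_baseline",
    "baseline_utility",
    "expected_cost",
    "expected_qaly",
    "cases_per_1000",
    "evaluate_arm",
    "enumerate_leaves",
    "evaluate_arm_bruteforce",
    "icer",
    "net_monetary_benefit",
    "cea_table",
]

AE_CONVENTIONS = (
    "baseline_minus_disutility",
    "nonresponse_minus_disutility",
    "response_mix_minus_disutility",
)

# Three times 2022 per-capita GDP, USD per QALY.
DEFAULT_WTP = 36832.95

_WEEKS_PER_YEAR = 52


@dataclass
class ArmParameters:
    """One strategy arm: AE discontinuation and response probabilities, dose."""

    name: str
    p_discontinue_ae: float
    p_posthoc: float
    p_partial: float
    daily_dose_mg: float

    def validate(self) -> None:
        problems = []
        for field_name in ("p_discontinue_ae", "p_posthoc", "p_partial"):
            value = getattr(self, field_name)
            if not 0.0 <= value <= 1.0:
                problems.append(f"{self.name}.{field_name} must be in [0, 1], got {value}")
        if self.p_posthoc + self.p_partial > 1.0 + 1e-12:
            problems.append(
                f"{self.name}: p_posthoc + p_partial must be <= 1, "
                f"got {self.p_posthoc + self.p_partial}"
            )
        if self.daily_dose_mg < 0:
            problems.append(f"{self.name}.daily_dose_mg must be >= 0")
        if problems:
            raise ValueError("; ".join(problems))

    @property
    def p_nonresponse(self) -> float:
        return 1.0 - self.p_posthoc - self.p_partial


@dataclass
class EconomicParameters:
    weekly_direct_medical_cost: float = 31.50
    drug_price_per_5mg: float = 0.72
    horizon_weeks: int = 52
    ae_treatment_weeks: int = 8  # drug exposure before AE discontinuation
    days_per_horizon: int | None = None  # defaults to horizon_weeks * 7
    discount_rate: float = 0.0  # per-year; 0 for the 1-year base case

    def validate(self) -> None:
        problems = []
        if self.weekly_direct_medical_cost < 0 or self.drug_price_per_5mg < 0:
            problems.append("costs must be >= 0")
        if self.ae_treatment_weeks > self.horizon_weeks:
            problems.append("ae_treatment_weeks must not exceed horizon_weeks")
        if self.discount_rate < 0:
            problems.append("discount_rate must be >= 0")
        if problems:
            raise ValueError("; ".join(problems))

    @property
    def drug_days(self) -> int:
        return self.days_per_horizon if self.days_per_horizon is not None else self.horizon_weeks * 7

    @property
    def horizon_years(self) -> float:
        return self.horizon_weeks / _WEEKS_PER_YEAR

    @property
    def discount_factor(self) -> float:
        # midpoint-of-horizon discounting; identity at the default rate 0
        return (1.0 + self.discount_rate) ** (-self.horizon_years / 2.0)


@dataclass
class UtilityParameters:
    u_posthoc: float = 0.934
    u_partial: float = 0.919
    u_nonresponse: float = 0.902
    disutility_ae: float = -0.090
    baseline_ygtss_total: float = 30.37
    mapping_intercept: float = REFERENCE_INTERCEPT
    mapping_slope: float = REFERENCE_SLOPE
    ae_utility_convention: str = "baseline_minus_disutility"

    def validate(self) -> None:
        problems = []
        if not self.u_posthoc >= self.u_partial >= self.u_nonresponse:
            problems.append("need u_posthoc >= u_partial >= u_nonresponse")
        if self.disutility_ae > 0:
            problems.append(f"disutility_ae must be <= 0, got {self.disutility_ae}")
        if self.ae_utility_convention not in AE_CONVENTIONS:
            problems.append(
                f"unknown ae_utility_convention {self.ae_utility_convention!r}; "
                f"expected one of {AE_CONVENTIONS}"
            )
        if problems:
            raise ValueError("; ".join(problems))


@dataclass(frozen=True)
class ArmResult:
    name: str
    expected_cost: float
    expected_qaly: float
    posthoc_per_1000: int
    partial_per_1000: int
    responders_per_1000: int


@dataclass(frozen=True)
class IncrementalResult:
    """Comparator-minus-reference increments and their classification.

    ``classification`` is ``"icer"`` when the ratio is meaningful,
    ``"dominant"`` / ``"dominated"`` for the comparator in the unambiguous
    quadrants, and ``"undefined"`` when the QALY increment is zero.
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    classification: str


def disutility_from_baseline(
    baseline_ygtss_total: float,
    mapping_intercept: float = REFERENCE_INTERCEPT,
    mapping_slope: float = REFERENCE_SLOPE,
) -> float:
    """AE disutility as 10% of the mapped pre-treatment utility (negative)."""
    return -0.10 * (mapping_intercept + mapping_slope * baseline_ygtss_total)


def baseline_utility(util: UtilityParameters) -> float:
    return util.mapping_intercept + util.mapping_slope * util.baseline_ygtss_total


def _continuer_mix_utility(arm: ArmParameters, util: UtilityParameters) -> float:
    return (
        arm.p_posthoc * util.u_posthoc
        + arm.p_partial * util.u_partial
        + arm.p_nonresponse * util.u_nonresponse
    )


def _ae_branch_utility(arm: ArmParameters, util: UtilityParameters) -> float:
    convention = util.ae_utility_convention
    if convention == "baseline_minus_disutility":
        anchor = baseline_utility(util)
    elif convention == "nonresponse_minus_disutility":
        anchor = util.u_nonresponse
    elif convention == "response_mix_minus_disutility":
        anchor = _continuer_mix_utility(arm, util)
    else:
        raise ValueError(
            f"unknown ae_utility_convention {convention!r}; expected one of {AE_CONVENTIONS}"
        )
    return anchor + util.disutility_ae


def _daily_drug_cost(arm: ArmParameters, econ: EconomicParameters) -> float:
    return econ.drug_price_per_5mg * (arm.daily_dose_mg / 5.0)


def expected_cost(arm: ArmParameters, econ: EconomicParameters) -> float:
    """Expected per-patient cost over the horizon.

    Direct medical cost accrues weekly for every patient; drug cost accrues
    daily for ``drug_days`` (364 by default) in continuers and for
    ``ae_treatment_weeks`` x 7 days in AE-discontinuers.
    """
    arm.validate()
    econ.validate()
    direct = econ.weekly_direct_medical_cost * econ.horizon_weeks
    daily = _daily_drug_cost(arm, econ)
    p_disc = arm.p_discontinue_ae
    drug = daily * ((1.0 - p_disc) * econ.drug_days + p_disc * econ.ae_treatment_weeks * 7)
    return (direct + drug) * econ.discount_factor


def expected_qaly(
    arm: ArmParameters,
    util: UtilityParameters,
    econ: EconomicParameters,
) -> float:
    """Expected per-patient QALYs: branch utilities x probabilities x years."""
    arm.validate()
    util.validate()
    econ.validate()
    p_disc = arm.p_discontinue_ae
    mix = _continuer_mix_utility(arm, util)
    ae = _ae_branch_utility(arm, util)
    utility = (1.0 - p_disc) * mix + p_disc * ae
    return utility * econ.horizon_years * econ.discount_factor


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def cases_per_1000(arm: ArmParameters) -> tuple[int, int, int]:
    """(post hoc, partial, total) responders per 1000 treated patients.

    Response probabilities are conditional on not discontinuing; counts are
    rounded half-away-from-zero, and the total sums the rounded counts.
    """
    arm.validate()
    stay = 1.0 - arm.p_discontinue_ae
    posthoc = _round_half_away(1000.0 * arm.p_posthoc * stay)
    partial = _round_half_away(1000.0 * arm.p_partial * stay)
    return posthoc, partial, posthoc + partial


def evaluate_arm(
    arm: ArmParameters,
    econ: EconomicParameters,
    util: UtilityParameters,
) -> ArmResult:
    posthoc, partial, total = cases_per_1000(arm)
    return ArmResult(
        name=arm.name,
        expected_cost=expected_cost(arm, econ),
        expected_qaly=expected_qaly(arm, util, econ),
        posthoc_per_1000=posthoc,
        partial_per_1000=partial,
        responders_per_1000=total,
    )


def enumerate_leaves(
    arm: ArmParameters,
    econ: EconomicParameters,
    util: UtilityParameters,
) -> list[tuple[str, float, float, float]]:
    """All four leaf paths as (label, probability, cost, utility).

    Independent oracle for the roll-back: probabilities sum to one and the
    probability-weighted payoffs equal the arm expectations.
    """
    arm.validate()
    econ.validate()
    util.validate()
    direct = econ.weekly_direct_medical_cost * econ.horizon_weeks
    daily = _daily_drug_cost(arm, econ)
    cost_continue = direct + daily * econ.drug_days
    cost_ae = direct + daily * econ.ae_treatment_weeks * 7
    p_disc = arm.p_discontinue_ae
    stay = 1.0 - p_disc
    return [
        ("discontinue_ae", p_disc, cost_ae, _ae_branch_utility(arm, util)),
        ("posthoc", stay * arm.p_posthoc, cost_continue, util.u_posthoc),
        ("partial", stay * arm.p_partial, cost_continue, util.u_partial),
        ("nonresponse", stay * arm.p_nonresponse, cost_continue, util.u_nonresponse),
    ]


def evaluate_arm_bruteforce(
    arm: ArmParameters,
    econ: EconomicParameters,
    util: UtilityParameters,
) -> tuple[float, float]:
    """(expected cost, expected QALY) by direct leaf enumeration."""
    leaves = enumerate_leaves(arm, econ, util)
    cost = sum(p * c for _, p, c, _ in leaves)
    qaly = sum(p * u for _, p, _, u in leaves) * econ.horizon_years
    return cost * econ.discount_factor, qaly * econ.discount_factor


def icer(reference: ArmResult, comparator: ArmResult) -> IncrementalResult:
    """Comparator-vs-reference increments with dominance classification."""
    delta_cost = comparator.expected_cost - reference.expected_cost
    delta_qaly = comparator.expected_qaly - reference.expected_qaly
    if delta_qaly == 0.0:
        return IncrementalResult(delta_cost, delta_qaly, None, "undefined")
    if delta_cost > 0 and delta_qaly < 0:
        return IncrementalResult(delta_cost, delta_qaly, None, "dominated")
    if delta_cost < 0 and delta_qaly > 0:
        return IncrementalResult(delta_cost, delta_qaly, None, "dominant")
    return IncrementalResult(delta_cost, delta_qaly, delta_cost / delta_qaly, "icer")


def net_monetary_benefit(result: IncrementalResult, wtp: float) -> float:
    """``wtp * dQALY - dcost``; positive favours the comparator."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * result.delta_qaly - result.delta_cost


@dataclass
class CEAParameters:
    """Everything the tree, OWSA and PSA need: three arms plus conventions."""

    low: ArmParameters = field(
        default_factory=lambda: ArmParameters("low_dose", 0.023, 0.405, 0.333, 5.0)
    )
    high: ArmParameters = field(
        default_factory=lambda: ArmParameters("high_dose", 0.156, 0.571, 0.314, 10.0)
    )
    placebo: ArmParameters = field(
        default_factory=lambda: ArmParameters("placebo", 0.023, 0.167, 0.548, 0.0)
    )
    econ: EconomicParameters = field(default_factory=EconomicParameters)
    util: UtilityParameters = field(default_factory=UtilityParameters)
    wtp: float = DEFAULT_WTP

    def validate(self) -> None:
        for arm in (self.low, self.high, self.placebo):
            arm.validate()
        self.econ.validate()
        self.util.validate()
        if self.wtp < 0:
            raise ValueError(f"wtp must be >= 0, got {self.wtp}")

    def with_convention(self, convention: str) -> "CEAParameters":
        return replace(self, util=replace(self.util, ae_utility_convention=convention))


def default_parameters() -> CEAParameters:
    """Baseline inputs for the base-case analysis."""
    return CEAParameters()


def cea_table(params: CEAParameters, convention: str | None = None) -> pd.DataFrame:
    """Base-case results table: one row per strategy, low dose as reference.

    The placebo arm is reported without an ICER; the headline comparison is
    high dose versus low dose.
    """
    if convention is not None:
        params = params.with_convention(convention)
    params.validate()

    low = evaluate_arm(params.low, params.econ, params.util)
    high = evaluate_arm(params.high, params.econ, params.util)
    placebo = evaluate_arm(params.placebo, params.econ, params.util)
    inc = icer(low, high)

    def row(result: ArmResult, incremental: IncrementalResult | None) -> dict:
        return {
            "strategy": result.name,
            "cost_usd": round(result.expected_cost, 2),
            "incremental_cost_usd": (
                round(incremental.delta_cost, 2) if incremental else None
            ),
            "qaly": result.expected_qaly,
            "incremental_qaly": incremental.delta_qaly if incremental else None,
            "icer_usd_per_qaly": (
                incremental.icer if incremental and incremental.icer is not None else None
            ),
            "classification": incremental.classification if incremental else None,
            "partial_per_1000": result.partial_per_1000,
            "posthoc_per_1000": result.posthoc_per_1000,
            "responders_per_1000": result.responders_per_1000,
        }

    return pd.DataFrame(
        [row(low, None), row(high, inc), row(placebo, None)]
    )
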