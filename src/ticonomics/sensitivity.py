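"""One-way and probabilistic sensitivity analyses around the decision tree.

One-way analysis perturbs each parameter to its range bounds and reports the
resulting high-vs-low-dose comparison as tornado entries sorted by ICER
swing, flagging dominance instead of coercing it to a number. Probabilistic
analysis draws all ranged parameters independently (gamma for nonnegative
quantities, beta for probabilities and the disutility magnitude), with the
printed range read as a 95% interval: mean = base, SD = (high - low) / 3.92,
parameterized by method of moments. Cost-effectiveness acceptability curves
are computed from net monetary benefit, which stays defined when the QALY
increment crosses zero.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cea import (
    CEAParameters,
    IncrementalResult,
    evaluate_arm,
    icer,
    net_monetary_benefit,
)

__all__ = [
    "ParameterRange",
    "TornadoEntry",
    "PSAResult",
    "PARAMETER_PATHS",
    "default_ranges",
    "apply_value",
    "owsa",
    "tornado_frame",
    "draw_parameters",
    "run_psa",
    "ceac",
    "export_scatter",
]

_RANGE_TO_SD = 3.92  # width of a +/-1.96 SD interval

DISTRIBUTIONS = ("gamma", "beta", "fixed")

# Dotted attribute paths into CEAParameters for every tunable quantity.
PARAMETER_PATHS: dict[str, str] = {
    "direct_medical_cost_weekly": "econ.weekly_direct_medical_cost",
    "drug_price_per_5mg": "econ.drug_price_per_5mg",
    "p_discontinue_ae_low": "low.p_discontinue_ae",
    "p_discontinue_ae_high": "high.p_discontinue_ae",
    "p_discontinue_ae_placebo": "placebo.p_discontinue_ae",
    "p_posthoc_low": "low.p_posthoc",
    "p_posthoc_high": "high.p_posthoc",
    "p_posthoc_placebo": "placebo.p_posthoc",
    "p_partial_low": "low.p_partial",
    "p_partial_high": "high.p_partial",
    "p_partial_placebo": "placebo.p_partial",
    "baseline_ygtss_total": "util.baseline_ygtss_total",
    "disutility_ae": "util.disutility_ae",
    "u_posthoc": "util.u_posthoc",
    "u_partial": "util.u_partial",
    "u_nonresponse": "util.u_nonresponse",
}


class RangeError(ValueError):
    """Raised for infeasible or unknown sensitivity ranges."""


@dataclass(frozen=True)
class ParameterRange:
    name: str
    base: float
    low: float
    high: float
    distribution: str = "fixed"

    def __post_init__(self) -> None:
        if self.name not in PARAMETER_PATHS:
            raise RangeError(
                f"unknown parameter {self.name!r}; known: {sorted(PARAMETER_PATHS)}"
            )
        if not self.low <= self.base <= self.high:
            raise RangeError(
                f"{self.name}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.distribution not in DISTRIBUTIONS:
            raise RangeError(
                f"{self.name}: distribution must be one of {DISTRIBUTIONS}"
            )

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_low: float | None
    icer_at_high: float | None
    status_low: str
    status_high: str
    nmb_at_low: float
    nmb_at_high: float
    swing: float  # |icer difference|; NaN when either side has no ICER


@dataclass
class PSAResult:
    n_iterations: int
    seed: int | None
    delta_cost: np.ndarray
    delta_qaly: np.ndarray

    def __post_init__(self) -> None:
        if len(self.delta_cost) != self.n_iterations or len(self.delta_qaly) != self.n_iterations:
            raise ValueError("n_iterations must equal the number of stored pairs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly}
        )

    def summary(self, quantiles=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        frame = self.to_frame()
        return frame.quantile(list(quantiles))

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, seed: int | None = None) -> "PSAResult":
        frame = pd.read_csv(path)
        return cls(
            n_iterations=len(frame),
            seed=seed,
            delta_cost=frame["delta_cost"].to_numpy(dtype=float),
            delta_qaly=frame["delta_qaly"].to_numpy(dtype=float),
        )


def _get_path(params: CEAParameters, path: str) -> float:
    obj = params
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def apply_value(params: CEAParameters, name: str, value: float) -> CEAParameters:
    """A copy of ``params`` with one named parameter replaced."""
    if name not in PARAMETER_PATHS:
        raise RangeError(f"unknown parameter {name!r}")
    out = copy.deepcopy(params)
    *parents, leaf = PARAMETER_PATHS[name].split(".")
    obj = out
    for part in parents:
        obj = getattr(obj, part)
    setattr(obj, leaf, float(value))
    return out


def default_ranges(params: CEAParameters, include_placebo: bool = False) -> list[ParameterRange]:
    """Baseline sensitivity ranges for every varied parameter.

    Costs and the baseline tic score carry explicit reference bounds (the
    drug price band is asymmetric and used verbatim); probabilities default
    to +/-10%, the AE disutility to +/-50%. Response-level utilities carry no
    reference range and are held fixed. Placebo-arm probabilities are
    excluded from the headline pairwise analysis unless requested.
    """
    p = params
    ranges = [
        ParameterRange(
            "direct_medical_cost_weekly",
            p.econ.weekly_direct_medical_cost,
            round(p.econ.weekly_direct_medical_cost * 0.8, 10),
            round(p.econ.weekly_direct_medical_cost * 1.2, 10),
            "gamma",
        ),
        ParameterRange("drug_price_per_5mg", p.econ.drug_price_per_5mg, 0.32, 1.52, "gamma"),
        ParameterRange(
            "p_discontinue_ae_low",
            p.low.p_discontinue_ae,
            round(p.low.p_discontinue_ae * 0.9, 10),
            round(p.low.p_discontinue_ae * 1.1, 10),
            "beta",
        ),
        ParameterRange(
            "p_discontinue_ae_high",
            p.high.p_discontinue_ae,
            round(p.high.p_discontinue_ae * 0.9, 10),
            round(p.high.p_discontinue_ae * 1.1, 10),
            "beta",
        ),
        ParameterRange(
            "p_posthoc_low",
            p.low.p_posthoc,
            round(p.low.p_posthoc * 0.9, 10),
            round(p.low.p_posthoc * 1.1, 10),
            "beta",
        ),
        ParameterRange(
            "p_posthoc_high",
            p.high.p_posthoc,
            round(p.high.p_posthoc * 0.9, 10),
            round(p.high.p_posthoc * 1.1, 10),
            "beta",
        ),
        ParameterRange(
            "p_partial_low",
            p.low.p_partial,
            round(p.low.p_partial * 0.9, 10),
            round(p.low.p_partial * 1.1, 10),
            "beta",
        ),
        ParameterRange(
            "p_partial_high",
            p.high.p_partial,
            round(p.high.p_partial * 0.9, 10),
            round(p.high.p_partial * 1.1, 10),
            "beta",
        ),
        ParameterRange(
            "baseline_ygtss_total",
            p.util.baseline_ygtss_total,
            round(p.util.baseline_ygtss_total * 0.8, 10),
            round(p.util.baseline_ygtss_total * 1.2, 10),
            "gamma",
        ),
        ParameterRange(
            "disutility_ae",
            p.util.disutility_ae,
            round(p.util.disutility_ae * 1.5, 10),
            round(p.util.disutility_ae * 0.5, 10),
            "beta",
        ),
    ]
    if include_placebo:
        ranges += [
            ParameterRange(
                "p_discontinue_ae_placebo",
                p.placebo.p_discontinue_ae,
                round(p.placebo.p_discontinue_ae * 0.9, 10),
                round(p.placebo.p_discontinue_ae * 1.1, 10),
                "beta",
            ),
            ParameterRange(
                "p_posthoc_placebo",
                p.placebo.p_posthoc,
                round(p.placebo.p_posthoc * 0.9, 10),
                round(p.placebo.p_posthoc * 1.1, 10),
                "beta",
            ),
            ParameterRange(
                "p_partial_placebo",
                p.placebo.p_partial,
                round(p.placebo.p_partial * 0.9, 10),
                round(p.placebo.p_partial * 1.1, 10),
                "beta",
            ),
        ]
    return ranges


def _pairwise(params: CEAParameters) -> IncrementalResult:
    low = evaluate_arm(params.low, params.econ, params.util)
    high = evaluate_arm(params.high, params.econ, params.util)
    return icer(low, high)


def owsa(
    params: CEAParameters,
    ranges: Sequence[ParameterRange],
    convention: str | None = None,
) -> list[TornadoEntry]:
    """High-vs-low-dose tornado: each parameter swung to its bounds alone.

    Entries are sorted by descending ICER swing; sides without a defined
    ICER (dominance, zero QALY increment) keep their classification label
    and a NaN swing, sorting last.
    """
    if convention is not None:
        params = params.with_convention(convention)
    params.validate()

    entries = []
    for prange in ranges:
        results = {}
        for side, value in (("low", prange.low), ("high", prange.high)):
            perturbed = apply_value(params, prange.name, value)
            inc = _pairwise(perturbed)
            results[side] = (inc, net_monetary_benefit(inc, params.wtp))
        inc_low, nmb_low = results["low"]
        inc_high, nmb_high = results["high"]
        if inc_low.icer is not None and inc_high.icer is not None:
            swing = abs(inc_high.icer - inc_low.icer)
        else:
            swing = math.nan
        entries.append(
            TornadoEntry(
                parameter=prange.name,
                icer_at_low=inc_low.icer,
                icer_at_high=inc_high.icer,
                status_low=inc_low.classification,
                status_high=inc_high.classification,
                nmb_at_low=nmb_low,
                nmb_at_high=nmb_high,
                swing=swing,
            )
        )
    return sorted(
        entries,
        key=lambda e: (math.isnan(e.swing), -(e.swing if not math.isnan(e.swing) else 0.0)),
    )


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in entries])


def _gamma_draw(rng: np.random.Generator, prange: ParameterRange) -> float:
    mean = prange.base
    sd = (prange.high - prange.low) / _RANGE_TO_SD
    if mean <= 0:
        raise RangeError(f"{prange.name}: gamma requires a positive base, got {mean}")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return float(rng.gamma(shape, scale))


def _beta_draw(rng: np.random.Generator, prange: ParameterRange) -> float:
    negate = prange.base < 0
    if negate:
        mean, lo, hi = -prange.base, -prange.high, -prange.low
    else:
        mean, lo, hi = prange.base, prange.low, prange.high
    sd = (hi - lo) / _RANGE_TO_SD
    if not 0 < mean < 1:
        raise RangeError(f"{prange.name}: beta requires base in (0, 1), got {prange.base}")
    var = sd**2
    if var >= mean * (1 - mean):
        raise RangeError(
            f"{prange.name}: SD {sd:.4g} too large for a beta with mean {mean:.4g}"
        )
    nu = mean * (1 - mean) / var - 1.0
    draw = float(rng.beta(mean * nu, (1 - mean) * nu))
    return -draw if negate else draw


def draw_parameters(
    ranges: Sequence[ParameterRange], rng: np.random.Generator
) -> dict[str, float]:
    """One independent random value per range (base for fixed/degenerate)."""
    draws = {}
    for prange in ranges:
        if prange.distribution == "fixed" or prange.degenerate:
            draws[prange.name] = prange.base
        elif prange.distribution == "gamma":
            draws[prange.name] = _gamma_draw(rng, prange)
        else:
            draws[prange.name] = _beta_draw(rng, prange)
    return draws


def _apply_draws(params: CEAParameters, draws: dict[str, float]) -> CEAParameters:
    out = copy.deepcopy(params)
    for name, value in draws.items():
        *parents, leaf = PARAMETER_PATHS[name].split(".")
        obj = out
        for part in parents:
            obj = getattr(obj, part)
        setattr(obj, leaf, float(value))
    return out


def run_psa(
    params: CEAParameters,
    ranges: Sequence[ParameterRange],
    n_iterations: int = 1000,
    seed: int | None = None,
    convention: str | None = None,
) -> PSAResult:
    """Monte-Carlo PSA of high vs low dose; bit-reproducible for a seed."""
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    if convention is not None:
        params = params.with_convention(convention)
    params.validate()
    rng = np.random.default_rng(seed)
    delta_cost = np.empty(n_iterations)
    delta_qaly = np.empty(n_iterations)
    for i in range(n_iterations):
        # rejection-resample the rare draws whose independent response
        # probabilities sum past 1 within an arm
        for _ in range(1000):
            draws = draw_parameters(ranges, rng)
            drawn = _apply_draws(params, draws)
            try:
                drawn.validate()
                break
            except ValueError:
                continue
        else:
            raise RangeError("could not draw a valid parameter set in 1000 tries")
        inc = _pairwise(drawn)
        delta_cost[i] = inc.delta_cost
        delta_qaly[i] = inc.delta_qaly
    return PSAResult(n_iterations, seed, delta_cost, delta_qaly)


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Probability each strategy is cost-effective across a WTP grid.

    The comparator (high dose) wins an iteration when its net monetary
    benefit is positive; exact ties go to the cheaper strategy. The two
    probabilities sum to 1 at every grid point.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if psa.n_iterations == 0:
        raise ValueError("PSA result is empty")
    rows = []
    for wtp in grid:
        nmb = wtp * psa.delta_qaly - psa.delta_cost
        wins_high = (nmb > 0) | ((nmb == 0) & (psa.delta_cost < 0))
        p_high = float(np.mean(wins_high))
        rows.append({"wtp": float(wtp), "p_high_dose": p_high, "p_low_dose": 1.0 - p_high})
    return pd.DataFrame(rows)


def export_scatter(psa: PSAResult, wtp: float, path: str | Path) -> pd.DataFrame:
    """Plot-ready incremental scatter with a threshold-position flag.

    ``above`` means incremental cost exceeds ``wtp x`` incremental QALYs
    (the comparator fails the threshold there); exact equality is flagged
    ``on-threshold``.
    """
    threshold = wtp * psa.delta_qaly
    position = np.where(
        psa.delta_cost > threshold,
        "above",
        np.where(psa.delta_cost < threshold, "below", "on-threshold"),
    )
    frame = pd.DataFrame(
        {
            "delta_qaly": psa.delta_qaly,
            "delta_cost": psa.delta_cost,
            "position": position,
        }
    )
    frame.to_csv(path, index=False)
    return frame
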