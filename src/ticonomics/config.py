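"""Parameter-file loading, result writers, run manifests and the pipeline.

Parameter files are YAML (or JSON, a YAML subset) with optional top-level
sections ``cea``, ``cohort``, ``psa``, ``ceac`` and ``ranges``. Anything
missing is filled from the package baselines with an INFO notice; unknown
keys and invariant violations are rejected with every offending key named.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .cea import (
    ArmParameters,
    CEAParameters,
    EconomicParameters,
    UtilityParameters,
    cea_table,
    default_parameters,
)
from .cohort import CohortConfig, generate_cohort, write_cohort
from .mapping import (
    FAMILIES,
    MODEL_PREDICTORS,
    MappingSpec,
    compare_models,
    fit_mapping,
    validation_metrics,
)
from .sensitivity import (
    ParameterRange,
    default_ranges,
    ceac,
    export_scatter,
    owsa,
    run_psa,
    tornado_frame,
)

__all__ = [
    "ParameterValidationError",
    "PipelineError",
    "RunConfig",
    "RunManifest",
    "load_params",
    "write_params",
    "params_to_dict",
    "full_run",
]

logger = logging.getLogger("ticonomics")


class ParameterValidationError(ValueError):
    """Schema or invariant violation in a parameter file."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


class PipelineError(RuntimeError):
    """A full-run stage failed; the message names the stage."""


@dataclass
class RunConfig:
    cea: CEAParameters
    ranges: list[ParameterRange]
    cohort: CohortConfig
    psa_iterations: int = 1000
    psa_seed: int = 0
    ceac_wtp_max: float = 200_000.0
    ceac_wtp_step: float = 1000.0


_ARM_KEYS = {"p_discontinue_ae", "p_posthoc", "p_partial", "daily_dose_mg"}
_ARM_NAMES = ("low", "high", "placebo")


def _check_keys(section: str, data: dict, allowed: set[str], problems: list[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        problems.append(f"{section}: unknown keys {sorted(unknown)}")


def _build_dataclass(cls, defaults, data: dict, section: str, problems: list[str]):
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, data, names, problems)
    kwargs = {k: v for k, v in data.items() if k in names}
    filled = names - set(kwargs) - ({"name"} if "name" in names else set())
    if data and filled:
        logger.info("%s: filled from defaults: %s", section, sorted(filled))
    try:
        return dataclasses.replace(defaults, **kwargs)
    except (TypeError, ValueError) as exc:
        problems.append(f"{section}: {exc}")
        return defaults


def load_params(path: str | Path | None = None) -> RunConfig:
    """Load a run configuration, filling gaps from the package baselines."""
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            logger.info("%s: empty file, using full defaults", path)
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParameterValidationError([f"{path}: top level must be a mapping"])
        raw = loaded

    problems: list[str] = []
    _check_keys("top-level", raw, {"cea", "cohort", "psa", "ceac", "ranges"}, problems)

    cea_raw = raw.get("cea") or {}
    _check_keys("cea", cea_raw, {"arms", "econ", "util", "wtp"}, problems)
    params = default_parameters()

    arms_raw = cea_raw.get("arms") or {}
    _check_keys("cea.arms", arms_raw, set(_ARM_NAMES), problems)
    for arm_name in _ARM_NAMES:
        arm_raw = arms_raw.get(arm_name) or {}
        _check_keys(f"cea.arms.{arm_name}", arm_raw, _ARM_KEYS, problems)
        arm = getattr(params, arm_name)
        try:
            setattr(params, arm_name, dataclasses.replace(arm, **arm_raw))
        except TypeError as exc:
            problems.append(f"cea.arms.{arm_name}: {exc}")

    params.econ = _build_dataclass(
        EconomicParameters, params.econ, cea_raw.get("econ") or {}, "cea.econ", problems
    )
    params.util = _build_dataclass(
        UtilityParameters, params.util, cea_raw.get("util") or {}, "cea.util", problems
    )
    if "wtp" in cea_raw:
        params.wtp = float(cea_raw["wtp"])

    if not problems:
        try:
            params.validate()
        except ValueError as exc:
            problems.append(str(exc))

    cohort_raw = raw.get("cohort") or {}
    try:
        cohort_cfg = _build_dataclass(
            CohortConfig, CohortConfig(), cohort_raw, "cohort", problems
        )
    except ValueError as exc:  # CohortConfig validates in __post_init__
        problems.append(f"cohort: {exc}")
        cohort_cfg = CohortConfig()

    psa_raw = raw.get("psa") or {}
    _check_keys("psa", psa_raw, {"n_iterations", "seed"}, problems)
    psa_iterations = int(psa_raw.get("n_iterations", 1000))
    psa_seed = int(psa_raw.get("seed", 0))
    if psa_iterations < 1:
        problems.append(f"psa.n_iterations must be >= 1, got {psa_iterations}")

    ceac_raw = raw.get("ceac") or {}
    _check_keys("ceac", ceac_raw, {"wtp_max", "step"}, problems)

    ranges_raw = raw.get("ranges")
    if ranges_raw is None:
        ranges = default_ranges(params)
    else:
        ranges = []
        for i, entry in enumerate(ranges_raw):
            try:
                ranges.append(ParameterRange(**entry))
            except (TypeError, ValueError) as exc:
                problems.append(f"ranges[{i}]: {exc}")

    if problems:
        raise ParameterValidationError(problems)

    return RunConfig(
        cea=params,
        ranges=ranges,
        cohort=cohort_cfg,
        psa_iterations=psa_iterations,
        psa_seed=psa_seed,
        ceac_wtp_max=float(ceac_raw.get("wtp_max", 200_000.0)),
        ceac_wtp_step=float(ceac_raw.get("step", 1000.0)),
    )


def params_to_dict(config: RunConfig) -> dict:
    def arm_dict(arm: ArmParameters) -> dict:
        d = dataclasses.asdict(arm)
        d.pop("name")
        return d

    return {
        "cea": {
            "wtp": config.cea.wtp,
            "arms": {name: arm_dict(getattr(config.cea, name)) for name in _ARM_NAMES},
            "econ": dataclasses.asdict(config.cea.econ),
            "util": dataclasses.asdict(config.cea.util),
        },
        "cohort": dataclasses.asdict(config.cohort),
        "psa": {"n_iterations": config.psa_iterations, "seed": config.psa_seed},
        "ceac": {"wtp_max": config.ceac_wtp_max, "step": config.ceac_wtp_step},
        "ranges": [dataclasses.asdict(r) for r in config.ranges],
    }


def write_params(config: RunConfig, path: str | Path) -> None:
    """Serialize a run configuration to YAML; round-trips through load_params."""
    Path(path).write_text(
        yaml.safe_dump(params_to_dict(config), sort_keys=True), encoding="utf-8"
    )


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(params_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    timestamp: str
    config_hash: str
    seeds: dict[str, int]
    version: str = __version__
    convention: str = "baseline_minus_disutility"
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True),
            encoding="utf-8",
        )


def full_run(
    config: RunConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Run the whole pipeline and write a report bundle to ``out_dir``.

    Stages: cohort simulation, mapping fits and comparison, base-case tree
    evaluation, one-way sensitivity, PSA, CEAC, manifest. ``seed``
    overrides both the cohort and PSA seeds. Stochastic outputs are
    byte-identical across reruns of the same configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(
            config,
            cohort=dataclasses.replace(config.cohort, seed=seed),
            psa_seed=seed,
        )
    paths: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _Ctx()

    with stage("simulate-cohort"):
        records = generate_cohort(config.cohort)
        paths["cohort"] = out / "cohort.csv"
        write_cohort(records, paths["cohort"])

    with stage("fit-mapping"):
        fits, metrics = [], []
        for family in FAMILIES:
            for model in MODEL_PREDICTORS:
                fit = fit_mapping(records, MappingSpec(family, model))
                fits.append(fit)
                metrics.append(validation_metrics(fit, records))
        comparison = compare_models(fits, metrics)
        paths["mapping"] = out / "mapping_comparison.csv"
        comparison.to_csv(paths["mapping"], index=False)

    with stage("run-cea"):
        table = cea_table(config.cea)
        paths["cea"] = out / "cea_results.csv"
        table.to_csv(paths["cea"], index=False)

    with stage("owsa"):
        entries = owsa(config.cea, config.ranges)
        paths["tornado"] = out / "tornado.csv"
        tornado_frame(entries).to_csv(paths["tornado"], index=False)

    with stage("psa"):
        psa_result = run_psa(
            config.cea, config.ranges, config.psa_iterations, config.psa_seed
        )
        paths["psa"] = out / "psa.csv"
        psa_result.write_csv(paths["psa"])

    with stage("ceac"):
        import numpy as np

        grid = np.arange(0.0, config.ceac_wtp_max + config.ceac_wtp_step, config.ceac_wtp_step)
        curve = ceac(psa_result, grid)
        paths["ceac"] = out / "ceac.csv"
        curve.to_csv(paths["ceac"], index=False)
        paths["scatter"] = out / "psa_scatter.csv"
        export_scatter(psa_result, config.cea.wtp, paths["scatter"])

    with stage("manifest"):
        manifest = RunManifest(
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            config_hash=_config_hash(config),
            seeds={"cohort": config.cohort.seed, "psa": config.psa_seed},
            convention=config.cea.util.ae_utility_convention,
            outputs={k: str(v) for k, v in paths.items()},
        )
        paths["manifest"] = out / "manifest.json"
        manifest.write(paths["manifest"])

    return paths
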