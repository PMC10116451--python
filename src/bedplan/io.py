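"""Configuration loading, packaged fixtures, and result serialization.

Problem configs are YAML files with ``grades``, ``district``, ``horizon``
and optional ``scenario`` / ``ga`` blocks; every load is validated field by
field and failures raise :class:`ConfigError` naming the offending key.
The packaged Nanjing parameterization is addressable as
``nanjing/<District>`` (e.g. ``nanjing/Xuanwu``).

Plans are written as CSV (cycle, grade, count), archives as CSV with one
flattened plan per row plus both objectives, and TOPSIS decisions as JSON.
All CSV output is comma-separated, UTF-8, header row, ``.`` decimal, with
reals printed to 12 significant digits so a read-back reproduces them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import DistrictState, GradeParameters, PlanningProblem
from .nsga import GAConfig, ParetoArchive
from .scenario import RateSchedule, build_smart_problem
from .topsis import TopsisResult

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "load_problem",
    "load_smart_problem",
    "ga_config_from",
    "problem_to_config",
    "nanjing_districts",
    "config_digest",
    "write_plan",
    "read_plan",
    "write_archive",
    "read_archive",
    "write_decision",
    "write_manifest",
]

FLOAT_FORMAT = "%.12g"


class ConfigError(ValueError):
    """A problem config failed validation; the message names the field."""


def _get(block: dict, key: str, path: str, required: bool = True, default=None):
    if key not in block:
        if required:
            raise ConfigError(f"missing required field '{path}.{key}'")
        return default
    return block[key]


def _numeric_list(value, path: str) -> list[float]:
    if not isinstance(value, (list, tuple)) or not all(
        isinstance(v, (int, float)) and not isinstance(v, bool) for v in value
    ):
        raise ConfigError(f"'{path}' must be a list of numbers")
    return [float(v) for v in value]


def load_config(path) -> dict:
    """Read a YAML problem config into a plain dict."""
    text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def _grades_from(cfg: dict) -> GradeParameters:
    block = _get(cfg, "grades", "")
    if not isinstance(block, dict):
        raise ConfigError("'grades' must be a mapping")
    try:
        return GradeParameters(
            cost=_numeric_list(_get(block, "cost", "grades"), "grades.cost"),
            income=_numeric_list(_get(block, "income", "grades"), "grades.income"),
            beds=_numeric_list(_get(block, "beds", "grades"), "grades.beds"),
            min_share=_numeric_list(_get(block, "min_share", "grades"), "grades.min_share"),
            labels=tuple(block["labels"]) if "labels" in block else None,
        )
    except ValueError as exc:
        raise ConfigError(f"invalid 'grades' block: {exc}") from exc


def _district_from(cfg: dict, grades: GradeParameters) -> DistrictState:
    block = _get(cfg, "district", "")
    if not isinstance(block, dict):
        raise ConfigError("'district' must be a mapping")
    name = str(_get(block, "name", "district"))
    counts = block.get("institutions")
    beds = block.get("initial_beds")
    if counts is None and beds is None:
        raise ConfigError("'district' needs 'institutions' and/or 'initial_beds'")
    try:
        if beds is None:
            return DistrictState.from_counts(name, np.asarray(counts, dtype=np.int64), grades)
        if counts is None:
            counts = [0] * grades.n_grades
        return DistrictState(
            name=name,
            institution_counts=np.asarray(counts, dtype=np.int64),
            initial_beds=np.asarray(beds, dtype=np.int64),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid 'district' block: {exc}") from exc


def _problem_from_config(cfg: dict) -> PlanningProblem:
    grades = _grades_from(cfg)
    district = _district_from(cfg, grades)
    horizon = _get(cfg, "horizon", "")
    if not isinstance(horizon, dict):
        raise ConfigError("'horizon' must be a mapping")
    cycles = _get(horizon, "cycles", "horizon")
    population = _get(horizon, "population", "horizon")
    bed_rate = _get(horizon, "bed_rate", "horizon")
    upper_bounds = horizon.get("upper_bounds")
    if upper_bounds is not None:
        upper_bounds = np.asarray(upper_bounds, dtype=np.int64)
    try:
        return PlanningProblem(
            district=district,
            grades=grades,
            n_cycles=int(cycles),
            bed_rate_targets=np.array([float(bed_rate)]),
            horizon_population=float(population),
            upper_bounds=upper_bounds,
        )
    except ValueError as exc:
        raise ConfigError(f"invalid 'horizon' block: {exc}") from exc


def _nanjing_config() -> dict:
    text = resources.files("bedplan").joinpath("data/nanjing.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


def nanjing_districts() -> tuple[str, ...]:
    """Names of the districts in the packaged Nanjing fixture."""
    return tuple(_nanjing_config()["districts"])


def _resolve_config(source) -> dict:
    """A config dict from a ``nanjing/<district>`` fixture name or a path."""
    if isinstance(source, dict):
        return source
    source = str(source)
    if source.startswith("nanjing/"):
        district = source.split("/", 1)[1]
        fixture = _nanjing_config()
        if district not in fixture["districts"]:
            raise ConfigError(
                f"unknown district '{district}'; known: {', '.join(fixture['districts'])}"
            )
        cfg = {k: fixture[k] for k in ("grades", "horizon", "scenario")}
        cfg["district"] = {"name": district, "institutions": fixture["districts"][district]}
        return cfg
    if not Path(source).exists():
        raise ConfigError(f"config file not found: {source}")
    return load_config(source)


def load_problem(source) -> PlanningProblem:
    """Load a baseline (horizon-mode) problem from a path, fixture name, or dict."""
    return _problem_from_config(_resolve_config(source))


def load_smart_problem(source) -> PlanningProblem:
    """Load a problem and apply its ``scenario`` block (smart-community mode)."""
    cfg = _resolve_config(source)
    base = _problem_from_config(cfg)
    block = cfg.get("scenario", {})
    if not isinstance(block, dict):
        raise ConfigError("'scenario' must be a mapping")
    try:
        schedule = RateSchedule(
            base_rate=float(_get(block, "base_rate", "scenario")),
            increments=tuple(_numeric_list(_get(block, "increments", "scenario"), "scenario.increments")),
        )
        return build_smart_problem(
            base,
            switch_cycle=int(block.get("switch_cycle", 3)),
            income_factor=float(block.get("income_factor", 0.5)),
            schedule=schedule,
            reference_population=block.get("reference_population"),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid 'scenario' block: {exc}") from exc


def ga_config_from(source, seed: int | None = None, **overrides) -> GAConfig:
    """Build a :class:`GAConfig` from a config's ``ga`` block plus overrides."""
    cfg = _resolve_config(source)
    block = cfg.get("ga", {})
    if not isinstance(block, dict):
        raise ConfigError("'ga' must be a mapping")
    kwargs = dict(block)
    kwargs.update(overrides)
    if seed is not None:
        kwargs["seed"] = seed
    try:
        return GAConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid 'ga' block: {exc}") from exc


def problem_to_config(problem: PlanningProblem) -> dict:
    """Serialise a horizon-mode problem to a config dict (inverse of load)."""
    if problem.mode != "horizon":
        raise ValueError("only horizon-mode problems serialise to a baseline config")
    g = problem.grades
    return {
        "grades": {
            "labels": list(g.labels),
            "cost": [float(v) for v in g.cost],
            "income": [float(v) for v in g.income],
            "beds": [float(v) for v in g.beds],
            "min_share": [float(v) for v in g.min_share],
        },
        "district": {
            "name": problem.district.name,
            "institutions": [int(v) for v in problem.district.institution_counts],
            "initial_beds": [int(v) for v in problem.district.initial_beds],
        },
        "horizon": {
            "cycles": int(problem.n_cycles),
            "population": float(problem.horizon_population),
            "bed_rate": float(problem.bed_rate_targets[0]),
            "upper_bounds": [[int(v) for v in row] for row in problem.bounds()],
        },
    }


def config_digest(cfg: dict) -> str:
    """SHA-256 of the canonical JSON form of a config dict."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every result file."""

    config_digest: str
    seed: int | None
    mode: str
    created: str
    version: str

    @classmethod
    def create(cls, cfg: dict, seed: int | None, mode: str) -> "RunManifest":
        return cls(
            config_digest=config_digest(cfg),
            seed=seed,
            mode=mode,
            created=datetime.now(timezone.utc).isoformat(),
            version=__version__,
        )


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2) + "\n", encoding="utf-8")


def _plan_frame(plan: np.ndarray, problem: PlanningProblem) -> pd.DataFrame:
    m, n = plan.shape
    return pd.DataFrame(
        {
            "cycle": np.repeat(np.arange(1, m + 1), n),
            "grade": list(problem.grades.labels) * m,
            "count": np.asarray(plan, dtype=np.int64).ravel(),
        }
    )


def write_plan(plan: np.ndarray, problem: PlanningProblem, path) -> None:
    """Write one plan as CSV with columns cycle, grade, count."""
    _plan_frame(np.asarray(plan), problem).to_csv(path, index=False)


def read_plan(path, problem: PlanningProblem) -> np.ndarray:
    """Read a plan CSV back into an M x N integer matrix."""
    df = pd.read_csv(path)
    plan = np.zeros((problem.n_cycles, problem.n_grades), dtype=np.int64)
    label_index = {label: j for j, label in enumerate(problem.grades.labels)}
    for _, row in df.iterrows():
        plan[int(row["cycle"]) - 1, label_index[row["grade"]]] = int(row["count"])
    return plan


def _archive_columns(problem: PlanningProblem) -> list[str]:
    return [
        f"x{i + 1}_{label}"
        for i in range(problem.n_cycles)
        for label in problem.grades.labels
    ]


def write_archive(archive: ParetoArchive, problem: PlanningProblem, path) -> None:
    """Write an archive as CSV: flattened plan cells, F1, F2, feasible."""
    cols = _archive_columns(problem)
    df = pd.DataFrame(archive.plans.reshape(len(archive), -1), columns=cols)
    df["F1"] = archive.economic_benefits
    df["F2"] = archive.social_costs
    df["feasible"] = archive.feasible.astype(bool)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_archive(path, problem: PlanningProblem) -> ParetoArchive:
    """Read an archive CSV back into a :class:`ParetoArchive`."""
    df = pd.read_csv(path)
    cols = _archive_columns(problem)
    plans = df[cols].to_numpy(dtype=np.int64).reshape(
        len(df), problem.n_cycles, problem.n_grades
    )
    objectives = np.stack([-df["F1"].to_numpy(float), df["F2"].to_numpy(float)], axis=1)
    return ParetoArchive(
        plans=plans, objectives=objectives, feasible=df["feasible"].to_numpy(bool)
    )


def write_decision(result: TopsisResult, plan: np.ndarray, problem: PlanningProblem, path) -> None:
    """Write a TOPSIS decision (all intermediate matrices) as JSON."""
    payload = {
        "selected_index": int(result.selected),
        "weights": result.weights.tolist(),
        "closeness": result.closeness.tolist(),
        "d_plus": result.d_plus.tolist(),
        "d_minus": result.d_minus.tolist(),
        "ideal": result.ideal.tolist(),
        "anti_ideal": result.anti_ideal.tolist(),
        "objectives_min_convention": result.matrix.tolist(),
        "selected_plan": np.asarray(plan, dtype=np.int64).tolist(),
        "economic_benefit": float(-result.matrix[result.selected, 0]),
        "social_cost": float(result.matrix[result.selected, 1]),
        "grades": list(problem.grades.labels),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
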