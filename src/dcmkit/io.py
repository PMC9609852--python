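"""Experiment configuration, concentration-table IO and the pipeline runner.

CSV is the lingua franca: times in hours, concentrations in mg/mL, release in
percent of dose, segments indexed 1..10 from the caecal end.  Every artifact
written by :func:`run_pipeline` carries the configuration hash and seed for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import comparison, reconstruction
from .errors import ConfigError, DataError
from .patterns import load_pattern
from .reconstruction import (
    STUDY_SCHEDULE_H,
    LumenGeometry,
    SegmentalConcentrationSeries,
)

__all__ = [
    "ExperimentConfig",
    "read_concentration_table",
    "write_concentration_table",
    "run_pipeline",
]

log = logging.getLogger("dcmkit")

_REQUIRED_COLUMNS = ("time_h", "port", "concentration_mg_per_ml")


def read_concentration_table(path) -> SegmentalConcentrationSeries:
    """Read a segmental concentration CSV, validating rows.

    Required columns: ``time_h``, ``port``, ``concentration_mg_per_ml``;
    ``replicate`` is optional (defaults to 0).  Lines starting with ``#`` are
    treated as comments.  Malformed rows raise a :class:`DataError` listing
    the offending line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"concentration table not found: {path}")
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise DataError(f"concentration table {path} is empty")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    bad_lines = []
    for col in ("time_h", "concentration_mg_per_ml"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad_lines += (frame.index[coerced.isna() & frame[col].notna()] + 2).tolist()
        frame[col] = coerced
    port = pd.to_numeric(frame["port"], errors="coerce")
    bad_lines += (frame.index[port.isna()] + 2).tolist()
    if bad_lines:
        raise DataError(f"{path}: malformed rows at lines {sorted(set(bad_lines))}")
    frame["port"] = port.astype(int)
    series = SegmentalConcentrationSeries(frame)
    log.info(
        "read %s: %d records, %d timepoints, ports %s, %d replicate(s)",
        path, len(series), len(series.times), series.ports, len(series.replicates),
    )
    return series


def write_concentration_table(series: SegmentalConcentrationSeries, path,
                              header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        series.frame.to_csv(fh, index=False)


@dataclass
class ExperimentConfig:
    """Full description of one analysis (or simulation + analysis) run."""

    pattern: str = "static"                 # packaged name or YAML path
    dose: float = 200.0                     # mg
    schedule: tuple[float, ...] = STUDY_SCHEDULE_H
    window: tuple[float, float] = comparison.DEFAULT_WINDOW
    seed: int = 0
    noise_cv: float = 0.07
    simulate: bool = False                  # generate data instead of reading it
    concentrations: str | None = None       # input CSV when simulate is False
    geometry: dict = field(default_factory=dict)   # LumenGeometry overrides
    log_level: str = "INFO"

    def __post_init__(self):
        sched = tuple(self.schedule)
        if list(sched) != sorted(set(sched)):
            raise ConfigError("schedule must be sorted and unique")
        if self.dose <= 0:
            raise ConfigError("dose must be positive")
        lo, hi = self.window
        if not lo < hi:
            raise ConfigError("window lower bound must be below the upper bound")
        self.schedule = sched
        self.window = (float(lo), float(hi))

    def build_geometry(self) -> LumenGeometry:
        return LumenGeometry(**self.geometry)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"invalid experiment config {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: ExperimentConfig) -> str:
    return f"config_hash={config.hash()} seed={config.seed}"


def run_pipeline(config: ExperimentConfig, outdir) -> dict:
    """Execute (simulate ->) reconstruct -> fit -> compare, writing artifacts.

    Returns a dict of artifact paths.  When ``config.simulate`` is true, a
    synthetic dataset is generated with the configured motility pattern and
    the reconstructed profile is compared against the simulator ground truth;
    otherwise ``config.concentrations`` is read and only reconstruction and
    fitting run.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    tag = _provenance(config)
    geometry = config.build_geometry()
    truth_profile = None

    try:
        if config.simulate:
            from .simulate import SimulationConfig, ground_truth_release, simulate

            pattern = load_pattern(config.pattern)
            sim = simulate(
                SimulationConfig(
                    pattern=pattern,
                    dose=config.dose,
                    noise_cv=config.noise_cv,
                    seed=config.seed,
                    schedule=config.schedule,
                    geometry=geometry,
                )
            )
            series = sim.measured
            truth_profile = ground_truth_release(sim)
            artifacts["concentrations"] = outdir / "concentrations.csv"
            write_concentration_table(series, artifacts["concentrations"], tag)
            artifacts["truth"] = outdir / "truth.csv"
            truth_profile.to_csv(artifacts["truth"], tag)
            config.to_yaml(outdir / "config.yaml")
            artifacts["config"] = outdir / "config.yaml"
        else:
            if not config.concentrations:
                raise ConfigError("config field 'concentrations' is required unless simulate=true")
            series = read_concentration_table(config.concentrations)
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"[stage: input] {exc}") from exc

    try:
        profile = reconstruction.release_profile(series, geometry, dose=config.dose)
        artifacts["profile"] = outdir / "profile.csv"
        profile.to_csv(artifacts["profile"], tag)
        summary = {
            "provenance": tag,
            "dose_mg": config.dose,
            "final_fraction_pct": float(profile.released_fraction[-1]),
            "monotonicity_violations": profile.monotonicity_violations,
        }
    except Exception as exc:
        raise DataError(f"[stage: reconstruct] {exc}") from exc

    try:
        fit = comparison.fit_power_law(profile)
        artifacts["fit"] = outdir / "fit.json"
        artifacts["fit"].write_text(
            json.dumps({"provenance": tag, **fit.to_dict()}, indent=2)
        )
        summary["power_law"] = fit.to_dict()
    except Exception as exc:
        raise DataError(f"[stage: fit] {exc}") from exc

    if truth_profile is not None:
        try:
            sim_result = comparison.similarity(
                truth_profile, profile, window=config.window
            )
            summary["similarity_vs_truth"] = asdict(sim_result)
        except DataError as exc:
            summary["similarity_vs_truth"] = {"error": f"[stage: compare] {exc}"}

    artifacts["summary"] = outdir / "summary.json"
    artifacts["summary"].write_text(json.dumps(summary, indent=2))
    return {k: str(v) for k, v in artifacts.items()}
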