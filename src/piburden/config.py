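"""Run configuration: YAML loading, strict validation, result serialization.

Configs are flat YAML mappings; unknown keys are rejected by name so typos
fail loudly.  Raw (unrounded) counts are always what gets serialized;
nearest-100 rounding appears only in the human-readable summary files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "save_config", "write_results"]


@dataclass
class RunConfig:
    """Settings for one pipeline run, with documented defaults."""

    seed: int = 12345
    scale: float = 1.0
    horizon: int = 7
    base_year_prevalence: int = 2006  # survey year for the base-case scenario
    alt_year_prevalence: int = 2012
    n_draws: int = 1000
    tol: float = 0.01
    max_iter: int = 100
    damping: float = 1.0
    outdir: str = "results"
    verbose: bool = False

    def validate(self) -> None:
        checks = [
            (self.scale > 0, "scale must be positive"),
            (self.horizon >= 1, "horizon must be at least 1"),
            (self.n_draws >= 2, "n_draws must be at least 2"),
            (self.tol > 0, "tol must be positive"),
            (self.max_iter >= 1, "max_iter must be at least 1"),
            (0 < self.damping <= 1, "damping must lie in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take their documented defaults; unknown keys raise a
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    try:
        cfg = RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def write_results(result, outdir, cfg: RunConfig | None = None) -> list[Path]:
    """Serialize a result object to CSV plus a run manifest.

    Dispatches on type: simulation results become a long-format CSV;
    scenario deltas become a raw CSV plus a nearest-100 rounded summary;
    Monte Carlo summaries become a single CSV.  Returns the paths written.
    """
    from .calibration import CalibrationFactors
    from .cohort_model import SimulationResult
    from .scenario_engine import OutcomeDelta
    from .uncertainty import MonteCarloSummary

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    if isinstance(result, SimulationResult):
        p = outdir / f"simulation_{result.scenario_name or 'run'}.csv"
        result.to_frame().to_csv(p, index=False)
        paths.append(p)
    elif isinstance(result, OutcomeDelta):
        p = outdir / f"delta_{result.base_name}_vs_{result.alt_name}.csv"
        result.to_frame().to_csv(p, index_label="outcome")
        paths.append(p)
        p2 = outdir / f"delta_{result.base_name}_vs_{result.alt_name}_summary.csv"
        result.summary_table().to_csv(p2, index_label="outcome")
        paths.append(p2)
    elif isinstance(result, MonteCarloSummary):
        p = outdir / "monte_carlo_summary.csv"
        result.to_frame().to_csv(p, index_label="outcome")
        paths.append(p)
        if result.draws is not None:
            p2 = outdir / "monte_carlo_draws.csv"
            result.draws.to_csv(p2, index_label="draw")
            paths.append(p2)
    elif isinstance(result, CalibrationFactors):
        p = outdir / "calibration_factors.csv"
        result.to_frame().to_csv(p, index=False)
        paths.append(p)
        p2 = outdir / "calibration_trace.csv"
        with open(p2, "w") as fh:
            fh.write("iteration,max_relative_residual\n")
            for i, r in enumerate(result.trace):
                fh.write(f"{i},{r}\n")
        paths.append(p2)
    else:
        raise ConfigError(f"cannot serialize result of type {type(result).__name__}")

    manifest = {
        "package_version": __version__,
        "result_type": type(result).__name__,
        "files": [p.name for p in paths],
    }
    if cfg is not None:
        manifest["config"] = cfg.to_dict()
        manifest["config_hash"] = cfg.content_hash()
        manifest["seed"] = cfg.seed
    mpath = outdir / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths.append(mpath)
    return paths
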