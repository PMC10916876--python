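"""Run configuration (YAML-backed), logging setup and provenance records."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "setup_logging",
    "write_provenance",
]


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SelectionBlock(_Block):
    max_iter: int = 100
    alpha: float = 0.05
    estimator_max_depth: int = 5
    estimator_trees: int | Literal["auto"] = "auto"


class GatesBlock(_Block):
    r2_threshold: float = 0.25
    mcc_threshold: float = 0.50


class CVBlock(_Block):
    n_repeats: int = 5
    n_outer_folds: int = 4
    inner_folds: int = 5
    n_candidates: int = 8
    min_resources: int = 25
    max_resources: int = 500


class ScoringBlock(_Block):
    log10_mode: bool = False


class InterpretationBlock(_Block):
    sd_convention: Literal["population", "sample"] = "population"
    strict: bool = True


class RunConfig(_Block):
    seed: int = 0
    log_level: str = "INFO"
    selection: SelectionBlock = SelectionBlock()
    gates: GatesBlock = GatesBlock()
    cv: CVBlock = CVBlock()
    scoring: ScoringBlock = ScoringBlock()
    interpretation: InterpretationBlock = InterpretationBlock()

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from None
    if raw is None:
        return RunConfig()
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{path}: {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError("\n".join(lines)) from None


def setup_logging(level: str = "INFO", json_path: str | Path | None = None) -> None:
    """Structured text logs to stderr, optional JSON-lines log file."""
    root = logging.getLogger("biomorph")
    root.setLevel(level.upper())
    root.handlers.clear()
    text = logging.StreamHandler(sys.stderr)
    text.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root.addHandler(text)
    if json_path is not None:
        class _JsonFormatter(logging.Formatter):
            def format(self, record: logging.LogRecord) -> str:
                return json.dumps(
                    {
                        "time": self.formatTime(record),
                        "name": record.name,
                        "level": record.levelname,
                        "message": record.getMessage(),
                    }
                )

        jh = logging.FileHandler(json_path)
        jh.setFormatter(_JsonFormatter())
        root.addHandler(jh)


def write_provenance(
    outdir: str | Path,
    command: str,
    config: RunConfig,
    inputs: dict[str, str | Path] | None = None,
) -> Path:
    """Write a provenance sidecar: command, config digest, seed, input digests."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digests = {}
    for name, p in (inputs or {}).items():
        p = Path(p)
        if p.exists():
            digests[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    payload = {
        "command": command,
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "inputs": digests,
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
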