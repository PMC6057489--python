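"""Run configuration: one YAML/JSON file drives the whole analysis."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


_KNOWN_INPUTS = {
    "chrom_sizes",
    "peaks_before",
    "peaks_after",
    "genes",
    "catalog",
    "precedence",
    "expression",
    "fragments_before",
    "fragments_after",
    "fasta",
    "pwms",
}
_KNOWN_PARAMS = {
    "tss_window_half",
    "min_new_dist",
    "assoc_window",
    "expression_threshold",
    "motif_threshold",
    "coverage_window",
    "bin_width",
}
_REQUIRED_INPUTS = ("chrom_sizes", "peaks_before", "peaks_after", "genes")


@dataclass
class RunConfig:
    """Fully resolved configuration with defaults applied."""

    chrom_sizes: Path
    peaks_before: Path
    peaks_after: Path
    genes: Path
    outdir: Path
    catalog: dict[str, Path] = field(default_factory=dict)
    precedence: list[str] = field(default_factory=list)
    expression: Path | None = None
    fragments_before: Path | None = None
    fragments_after: Path | None = None
    fasta: Path | None = None
    pwms: Path | None = None
    tss_window_half: int = 1000
    min_new_dist: int = 5000
    assoc_window: int = 1000
    expression_threshold: float = 1.0
    motif_threshold: float | None = None
    coverage_window: int = 1000
    bin_width: int = 1000
    seed: int = 0

    def content_hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in sorted(self.__dict__.items())
            if k != "outdir"
        }
        payload["catalog"] = {k: str(v) for k, v in self.catalog.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def validate_config(path, outdir: str | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys warn (forward compatibility); missing required paths and
    non-positive parameters are collected into one error.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a YAML/JSON mapping")
    base = Path(path).parent
    errors: list[str] = []

    inputs = raw.get("inputs", {}) or {}
    params = raw.get("params", {}) or {}
    for k in set(raw) - {"inputs", "params", "outdir", "seed"}:
        warnings.warn(f"unknown top-level config key {k!r} ignored", stacklevel=2)
    for k in set(inputs) - _KNOWN_INPUTS:
        warnings.warn(f"unknown input key {k!r} ignored", stacklevel=2)
    for k in set(params) - _KNOWN_PARAMS:
        warnings.warn(f"unknown parameter {k!r} ignored", stacklevel=2)

    def _path(value) -> Path:
        p = Path(value)
        return p if p.is_absolute() else base / p

    resolved: dict[str, object] = {}
    for key in _REQUIRED_INPUTS:
        if key not in inputs:
            errors.append(f"missing required input {key!r}")
            continue
        p = _path(inputs[key])
        if not p.exists():
            errors.append(f"input {key!r}: no such file {p}")
        resolved[key] = p
    for key in ("expression", "fragments_before", "fragments_after", "fasta", "pwms"):
        if key in inputs and inputs[key] is not None:
            p = _path(inputs[key])
            if not p.exists():
                errors.append(f"input {key!r}: no such file {p}")
            resolved[key] = p
    catalog = {}
    for label, value in (inputs.get("catalog") or {}).items():
        p = _path(value)
        if not p.exists():
            errors.append(f"catalog class {label!r}: no such file {p}")
        catalog[str(label)] = p
    resolved["catalog"] = catalog
    resolved["precedence"] = [str(x) for x in inputs.get("precedence", [])]

    for key in _KNOWN_PARAMS:
        if key in params and params[key] is not None:
            v = params[key]
            if key != "motif_threshold" and (not isinstance(v, (int, float)) or v <= 0):
                errors.append(f"parameter {key!r} must be positive, got {v!r}")
            else:
                resolved[key] = v

    out = outdir or raw.get("outdir")
    if out is None:
        errors.append("missing 'outdir'")
    else:
        resolved["outdir"] = _path(out)
    if "seed" in raw:
        resolved["seed"] = int(raw["seed"])

    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(**resolved)  # type: ignore[arg-type]
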