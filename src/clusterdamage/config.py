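"""Run configuration: YAML loading with strict validation.

A config file is a nested mapping; unknown keys are rejected with the
offending field named.  All sections are optional and default to the
standard parameter set (nucleosome fractions, printed q0 ladder, smeared
17.5 eV threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import yaml

from .cluster_algebra import PRINTED_Q0_TABLE, ClusterGeometry, RadicalFates
from .core_model import DEFAULT_J_CAP, EventProbabilities, ThresholdDistribution
from .yields import DamageModel

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Raised for malformed or contradictory run configuration."""


_SECTIONS = {
    "events": {"p_a", "p_b", "p_c", "p_d"},
    "fates": {"r1", "r2", "r3"},
    "geometry": {"n_bp", "window_bp", "q0_table", "q0_constant", "q0_source"},
    "threshold": {"mean_ev", "sd_ev", "lower_cut_ev", "n_nodes"},
}
_TOP_LEVEL = set(_SECTIONS) | {"mode", "j_cap", "seed", "spectra", "out_dir"}


@dataclass
class RunConfig:
    """Resolved run configuration for the command-line entry points."""

    events: EventProbabilities = field(default_factory=EventProbabilities)
    fates: RadicalFates = field(default_factory=RadicalFates)
    geometry: ClusterGeometry = field(default_factory=ClusterGeometry)
    threshold: ThresholdDistribution = field(default_factory=ThresholdDistribution)
    mode: str = "exact"
    j_cap: int = DEFAULT_J_CAP
    seed: int = 0
    spectra: List[str] = field(default_factory=list)
    out_dir: str = "."

    def model(self) -> DamageModel:
        return DamageModel(
            events=self.events, geometry=self.geometry, fates=self.fates,
            thresholds=self.threshold, mode=self.mode, j_cap=self.j_cap,
        )


def _check_keys(mapping: Mapping, allowed: set, context: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(
                f"unknown key {key!r} in {context}; allowed: {sorted(allowed)}"
            )


def load_config(path: Optional[str] = None,
                overrides: Optional[Mapping] = None) -> RunConfig:
    """Load a YAML config file (all keys optional), applying overrides.

    ``overrides`` is a flat mapping of top-level keys (``mode``, ``seed``,
    ...) applied after the file, used by the CLI flags.
    """
    data: Dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        data = raw
    _check_keys(data, _TOP_LEVEL, "config")
    for section, allowed in _SECTIONS.items():
        if section in data:
            if not isinstance(data[section], dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            _check_keys(data[section], allowed, f"section {section!r}")
    if overrides:
        for key, value in overrides.items():
            if value is None:
                continue
            if key not in _TOP_LEVEL:
                raise ConfigError(f"unknown override {key!r}")
            data[key] = value

    try:
        events = EventProbabilities(**data.get("events", {}))
        fates = RadicalFates(**data.get("fates", {}))
        geo_raw = dict(data.get("geometry", {}))
        q0_source = geo_raw.pop("q0_source", "printed-table")
        if q0_source not in ("printed-table", "mc-estimate"):
            raise ConfigError(
                f"q0_source must be 'printed-table' or 'mc-estimate', got {q0_source!r}"
            )
        if "q0_table" in geo_raw:
            geo_raw["q0_table"] = {int(k): float(v)
                                   for k, v in geo_raw["q0_table"].items()}
        geometry = ClusterGeometry(**geo_raw)
        if q0_source == "mc-estimate":
            geometry = _mc_geometry(geometry, int(data.get("seed", 0)))
        threshold = ThresholdDistribution(**data.get("threshold", {}))
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    mode = data.get("mode", "exact")
    if mode not in ("exact", "paper_approx"):
        raise ConfigError(f"mode must be 'exact' or 'paper_approx', got {mode!r}")
    spectra = data.get("spectra", [])
    if isinstance(spectra, str):
        spectra = [spectra]
    return RunConfig(
        events=events, fates=fates, geometry=geometry, threshold=threshold,
        mode=mode, j_cap=int(data.get("j_cap", DEFAULT_J_CAP)),
        seed=int(data.get("seed", 0)), spectra=list(spectra),
        out_dir=str(data.get("out_dir", ".")),
    )


def _mc_geometry(geometry: ClusterGeometry, seed: int) -> ClusterGeometry:
    """Replace the printed q0 ladder with uniform-placement MC estimates."""
    from .mc_oracle import estimate_q0

    table = {
        j: estimate_q0(j, geometry, convention="uniform-bp",
                       n_trials=200_000, seed=seed + j)[0]
        for j in range(2, 8)
    }
    # enforce the ladder's monotonicity against MC noise
    for j in range(3, 8):
        table[j] = min(table[j], table[j - 1])
    return ClusterGeometry(n_bp=geometry.n_bp, window_bp=geometry.window_bp,
                           q0_table=table)
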