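"""Run configuration: a single YAML key-value file with a documented schema.

Schema (all keys optional unless a command requires them):

.. code-block:: yaml

    reference: ref_S1.pdb          # orientation reference / topology
    references:                    # loop reference states
      S1: ref_S1.pdb
      S1p: ref_S1p.pdb             # S1p is read as the label S1'
      S2: ref_S2.pdb
    trajectory: traj.pdb           # multi-model PDB
    params: params.csv             # nonbond parameter table
    force_log: force.csv           # cv-mode force series (time_ns, force_pN)
    dt_ns: 0.05                    # frame spacing if no explicit times
    selections:                    # named selection expressions
      align: "chain A and resid 90-119"
      loop: "chain A and resid 81-89"
      hinge: "chain A and resid 120-121 and heavy"
      body: "chain A and resid 122-141 and heavy"
      receptor: "chain A"
      ligand: "chain B"
      fixed: "chain A and resid 222"
      pulled: "chain B and resid 618"
    thresholds:
      state_rmsd_A: 4.0
      zero_tol_kcal: 0.5
      persistence_frames: 5
      min_dwell_frames: 5
    cutoff:
      r_on_A: 10.0
      r_off_A: 12.0

Schema violations are collected and reported all at once.  CLI flags
override file keys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .structio import UNITS

__all__ = ["RunConfig", "ConfigError", "DEFAULT_THRESHOLDS", "DEFAULT_CUTOFF"]

DEFAULT_THRESHOLDS = {
    "state_rmsd_A": 4.0,
    "zero_tol_kcal": 0.5,
    "persistence_frames": 5,
    "min_dwell_frames": 5,
}

DEFAULT_CUTOFF = {"r_on_A": 10.0, "r_off_A": 12.0}

_PATH_KEYS = ("reference", "trajectory", "params", "force_log")


class ConfigError(ValueError):
    """One or more configuration problems; the message lists all of them."""


@dataclass
class RunConfig:
    """Validated analysis configuration."""

    reference: Path | None = None
    references: dict[str, Path] = field(default_factory=dict)
    trajectory: Path | None = None
    params: Path | None = None
    force_log: Path | None = None
    dt_ns: float = 1.0
    selections: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    cutoff: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFF))
    base_dir: Path = Path(".")

    @classmethod
    def load(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        """Load and validate; problems are enumerated all at once."""
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if overrides:
            raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str | Path = ".") -> "RunConfig":
        base_dir = Path(base_dir)
        errors: list[str] = []
        cfg = cls(base_dir=base_dir)

        def _resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base_dir / q

        for key in _PATH_KEYS:
            if raw.get(key) is not None:
                p = _resolve(str(raw[key]))
                if not p.exists():
                    errors.append(f"{key}: file not found: {p}")
                setattr(cfg, key, p)
        for label, p in (raw.get("references") or {}).items():
            q = _resolve(str(p))
            if not q.exists():
                errors.append(f"references.{label}: file not found: {q}")
            cfg.references[str(label).replace("S1p", "S1'")] = q
        if raw.get("dt_ns") is not None:
            cfg.dt_ns = float(raw["dt_ns"])
            if cfg.dt_ns <= 0:
                errors.append("dt_ns: must be positive")
        cfg.selections.update({str(k): str(v) for k, v in (raw.get("selections") or {}).items()})
        cfg.thresholds.update({str(k): float(v) for k, v in (raw.get("thresholds") or {}).items()})
        for k, v in cfg.thresholds.items():
            if v <= 0:
                errors.append(f"thresholds.{k}: must be positive, got {v}")
        cfg.cutoff.update({str(k): float(v) for k, v in (raw.get("cutoff") or {}).items()})
        if not (0 < cfg.cutoff["r_on_A"] < cfg.cutoff["r_off_A"]):
            errors.append(f"cutoff: need 0 < r_on_A < r_off_A, got {cfg.cutoff}")
        if errors:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
        return cfg

    def to_dict(self) -> dict:
        return {
            "reference": str(self.reference) if self.reference else None,
            "references": {k.replace("S1'", "S1p"): str(v) for k, v in self.references.items()},
            "trajectory": str(self.trajectory) if self.trajectory else None,
            "params": str(self.params) if self.params else None,
            "force_log": str(self.force_log) if self.force_log else None,
            "dt_ns": self.dt_ns,
            "selections": dict(self.selections),
            "thresholds": dict(self.thresholds),
            "cutoff": dict(self.cutoff),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the configuration content."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def manifest(self, command: str, seed: int | None = None,
                 extra: dict | None = None) -> dict:
        from . import __version__
        m = {
            "command": command,
            "config_digest": self.digest(),
            "inputs": {k: str(getattr(self, k)) for k in _PATH_KEYS if getattr(self, k)},
            "version": __version__,
            "seed": seed,
            "units": dict(UNITS),
        }
        if extra:
            m.update(extra)
        return m
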