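"""Run configuration shared by the CLI and the pipeline entry points."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline knobs with their defaults.

    The defaults mirror the standard protocol: +/-7-residue windows,
    RBF beta grid {1..5} per view, small EasyMKL regularization, unit
    SVM penalty, the 25-positive kinase filter, 10-fold CV, operating
    points at 95%/90% specificity and the 1/2/5/10/20% retrieval
    fractions.  The full config is echoed into every output file.
    """

    flank: int = 7
    betas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    lambda_reg: float = 0.1
    C: float = 1.0
    ppi_mode: str = "binary"
    min_positives: int = 25
    cv_k: int = 10
    seed: int = 0
    specificity_targets: tuple[float, ...] = (0.95, 0.90)
    topk_fractions: tuple[float, ...] = (0.01, 0.02, 0.05, 0.10, 0.20)
    views: tuple[str, ...] = ("seq", "func")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("betas", "specificity_targets", "topk_fractions", "views"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_sources(cls, yaml_path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build a config from an optional YAML file; explicit keyword
        overrides (CLI flags) win over the file."""
        data: dict = {}
        if yaml_path is not None:
            loaded = yaml.safe_load(Path(yaml_path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {yaml_path} must hold a mapping")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("betas", "specificity_targets", "topk_fractions", "views"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def content_hash(path: str | Path) -> str:
    """Short sha256 content hash used for input provenance in outputs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
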