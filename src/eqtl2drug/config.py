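"""Run configuration: a flat YAML file mirrored one-to-one by CLI flags."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import List, Optional, Tuple

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    """Everything a pipeline run needs: input paths plus thresholds.

    Defaults: ``p_threshold`` 5e-3 (a deliberately permissive cutoff — the
    point is to feed the expression filter, not to claim genome-wide
    significance), ``q_fraction`` 0.05 (top 5% of catalog q-values),
    ``min_ortholog_identity`` 50 percent.
    """

    gwas: str = ""
    eqtls: List[str] = field(default_factory=list)
    interactions: str = ""
    annotation: Optional[str] = None
    known_genes: Optional[str] = None
    exclude_genes: List[str] = field(default_factory=list)
    include_pairs: Optional[str] = None
    orthologs: Optional[str] = None
    cns_tissues: Optional[List[str]] = None
    p_threshold: float = 5e-3
    q_fraction: float = 0.05
    per_tissue_q: bool = False
    approved_only: bool = True
    control_from_full: bool = False
    yates: bool = False
    min_ortholog_identity: float = 50.0
    seed: int = 0
    outdir: str = "eqtl2drug_out"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**data)


def validate_config(path) -> Tuple[Optional[RunConfig], List[str]]:
    """Parse and validate a config file, collecting every error (not just the first).

    Returns ``(config, errors)``; config is None when parsing itself failed.
    """
    try:
        cfg = RunConfig.from_yaml(path)
    except (ConfigurationError, yaml.YAMLError, OSError, TypeError) as exc:
        return None, [str(exc)]
    errors = validate(cfg)
    return cfg, errors


def validate(cfg: RunConfig) -> List[str]:
    errors: List[str] = []
    if not 0 < cfg.p_threshold < 1:
        errors.append(f"p_threshold must be in (0,1), got {cfg.p_threshold}")
    if not 0 < cfg.q_fraction <= 1:
        errors.append(f"q_fraction must be in (0,1], got {cfg.q_fraction}")
    if not 0 <= cfg.min_ortholog_identity <= 100:
        errors.append(
            f"min_ortholog_identity must be in [0,100], got {cfg.min_ortholog_identity}"
        )
    if not isinstance(cfg.seed, int):
        errors.append(f"seed must be an integer, got {cfg.seed!r}")
    if not cfg.gwas:
        errors.append("gwas input path is required")
    if not cfg.eqtls:
        errors.append("at least one eqtl input path is required")
    if not cfg.interactions:
        errors.append("interactions input path is required")
    for label, p in [
        ("gwas", cfg.gwas),
        ("interactions", cfg.interactions),
        ("annotation", cfg.annotation),
        ("known_genes", cfg.known_genes),
        ("include_pairs", cfg.include_pairs),
        ("orthologs", cfg.orthologs),
        *[("eqtls", p) for p in cfg.eqtls],
    ]:
        if p and not Path(p).exists():
            errors.append(f"{label} file not found: {p}")
    return errors
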