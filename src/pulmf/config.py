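"""Run configuration: every tunable of the pipeline in one dataclass, with
YAML loading and CLI-override precedence (CLI > file > defaults)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

import yaml

from .hetnet import RwrConfig
from .lmf import LmfConfig
from .pu import SpyConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # similarity
    gamma_m_prime: float = 1.0
    gamma_d_prime: float = 1.0
    gamma_fuse: float = 0.9
    # heterogeneous-network walk
    lambda_jump: float = 0.9
    theta: float = 0.5
    eta: float = 0.9
    rwr_tol: float = 1e-11
    rwr_max_iter: int = 10_000
    rwr_mode: str = "disease"
    # PU negative selection
    spy_fraction: float = 0.10
    nmdar: float = 1.0
    pu_repeats: int = 1
    # matrix factorization
    rank: int = 20
    c_weight: float = 8.0
    lambda_m: float = 0.125
    lambda_d: float = 0.125
    alpha: float = 0.25
    knn: int = 5
    learning_rate: float = 0.1
    iters: int = 100
    # global
    seed: int = 0
    threshold: float = 0.5
    _user_set: frozenset = dataclasses.field(default_factory=frozenset, repr=False, compare=False)

    def rwr_config(self) -> RwrConfig:
        return RwrConfig(
            theta=self.theta,
            eta=self.eta,
            tol=self.rwr_tol,
            max_iter=self.rwr_max_iter,
            mode=self.rwr_mode,
        )

    def spy_config(self, seed: int | None = None) -> SpyConfig:
        return SpyConfig(
            spy_fraction=self.spy_fraction,
            nmdar=self.nmdar,
            seed=self.seed if seed is None else seed,
            repeats=self.pu_repeats,
        )

    def lmf_config(self, seed: int | None = None) -> LmfConfig:
        return LmfConfig(
            r=self.rank,
            c=self.c_weight,
            lambda_m=self.lambda_m,
            lambda_d=self.lambda_d,
            alpha=self.alpha,
            K=self.knn,
            learning_rate=self.learning_rate,
            max_iter=self.iters,
            seed=self.seed if seed is None else seed,
        )

    def to_dict(self) -> dict[str, Any]:
        d = {f.name: getattr(self, f.name) for f in fields(self) if not f.name.startswith("_")}
        d["defaulted"] = sorted(set(d) - set(self._user_set))
        return d


def load_config(
    path: str | Path | None = None, overrides: dict[str, Any] | None = None
) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus explicit overrides.

    Unknown keys raise; the set of user-provided keys is recorded so run
    metadata can flag which values fell back to defaults.
    """
    values: dict[str, Any] = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        values.update(loaded)
    for key, val in (overrides or {}).items():
        if val is not None:
            values[key] = val

    valid = {f.name for f in fields(RunConfig) if not f.name.startswith("_")}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values, _user_set=frozenset(values))
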