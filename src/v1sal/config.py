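"""Run configuration: a flat, serializable record of every knob of a
run, loadable from YAML with CLI overrides, hashed for provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to re-execute a run deterministically."""

    # model / training
    variant: str = "invariant"
    patch_side: int = 16
    n_filters: int = 49
    grid_shape: tuple = (7, 7)
    retained_dim: int | None = None
    neighborhood_side: int = 3
    pool_side: int = 3
    overlap: int = 1
    refine_threshold: float = 0.1
    n_patches: int = 20_000
    n_iterations: int = 3000
    batch_size: int = 500
    # suppression
    alpha: float = 1.8
    sigma_ex: float = 2.0
    sigma_unit: str = "rf"
    sigma_ratio: float = 4.0
    boundary: str = "reflect"
    # combination
    combine_strategy: str = "auto"
    combine_iterations: int = 10
    n_clusters: int = 8
    random_group_size: int | None = None
    # bookkeeping
    basis_path: str | None = None
    output_dir: str = "."
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def override(self, **kw) -> "RunConfig":
        d = self.to_dict()
        d.update({k: v for k, v in kw.items() if v is not None})
        return self.from_dict(d)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def build_model(self):
        from .model import SaliencyModel

        return SaliencyModel(
            variant=self.variant,
            patch_side=self.patch_side,
            n_filters=self.n_filters,
            grid_shape=self.grid_shape,
            retained_dim=self.retained_dim,
            neighborhood_side=self.neighborhood_side,
            pool_side=self.pool_side,
            overlap=self.overlap,
            refine_threshold=self.refine_threshold,
            n_patches=self.n_patches,
            n_iterations=self.n_iterations,
            batch_size=self.batch_size,
            alpha=self.alpha,
            sigma_ex=self.sigma_ex,
            sigma_unit=self.sigma_unit,
            sigma_ratio=self.sigma_ratio,
            boundary=self.boundary,
            combine_strategy=self.combine_strategy,
            combine_iterations=self.combine_iterations,
            n_clusters=self.n_clusters,
            random_group_size=self.random_group_size,
            seed=self.seed,
        )
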