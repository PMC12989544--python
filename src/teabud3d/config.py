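"""Pipeline configuration: nested, validated, YAML-round-trippable.

A :class:`PipelineConfig` gathers every tunable of the perception pipeline in
named sections. Unknown keys are rejected at load time, and every run writes
the fully resolved configuration next to its results so it can be re-run to
identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .clustering import ClusteringConfig
from .errors import ConfigurationError
from .picking import PickingConfig
from .stability import StabilityProtocol
from .synthetic import SceneSpec

__all__ = ["FilterConfig", "PipelineConfig"]


@dataclass(frozen=True)
class FilterConfig:
    """Semantic gating and outlier-removal settings.

    ``order`` lists the outlier filters applied after the density-gated
    semantic split; both filters are single-pass. Radius/k defaults are
    engineering choices for the synthetic default scene.
    """

    sigma_min: float = 0.45
    prob_min: float = 0.5
    sor_k: int = 16
    sor_std_ratio: float = 2.0
    ror_radius: float = 0.01
    ror_min_neighbors: int = 4
    order: tuple[str, ...] = ("sor", "ror")

    def __post_init__(self) -> None:
        if set(self.order) - {"sor", "ror"}:
            raise ConfigurationError(f"unknown filter stages in order: {self.order}")


_SECTIONS = {
    "scene": SceneSpec,
    "filtering": FilterConfig,
    "clustering": ClusteringConfig,
    "picking": PickingConfig,
    "stability": StabilityProtocol,
}


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings plus the global seed.

    The global seed fans out to per-stage seeds (scene uses ``seed``, picking
    ``seed + 1000``, stability ``seed + 2000``) so stages stay independently
    reproducible.
    """

    scene: SceneSpec = field(default_factory=SceneSpec)
    filtering: FilterConfig = field(default_factory=FilterConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    picking: PickingConfig = field(default_factory=PickingConfig)
    stability: StabilityProtocol = field(default_factory=StabilityProtocol)
    seed: int = 0
    out_dir: str = "teabud3d_out"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-derive every stage seed from a new global seed."""
        return dataclasses.replace(
            self,
            seed=seed,
            scene=dataclasses.replace(self.scene, seed=seed),
            picking=dataclasses.replace(self.picking, seed=seed + 1000),
            stability=dataclasses.replace(self.stability, seed=seed + 2000),
        )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a nested dict, rejecting unknown keys anywhere."""
        if not isinstance(data, dict):
            raise ConfigurationError("config root must be a mapping")
        top_known = set(_SECTIONS) | {"seed", "out_dir"}
        unknown = set(data) - top_known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for name, section_cls in _SECTIONS.items():
            if name in data:
                sub = data[name] or {}
                if not isinstance(sub, dict):
                    raise ConfigurationError(f"section {name!r} must be a mapping")
                valid = {f.name for f in dataclasses.fields(section_cls)}
                bad = set(sub) - valid
                if bad:
                    raise ConfigurationError(
                        f"unknown keys in section {name!r}: {sorted(bad)}")
                if "order" in sub and name == "filtering":
                    sub = dict(sub, order=tuple(sub["order"]))
                kwargs[name] = section_cls(**sub)
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "out_dir" in data:
            kwargs["out_dir"] = str(data["out_dir"])
        cfg = cls(**kwargs)
        return cfg.with_seed(cfg.seed) if "seed" in data else cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out: dict = {}
        for name, section_cls in _SECTIONS.items():
            sec = dataclasses.asdict(getattr(self, name))
            if name == "filtering":
                sec["order"] = list(sec["order"])
            out[name] = sec
        out["seed"] = self.seed
        out["out_dir"] = self.out_dir
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
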