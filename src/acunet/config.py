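"""Pipeline configuration: defaults, validation, YAML/JSON round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .hubs import HUB_MODES, PAPER2021_SUPPLEMENTARY
from .metrics import ORDER_POLICIES
from .network import PROPORTION_MODES


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the network pipeline and the trial statistics.

    The defaults constitute the ``paper2021`` profile: the shipped
    configuration under which the packaged corpus reproduces the published
    three-community network with hubs CV4, SP6 and SP10 and the eight-point
    prescription.
    """

    # network construction
    proportion_mode: str = "global"
    min_weight: float = 0.0
    backbone_objective: str = "max"   # "min" extracts the literal minimum tree
    # community detection
    gamma: float = 1.0
    use_weights: bool = True
    louvain_order: str = "node-order"
    louvain_seed: int | None = None
    restarts: int = 1
    # hub selection / prescription
    hub_mode: str = "community-center"
    top_k: int = 3
    supplementary: tuple[str, ...] = PAPER2021_SUPPLEMENTARY
    # trial statistics
    exact_threshold: int = 20
    continuity: bool = True
    yates: bool = False

    def __post_init__(self) -> None:
        if self.proportion_mode not in PROPORTION_MODES:
            raise ValidationError(f"proportion_mode must be one of {PROPORTION_MODES}")
        if self.louvain_order not in ORDER_POLICIES:
            raise ValidationError(f"louvain_order must be one of {ORDER_POLICIES}")
        if self.hub_mode not in HUB_MODES:
            raise ValidationError(f"hub_mode must be one of {HUB_MODES}")
        if self.backbone_objective not in ("max", "min"):
            raise ValidationError("backbone_objective must be 'max' or 'min'")
        if self.min_weight < 0:
            raise ValidationError("min_weight must be >= 0")
        if self.restarts < 1:
            raise ValidationError("restarts must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        data["supplementary"] = list(data["supplementary"])
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(data, fh)
            else:
                json.dump(data, fh, indent=2)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        if "supplementary" in data:
            data["supplementary"] = tuple(data["supplementary"])
        return cls(**data)


def paper2021_config() -> PipelineConfig:
    """The shipped default profile (see :class:`PipelineConfig`)."""
    return PipelineConfig()
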