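"""Pipeline configuration with the tuned defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class BDHNSConfig:
    """All tunables of the prediction pipeline.

    Defaults follow the tuned operating point: restart probability 0.1,
    20 walk steps, embedding dimension 64; the jump probability between
    the two sub-networks and the selection threshold default to 0.5 and
    0.0. ``attributes`` chooses the node attribute source for the graph
    convolution: the walk profile (default) or the raw transition
    matrix. ``use_walk=False`` and ``use_selection=False`` are the two
    ablation switches.
    """

    microbe_bandwidth_scale: float = 1.0
    disease_bandwidth_scale: float = 1.0
    semantic_decay: float = 0.5
    jump_phi: float = 0.5
    restart_r: float = 0.1
    walk_steps: int = 20
    early_stop_tol: float | None = None
    gcn_layers: int = 1
    embed_dim: int | None = 64
    projection_seed: int = 13
    select_threshold_m: float = 0.0
    attributes: str = "walk_profile"
    use_walk: bool = True
    use_selection: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.jump_phi < 1:
            raise ValueError("jump_phi must lie in (0, 1)")
        if not 0 < self.restart_r <= 1:
            raise ValueError("restart_r must lie in (0, 1]")
        if not 0 < self.semantic_decay < 1:
            raise ValueError("semantic_decay must lie in (0, 1)")
        if self.attributes not in ("walk_profile", "transition_matrix"):
            raise ValueError(
                "attributes must be 'walk_profile' or 'transition_matrix'"
            )

    def replace(self, **changes) -> "BDHNSConfig":
        return replace(self, **changes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BDHNSConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")
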