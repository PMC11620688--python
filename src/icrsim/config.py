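"""Run configuration: YAML serialization of every model constant.

Defaults are the model constants (two-sphere average cornea, Yeoh
coefficients, 15 mmHg IOP, the 15 x 1200 um slit at 75% depth, 60 kPa
tunnel inflation).  Pressures may be given in kPa or mmHg (converted with
133.322 Pa/mmHg); lengths are mm.  Unknown keys are rejected.  A
configuration hash is embedded in output file headers so results are
traceable to their inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .geometry import CorneaGeometry
from .implantation import ProtocolConfig
from .material import RingMaterial, YeohParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class CampaignBlock:
    diameters: tuple = (5.0, 5.5, 6.0)
    sizes: tuple | None = None        # None = all five
    target_elements: int = 2900
    slit_width: float = 1.2           # mm
    slit_height: float = 0.015        # mm
    depth_fraction: float = 0.75


@dataclass(frozen=True)
class RunConfig:
    geometry: CorneaGeometry = field(default_factory=CorneaGeometry)
    material: YeohParams = field(default_factory=YeohParams)
    ring_material: RingMaterial = field(default_factory=RingMaterial)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    campaign: CampaignBlock = field(default_factory=CampaignBlock)
    seed: int = 0                     # used only by test fixtures
    output_dir: str = "results"
    parallelism: int = 1

    def to_dict(self) -> dict:
        raw = {
            "geometry": asdict(self.geometry),
            "material": asdict(self.material),
            "ring_material": asdict(self.ring_material),
            "protocol": asdict(self.protocol),
            "campaign": asdict(self.campaign),
            "seed": self.seed,
            "output_dir": self.output_dir,
            "parallelism": self.parallelism,
        }
        return json.loads(json.dumps(raw, default=list))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_BLOCKS = {"geometry": CorneaGeometry, "material": YeohParams,
           "ring_material": RingMaterial, "protocol": ProtocolConfig,
           "campaign": CampaignBlock}
_MMHG_KEYS = {"iop_mmhg"}


def _build(cls, data: dict, block: str):
    valid = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        base, unit = key, None
        if key.endswith("_kpa") and key not in valid:
            base, unit = key[:-4], "kpa"
        if key.endswith("_mmhg") and key not in valid:
            base, unit = key[:-5], "mmhg"
        if base not in valid:
            raise ValueError(f"unknown key {key!r} in block {block!r}")
        if unit == "mmhg" and base == "iop_kpa":
            value = value * 133.322e-3
        if isinstance(value, list):
            value = tuple(value)
        kwargs[base] = value
    # mmHg convenience for the protocol IOP given in kPa
    if block == "protocol" and "iop_kpa" in kwargs:
        kwargs["iop_mmhg"] = kwargs.pop("iop_kpa") / 133.322e-3
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; an empty file yields all defaults."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCKS:
            kwargs[key] = _build(_BLOCKS[key], value or {}, key)
        elif key in ("seed", "output_dir", "parallelism"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown top-level key {key!r}")
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=True, default_flow_style=None)
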