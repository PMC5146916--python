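"""Declarative run configuration with YAML round-trip and run manifests."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .protocol import ProtocolConfig

#: explicit unit-system stanza embedded in every config and manifest
UNITS_STANZA = {
    "system": "reduced Lennard-Jones",
    "length": "a = sigma_P (0.3 nm)",
    "energy": "epsilon (2.74e-21 J)",
    "mass": "m (1.6e-25 kg)",
    "k_B": 1,
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: protocol, label, output paths."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    label: str = "run"
    output_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.protocol)
        if d["membrane_cells"] is not None:
            d["membrane_cells"] = list(d["membrane_cells"])
        return {"label": self.label, "output_dir": self.output_dir,
                "units": dict(UNITS_STANZA), "protocol": d}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        proto = dict(data.get("protocol", {}))
        if proto.get("membrane_cells") is not None:
            proto["membrane_cells"] = tuple(proto["membrane_cells"])
        if isinstance(proto.get("tether_k"), str):
            proto["tether_k"] = float(proto["tether_k"])
        known = {f.name for f in dataclasses.fields(ProtocolConfig)}
        unknown = set(proto) - known
        if unknown:
            raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(protocol=ProtocolConfig(**proto),
                   label=data.get("label", "run"),
                   output_dir=data.get("output_dir", "results"))

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def manifest(self, extra: dict | None = None) -> dict:
        """Resolved configuration plus code version; a run is re-executable
        from its manifest alone."""
        from . import __version__
        out = self.to_dict()
        out["code_version"] = __version__
        if extra:
            out.update(extra)
        return out
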