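"""Ground-truth sidecars for synthetic datasets.

Every generator in :mod:`baokit.synthetic_data` returns its dataset together
with a :class:`SimTruth` that records the seed and every planted parameter a
downstream recovery test needs. Truths serialize to a ``<name>.truth.json``
sidecar next to the dataset files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class SimTruth:
    """Planted ground truth for one generator call."""

    generator_name: str
    seed: int
    planted_params: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.planted_params[key]

    def to_dict(self) -> dict:
        return {
            "generator_name": self.generator_name,
            "seed": int(self.seed),
            "planted_params": _jsonable(self.planted_params),
        }

    def write(self, path) -> Path:
        """Write the ``<name>.truth.json`` sidecar and return its path."""
        path = Path(path)
        if not path.name.endswith(".truth.json"):
            path = path.with_name(path.name + ".truth.json")
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return path

    @classmethod
    def read(cls, path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["generator_name"], d["seed"], d["planted_params"])
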