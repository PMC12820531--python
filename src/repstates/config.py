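"""Run configuration: a single TOML file with per-stage sections.

All thresholds default to the study's analysis settings (burst threshold
F = 6x background, 50-photon minima, stoichiometry window 0.2-0.8, 300 s
background segments, BIC' threshold 0.005, 30 ms level filter), so a
default config reproduces the reference pipeline; configs serialise and
reload bit-exactly.
"""

from __future__ import annotations

import tomllib
from copy import deepcopy
from dataclasses import dataclass, field
from pathlib import Path

DEFAULTS: dict = {
    "seed": 1,
    "simulate": {
        "fixture": "low_salt",
        "n_bursts": 500,
        "species_fractions": [0.75, 0.15, 0.10],
    },
    "bursts": {
        "search": "dcbs",  # 'dcbs' or 'apbs'
        "F": 6.0,
        "m": 10,
        "min_size": 50,
        "min_per_channel": 50,
        "min_aa": 50,
        "s_min": 0.2,
        "s_max": 0.8,
        "segment_length_s": 300.0,
    },
    "gmm": {"k_max": 6, "n_restarts": 10},
    "h2mm": {"k_max": 5, "tol": 1e-6, "max_iter": 3600, "bic_prime_threshold": 0.005},
    "trap": {"bin_ms": 1.0, "min_level_ms": 30.0, "alpha": 0.05},
    "decay": {"n_components": 3},
    "avfret": {"r0": 70.0, "grid_spacing": 1.0, "n_samples": 1000000},
}


@dataclass
class RunConfig:
    values: dict = field(default_factory=lambda: deepcopy(DEFAULTS))

    def __getitem__(self, key):
        return self.values[key]

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        vals = deepcopy(DEFAULTS)
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(vals.get(k), dict):
                vals[k].update(v)
            else:
                vals[k] = v
        return cls(values=vals)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(to_toml(self.values))


def to_toml(d: dict) -> str:
    """Minimal TOML emitter for one level of sections with scalar/list values."""
    lines = []
    for k, v in d.items():
        if not isinstance(v, dict):
            lines.append(f"{k} = {_fmt(v)}")
    for k, v in d.items():
        if isinstance(v, dict):
            lines.append(f"\n[{k}]")
            for kk, vv in v.items():
                lines.append(f"{kk} = {_fmt(vv)}")
    return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)}")
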