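"""Run configuration and the plain key-value config format."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    """Pipeline defaults: the scoring weight, cutoffs and run mode.

    ``w`` up-weights true template ligands in the mTC score;
    ``mtc_cutoff`` flags predicted interactions; the identity and TC
    cutoffs drive benchmark-mode exclusions.
    """

    w: float = 0.1
    mtc_cutoff: float = 0.90
    seq_identity_cutoff: float = 95.0
    ligand_tc_cutoff: float = 0.99
    ef_fractions: tuple[float, ...] = (0.01, 0.05, 0.1)
    serious_list_path: str | None = None
    seed: int = 0
    mode: str = "predict"

    def __post_init__(self) -> None:
        if self.mode not in ("predict", "benchmark"):
            raise ValueError("mode must be 'predict' or 'benchmark'")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")

    @property
    def benchmark(self) -> bool:
        return self.mode == "benchmark"

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_FIELD_TYPES = {
    "w": float,
    "mtc_cutoff": float,
    "seq_identity_cutoff": float,
    "ligand_tc_cutoff": float,
    "seed": int,
    "mode": str,
    "serious_list_path": str,
}


def load_config(path) -> RunConfig:
    """Parse a `key = value` config file (one pair per line, # comments)."""
    cfg = RunConfig()
    updates = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key == "ef_fractions":
            updates[key] = tuple(float(v) for v in raw.split(","))
        elif key in _FIELD_TYPES:
            updates[key] = _FIELD_TYPES[key](raw)
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    return replace(cfg, **updates)
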