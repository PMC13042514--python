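"""Pipeline configuration and provenance.

All decision thresholds live here with their study defaults: half-life fold
1.5, TE fold 1.5 with p < 0.05, delta-Psi 0.1 with FDR < 0.05, GLORI rate
0.1, exon-to-m6A window 10 kb, and the TRIBE gates (5-99% rate, 1.5x control,
>= 2 mutations). Every run writes a resolved copy of its configuration next
to the outputs, stamped with the package version, a config hash, and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import yaml

__version__ = "0.1.0"

log = logging.getLogger("reading_m6a")


@dataclass
class PipelineConfig:
    seed: int
    cell_type: str = "synthetic"
    # thresholds (study defaults)
    hl_fold: float = 1.5
    te_fold: float = 1.5
    te_p: float = 0.05
    dpsi_min: float = 0.1
    psi_fdr: float = 0.05
    glori_rate_min: float = 0.1
    exon_m6a_window: int = 10_000
    tribe_rate_min: float = 0.05
    tribe_rate_max: float = 0.99
    tribe_control_ratio: float = 1.5
    tribe_min_mutations: int = 2
    # inputs (optional: the synthetic generator fills anything missing)
    paths: dict = field(default_factory=dict)
    # simulation overrides forwarded to SimulationConfig
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in payload:
            raise ValueError("config requires a seed")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance_header(self) -> str:
        return (f"# reading-m6a v{__version__} config={self.config_hash} "
                f"seed={self.seed}\n")

    def write_resolved(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.provenance_header())
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
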