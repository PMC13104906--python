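"""Run configuration: resolutions, thresholds, seeds, output location.

Serialized verbatim into every output bundle's metadata so a run is a pure
function of (input files, config, seeds).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    scab_binsize: int = 1_000_000
    eig_binsize: int = 100_000
    insulation_binsize: int = 25_000
    insulation_window: int = 250_000
    diffmap_binsize: int = 1_000_000
    apa_binsize: int = 50_000
    apa_half_window: int = 5
    saddle_quantile: float = 0.2
    scab_min_separation: int = 3_000_000
    scab_min_support: int = 10
    boundary_threshold: float = -0.2
    min_contacts_qc: int = 10_000
    equalize_depth: bool = True
    pseudocount_cpm: float = 0.5
    fdr: float = 0.05
    n_modes: int = 5
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        if not (0 < self.saddle_quantile < 0.5):
            raise ValueError("saddle_quantile must lie in (0, 0.5)")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if self.insulation_window % self.insulation_binsize:
            raise ValueError("insulation window must be a multiple of its bin size")
        if self.pseudocount_cpm <= 0:
            raise ValueError("pseudocount must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
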