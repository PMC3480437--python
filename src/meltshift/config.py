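"""Analysis thresholds, in one place and configurable.

The underlying publication-style judgements ("a noticeable Tm increase",
"two peaks", "specific to the kinase") are made explicit here so every
call in the pipeline is reproducible.  Temperatures are °C.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class AnalysisConfig:
    #: minimum |ΔTm| for a shift to count as detected
    theta_detect: float = 0.5
    #: minimum ΔTm on every target for a screen hit
    hit_threshold: float = 3.0
    #: minimum target-transition shift for a "specific" fusion-control call
    #: (defaults to the hit threshold)
    theta_specific: float = 3.0
    #: maximum tag-transition movement tolerated for a specific call
    theta_tolerance: float = 1.0
    #: minimum separation between two fitted transitions
    min_separation: float = 4.0
    #: R² gate for two_state / biphasic classification
    r2_gate: float = 0.99
    #: minimum transition amplitude relative to the trace maximum
    rel_amplitude_gate: float = 0.2
    #: BIC margin required to accept the two-transition model
    delta_bic: float = 10.0
    #: each transition must carry this fraction of the total amplitude
    amp_fraction_gate: float = 0.15
    #: fitted Tm closer than this to the window edge is flagged boundary_tm
    boundary_margin: float = 2.0
    #: window for assigning a transition to a component reference Tm
    assign_window: float = 2.0
    #: complex Tm must exceed both component references by this margin
    coop_margin: float = 1.0
    #: ligand Tms within this of each other rank as tied
    tie_tol: float = 0.1
    #: max sd of Tm across a concentration series to call Tm conc-independent
    tm_spread_tol: float = 0.3
    #: aggregation attenuation rate used by the decay-aware fit models (1/°C);
    #: held fixed during fitting — freeing it creates a flat k-Tm ridge
    decay_rate: float = 0.08
    #: aggregation onset past a transition midpoint in the fit models (°C)
    decay_onset: float = 6.0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be > 0, got {value}")

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash embedded in output artifacts."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


DEFAULT_CONFIG = AnalysisConfig()
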