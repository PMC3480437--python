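"""Core containers for melt-curve data.

A :class:`MeltCurve` is one well's temperature/fluorescence trace together
with its experimental condition; it is the currency passed between every
stage of the pipeline.  Conditions are hashable so replicate grouping can
partition curves by exact condition identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

#: tolerance for the uniform-temperature-step invariant, in °C
STEP_TOL = 1e-6


class MeltCurveError(ValueError):
    """Raised when a curve violates a structural invariant."""


def _as_pairs(items) -> Tuple[Tuple[str, float], ...]:
    out = []
    for name, conc in items or ():
        conc = float(conc)
        if conc < 0:
            raise MeltCurveError(f"negative concentration for {name!r}: {conc}")
        out.append((str(name), conc))
    return tuple(out)


@dataclass(frozen=True)
class ConditionMeta:
    """What is in the well: proteins/ligands in µM, additives in mM.

    ``tag_fusion`` marks a fusion construct as ``(tag_name, target_name)``,
    e.g. ``("MBP", "SnRK2.3")`` for an MBP-tagged kinase used as an internal
    specificity control.
    """

    proteins: Tuple[Tuple[str, float], ...] = ()
    ligands: Tuple[Tuple[str, float], ...] = ()
    additives: Tuple[Tuple[str, float], ...] = ()
    tag_fusion: Optional[Tuple[str, str]] = None

    def __post_init__(self):
        object.__setattr__(self, "proteins", _as_pairs(self.proteins))
        object.__setattr__(self, "ligands", _as_pairs(self.ligands))
        object.__setattr__(self, "additives", _as_pairs(self.additives))
        if self.tag_fusion is not None:
            object.__setattr__(self, "tag_fusion", tuple(self.tag_fusion))

    def to_dict(self) -> dict:
        return {
            "proteins": [list(p) for p in self.proteins],
            "ligands": [list(p) for p in self.ligands],
            "additives": [list(p) for p in self.additives],
            "tag_fusion": list(self.tag_fusion) if self.tag_fusion else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionMeta":
        return cls(
            proteins=tuple((str(n), float(c)) for n, c in d.get("proteins", ()) or ()),
            ligands=tuple((str(n), float(c)) for n, c in d.get("ligands", ()) or ()),
            additives=tuple((str(n), float(c)) for n, c in d.get("additives", ()) or ()),
            tag_fusion=tuple(d["tag_fusion"]) if d.get("tag_fusion") else None,
        )


@dataclass
class MeltCurve:
    """One well's melt trace: temperatures (°C) vs fluorescence (a.u.)."""

    sample_id: str
    well: str
    replicate: int
    temperatures: np.ndarray
    fluorescence: np.ndarray
    condition: ConditionMeta = field(default_factory=ConditionMeta)

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.replicate < 1:
            raise MeltCurveError(f"replicate index must be >= 1, got {self.replicate}")
        if self.temperatures.ndim != 1 or self.temperatures.size < 2:
            raise MeltCurveError("temperatures must be a 1-d array with >= 2 points")
        if self.fluorescence.shape != self.temperatures.shape:
            raise MeltCurveError(
                f"length mismatch in well {self.well}: "
                f"{self.fluorescence.size} fluorescence vs {self.temperatures.size} temperatures"
            )
        steps = np.diff(self.temperatures)
        if np.any(steps <= 0):
            raise MeltCurveError(f"temperatures not strictly increasing in well {self.well}")
        if np.max(np.abs(steps - steps[0])) > STEP_TOL:
            raise MeltCurveError(f"non-uniform temperature step in well {self.well}")
        if not np.all(np.isfinite(self.fluorescence)):
            i = int(np.argmax(~np.isfinite(self.fluorescence)))
            raise MeltCurveError(
                f"non-finite fluorescence in well {self.well} "
                f"at {self.temperatures[i]:g} °C"
            )
        if np.any(self.fluorescence < 0):
            raise MeltCurveError(f"negative fluorescence in well {self.well}")

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])

    def __len__(self) -> int:
        return int(self.temperatures.size)

    def window(self, stop: int) -> "MeltCurve":
        """Return a copy truncated to the first ``stop`` points."""
        return replace(
            self,
            temperatures=self.temperatures[:stop].copy(),
            fluorescence=self.fluorescence[:stop].copy(),
        )

    def values_equal(self, other: "MeltCurve") -> bool:
        return (
            self.sample_id == other.sample_id
            and self.well == other.well
            and self.replicate == other.replicate
            and np.array_equal(self.temperatures, other.temperatures)
            and np.array_equal(self.fluorescence, other.fluorescence)
            and self.condition == other.condition
        )
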