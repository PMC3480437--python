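"""Read/write melt-curve CSVs and plate-layout configs; group replicates.

Two CSV dialects are supported (comma-separated, header row, UTF-8,
"." decimal, temperatures in °C):

* long:  ``well,temperature_C,fluorescence`` — one row per (well, T)
* wide:  ``temperature_C,<well>,<well>,...`` — one fluorescence column per well

A layout config (YAML or an equivalent in-memory mapping) assigns each well
its :class:`~meltshift.curves.ConditionMeta`::

    wells:
      A1: {sample_id: PYL1_apo, replicate: 1,
           proteins: [[PYL1, 10.0]], ligands: [], additives: []}

Wells present in the CSV but absent from the layout are skipped with a
logged warning.  Duplicate (well, temperature) rows are an error — they
surface instrument-export faults and are never averaged away.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .curves import ConditionMeta, MeltCurve

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("well", "temperature_C", "fluorescence")


class PlateFormatError(ValueError):
    """CSV does not conform to either supported dialect."""


class PlateDataError(ValueError):
    """CSV parses but the data violate an invariant (NA, duplicates, ...)."""


def load_layout(layout: Union[str, Path, Mapping]) -> Dict[str, dict]:
    """Return the per-well layout mapping from a YAML path or a mapping."""
    if isinstance(layout, (str, Path)):
        with open(layout, "r", encoding="utf-8") as fh:
            layout = yaml.safe_load(fh)
    if not isinstance(layout, Mapping) or "wells" not in layout:
        raise PlateFormatError("layout must be a mapping with a 'wells' section")
    return {str(w): dict(entry or {}) for w, entry in layout["wells"].items()}


def _condition_from_entry(entry: Mapping) -> ConditionMeta:
    return ConditionMeta.from_dict(dict(entry))


def _well_sort_key(well: str):
    # A10 sorts after A2: split the leading row letters from the column number
    i = 0
    while i < len(well) and not well[i].isdigit():
        i += 1
    try:
        return (well[:i], int(well[i:] or 0))
    except ValueError:
        return (well, 0)


def read_plate_csv(
    path: Union[str, Path], layout: Union[str, Path, Mapping]
) -> List[MeltCurve]:
    """Parse a long- or wide-format plate export into MeltCurves.

    Returns one curve per well found in both the CSV and the layout, rows
    sorted by temperature.  Replicate indices come from the layout, or are
    assigned per condition by well sort order when absent.
    """
    wells_layout = load_layout(layout)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise PlateDataError(f"no curves parsed from {path}")
    cols = list(df.columns)

    per_well: Dict[str, pd.DataFrame] = {}
    if set(LONG_COLUMNS).issubset(cols):
        for well, sub in df.groupby("well", sort=False):
            per_well[str(well)] = sub[["temperature_C", "fluorescence"]]
    elif "temperature_C" in cols and len(cols) >= 2:
        for well in cols:
            if well == "temperature_C":
                continue
            per_well[str(well)] = df[["temperature_C", well]].rename(
                columns={well: "fluorescence"}
            )
    else:
        raise PlateFormatError(
            f"{path}: expected columns {LONG_COLUMNS} (long) or "
            "'temperature_C' plus one column per well (wide); got "
            f"{cols}"
        )

    curves: List[MeltCurve] = []
    pending: List[tuple] = []
    for well in sorted(per_well, key=_well_sort_key):
        if well not in wells_layout:
            logger.warning("well %s not in layout; skipped", well)
            continue
        sub = per_well[well].sort_values("temperature_C")
        temps = sub["temperature_C"].to_numpy(dtype=float)
        fluo = sub["fluorescence"].to_numpy(dtype=float)
        if np.any(~np.isfinite(fluo)):
            i = int(np.argmax(~np.isfinite(fluo)))
            raise PlateDataError(
                f"missing/non-numeric fluorescence in well {well} at {temps[i]:g} °C"
            )
        dup = pd.Index(temps).duplicated()
        if dup.any():
            t = temps[np.argmax(dup)]
            raise PlateDataError(f"duplicate (well, temperature) row: well {well}, {t:g} °C")
        entry = wells_layout[well]
        pending.append((well, entry, temps, fluo))

    # replicate assignment: explicit index wins; otherwise enumerate wells of
    # the same condition in well sort order (deterministic)
    counters: Dict[ConditionMeta, int] = defaultdict(int)
    for well, entry, temps, fluo in pending:
        cond = _condition_from_entry(entry)
        if entry.get("replicate") is not None:
            rep = int(entry["replicate"])
        else:
            counters[cond] += 1
            rep = counters[cond]
        curves.append(
            MeltCurve(
                sample_id=str(entry.get("sample_id", well)),
                well=well,
                replicate=rep,
                temperatures=temps,
                fluorescence=fluo,
                condition=cond,
            )
        )
    return curves


def write_curves(curves: Sequence[MeltCurve], path: Union[str, Path]) -> Path:
    """Write curves as a long-format CSV (lossless float round-trip)."""
    if not curves:
        raise ValueError("write_curves: empty curve list")
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "well": c.well,
                    "temperature_C": c.temperatures,
                    "fluorescence": c.fluorescence,
                }
            )
        )
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def layout_from_curves(curves: Sequence[MeltCurve]) -> dict:
    """Build the layout mapping that reproduces ``curves`` on re-read."""
    wells = {}
    for c in curves:
        wells[c.well] = {
            "sample_id": c.sample_id,
            "replicate": int(c.replicate),
            **c.condition.to_dict(),
        }
    return {"wells": wells}


def write_layout(curves: Sequence[MeltCurve], path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(layout_from_curves(curves), fh, sort_keys=True)
    return path


@dataclass
class ReplicateGroup:
    condition: ConditionMeta
    curves: List[MeltCurve]

    @property
    def n(self) -> int:
        return len(self.curves)

    @property
    def sample_ids(self) -> List[str]:
        return [c.sample_id for c in self.curves]


def group_replicates(curves: Sequence[MeltCurve]) -> List[ReplicateGroup]:
    """Partition curves by identical ConditionMeta (insertion order kept)."""
    by_cond: Dict[ConditionMeta, List[MeltCurve]] = {}
    for c in curves:
        by_cond.setdefault(c.condition, []).append(c)
    return [ReplicateGroup(cond, cs) for cond, cs in by_cond.items()]
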