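"""Inhibitor-screen hit calling, ranking, and fusion-tag specificity.

A compound is a *hit* only if it raises the Tm of **every** target protein
by at least the hit threshold (3 °C default) — the all-targets rule that
separates genuine pan-kinase stabilizers from single-target or spurious
effects.  Hits are ranked by their minimum shift across targets: for
ligands with comparable binding enthalpies (protein-kinase inhibitors
typically), ΔTm tracks affinity, so the ranking is an affinity/potency
proxy — not an IC50 prediction.

The fusion-tag internal control: a tag-target fusion melts in two
transitions, one per module.  A specific binder moves only the target
transition; salts or fluorescence artifacts move both; a very strong
stabilizer can push the target transition into the tag's, merging the two
peaks — still classifiable because the merged Tm sits at the tag
transition while far above the target reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .fitting import BIPHASIC, MERGED, MeltFitResult
from .shifts import ShiftResult, delta_tm_biphasic

SPECIFIC = "specific"
SPECIFIC_MERGED = "specific_merged"
NONSPECIFIC_STABILIZER = "nonspecific_stabilizer"
NONSPECIFIC_DESTABILIZER = "nonspecific_destabilizer"
NO_EFFECT = "no_effect"
INDETERMINATE = "indeterminate"


class FusionControlError(ValueError):
    """The apo fusion profile cannot serve as an internal control."""


@dataclass
class CompoundCall:
    compound: str
    shifts: Dict[str, Optional[ShiftResult]]
    hit: bool
    rank_key: float  # minimum ΔTm across targets, °C
    specificity: str = INDETERMINATE

    def shift_means(self) -> Dict[str, Optional[float]]:
        return {
            k: (v.delta_tm_mean if v is not None else None)
            for k, v in self.shifts.items()
        }


def call_hits(
    screen: Dict[str, Dict[str, Optional[ShiftResult]]],
    threshold: Optional[float] = None,
    targets: Optional[Sequence[str]] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> List[CompoundCall]:
    """Apply the all-targets hit rule to a screen's ΔTm table.

    ``screen`` maps compound → target protein → ShiftResult (None for a
    missing measurement, which makes the compound indeterminate and
    excludes it from the hit list).  Returns calls ranked by rank_key
    descending, ties broken by compound id.
    """
    thr = config.hit_threshold if threshold is None else float(threshold)
    if targets is None:
        targets = sorted({t for row in screen.values() for t in row})
    calls = []
    for compound in sorted(screen):
        row = screen[compound]
        missing = [t for t in targets if row.get(t) is None]
        if missing:
            calls.append(
                CompoundCall(
                    compound=compound,
                    shifts={t: row.get(t) for t in targets},
                    hit=False,
                    rank_key=float("-inf"),
                    specificity=INDETERMINATE,
                )
            )
            continue
        means = {t: row[t].delta_tm_mean for t in targets}
        rank_key = min(means.values())
        calls.append(
            CompoundCall(
                compound=compound,
                shifts={t: row[t] for t in targets},
                hit=bool(rank_key >= thr),
                rank_key=rank_key,
            )
        )
    calls.sort(key=lambda c: (-c.rank_key, c.compound))
    return calls


def rank_by_affinity_proxy(calls: Sequence[CompoundCall]) -> List[CompoundCall]:
    """Descending by minimum shift across targets; id order breaks ties."""
    return sorted(calls, key=lambda c: (-c.rank_key, c.compound))


def _fusion_component_tms(
    fits: Sequence[MeltFitResult],
    target_ref_tm: float,
    tag_ref_tm: float,
    window: float,
) -> Tuple[float, float]:
    """Mean (target, tag) transition Tms of biphasic fusion fits."""
    target_tms, tag_tms = [], []
    for f in fits:
        lo, hi = f.transitions[0].tm, f.transitions[1].tm
        # target and tag are ordered like their references
        if target_ref_tm < tag_ref_tm:
            t_tm, g_tm = lo, hi
        else:
            t_tm, g_tm = hi, lo
        target_tms.append(t_tm)
        tag_tms.append(g_tm)
    return float(np.mean(target_tms)), float(np.mean(tag_tms))


def fusion_control_classify(
    fusion_apo: Sequence[MeltFitResult],
    fusion_cond: Sequence[MeltFitResult],
    refs: Tuple[float, float],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> str:
    """Classify a condition's effect using the fusion's two transitions.

    ``refs`` is (target reference Tm, tag reference Tm) from the untagged
    proteins.  The apo fusion must be biphasic with transitions assignable
    to (target, tag); shifts are computed per transition against the apo
    fusion.  Decision rules (thresholds from the config):

    * specific — target moves ≥ θ_specific, tag stays within θ_tolerance
    * specific_merged — the condition collapses to a single transition
      (merged_transitions flag) sitting within θ_tolerance above the tag
      reference but ≥ θ_specific above the target reference
    * nonspecific_stabilizer / _destabilizer — both transitions move
      ≥ θ_tolerance in the same direction
    * no_effect — both transitions stay within θ_tolerance
    * indeterminate — anything else
    """
    target_ref, tag_ref = refs
    apo_bi = [f for f in fusion_apo if f.n_transitions == 2 and f.classification == BIPHASIC]
    if len(apo_bi) <= len(fusion_apo) / 2:
        raise FusionControlError(
            "apo fusion profile is not biphasic; internal control unusable"
        )
    apo_target, apo_tag = _fusion_component_tms(
        apo_bi, target_ref, tag_ref, config.assign_window
    )
    for tm, ref, label in ((apo_target, target_ref, "target"), (apo_tag, tag_ref, "tag")):
        if abs(tm - ref) > config.assign_window:
            raise FusionControlError(
                f"apo fusion {label} transition ({tm:.2f} °C) does not match "
                f"its reference ({ref:.2f} °C)"
            )

    cond_bi = [f for f in fusion_cond if f.n_transitions == 2 and f.classification == BIPHASIC]
    if len(cond_bi) > len(fusion_cond) / 2:
        cond_target, cond_tag = _fusion_component_tms(
            cond_bi, target_ref, tag_ref, config.assign_window
        )
        target_shift = cond_target - apo_target
        tag_shift = cond_tag - apo_tag
        theta_s = config.theta_specific
        theta_t = config.theta_tolerance
        if abs(target_shift) >= theta_s and abs(tag_shift) < theta_t:
            return SPECIFIC
        if (
            abs(target_shift) >= theta_t
            and abs(tag_shift) >= theta_t
            and np.sign(target_shift) == np.sign(tag_shift)
        ):
            return NONSPECIFIC_STABILIZER if target_shift > 0 else NONSPECIFIC_DESTABILIZER
        if abs(target_shift) < theta_t and abs(tag_shift) < theta_t:
            return NO_EFFECT
        return INDETERMINATE

    # condition collapsed to one transition: merged-peak logic
    singles = [f for f in fusion_cond if f.n_transitions == 1]
    if singles and any(MERGED in f.flags for f in singles):
        tm_single = float(np.mean([f.tm for f in singles]))
        if (
            tm_single - tag_ref < config.theta_tolerance
            and tm_single - target_ref >= config.theta_specific
        ):
            return SPECIFIC_MERGED
    return INDETERMINATE
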