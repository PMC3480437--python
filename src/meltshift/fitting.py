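"""Boltzmann melt-curve fitting and curve classification.

Single-transition Tm estimation uses the standard DSF Boltzmann sigmoid

    F(T) = LL + (UL − LL) / (1 + exp((Tm − T)/a))

with flat plateaus, fitted by least squares over the window that ends at
the global fluorescence maximum — the classic protocol, in which the
post-peak aggregation decline is discarded rather than modelled.

Deciding whether a profile is monophasic or biphasic needs the rest of
the trace: in a mixture, the second species' transition can ride on the
first species' aggregation decline as a peak or a mere shoulder, and a
model truncated at the first apex never sees it.  Model comparison is
therefore done on the *full* trace with decay-aware variants in which
every transition's contribution is attenuated past its own apex,

    F(T) = LL + Σ_i A_i · sig(Tm_i, a_i) · exp(−k·max(0, T − Tm_i − onset)),

one or two transitions, shared decay rate k.  The 1-vs-2 choice is by BIC
with explicit gates: the extra transition must earn a BIC improvement of
at least ``delta_bic``, carry at least ``amp_fraction_gate`` of the total
amplitude, and be separated by at least ``min_separation``.

Quality control mirrors standard DSF practice: a curve counts as a clean
two-state transition only if the fit converged with R² above the gate
(0.99 default), the amplitude is a substantial fraction of the signal,
the midpoint is away from the window edges, and the initial fluorescence
is not anomalously high.

``MeltCurveModel`` / ``MeltFitResult`` are the object API;
:func:`preprocess`, :func:`fit_boltzmann`, :func:`fit_two_transitions`,
:func:`classify_curve` and :func:`tm_from_derivative` are the equivalent
functional surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from lmfit import Model, Parameters

from .config import AnalysisConfig, DEFAULT_CONFIG
from .curves import MeltCurve

logger = logging.getLogger(__name__)

# classification labels
TWO_STATE = "two_state"
BIPHASIC = "biphasic"
NON_TWO_STATE = "non_two_state"

# flags
HIGH_INITIAL = "high_initial_fluorescence"
BOUNDARY_TM = "boundary_tm"
MERGED = "merged_transitions"

#: aggregation sets in this far past a transition's midpoint (°C)
DECAY_ONSET = 6.0


class DegenerateCurveError(ValueError):
    """Too few points remain after preprocessing to fit anything."""


def _sigmoid(t, tm, a):
    return 1.0 / (1.0 + np.exp(np.clip((tm - t) / a, -500.0, 500.0)))


def _decay(t, tm, k, onset=DECAY_ONSET):
    return np.exp(-k * np.maximum(0.0, t - tm - onset))


def _boltzmann(t, ll, amp, tm, a):
    return ll + amp * _sigmoid(t, tm, a)


def _single_decay(t, ll, amp, tm, a, k, onset):
    # the folded-state baseline ll belongs to the native protein and
    # disappears across the transition; the unfolded signal then decays
    # as aggregation buries the exposed hydrophobic surface
    s = _sigmoid(t, tm, a)
    return ll * (1.0 - s) + (ll + amp) * s * _decay(t, tm, k, onset)


def _double_decay(t, ll, a1, tm1, s1, a2, sep, s2, k, onset):
    # per-transition native floors, split in proportion to amplitude
    tm2 = tm1 + sep
    total = a1 + a2 + 1e-300
    s_1, s_2 = _sigmoid(t, tm1, s1), _sigmoid(t, tm2, s2)
    ll1, ll2 = ll * a1 / total, ll * a2 / total
    return (
        ll1 * (1.0 - s_1) + (ll1 + a1) * s_1 * _decay(t, tm1, k, onset)
        + ll2 * (1.0 - s_2) + (ll2 + a2) * s_2 * _decay(t, tm2, k, onset)
    )


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average with edge replication (deterministic)."""
    padded = np.concatenate([y[:1], y, y[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def preprocess(
    curve: MeltCurve, config: AnalysisConfig = DEFAULT_CONFIG
) -> Tuple[MeltCurve, Set[str]]:
    """Truncate at the global fluorescence maximum; flag odd baselines.

    Fluorescence values are never altered — only the window shrinks.
    Flags ``high_initial_fluorescence`` when the first point exceeds half
    the trace maximum (apo curves without a proper folded baseline).
    """
    if len(curve) < 10:
        raise DegenerateCurveError(
            f"{curve.sample_id}: need >= 10 points, got {len(curve)}"
        )
    f = curve.fluorescence
    stop = int(np.argmax(f)) + 1
    if stop < 8:
        raise DegenerateCurveError(
            f"{curve.sample_id}: only {stop} points before the fluorescence maximum"
        )
    flags: Set[str] = set()
    if f[0] > 0.5 * f.max():
        flags.add(HIGH_INITIAL)
    return curve.window(stop), flags


def tm_from_derivative(curve: MeltCurve) -> float:
    """Temperature of the max of dF/dT after 3-point smoothing (°C)."""
    f = _smooth3(curve.fluorescence)
    d = np.gradient(f, curve.temperatures)
    if np.ptp(curve.fluorescence) <= 1e-12:
        logger.warning("%s: flat trace; derivative Tm is the grid argmax", curve.sample_id)
    return float(curve.temperatures[int(np.argmax(d))])


def _derivative_peaks(curve: MeltCurve, min_sep: float) -> List[float]:
    """Local maxima of the smoothed derivative, strongest first."""
    f = _smooth3(curve.fluorescence)
    d = np.gradient(f, curve.temperatures)
    t = curve.temperatures
    idx = [i for i in range(1, len(d) - 1) if d[i] >= d[i - 1] and d[i] >= d[i + 1]]
    idx.sort(key=lambda i: -d[i])
    peaks: List[float] = []
    for i in idx:
        if all(abs(t[i] - p) >= min_sep for p in peaks):
            peaks.append(float(t[i]))
    return peaks


@dataclass
class TransitionParams:
    tm: float
    slope_a: float
    amplitude: float
    tm_stderr: Optional[float] = None


@dataclass
class MeltFitResult:
    """Result of a single- or two-transition melt-curve fit.

    ``transitions`` is sorted by Tm.  ``ll``/``ul`` are the lower plateau
    and the total un-attenuated upper level of the model; ``r_squared``
    is computed on the fitted window only.  ``classification`` is one of
    ``two_state``, ``biphasic``, ``non_two_state``.
    """

    sample_id: str
    n_transitions: int
    transitions: List[TransitionParams]
    ll: float
    ul: float
    r_squared: float
    fit_window: Tuple[float, float]
    converged: bool
    bic: float
    n_points: int
    flags: Set[str] = field(default_factory=set)
    classification: str = NON_TWO_STATE
    curve: Optional[MeltCurve] = None

    @property
    def tm(self) -> float:
        """Midpoint of the (single) transition; first transition if two."""
        return self.transitions[0].tm

    @property
    def tms(self) -> List[float]:
        return [tr.tm for tr in self.transitions]

    @property
    def amplitude(self) -> float:
        return self.ul - self.ll

    def summary(self) -> str:
        lines = [
            f"Melt-curve fit: {self.sample_id}",
            f"  model:          {self.n_transitions}-transition Boltzmann",
            f"  window:         {self.fit_window[0]:.1f}-{self.fit_window[1]:.1f} °C"
            f" ({self.n_points} pts)",
            f"  classification: {self.classification}",
            f"  R²:             {self.r_squared:.5f}",
            f"  flags:          {sorted(self.flags) or '-'}",
        ]
        for k, tr in enumerate(self.transitions, 1):
            se = f" ± {tr.tm_stderr:.3f}" if tr.tm_stderr is not None else ""
            lines.append(
                f"  Tm{k}: {tr.tm:.2f}{se} °C   slope a: {tr.slope_a:.2f} °C"
                f"   amplitude: {tr.amplitude:.3g}"
            )
        return "\n".join(lines)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def _bic(y: np.ndarray, yhat: np.ndarray, k: int) -> float:
    n = y.size
    ssr = max(float(np.sum((y - yhat) ** 2)), 1e-300)
    return n * np.log(ssr / n) + k * np.log(n)


class MeltCurveModel:
    """Model object wrapping one melt curve.

    ``fit(n_transitions=1)`` runs the classic truncated-window Boltzmann
    fit (the precise Tm estimator).  ``fit()`` additionally compares the
    one- and two-transition decay-aware models on the full trace and
    returns the selected model.

    Parameters
    ----------
    curve : MeltCurve
        Raw trace; preprocessing (window truncation, baseline flags) runs
        in the constructor unless ``preprocessed=True``.
    config : AnalysisConfig
        Thresholds (R² gate, min transition separation, BIC margin, ...).
    """

    def __init__(
        self,
        curve: MeltCurve,
        config: AnalysisConfig = DEFAULT_CONFIG,
        preprocessed: bool = False,
    ):
        self.config = config
        self.full = curve
        if preprocessed:
            self.windowed, self.flags = curve, set()
        else:
            self.windowed, self.flags = preprocess(curve, config)

    # -- shared machinery --------------------------------------------------
    def _edge_flags(self, tms: Sequence[float], t: np.ndarray) -> Set[str]:
        flags = set(self.flags)
        if min(min(tm - t[0], t[-1] - tm) for tm in tms) < self.config.boundary_margin:
            flags.add(BOUNDARY_TM)
        return flags

    def _failed_result(self, n_transitions: int, curve: MeltCurve) -> MeltFitResult:
        t, f = curve.temperatures, curve.fluorescence
        return MeltFitResult(
            sample_id=curve.sample_id,
            n_transitions=n_transitions,
            transitions=[TransitionParams(tm=float(np.mean(t)), slope_a=1.0, amplitude=0.0)],
            ll=float(f.mean()),
            ul=float(f.mean()),
            r_squared=0.0,
            fit_window=(float(t[0]), float(t[-1])),
            converged=False,
            bic=np.inf,
            n_points=t.size,
            flags=set(self.flags),
            curve=curve,
        )

    def _baseline_inits(self, f: np.ndarray) -> Tuple[float, float]:
        dec = max(f.size // 10, 1)
        srt = np.sort(f)
        return float(srt[:dec].mean()), float(srt[-dec:].mean())

    def _windowed_r2(self, yhat: np.ndarray) -> float:
        """R² of a full-trace fit evaluated over the protocol window only.

        Quality control in DSF is defined on the pre-aggregation window;
        the decay tail (where baseline idiosyncrasies accumulate) informs
        the fit but not the quality gate.
        """
        n = len(self.windowed)
        return _r_squared(self.full.fluorescence[:n], yhat[:n])

    # -- single transition, plain Boltzmann on the truncated window --------
    def _fit_single_plain(self) -> MeltFitResult:
        curve = self.windowed
        t, f = curve.temperatures, curve.fluorescence
        ll0, ul0 = self._baseline_inits(f)
        model = Model(_boltzmann)
        p = Parameters()
        p.add("ll", value=ll0)
        p.add("amp", value=max(ul0 - ll0, 1e-9), min=0.0)
        p.add("tm", value=tm_from_derivative(curve), min=t[0] - 5.0, max=t[-1] + 5.0)
        p.add("a", value=2.0, min=0.05, max=8.0)
        try:
            res = model.fit(f, p, t=t)
        except Exception as exc:  # pragma: no cover - lmfit rarely raises here
            logger.warning("%s: Boltzmann fit failed: %s", curve.sample_id, exc)
            return self._failed_result(1, curve)
        tm = float(res.params["tm"].value)
        stderr = res.params["tm"].stderr
        return MeltFitResult(
            sample_id=curve.sample_id,
            n_transitions=1,
            transitions=[
                TransitionParams(
                    tm=tm,
                    slope_a=float(res.params["a"].value),
                    amplitude=float(res.params["amp"].value),
                    tm_stderr=float(stderr) if stderr is not None else None,
                )
            ],
            ll=float(res.params["ll"].value),
            ul=float(res.params["ll"].value + res.params["amp"].value),
            r_squared=_r_squared(f, res.best_fit),
            fit_window=(float(t[0]), float(t[-1])),
            converged=bool(res.success),
            bic=_bic(f, res.best_fit, 4),
            n_points=t.size,
            flags=self._edge_flags([tm], t),
            curve=curve,
        )

    # -- single transition with decay, full trace --------------------------
    def _fit_single_decay(self) -> MeltFitResult:
        curve = self.full
        t, f = curve.temperatures, curve.fluorescence
        ll0, _ = self._baseline_inits(f)
        model = Model(_single_decay)
        p = Parameters()
        p.add("ll", value=ll0)
        p.add("amp", value=max(float(f.max()) - ll0, 1e-9), min=0.0)
        p.add("tm", value=tm_from_derivative(self.windowed), min=t[0] - 5.0, max=t[-1] + 5.0)
        p.add("a", value=2.0, min=0.05, max=8.0)
        p.add("k", value=self.config.decay_rate, vary=False)
        p.add("onset", value=self.config.decay_onset, vary=False)
        try:
            res = model.fit(f, p, t=t)
        except Exception as exc:  # pragma: no cover
            logger.warning("%s: decay-model fit failed: %s", curve.sample_id, exc)
            return self._failed_result(1, curve)
        tm = float(res.params["tm"].value)
        stderr = res.params["tm"].stderr
        return MeltFitResult(
            sample_id=curve.sample_id,
            n_transitions=1,
            transitions=[
                TransitionParams(
                    tm=tm,
                    slope_a=float(res.params["a"].value),
                    amplitude=float(res.params["amp"].value),
                    tm_stderr=float(stderr) if stderr is not None else None,
                )
            ],
            ll=float(res.params["ll"].value),
            ul=float(res.params["ll"].value + res.params["amp"].value),
            r_squared=self._windowed_r2(res.best_fit),
            fit_window=(float(t[0]), float(t[-1])),
            converged=bool(res.success),
            bic=_bic(f, res.best_fit, 4),
            n_points=t.size,
            flags=self._edge_flags([tm], t),
            curve=curve,
        )

    # -- two transitions with decay, full trace ----------------------------
    def _double_inits(self, reference_tms) -> List[Tuple[float, float]]:
        """Candidate (Tm1, Tm2) starts: derivative peaks, references, and
        offsets around the main transition (a minority species can be a
        shoulder on the major one's decay, invisible as a peak)."""
        cfg = self.config
        inits = []
        peaks = _derivative_peaks(self.full, cfg.min_separation)
        if len(peaks) >= 2:
            inits.append(tuple(sorted(peaks[:2])))
        if reference_tms is not None and len(reference_tms) == 2:
            inits.append(tuple(sorted(float(x) for x in reference_tms)))
        c = tm_from_derivative(self.windowed)
        off = max(cfg.min_separation + 1.0, 5.0)
        inits.extend([(c, c + off), (c - off, c)])
        return inits

    def _fit_double(self, reference_tms: Optional[Sequence[float]]) -> Optional[MeltFitResult]:
        cfg = self.config
        curve = self.full
        t, f = curve.temperatures, curve.fluorescence
        ll0, _ = self._baseline_inits(f)
        amp0 = max(float(f.max()) - ll0, 1e-9)
        model = Model(_double_decay)
        best = None
        # multi-start over midpoint pairs and amplitude splits: a minority
        # transition is easily swallowed by a poor local minimum otherwise
        for tm1_0, tm2_0 in self._double_inits(reference_tms):
            for a1_frac in (0.5, 0.8):
                p = Parameters()
                p.add("ll", value=ll0)
                p.add("a1", value=amp0 * a1_frac, min=0.0)
                p.add("a2", value=amp0 * (1.0 - a1_frac), min=0.0)
                p.add("tm1", value=tm1_0, min=t[0] - 10.0, max=t[-1] + 10.0)
                p.add("sep", value=max(tm2_0 - tm1_0, cfg.min_separation), min=cfg.min_separation, max=80.0)
                p.add("s1", value=2.0, min=0.05, max=8.0)
                p.add("s2", value=2.0, min=0.05, max=8.0)
                p.add("k", value=cfg.decay_rate, vary=False)
                p.add("onset", value=cfg.decay_onset, vary=False)
                try:
                    res = model.fit(f, p, t=t)
                except Exception as exc:  # pragma: no cover
                    logger.warning("%s: two-transition fit failed: %s", curve.sample_id, exc)
                    continue
                ssr = float(np.sum((f - res.best_fit) ** 2))
                if best is None or ssr < best[0]:
                    best = (ssr, res)
        if best is None:
            return None
        res = best[1]
        tm1 = float(res.params["tm1"].value)
        tm2 = tm1 + float(res.params["sep"].value)
        e1 = res.params["tm1"].stderr
        trs = [
            TransitionParams(
                tm=tm1,
                slope_a=float(res.params["s1"].value),
                amplitude=float(res.params["a1"].value),
                tm_stderr=float(e1) if e1 is not None else None,
            ),
            TransitionParams(
                tm=tm2,
                slope_a=float(res.params["s2"].value),
                amplitude=float(res.params["a2"].value),
            ),
        ]
        ll = float(res.params["ll"].value)
        return MeltFitResult(
            sample_id=curve.sample_id,
            n_transitions=2,
            transitions=trs,
            ll=ll,
            ul=ll + trs[0].amplitude + trs[1].amplitude,
            r_squared=self._windowed_r2(res.best_fit),
            fit_window=(float(t[0]), float(t[-1])),
            converged=bool(res.success),
            bic=_bic(f, res.best_fit, 7),
            n_points=t.size,
            flags=self._edge_flags([tm1, tm2], t),
            curve=curve,
        )

    def _accept_double(self, single: MeltFitResult, double: Optional[MeltFitResult]) -> bool:
        cfg = self.config
        if double is None or not double.converged:
            return False
        a1, a2 = (tr.amplitude for tr in double.transitions)
        total = a1 + a2
        if total <= 0:
            return False
        if min(a1, a2) / total < cfg.amp_fraction_gate:
            return False
        sep = double.transitions[1].tm - double.transitions[0].tm
        # a separation stuck at the lower bound means the optimizer wanted
        # the transitions closer than min_separation: merged, not biphasic
        if sep < cfg.min_separation + 0.02:
            return False
        return (single.bic - double.bic) >= cfg.delta_bic

    # -- public fit --------------------------------------------------------
    def fit(
        self,
        n_transitions: Optional[int] = None,
        reference_tms: Optional[Sequence[float]] = None,
    ) -> MeltFitResult:
        """Fit the curve; ``n_transitions=None`` selects 1 vs 2 by BIC.

        When ``reference_tms`` are supplied (e.g. the two components of a
        fusion protein) they seed the two-transition fit, and rejection of
        the two-transition model is reported with a ``merged_transitions``
        flag on the single fit.
        """
        if n_transitions == 1:
            return self._classify(self._fit_single_plain())
        double = self._fit_double(reference_tms)
        if n_transitions == 2:
            if double is None:
                return self._classify(self._failed_result(2, self.full))
            return self._classify(double)
        single = self._fit_single_decay()
        if self._accept_double(single, double):
            return self._classify(double)
        refs_distinct = (
            reference_tms is not None
            and len(reference_tms) == 2
            and abs(reference_tms[1] - reference_tms[0]) >= self.config.min_separation
        )
        if refs_distinct:
            single.flags.add(MERGED)
        return self._classify(single)

    def _classify(self, fit: MeltFitResult) -> MeltFitResult:
        fit.classification = classify_curve(fit, fit.curve, self.config)
        return fit


def classify_curve(
    fit: MeltFitResult, curve: MeltCurve, config: AnalysisConfig = DEFAULT_CONFIG
) -> str:
    """two_state / biphasic / non_two_state from fit quality and flags."""
    f_max = float(curve.fluorescence.max())
    rel_amp = fit.amplitude / f_max if f_max > 0 else 0.0
    gates = (
        fit.converged
        and fit.r_squared >= config.r2_gate
        and rel_amp >= config.rel_amplitude_gate
        and BOUNDARY_TM not in fit.flags
    )
    if fit.n_transitions == 1:
        if gates and HIGH_INITIAL not in fit.flags:
            return TWO_STATE
        return NON_TWO_STATE
    return BIPHASIC if gates else NON_TWO_STATE


# ---------------------------------------------------------------------------
# functional surface


def fit_boltzmann(
    curve: MeltCurve,
    config: AnalysisConfig = DEFAULT_CONFIG,
    preprocessed: bool = True,
) -> MeltFitResult:
    """Single-transition Boltzmann fit of an (already preprocessed) curve."""
    return MeltCurveModel(curve, config, preprocessed=preprocessed).fit(n_transitions=1)


def fit_two_transitions(
    curve: MeltCurve,
    reference_tms: Optional[Sequence[float]] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> MeltFitResult:
    """Two-vs-one transition fit with BIC model selection (full trace)."""
    return MeltCurveModel(curve, config).fit(reference_tms=reference_tms)


def fit_melt_curve(
    curve: MeltCurve,
    config: AnalysisConfig = DEFAULT_CONFIG,
    compare_two: bool = False,
    reference_tms: Optional[Sequence[float]] = None,
) -> MeltFitResult:
    """Preprocess + fit one raw curve (the pipeline entry point).

    The two-transition model is only tried when requested — single-species
    screens stay cheap — or when reference Tms are available.
    """
    model = MeltCurveModel(curve, config)
    if compare_two or reference_tms is not None:
        return model.fit(reference_tms=reference_tms)
    return model.fit(n_transitions=1)


def fit_group(
    curves: Sequence[MeltCurve],
    config: AnalysisConfig = DEFAULT_CONFIG,
    compare_two: bool = False,
    reference_tms: Optional[Sequence[float]] = None,
) -> List[MeltFitResult]:
    return [
        fit_melt_curve(c, config, compare_two=compare_two, reference_tms=reference_tms)
        for c in curves
    ]
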