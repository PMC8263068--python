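"""Forward model of nascent transcription driven by combinatorial TF logic.

A gene regulatory strategy (GRS) couples a thermodynamic promoter model --
an AND/OR logic gate over up to three transcription-factor activities, each
with its own dissociation constant ``Kd`` -- to a single ODE for nascent
(chromatin-associated) mRNA::

    dRNA/dt = ksyn * f(t) - kproc * RNA
    f(t)    = (1 - k0) * G(TF1(t), TF2(t), TF3(t)) + k0

``G`` is the fractional gate occupancy built from first-order Hill terms
``h_i = TF_i / (Kd_i + TF_i)`` (no cooperativity): AND gates multiply
occupancies, OR gates take the complement of the product of complements.
TF activities are normalized fractions in [0, 1]; expression is in RPKM,
time in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "LOGICS",
    "GRSParameters",
    "TFTrajectory",
    "ExpressionTimecourse",
    "gate_activity",
    "promoter_activity",
    "simulate_timecourse",
    "steady_state",
    "build_waveform",
    "normalize_panel",
    "constant_input_response",
    "DEFAULT_TIMEPOINTS",
]

#: The 8 triple-TF logic gates; "." is AND, "+" is OR.  Single and dual
#: logics are triple gates with null regulation strength (huge Kd) for one
#: or two TFs, so these 8 span all 17 single/dual/triple AND/OR logics.
LOGICS: tuple[str, ...] = (
    "TF1.TF2.TF3",
    "TF1.(TF2+TF3)",
    "TF2.(TF1+TF3)",
    "TF3.(TF1+TF2)",
    "TF1+(TF2.TF3)",
    "TF2+(TF1.TF3)",
    "TF3+(TF1.TF2)",
    "TF1+TF2+TF3",
)

#: Nominal sampling grid of the stimulus-response timecourses (minutes).
DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 15.0, 30.0, 60.0)

#: Numeric stand-in for a null regulation strength (Kd >> 1).
NULL_KD: float = 1e6


@dataclass(frozen=True)
class GRSParameters:
    """One gene regulatory strategy: gate topology plus kinetic parameters.

    Parameters
    ----------
    logic:
        One of :data:`LOGICS`.
    kd:
        Per-TF dissociation constants, in TF-activity units (dimensionless).
    ksyn:
        Maximal synthesis rate, RPKM/min.
    kproc:
        Nascent-RNA processing/release rate, 1/min.
    k0:
        Basal promoter activity, fraction of maximum in [0, 1].
    hill_n:
        Hill coefficient; fixed at 1 (no cooperativity).
    """

    logic: str
    kd: tuple[float, float, float]
    ksyn: float = 1.0
    kproc: float = 0.1
    k0: float = 0.0
    hill_n: int = 1

    def __post_init__(self) -> None:
        if self.logic not in LOGICS:
            raise ConfigurationError(f"unknown logic {self.logic!r}")
        if len(self.kd) != 3 or any(not np.isfinite(k) or k <= 0 for k in self.kd):
            raise InvalidParameterError(f"kd must be 3 positive numbers, got {self.kd}")
        if self.ksyn < 0:
            raise InvalidParameterError("ksyn must be >= 0")
        if self.kproc <= 0:
            raise InvalidParameterError("kproc must be > 0")
        if not 0.0 <= self.k0 <= 1.0:
            raise InvalidParameterError("k0 must lie in [0, 1]")
        if self.hill_n != 1:
            raise InvalidParameterError("hill_n is fixed at 1 in this model")

    @property
    def basal_steady_state(self) -> float:
        """Unstimulated steady-state expression ksyn*k0/kproc (RPKM)."""
        return self.ksyn * self.k0 / self.kproc


def _hill(tf: np.ndarray, kd: np.ndarray) -> np.ndarray:
    return tf / (kd + tf)


def gate_activity(logic: str, tf_activities, kd) -> np.ndarray | float:
    """Fractional gate occupancy G in [0, 1] for one of the 8 triple logics.

    ``tf_activities`` and ``kd`` are broadcast along their last axis of
    length 3, so a whole panel of TF levels can be evaluated in one call.
    """
    tf = np.asarray(tf_activities, dtype=float)
    kdv = np.asarray(kd, dtype=float)
    if tf.shape[-1] != 3 or kdv.shape[-1] != 3:
        raise InvalidInputError("tf_activities and kd must have last axis of length 3")
    if not np.all(np.isfinite(tf)) or not np.all(np.isfinite(kdv)):
        raise InvalidInputError("non-finite TF activity or Kd")
    if np.any(tf < 0):
        raise InvalidInputError("TF activities must be >= 0")
    if np.any(kdv <= 0):
        raise InvalidInputError("Kd must be > 0")
    h = _hill(tf, kdv)
    h1, h2, h3 = h[..., 0], h[..., 1], h[..., 2]
    if logic == "TF1.TF2.TF3":
        g = h1 * h2 * h3
    elif logic == "TF1.(TF2+TF3)":
        g = h1 * (1.0 - (1.0 - h2) * (1.0 - h3))
    elif logic == "TF2.(TF1+TF3)":
        g = h2 * (1.0 - (1.0 - h1) * (1.0 - h3))
    elif logic == "TF3.(TF1+TF2)":
        g = h3 * (1.0 - (1.0 - h1) * (1.0 - h2))
    elif logic == "TF1+(TF2.TF3)":
        g = 1.0 - (1.0 - h1) * (1.0 - h2 * h3)
    elif logic == "TF2+(TF1.TF3)":
        g = 1.0 - (1.0 - h2) * (1.0 - h1 * h3)
    elif logic == "TF3+(TF1.TF2)":
        g = 1.0 - (1.0 - h3) * (1.0 - h1 * h2)
    elif logic == "TF1+TF2+TF3":
        g = 1.0 - (1.0 - h1) * (1.0 - h2) * (1.0 - h3)
    else:
        raise ConfigurationError(f"unknown logic {logic!r}")
    if g.ndim == 0:
        return float(g)
    return g


def promoter_activity(G, k0) -> np.ndarray | float:
    """Fractional promoter activity f = (1 - k0) * G + k0, in [k0, 1]."""
    Ga = np.asarray(G, dtype=float)
    k0a = np.asarray(k0, dtype=float)
    if np.any(Ga < -1e-12) or np.any(Ga > 1 + 1e-12):
        raise InvalidInputError("gate activity G must lie in [0, 1]")
    if np.any(k0a < 0) or np.any(k0a > 1):
        raise InvalidInputError("k0 must lie in [0, 1]")
    f = (1.0 - k0a) * Ga + k0a
    if f.ndim == 0:
        return float(f)
    return f


# ---------------------------------------------------------------------------
# TF input waveforms
# ---------------------------------------------------------------------------

_WAVEFORM_KINDS = ("high", "low", "amplitude", "gradient", "delayed", "transient")


@dataclass(frozen=True)
class TFTrajectory:
    """A single TF activity waveform on [0, 60] min, held constant after 60.

    ``segments`` is set for piecewise-constant waveforms as a tuple of
    ``(t_start, t_end, value)`` half-open-at-left intervals covering
    [0, 60]; the ODE solver then uses the exact interval-wise solution.
    """

    kind: str
    level: float
    fn: Callable[[np.ndarray], np.ndarray] = field(repr=False, compare=False, default=None)
    segments: tuple[tuple[float, float, float], ...] | None = None

    def __call__(self, t) -> np.ndarray | float:
        ta = np.clip(np.asarray(t, dtype=float), 0.0, 60.0)
        out = np.asarray(self.fn(ta), dtype=float)
        if out.ndim == 0:
            return float(out)
        return out

    @property
    def is_piecewise_constant(self) -> bool:
        return self.segments is not None


def build_waveform(kind: str, level: float | None = None) -> TFTrajectory:
    """Construct one of the named perturbation waveforms.

    ``high`` is constant 1, ``low`` constant 0, ``amplitude`` constant at
    ``level`` (default 0.5), ``gradient`` ramps t/60, ``delayed`` switches
    0->1 at 30 min, ``transient`` switches 1->0 at 30 min.
    """
    if kind not in _WAVEFORM_KINDS:
        raise ConfigurationError(
            f"unknown waveform kind {kind!r}; expected one of {_WAVEFORM_KINDS}"
        )
    if level is not None and not (np.isfinite(level) and 0.0 <= level <= 1.0):
        raise ConfigurationError("waveform level must lie in [0, 1]")
    if kind == "high":
        lv = 1.0
        return TFTrajectory(kind, lv, fn=lambda t, lv=lv: np.full_like(t, lv),
                            segments=((0.0, 60.0, lv),))
    if kind == "low":
        return TFTrajectory(kind, 0.0, fn=lambda t: np.zeros_like(t),
                            segments=((0.0, 60.0, 0.0),))
    if kind == "amplitude":
        lv = 0.5 if level is None else float(level)
        return TFTrajectory(kind, lv, fn=lambda t, lv=lv: np.full_like(t, lv),
                            segments=((0.0, 60.0, lv),))
    if kind == "gradient":
        return TFTrajectory(kind, 1.0, fn=lambda t: np.clip(t / 60.0, 0.0, 1.0))
    if kind == "delayed":
        return TFTrajectory(
            kind, 1.0,
            fn=lambda t: np.where(t > 30.0, 1.0, 0.0),
            segments=((0.0, 30.0, 0.0), (30.0, 60.0, 1.0)),
        )
    # transient
    return TFTrajectory(
        kind, 1.0,
        fn=lambda t: np.where(t > 30.0, 0.0, 1.0),
        segments=((0.0, 30.0, 1.0), (30.0, 60.0, 0.0)),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionTimecourse:
    """Nascent mRNA (RPKM) sampled at strictly increasing timepoints (min)."""

    timepoints: tuple[float, ...]
    values: tuple[float, ...]
    rna0: float = 0.0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size and np.any(np.diff(tp) <= 0):
            raise InvalidInputError("timepoints must be strictly increasing")
        if any(v < -1e-9 for v in self.values):
            raise InvalidInputError("expression values must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _clip_tf(tf: np.ndarray) -> np.ndarray:
    if np.any(tf < 0) or np.any(tf > 1):
        warnings.warn("TF activities outside [0, 1] were clipped", stacklevel=3)
        return np.clip(tf, 0.0, 1.0)
    return tf


def _interval_step(rna0: float, f_const: float, ksyn: float, kproc: float,
                   dt: float) -> float:
    """Exact solution of the linear ODE over an interval of constant f."""
    ss = ksyn * f_const / kproc
    return ss + (rna0 - ss) * np.exp(-kproc * dt)


def simulate_timecourse(
    params: GRSParameters,
    inputs: Sequence[TFTrajectory],
    timepoints: Iterable[float] = DEFAULT_TIMEPOINTS,
    rna0: float | None = None,
    rtol: float = 1e-8,
) -> ExpressionTimecourse:
    """Integrate dRNA/dt = ksyn*f(t) - kproc*RNA under the given TF inputs.

    Piecewise-constant inputs are solved with the exact interval-wise
    closed form; any other input falls back to an adaptive RK45 integration
    with relative tolerance ``rtol``.  ``rna0`` defaults to 0 when k0 = 0
    and to the basal steady state ksyn*k0/kproc otherwise, so unstimulated
    series are flat.
    """
    if len(inputs) != 3:
        raise InvalidInputError("exactly three TF trajectories are required")
    tp = np.asarray(list(timepoints), dtype=float)
    if np.any(tp < 0):
        raise InvalidInputError("timepoints must be >= 0")
    if rna0 is None:
        rna0 = params.basal_steady_state
    if rna0 < 0:
        raise InvalidInputError("rna0 must be >= 0")

    if all(w.is_piecewise_constant for w in inputs):
        values = _simulate_piecewise_constant(params, inputs, tp, rna0)
    else:
        values = _simulate_adaptive(params, inputs, tp, rna0, rtol)
    return ExpressionTimecourse(tuple(tp), tuple(np.maximum(values, 0.0)), rna0=rna0)


def _segment_breaks(inputs: Sequence[TFTrajectory], t_max: float) -> np.ndarray:
    breaks = {0.0, t_max}
    for w in inputs:
        for t0, t1, _ in w.segments:
            breaks.add(t0)
            breaks.add(t1)
    return np.asarray(sorted(b for b in breaks if b <= t_max))


def _simulate_piecewise_constant(params, inputs, tp, rna0) -> np.ndarray:
    t_max = max(float(tp.max(initial=0.0)), 60.0)
    breaks = _segment_breaks(inputs, t_max)
    if breaks[-1] < t_max:
        breaks = np.append(breaks, t_max)
    # evaluate G at segment midpoints (waveforms are constant inside)
    out = np.empty_like(tp)
    rna = rna0
    t_prev = 0.0
    order = np.argsort(tp)
    idx = 0
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (t0 + t1)
        tf = _clip_tf(np.asarray([w(mid) for w in inputs]))
        f = promoter_activity(gate_activity(params.logic, tf, params.kd), params.k0)
        # sample points falling in (t_prev, t1]
        while idx < tp.size and tp[order[idx]] <= t1 + 1e-12:
            t_q = tp[order[idx]]
            if t_q <= t_prev + 1e-12 and t_q == 0.0:
                out[order[idx]] = rna0
            else:
                out[order[idx]] = _interval_step(rna, f, params.ksyn, params.kproc,
                                                 t_q - t_prev)
            idx += 1
        rna = _interval_step(rna, f, params.ksyn, params.kproc, t1 - t_prev)
        t_prev = t1
    # queries beyond the last break: promoter frozen at its final value
    while idx < tp.size:
        out[order[idx]] = _interval_step(rna, f, params.ksyn, params.kproc,
                                         tp[order[idx]] - t_prev)
        idx += 1
    return out


def _simulate_adaptive(params, inputs, tp, rna0, rtol) -> np.ndarray:
    def rhs(t, y):
        tf = _clip_tf(np.asarray([w(t) for w in inputs]))
        f = promoter_activity(gate_activity(params.logic, tf, params.kd), params.k0)
        return params.ksyn * f - params.kproc * y

    t_end = max(float(tp.max(initial=0.0)), 60.0)
    sol = solve_ivp(rhs, (0.0, t_end), [rna0], method="RK45", rtol=rtol,
                    atol=1e-10, dense_output=True, max_step=5.0)
    if not sol.success:  # pragma: no cover - RK45 on a linear ODE
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.sol(tp)[0]


def steady_state(params: GRSParameters, tf_levels) -> float:
    """Closed-form steady state ksyn*f/kproc under constant TF levels."""
    tf = _clip_tf(np.asarray(tf_levels, dtype=float))
    f = promoter_activity(gate_activity(params.logic, tf, params.kd), params.k0)
    return params.ksyn * f / params.kproc


def constant_input_response(
    f_total: np.ndarray,
    ksyn: np.ndarray,
    kproc: np.ndarray,
    k0: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Vectorized exact response under constant promoter activity.

    The gene starts from its basal steady state ksyn*k0/kproc; stimulation
    switches total promoter activity to ``f_total`` at t = 0.  All
    arguments broadcast; ``times`` may be per-sample (e.g. noise-shifted).
    Negative times are clamped to 0 (pre-stimulus steady state).
    """
    t = np.maximum(np.asarray(times, dtype=float), 0.0)
    ss = ksyn * f_total / kproc
    basal = ksyn * k0 / kproc
    return ss + (basal - ss) * np.exp(-kproc * t)


def normalize_panel(timecourses, target: float = 100.0):
    """Scale a collection of timecourses by one factor so the global max is 100.

    Accepts either a mapping/iterable of :class:`ExpressionTimecourse` or a
    plain ndarray; returns the same structure.  Relative shapes are
    preserved (the operation is a single global rescaling), so doubling
    ksyn before normalization leaves the result unchanged.
    """
    if isinstance(timecourses, np.ndarray):
        peak = float(timecourses.max(initial=0.0))
        if peak <= 0:
            raise DegenerateInputError("cannot normalize an all-zero panel")
        return timecourses * (target / peak)
    tc_list = list(timecourses.values()) if isinstance(timecourses, dict) else list(timecourses)
    peak = max((max(tc.values, default=0.0) for tc in tc_list), default=0.0)
    if peak <= 0:
        raise DegenerateInputError("cannot normalize an all-zero panel")
    scale = target / peak
    scaled = [
        ExpressionTimecourse(tc.timepoints, tuple(v * scale for v in tc.values),
                             rna0=tc.rna0 * scale)
        for tc in tc_list
    ]
    if isinstance(timecourses, dict):
        return dict(zip(timecourses.keys(), scaled))
    return scaled
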