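"""Absolute membrane potential from potentiometric-dye traces.

A population fluorimetry assay with the slow carbocyanine dye DiSC3(5)
reports sperm membrane potential (Em) as arbitrary fluorescence units
(AFU).  Absolute mV values are obtained by internal calibration at the
end of each recording: 1 µM valinomycin renders the membrane K+-selective
and clamps Em to the K+ equilibrium (Nernst) potential; sequential KCl
additions then step the clamped potential through a series of known
Nernst values.  The plateau fluorescences paired with their theoretical
potentials define a per-trace linear AFU↔mV map, and the initial
(pre-valinomycin) fluorescence is inverted through that map to give the
sample's resting Em.  Because every trace carries its own calibration,
the estimate is invariant to gain/offset changes in the raw fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from empredict.errors import (
    DegenerateFitError,
    FlatCalibrationError,
    InsufficientCalibrationError,
    InvalidInputError,
    TraceInvariantError,
    WindowTooShortError,
)

# Gas constant (J mol^-1 K^-1) and Faraday constant (C mol^-1)
GAS_CONSTANT = 8.314
FARADAY_CONSTANT = 96485.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdditionEvent:
    """One reagent addition during a recording.

    ``kind`` is ``"valinomycin"`` (no K+ added; clamps Em to E_K) or
    ``"KCl"`` (adds ``aliquot_volume`` µL of ``aliquot_concentration`` mM
    KCl to the cuvette).
    """

    time: float                       # s from recording start
    kind: Literal["valinomycin", "KCl"]
    aliquot_volume: float = 0.0       # µL
    aliquot_concentration: float = 0.0  # mM

    def __post_init__(self) -> None:
        if self.kind not in ("valinomycin", "KCl"):
            raise InvalidInputError(f"unknown event kind {self.kind!r}")
        if self.aliquot_volume < 0 or self.aliquot_concentration < 0:
            raise InvalidInputError(
                "aliquot volume and concentration must be non-negative"
            )


@dataclass
class FluorescenceTrace:
    """A time-stamped fluorescence recording with its addition log.

    Parameters
    ----------
    time : array of s, strictly increasing
    fluorescence : array of AFU, finite and > 0
    events : ordered reagent additions; valinomycin precedes all KCl
    initial_volume : cuvette volume in mL before any addition
    sample_id : optional identifier carried through to reports
    """

    time: np.ndarray
    fluorescence: np.ndarray
    events: list[AdditionEvent]
    initial_volume: float = 2.0  # mL
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.fluorescence.shape:
            raise TraceInvariantError("time and fluorescence must be 1-D and equal length")
        if self.time.size < 2:
            raise TraceInvariantError("trace needs at least two samples")
        if not np.all(np.diff(self.time) > 0):
            raise TraceInvariantError("time must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)) or np.any(self.fluorescence <= 0):
            raise TraceInvariantError("fluorescence must be finite and > 0")
        if self.initial_volume <= 0:
            raise TraceInvariantError("initial volume must be positive")
        self.events = sorted(self.events, key=lambda e: e.time)
        kinds = [e.kind for e in self.events]
        if "KCl" in kinds:
            if "valinomycin" not in kinds:
                raise TraceInvariantError("KCl additions require a prior valinomycin event")
            if kinds.index("valinomycin") > kinds.index("KCl"):
                raise TraceInvariantError("valinomycin must precede all KCl additions")
        if kinds.count("valinomycin") > 1:
            raise TraceInvariantError("at most one valinomycin event per trace")
        t0, t1 = self.time[0], self.time[-1]
        for ev in self.events:
            if not (t0 <= ev.time <= t1):
                raise TraceInvariantError(
                    f"event at t={ev.time} s lies outside the trace span [{t0}, {t1}] s"
                )

    @property
    def valinomycin_event(self) -> AdditionEvent:
        for ev in self.events:
            if ev.kind == "valinomycin":
                return ev
        raise TraceInvariantError("trace has no valinomycin event")


@dataclass(frozen=True)
class IonicContext:
    """Ionic and thermal conditions of the assay.

    ``k_out_initial`` is the external K+ of the recording medium (mM);
    for HEPES-buffered human tubal fluid, 4.7 mM KCl plus 0.3 mM KH2PO4
    gives 5.0 mM total K+.  ``k_in`` is the assumed intracellular K+
    (120 mM, a standard literature value for human sperm).  Temperature
    defaults to 37 °C.
    """

    k_out_initial: float = 5.0   # mM
    k_in: float = 120.0          # mM
    temperature: float = 310.15  # K

    def __post_init__(self) -> None:
        if min(self.k_out_initial, self.k_in, self.temperature) <= 0:
            raise InvalidInputError("ionic context values must be strictly positive")
        if self.k_out_initial >= self.k_in:
            raise InvalidInputError(
                "external K+ must be below intracellular K+ at assay start"
            )


@dataclass
class CalibrationCurve:
    """Paired (theoretical Em, plateau fluorescence) points with an OLS line.

    The line is fluorescence-on-Em: F = intercept + slope * Em, so mV are
    recovered as (F - intercept) / slope.
    """

    points: list[tuple[float, float]]  # (theoretical_em_mv, plateau_afu)
    slope: float                       # AFU / mV
    intercept: float                   # AFU
    r_squared: float

    @property
    def em_values(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def fluorescence_values(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass
class EmMeasurement:
    """One sample's absolute membrane potential with quality metadata."""

    em: float                       # mV
    condition: str = ""             # e.g. NC0, NC_t, CAP_t
    initial_fluorescence: float = float("nan")
    extrapolated: bool = False
    curve_r_squared: float = float("nan")
    sample_id: str = ""
    plateaus: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def nernst_potential(k_out: float, k_in: float, temperature: float = 310.15) -> float:
    """K+ equilibrium (Nernst) potential in mV.

    E_K = (R*T/F) * ln([K+]_out / [K+]_in), returned in millivolts.
    Strictly increasing in ``k_out``; zero iff the concentrations are equal.

    Raises
    ------
    InvalidInputError
        If any argument is not strictly positive.
    """
    if k_out <= 0 or k_in <= 0 or temperature <= 0:
        raise InvalidInputError("concentrations and temperature must be > 0")
    volts = GAS_CONSTANT * temperature / FARADAY_CONSTANT * math.log(k_out / k_in)
    return volts * 1000.0


def cumulative_potassium(
    context: IonicContext,
    events: Sequence[AdditionEvent],
    initial_volume: float,
) -> list[tuple[float, float, float]]:
    """External K+ and cuvette volume after each addition event.

    Each KCl aliquot is mixed into the running volume with full dilution
    correction:  K_new = (K_prev*V_prev + C_aliquot*V_aliquot) / (V_prev +
    V_aliquot).  A valinomycin event changes neither K+ nor (to the
    precision that matters here) the volume.

    Returns one ``(event_time_s, k_out_mM, total_volume_mL)`` tuple per
    event, in event order.
    """
    if initial_volume <= 0:
        raise InvalidInputError("initial volume must be positive")
    k = context.k_out_initial
    volume = initial_volume
    out: list[tuple[float, float, float]] = []
    for ev in sorted(events, key=lambda e: e.time):
        if ev.kind == "KCl":
            v_aliquot = ev.aliquot_volume / 1000.0  # µL -> mL
            if v_aliquot > 0:
                k = (k * volume + ev.aliquot_concentration * v_aliquot) / (volume + v_aliquot)
                volume += v_aliquot
        out.append((ev.time, k, volume))
    return out


def detect_plateaus(
    trace: FluorescenceTrace,
    window: float = 20.0,
    settle_delay: float = 10.0,
) -> list[dict]:
    """Mean fluorescence plateaus before and after each addition.

    The initial plateau is the ``window`` seconds immediately preceding
    the valinomycin event (recordings start at steady state).  Each
    event's plateau is the mean over ``[t_event + settle_delay,
    t_event + settle_delay + window]``, leaving ``settle_delay`` for the
    slow dye to re-equilibrate after the step.

    Returns dicts with keys ``event`` (``None`` for the initial plateau),
    ``fluorescence`` (mean AFU) and ``sd`` (AFU).

    Raises
    ------
    WindowTooShortError
        If any averaging window contains fewer than two samples, naming
        the offending event.
    """
    if window <= 0 or settle_delay < 0:
        raise InvalidInputError("window must be > 0 and settle_delay >= 0")

    def window_stats(lo: float, hi: float, label: str,
                     include_hi: bool = True) -> tuple[float, float]:
        if include_hi:
            mask = (trace.time >= lo) & (trace.time <= hi)
        else:  # pre-event window: the sample at hi already has the new level
            mask = (trace.time >= lo) & (trace.time < hi)
        n = int(mask.sum())
        if n < 2:
            raise WindowTooShortError(
                f"plateau window [{lo:.1f}, {hi:.1f}] s for {label} contains "
                f"{n} sample(s); need >= 2"
            )
        seg = trace.fluorescence[mask]
        return float(seg.mean()), float(seg.std(ddof=0))

    t_val = trace.valinomycin_event.time
    plateaus: list[dict] = []
    mean, sd = window_stats(t_val - window, t_val, "initial plateau",
                            include_hi=False)
    plateaus.append({"event": None, "fluorescence": mean, "sd": sd})
    for i, ev in enumerate(trace.events):
        lo = ev.time + settle_delay
        label = f"event {i} ({ev.kind} at t={ev.time:.1f} s)"
        next_t = trace.events[i + 1].time if i + 1 < len(trace.events) else trace.time[-1]
        if lo + window > next_t + 1e-9:
            raise WindowTooShortError(
                f"{label}: needs {settle_delay + window:.1f} s before the next "
                f"event/trace end but only {next_t - ev.time:.1f} s available"
            )
        mean, sd = window_stats(lo, lo + window, label)
        plateaus.append({"event": ev, "fluorescence": mean, "sd": sd})
    return plateaus


def build_calibration(
    plateaus: Sequence[dict],
    context: IonicContext,
    events: Sequence[AdditionEvent],
    initial_volume: float = 2.0,
    include_valinomycin_point: bool = True,
) -> CalibrationCurve:
    """Fit the per-trace AFU↔mV line from post-addition plateaus.

    Each post-valinomycin plateau is paired with the Nernst potential at
    the cumulative external K+ in force at that moment.  The valinomycin
    plateau itself anchors the hyperpolarized end of the curve at
    E_K(initial medium K+) — valinomycin clamps Em to E_K — unless
    ``include_valinomycin_point`` is False.  Ordinary least squares of
    fluorescence on theoretical Em gives slope, intercept and r².
    """
    k_timeline = dict(
        (t, k) for t, k, _ in cumulative_potassium(context, events, initial_volume)
    )
    points: list[tuple[float, float]] = []
    for p in plateaus:
        ev = p["event"]
        if ev is None:
            continue
        if ev.kind == "valinomycin":
            if include_valinomycin_point:
                em = nernst_potential(context.k_out_initial, context.k_in, context.temperature)
                points.append((em, p["fluorescence"]))
        else:
            em = nernst_potential(k_timeline[ev.time], context.k_in, context.temperature)
            points.append((em, p["fluorescence"]))
    if len(points) < 2:
        raise InsufficientCalibrationError(
            f"calibration needs >= 2 points, got {len(points)}"
        )
    em = np.array([p[0] for p in points])
    afu = np.array([p[1] for p in points])
    if np.ptp(em) == 0:
        raise DegenerateFitError("zero variance in theoretical Em; cannot fit a line")
    slope, intercept = np.polyfit(em, afu, 1)
    fitted = intercept + slope * em
    ss_res = float(np.sum((afu - fitted) ** 2))
    ss_tot = float(np.sum((afu - afu.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(points=points, slope=float(slope),
                            intercept=float(intercept), r_squared=float(r2))


def estimate_em(
    initial_fluorescence: float,
    curve: CalibrationCurve,
    mode: Literal["linear", "piecewise"] = "linear",
) -> EmMeasurement:
    """Invert the calibration to map an initial fluorescence to mV.

    ``linear`` (default) inverts the global OLS line:
    Em = (F - intercept) / slope.  ``piecewise`` interpolates Em linearly
    between the two calibration points whose fluorescences bracket F
    (extending the end segments outside the span).  Values outside the
    span of plateau fluorescences are flagged ``extrapolated`` but never
    rejected.
    """
    fl = curve.fluorescence_values
    extrapolated = not (fl.min() <= initial_fluorescence <= fl.max())
    if mode == "linear":
        if curve.slope == 0:
            raise FlatCalibrationError("calibration slope is zero")
        em = (initial_fluorescence - curve.intercept) / curve.slope
    elif mode == "piecewise":
        order = np.argsort(fl)
        fl_sorted = fl[order]
        em_sorted = curve.em_values[order]
        if np.ptp(fl_sorted) == 0:
            raise FlatCalibrationError("calibration plateaus are all equal")
        # np.interp clamps outside the span; extend end segments instead
        if initial_fluorescence <= fl_sorted[0]:
            i, j = 0, 1
        elif initial_fluorescence >= fl_sorted[-1]:
            i, j = len(fl_sorted) - 2, len(fl_sorted) - 1
        else:
            j = int(np.searchsorted(fl_sorted, initial_fluorescence))
            i = j - 1
        df = fl_sorted[j] - fl_sorted[i]
        if df == 0:
            raise FlatCalibrationError("bracketing plateaus have equal fluorescence")
        frac = (initial_fluorescence - fl_sorted[i]) / df
        em = float(em_sorted[i] + frac * (em_sorted[j] - em_sorted[i]))
    else:
        raise InvalidInputError(f"unknown interpolation mode {mode!r}")
    return EmMeasurement(
        em=float(em),
        initial_fluorescence=float(initial_fluorescence),
        extrapolated=bool(extrapolated),
        curve_r_squared=curve.r_squared,
    )


def process_trace(
    trace: FluorescenceTrace,
    context: IonicContext | None = None,
    window: float = 20.0,
    settle_delay: float = 10.0,
    mode: Literal["linear", "piecewise"] = "linear",
    include_valinomycin_point: bool = True,
    condition: str = "",
) -> EmMeasurement:
    """Full trace → Em pipeline: K+ bookkeeping, plateau extraction,
    calibration fit and inversion, with a structured quality record.

    Deterministic composition of :func:`cumulative_potassium`,
    :func:`detect_plateaus`, :func:`build_calibration` and
    :func:`estimate_em`; errors from sub-operations propagate with the
    trace identified in their message.
    """
    context = context or IonicContext()
    try:
        plateaus = detect_plateaus(trace, window=window, settle_delay=settle_delay)
        curve = build_calibration(
            plateaus, context, trace.events, trace.initial_volume,
            include_valinomycin_point=include_valinomycin_point,
        )
        result = estimate_em(plateaus[0]["fluorescence"], curve, mode=mode)
    except (WindowTooShortError, InsufficientCalibrationError,
            DegenerateFitError, FlatCalibrationError) as exc:
        raise type(exc)(f"trace {trace.sample_id or '<unnamed>'}: {exc}") from exc
    result.sample_id = trace.sample_id
    result.condition = condition
    result.plateaus = [
        {
            "event_kind": (p["event"].kind if p["event"] else "initial"),
            "event_time_s": (p["event"].time if p["event"] else None),
            "fluorescence_afu": p["fluorescence"],
            "sd_afu": p["sd"],
        }
        for p in plateaus
    ]
    return result


def process_traces(
    traces: Sequence[FluorescenceTrace],
    context: IonicContext | None = None,
    **kwargs,
) -> list[EmMeasurement]:
    """Batch form of :func:`process_trace`; order preserved."""
    return [process_trace(t, context, **kwargs) for t in traces]
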