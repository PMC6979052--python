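"""Seeded synthetic data with the statistical structure the analysis assumes.

Five generators mirror the five kinds of input the pipeline consumes:

* :func:`simulate_trace` — a forward model of the DiSC3(5) cuvette assay:
  affine steady-state fluorescence response to Em, first-order dye
  equilibration after each reagent step, additive Gaussian noise and
  linear drift.
* :func:`simulate_cohort` — donors with true and measured Em under
  non-capacitating (NC) and capacitating (CAP) conditions, drawn from a
  three-class behavior mixture (hyperpolarizing / depolarizing /
  unchanged) with class-conditional Em shifts.
* :func:`simulate_ivf_cohort` — per-patient oocyte and fertilization
  counts coupled to capacitated Em through a logistic link.
* :func:`simulate_casa` — per-sperm CASA kinematics as a two-component
  mixture (hyperactivated vs progressive), optionally Em-coupled.
* :func:`simulate_ar` — binomial acrosome-reaction counts, spontaneous
  and progesterone-stimulated arms.

All generators are pure functions of (spec, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from empredict.calibration import (
    AdditionEvent,
    FluorescenceTrace,
    IonicContext,
    cumulative_potassium,
    nernst_potential,
)
from empredict.errors import InvalidInputError

BEHAVIOR_CLASSES = ("hyperpolarizing", "depolarizing", "unchanged")


# ---------------------------------------------------------------------------
# Dye traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DyeModel:
    """Affine steady-state dye response with first-order kinetics.

    ``slope`` is AFU per mV with the convention that fluorescence rises
    as Em depolarizes (slope > 0 for DiSC3(5) suspension fluorescence).
    ``equilibration_tau`` is the dye's relaxation time constant after a
    potential step; ``drift`` is a slow linear baseline drift.
    """

    baseline: float = 600.0        # AFU at Em = 0 mV
    slope: float = 4.0             # AFU / mV
    equilibration_tau: float = 2.0  # s
    noise_sd: float = 0.0          # AFU
    drift: float = 0.0             # AFU / s

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise InvalidInputError("dye slope must be non-zero")
        if self.equilibration_tau <= 0:
            raise InvalidInputError("equilibration tau must be > 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise sd must be >= 0")

    def steady_state(self, em_mv: float) -> float:
        return self.baseline + self.slope * em_mv


def default_protocol(
    context: IonicContext | None = None,
    initial_volume: float = 2.0,
    stock_mM: float = 1000.0,
    targets_mM: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0),
    baseline_s: float = 60.0,
    spacing_s: float = 60.0,
) -> tuple[list[AdditionEvent], float]:
    """The default calibration protocol: valinomycin, then KCl aliquots
    sized (with dilution correction) to step cumulative external K+
    through ``targets_mM``.

    Returns the event list and the total recording duration needed to
    leave ``spacing_s`` of plateau after the last addition.
    """
    context = context or IonicContext()
    events = [AdditionEvent(time=baseline_s, kind="valinomycin")]
    k = context.k_out_initial
    volume = initial_volume
    t = baseline_s
    for target in targets_mM:
        if target <= k:
            raise InvalidInputError("K+ targets must be strictly increasing")
        if target >= stock_mM:
            raise InvalidInputError("K+ target must be below the stock concentration")
        t += spacing_s
        v_aliquot_ml = volume * (target - k) / (stock_mM - target)
        events.append(AdditionEvent(
            time=t, kind="KCl",
            aliquot_volume=v_aliquot_ml * 1000.0,
            aliquot_concentration=stock_mM,
        ))
        volume += v_aliquot_ml
        k = target
    duration = t + spacing_s
    return events, duration


def simulate_trace(
    true_em: float,
    dye: DyeModel | None = None,
    events: list[AdditionEvent] | None = None,
    context: IonicContext | None = None,
    initial_volume: float = 2.0,
    duration: float | None = None,
    sample_rate: float = 2.0,
    seed: int | None = None,
    sample_id: str = "",
) -> FluorescenceTrace:
    """Forward-simulate one cuvette recording at a known true Em.

    The pre-valinomycin segment sits at the steady-state fluorescence of
    ``true_em``.  At the valinomycin addition the signal relaxes (first
    order, time constant ``dye.equilibration_tau``) toward the
    fluorescence of E_K at the initial medium K+; each KCl addition
    relaxes toward E_K at the new cumulative K+.  Gaussian noise and
    linear drift are added on top.  Reproducible under a fixed seed.
    """
    dye = dye or DyeModel()
    context = context or IonicContext()
    if events is None:
        events, default_dur = default_protocol(context, initial_volume)
        duration = duration or default_dur
    if duration is None:
        duration = max(e.time for e in events) + 60.0
    events = sorted(events, key=lambda e: e.time)

    gaps = np.diff([e.time for e in events] + [duration])
    if np.any(gaps < 3 * dye.equilibration_tau):
        warnings.warn(
            "plateau spacing < 3*tau: plateaus may not settle before the next event",
            stacklevel=2,
        )

    n = int(round(duration * sample_rate)) + 1
    time = np.arange(n) / sample_rate
    rng = np.random.default_rng(seed)

    # target steady-state fluorescence for each segment between events
    k_timeline = cumulative_potassium(context, events, initial_volume)
    seg_bounds = [0.0] + [e.time for e in events] + [np.inf]
    seg_targets = [dye.steady_state(true_em)]
    for ev, (_, k_out, _) in zip(events, k_timeline):
        if ev.kind == "valinomycin":
            em = nernst_potential(context.k_out_initial, context.k_in, context.temperature)
        else:
            em = nernst_potential(k_out, context.k_in, context.temperature)
        seg_targets.append(dye.steady_state(em))

    fl = np.empty(n)
    start_val = seg_targets[0]  # value each segment relaxes from
    for i_seg, target in enumerate(seg_targets):
        lo, hi = seg_bounds[i_seg], seg_bounds[i_seg + 1]
        mask = (time >= lo) & (time < hi) if np.isfinite(hi) else (time >= lo)
        if i_seg == 0:
            fl[mask] = target  # steady state before any addition
        else:
            dt = time[mask] - lo
            fl[mask] = target + (start_val - target) * np.exp(-dt / dye.equilibration_tau)
            if np.isfinite(hi):
                start_val = target + (start_val - target) * np.exp(
                    -(hi - lo) / dye.equilibration_tau
                )

    fl = fl + dye.drift * time
    if dye.noise_sd > 0:
        fl = fl + rng.normal(0.0, dye.noise_sd, size=n)
    fl = np.maximum(fl, 1e-6)  # trace invariant: fluorescence > 0
    return FluorescenceTrace(
        time=time, fluorescence=fl, events=list(events),
        initial_volume=initial_volume, sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# Donor cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a donor cohort.

    Defaults reproduce the structure reported for normospermic donors:
    resting (NC) Em around -37.7 ± 9.9 mV shifting to about -57.8 ± 12.9
    mV after capacitation, with a hyperpolarizing-majority behavior
    mixture (53.6% hyperpolarizing / 32.8% depolarizing / 13.6%
    unchanged).  Behavior classes are generated via class-conditional
    Em-shift distributions truncated at the ±5 mV class boundary so the
    generated label always matches the noiseless classification.
    """

    n_donors: int = 49
    group: str = "normospermic"
    em_nc_mean: float = -37.7
    em_nc_sd: float = 9.9
    em_cap_mean: float = -57.8
    em_cap_sd: float = 12.9
    behavior_mixture: tuple[float, float, float] = (0.536, 0.328, 0.136)
    behavior_threshold: float = 5.0   # mV, class boundary on |delta Em|
    depolarizing_shift_mean: float = 10.0  # mV
    shift_sd: float = 8.0             # mV, within-class spread of delta Em
    measurement_noise_sd: float = 2.0  # mV, repeat-measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.behavior_mixture, dtype=float)
        if mix.shape != (3,) or np.any(mix < 0) or np.any(mix > 1):
            raise InvalidInputError("behavior mixture must be three proportions in [0,1]")
        if not np.isclose(mix.sum(), 1.0, atol=1e-9):
            raise InvalidInputError("behavior mixture must sum to 1")
        if self.n_donors < 1:
            raise InvalidInputError("n_donors must be >= 1")
        if min(self.em_nc_sd, self.em_cap_sd, self.shift_sd,
               self.measurement_noise_sd) < 0:
            raise InvalidInputError("standard deviations must be >= 0")
        if self.behavior_threshold <= 0:
            raise InvalidInputError("behavior threshold must be > 0")


NON_NORMOSPERMIC_MIXTURE = (0.273, 0.636, 0.091)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf) -> float:
    """Rejection-sample one value from N(mean, sd) restricted to [lo, hi]."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    # pathological spec (bounds many sds from the mean): fall back to clipping
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a donor cohort with true and measured NC/CAP Em values.

    Per donor: a behavior class from the mixture; a true NC Em from the
    NC distribution; a class-conditional Em shift (hyperpolarizing:
    centered at the CAP-NC group mean difference, truncated <= -threshold;
    depolarizing: truncated >= +threshold; unchanged: inside the open
    band).  Measured values add Gaussian measurement noise.
    """
    rng = np.random.default_rng(spec.seed)
    thr = spec.behavior_threshold
    hyper_shift_mean = spec.em_cap_mean - spec.em_nc_mean
    rows = []
    classes = rng.choice(3, size=spec.n_donors, p=list(spec.behavior_mixture))
    for i, ci in enumerate(classes):
        cls = BEHAVIOR_CLASSES[ci]
        em_nc = rng.normal(spec.em_nc_mean, spec.em_nc_sd)
        if cls == "hyperpolarizing":
            delta = _truncated_normal(rng, hyper_shift_mean, spec.shift_sd, hi=-thr)
        elif cls == "depolarizing":
            delta = _truncated_normal(rng, spec.depolarizing_shift_mean,
                                      spec.shift_sd, lo=thr)
        else:
            delta = _truncated_normal(rng, 0.0, thr / 2.0,
                                      lo=-thr + 1e-9, hi=thr - 1e-9)
        em_cap = em_nc + delta
        rows.append({
            "donor_id": f"{spec.group[:4].upper()}-{i + 1:03d}",
            "group": spec.group,
            "behavior_class": cls,
            "em_nc_true_mv": em_nc,
            "em_cap_true_mv": em_cap,
            "em_nc_mv": em_nc + rng.normal(0, spec.measurement_noise_sd),
            "em_cap_mv": em_cap + rng.normal(0, spec.measurement_noise_sd),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IVF outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IvfLinkSpec:
    """Logistic coupling from capacitated Em to per-oocyte fertilization.

    P(oocyte fertilized) = expit(intercept + slope * Em_CAP).  The default
    link crosses 0.5 near -48.6 mV with more-negative (hyperpolarized)
    Em favoring fertilization; a fertilization rate of at least
    ``success_threshold`` labels the IVF procedure successful.
    """

    n_patients: int = 21
    intercept: float = -7.29
    slope: float = -0.15          # per mV; negative: hyperpolarized favored
    oocytes_min: int = 4
    oocytes_max: int = 12
    success_threshold: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.success_threshold < 1:
            raise InvalidInputError("success threshold must lie in (0,1)")
        if self.oocytes_min < 1 or self.oocytes_max < self.oocytes_min:
            raise InvalidInputError("invalid oocyte count range")
        if self.n_patients < 1:
            raise InvalidInputError("n_patients must be >= 1")


def simulate_ivf_cohort(spec: IvfLinkSpec, donor_em: np.ndarray | list[float]) -> pd.DataFrame:
    """Binomial fertilization outcomes for patients with given Em_CAP.

    ``donor_em`` supplies one capacitated-sperm Em (mV) per patient; its
    length must equal ``spec.n_patients``.
    """
    em = np.asarray(donor_em, dtype=float)
    if em.shape != (spec.n_patients,):
        raise InvalidInputError(
            f"donor_em must have length n_patients={spec.n_patients}, got {em.shape}"
        )
    rng = np.random.default_rng(spec.seed)
    oocytes = rng.integers(spec.oocytes_min, spec.oocytes_max + 1, size=spec.n_patients)
    p = expit(spec.intercept + spec.slope * em)
    fertilized = rng.binomial(oocytes, p)
    rate = fertilized / oocytes
    return pd.DataFrame({
        "patient_id": [f"PT-{i + 1:03d}" for i in range(spec.n_patients)],
        "em_cap_mv": em,
        "oocytes": oocytes,
        "fertilized_2pn": fertilized,
        "fertilization_rate": rate,
        "ivf_success": rate >= spec.success_threshold,
    })


# ---------------------------------------------------------------------------
# CASA kinematics and acrosome reaction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CasaSpec:
    """Two-component per-sperm kinematics mixture.

    The hyperactivated component has high curvilinear velocity (VCL),
    low linearity (LIN) and wide lateral head displacement (ALH); the
    progressive component is the complement.  The hyperactivated weight
    can be coupled to Em through a logistic curve (more-negative Em →
    larger hyperactivated fraction), emulating the capacitation-linked
    rise in hyperactivation.
    """

    n_sperm: int = 200
    # (mean, sd) per parameter: hyperactivated component
    ha_vcl: tuple[float, float] = (185.0, 25.0)
    ha_lin: tuple[float, float] = (35.0, 8.0)
    ha_alh: tuple[float, float] = (6.5, 1.0)
    # progressive component
    prog_vcl: tuple[float, float] = (110.0, 25.0)
    prog_lin: tuple[float, float] = (65.0, 10.0)
    prog_alh: tuple[float, float] = (3.0, 1.0)
    base_ha_fraction: float = 0.15
    # Em coupling of the hyperactivated weight
    ha_max: float = 0.40
    em_half: float = -50.0   # mV at which the coupled fraction is ha_max/2
    em_scale: float = 5.0    # mV logistic width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sperm < 200:
            raise InvalidInputError("CASA analysis requires at least 200 sperm")
        if not 0 <= self.base_ha_fraction <= 1 or not 0 <= self.ha_max <= 1:
            raise InvalidInputError("hyperactivated fractions must lie in [0,1]")

    def ha_fraction_for_em(self, em_mv: float) -> float:
        """Em-coupled hyperactivated weight: logistic in -Em."""
        return float(self.ha_max * expit(-(em_mv - self.em_half) / self.em_scale))


def simulate_casa(spec: CasaSpec, em_mv: float | None = None) -> pd.DataFrame:
    """Per-sperm VCL/VSL/VAP/LIN/STR/ALH table for one sample.

    If ``em_mv`` is given the hyperactivated component weight follows
    ``spec.ha_fraction_for_em``; otherwise ``spec.base_ha_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    frac = spec.base_ha_fraction if em_mv is None else spec.ha_fraction_for_em(em_mv)
    is_ha = rng.random(spec.n_sperm) < frac

    def draw(params_ha, params_prog, lo, hi):
        out = np.where(
            is_ha,
            rng.normal(*params_ha, size=spec.n_sperm),
            rng.normal(*params_prog, size=spec.n_sperm),
        )
        return np.clip(out, lo, hi)

    vcl = draw(spec.ha_vcl, spec.prog_vcl, 0.0, np.inf)
    lin = draw(spec.ha_lin, spec.prog_lin, 0.0, 100.0)
    alh = draw(spec.ha_alh, spec.prog_alh, 0.0, np.inf)
    vsl = vcl * lin / 100.0
    # path velocity lies between straight-line and curvilinear velocity
    vap = vsl + rng.uniform(0.3, 0.7, size=spec.n_sperm) * (vcl - vsl)
    str_ = np.where(vap > 0, 100.0 * vsl / vap, 0.0)
    return pd.DataFrame({
        "VCL": vcl, "VSL": vsl, "VAP": vap,
        "LIN": lin, "STR": np.clip(str_, 0.0, 100.0), "ALH": alh,
    })


def simulate_ar(
    n: int,
    p_spont: float,
    p_induced: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binomial acrosome-reaction counts for the two assay arms.

    ``n`` sperm are scored per arm; the spontaneous arm reacts with
    probability ``p_spont`` and the progesterone-stimulated arm with
    ``p_induced``.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    for p in (p_spont, p_induced):
        if not 0 <= p <= 1:
            raise InvalidInputError("AR probabilities must lie in [0,1]")
    rng = np.random.default_rng(seed)
    reacted = rng.binomial(n, [p_spont, p_induced])
    return pd.DataFrame({
        "arm": ["spontaneous", "progesterone"],
        "reacted": reacted,
        "total": [n, n],
        "percent": 100.0 * reacted / n,
    })
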