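"""Isovolumic-pressure extrapolation from a single ejecting beat.

The ventricle never performs an isovolumic beat in the catheterization lab,
but its isovolumic pressure envelope can be extrapolated from the two limbs
of the measured beat during which the aortic valve is closed: the late
isovolumic contraction and the early isovolumic relaxation.  Those limbs
are fitted with the single-beat sinusoid

    P_iso(t) = P_a + (P_b / 2) * (1 - cos(w t + phi))

whose peak, Pisomax = P_a + P_b, is the pressure the ventricle would have
generated had ejection been prevented.  Pisomax anchors the end-systolic
elastance construction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, FitWindowError
from .flow import FlowLandmarks
from .signal import BeatSegment, DerivativeTrace, PressureTrace

__all__ = ["IsovolumicFit", "select_isovolumic_samples", "fit_isovolumic_pressure"]

#: dP/dt fractions bounding the fitted limbs.
CONTRACTION_THRESHOLD = 0.20
RELAXATION_THRESHOLD = 0.20

#: Plausibility ceiling for the extrapolated peak (mmHg); configurable.
DEFAULT_PISOMAX_CEILING = 500.0

MIN_LIMB_SAMPLES = 4
MIN_FIT_SAMPLES = 8

#: Aggregate weight of the relaxation limb relative to the contraction
#: limb (each limb's samples share its aggregate, so a long limb cannot
#: outvote a short one).
DEFAULT_RELAXATION_WEIGHT = 1.0


@dataclass
class IsovolumicFit:
    """Fitted isovolumic-pressure parameters.

    ``baseline`` (P_a, mmHg) and ``amplitude`` (P_b, mmHg) give
    ``pisomax = baseline + amplitude``; ``angular_frequency`` (rad/s) and
    ``phase`` (rad) fix the sinusoid timing.  ``converged`` is False when
    the optimizer failed or the extrapolated peak fell below the measured
    peak pressure — such beats are excluded from reporting.
    """

    baseline: float
    amplitude: float
    angular_frequency: float
    phase: float
    pisomax: float
    rms_residual: float
    n_fit_samples: int
    converged: bool

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Model pressure P_iso(t) in mmHg at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        return self.baseline + 0.5 * self.amplitude * (
            1.0 - np.cos(self.angular_frequency * t + self.phase)
        )


def select_isovolumic_samples(
    beat: BeatSegment,
    landmarks: FlowLandmarks,
    trace: PressureTrace,
    d1: DerivativeTrace,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample masks (contraction limb, relaxation limb) for the fit.

    Contraction limb: from where dP/dt first exceeds 20% of its beat
    maximum up to the flow onset.  Relaxation limb: from the flow
    termination until dP/dt has recovered above 20% of its beat minimum,
    or until pressure falls to the end-diastolic level — whichever comes
    first: below that level the mitral valve is opening and the ventricle
    is no longer relaxing isovolumically.  Both masks index the parent
    trace.
    """
    if len(d1) != len(trace):
        raise FitWindowError("first derivative not co-indexed with trace")
    fs = trace.sampling_rate
    t0 = trace.time[beat.start_index]
    i_onset = beat.start_index + int(round(landmarks.onset_time * fs))
    i_term = beat.start_index + int(round(landmarks.termination_time * fs))
    i_onset = min(max(i_onset, beat.start_index), beat.end_index - 1)
    i_term = min(max(i_term, beat.start_index), beat.end_index - 1)

    dpdt = d1.values
    dpdt_max = dpdt[beat.dpdt_max_index]
    dpdt_min = dpdt[beat.dpdt_min_index]

    # contraction: first exceedance of 20% of max dP/dt ... onset
    seg = np.arange(beat.start_index, i_onset + 1)
    above = seg[dpdt[seg] > CONTRACTION_THRESHOLD * dpdt_max]
    if len(above) == 0:
        raise FitWindowError("no contraction-limb samples above dP/dt threshold")
    contraction = np.arange(above[0], i_onset + 1)

    # relaxation: termination ... until dP/dt recovers above 20% of min
    # dP/dt or pressure reaches the end-diastolic level (mitral opening)
    seg = np.arange(i_term, beat.end_index)
    done = (dpdt[seg] > RELAXATION_THRESHOLD * dpdt_min) | (
        trace.pressure[seg] < beat.edp
    )
    hit = np.flatnonzero(done)
    stop = int(seg[hit[0]]) if len(hit) else beat.end_index
    relaxation = np.arange(i_term, stop)

    if len(contraction) < MIN_LIMB_SAMPLES or len(relaxation) < MIN_LIMB_SAMPLES:
        raise FitWindowError(
            f"isovolumic limbs too short: contraction={len(contraction)}, "
            f"relaxation={len(relaxation)} samples"
        )
    return contraction, relaxation


def fit_isovolumic_pressure(
    times: np.ndarray,
    pressures: np.ndarray,
    *,
    lvp_max: float | None = None,
    edp: float | None = None,
    omega_init: float | None = None,
    t_rise_center: float | None = None,
    weights: np.ndarray | None = None,
    omega_bounds: tuple[float, float] | None = None,
    phi_bounds: tuple[float, float] | None = None,
    pisomax_ceiling: float = DEFAULT_PISOMAX_CEILING,
) -> IsovolumicFit:
    """Nonlinear least-squares fit of the isovolumic sinusoid to limb samples.

    Parameters
    ----------
    times, pressures : ndarray
        Concatenated (contraction + relaxation) limb samples, seconds and
        mmHg.  Time origin is arbitrary; shifting it by ``d`` only shifts
        the fitted phase by ``-w d``.
    lvp_max, edp : float, optional
        Measured peak and end-diastolic pressures of the beat; used for
        initialization and the plausibility test ``pisomax >= lvp_max``.
    omega_init : float, optional
        Initial angular frequency (rad/s); default pi / (half the sample
        span), or pi over the dP/dt-max-to-min interval when the caller
        knows it.
    t_rise_center : float, optional
        A time on the rising limb used to phase the initial guess.
    weights : ndarray, optional
        Per-sample least-squares weights (default: uniform).  The per-beat
        wrapper uses them to give the two limbs equal aggregate weight, so
        a long relaxation limb cannot outvote a short contraction limb.
    omega_bounds, phi_bounds : tuple, optional
        Box constraints on the angular frequency (rad/s) and the phase
        (rad, in the ``t - t_rise_center`` frame).  Defaults are wide
        ((0, 20 pi] and +-2 pi); the per-beat wrapper narrows them around
        the systolic-interval initialization because with short limbs the
        sinusoid period is weakly identified from the samples alone.

    Returns
    -------
    IsovolumicFit
        With ``converged=False`` when the optimizer failed or the
        extrapolated peak is below the measured peak.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(pressures, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise FitWindowError("times and pressures must be matching 1-D arrays")
    if len(t) < MIN_FIT_SAMPLES:
        raise FitWindowError(
            f"need >= {MIN_FIT_SAMPLES} samples across both limbs, got {len(t)}"
        )

    p_lo = float(np.min(p)) if edp is None else float(edp)
    p_hi = float(np.max(p)) if lvp_max is None else float(lvp_max)
    span = float(t[-1] - t[0])
    if omega_init is None:
        omega_init = np.pi / max(span, 1e-3)
    amp0 = max(1.5 * (p_hi - p_lo), 1.0)
    # Fit in a time frame zeroed at the foot of the contraction limb so the
    # optimal phase stays near 0 regardless of the absolute time origin and
    # of where omega moves during the optimization.
    t_ref = float(t[0]) if t_rise_center is None else float(t_rise_center)
    tau = t - t_ref
    if weights is None:
        sqrt_w = np.ones_like(t)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != t.shape or np.any(weights < 0):
            raise FitWindowError("weights must be non-negative and match samples")
        sqrt_w = np.sqrt(weights)

    def residuals(theta: np.ndarray) -> np.ndarray:
        pa, pb, w, phi = theta
        return sqrt_w * (pa + 0.5 * pb * (1.0 - np.cos(w * tau + phi)) - p)

    w_lo, w_hi = omega_bounds if omega_bounds is not None else (1e-3, 20.0 * np.pi)
    f_lo, f_hi = phi_bounds if phi_bounds is not None else (-2.0 * np.pi, 2.0 * np.pi)
    lower = [-100.0, 1e-6, w_lo, f_lo]
    upper = [400.0, 800.0, w_hi, f_hi]
    x0 = np.clip(
        [p_lo, amp0, omega_init, 0.0],
        np.asarray(lower) + 1e-12,
        np.asarray(upper) - 1e-12,
    )
    try:
        sol = least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=500 * 4,
        )
        opt_ok = sol.success
        pa, pb, w, phi = sol.x
        res = sol.fun
    except Exception:
        opt_ok = False
        pa, pb, w, phi = x0
        res = residuals(x0)
    # report the phase in the caller's time frame
    phi = phi - w * t_ref
    res = pa + 0.5 * pb * (1.0 - np.cos(w * t + phi)) - p  # unweighted, mmHg

    pisomax = float(pa + pb)
    if pisomax > pisomax_ceiling:
        raise FitError(
            f"implausible isovolumic peak {pisomax:.1f} mmHg "
            f"(ceiling {pisomax_ceiling:.0f} mmHg)"
        )
    converged = bool(opt_ok)
    if lvp_max is not None and pisomax < lvp_max:
        converged = False
    if pisomax < float(np.max(p)):
        converged = False
    return IsovolumicFit(
        baseline=float(pa),
        amplitude=float(pb),
        angular_frequency=float(w),
        phase=float(phi),
        pisomax=pisomax,
        rms_residual=float(np.sqrt(np.mean(res**2))),
        n_fit_samples=len(t),
        converged=converged,
    )


def fit_beat_isovolumic(
    beat: BeatSegment,
    landmarks: FlowLandmarks,
    trace: PressureTrace,
    d1: DerivativeTrace,
    *,
    relax_weight: float = DEFAULT_RELAXATION_WEIGHT,
    relax_scale: float = 1.0,
    pisomax_ceiling: float = DEFAULT_PISOMAX_CEILING,
) -> IsovolumicFit:
    """Select limbs for a beat and fit the isovolumic sinusoid.

    Convenience wrapper used by the per-beat pipeline: limb selection per
    :func:`select_isovolumic_samples`, initialization of the angular
    frequency from the dP/dt-max-to-min interval.

    ``relax_scale`` multiplies the relaxation-limb pressures before the
    fit.  During isovolumic relaxation the ventricle holds its end-systolic
    rather than end-diastolic volume, so those pressures run a factor
    (Veed - SV)/Veed below the end-diastolic isovolumic envelope; the
    caller can undo the depression using the loop's own Veed estimate
    (see :func:`pvbeat.mechanics.analyze_beat`).
    """
    contraction, relaxation = select_isovolumic_samples(beat, landmarks, trace, d1)
    idx = np.concatenate([contraction, relaxation])
    pressures = trace.pressure[idx].copy()
    if relax_scale != 1.0:
        pressures[len(contraction):] *= relax_scale
    # per-limb aggregate weights, independent of sample counts
    weights = np.concatenate(
        [
            np.full(len(contraction), 1.0 / len(contraction)),
            np.full(len(relaxation), relax_weight / len(relaxation)),
        ]
    )
    t0 = trace.time[beat.start_index]
    t_half = (beat.dpdt_min_index - beat.dpdt_max_index) / trace.sampling_rate
    omega0 = np.pi / max(t_half, 1e-3)
    fit = fit_isovolumic_pressure(
        trace.time[idx] - t0,
        pressures,
        lvp_max=beat.lvp_max,
        edp=beat.edp,
        omega_init=omega0,
        t_rise_center=float(trace.time[beat.ed_index] - t0),
        weights=weights,
        # the dP/dt-extrema interval approximates the isovolumic half
        # period well; leaving omega free makes the short limbs' fit
        # ill-conditioned, so it is boxed around that estimate, and the
        # phase is boxed so the sinusoid trough stays near end-diastole
        omega_bounds=(0.6 * omega0, 1.7 * omega0),
        phi_bounds=(-1.2, 1.2),
        pisomax_ceiling=pisomax_ceiling,
    )
    return fit
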