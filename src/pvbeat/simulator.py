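"""Forward model of a pressure-overloaded left ventricle.

Generates synthetic LV pressure beats with *known* ground truth so the
single-beat estimation chain can be validated end to end.  The model is the
standard lumped circulation used for this purpose:

* a time-varying elastance ventricle, ``P_lv = E(t) (V - V0)`` with a
  double-Hill activation waveform ``e(t)`` normalized to peak 1, so the
  end-systolic elastance truly equals ``emax``;
* a stenotic aortic valve obeying a quadratic orifice law,
  ``dP = B Q^2``, in series with a blood-column inertance ``L`` that gives
  the physiological sharp end of ejection (without it the square-root
  orifice law sustains a long unphysiological flow tail at tiny
  gradients) — valve replacement is modeled as reducing ``B`` only,
  isolating the valvular component of afterload;
* a 3-element Windkessel afterload (characteristic resistance ``Zc``,
  peripheral resistance ``Rp``, compliance ``C``);
* constant-pressure left atrium filling through a linear mitral
  resistance.

Integration is fixed-step classical Runge-Kutta at >= 5 kHz; the model is
run to periodic steady state (peak-pressure change < 0.1% between cycles,
at least 10 cycles) before a beat is emitted.  A clamped-valve mode
re-runs the steady-state cycle with the aortic valve sealed, yielding the
true isovolumic peak pressure that the curve-fit extrapolation is supposed
to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import SimulationError
from .signal import PressureTrace

__all__ = [
    "SimulatorParams",
    "SimulatedBeat",
    "simulate_beat",
    "simulate_isovolumic_truth",
    "simulate_cohort",
    "severe_as_params",
    "post_tavi_params",
    "write_trace_csv",
    "PRESETS",
]


@dataclass(frozen=True)
class SimulatorParams:
    """Lumped-parameter model inputs.

    Units: elastances mmHg/mL, volumes mL, resistances mmHg*s/mL,
    compliance mL/mmHg, valve coefficient ``valve_b`` mmHg*s^2/mL^2,
    pressures mmHg, rates Hz / beats/min, time constants s.

    ``activation`` selects the normalized activation waveform e(t):

    ``"two-segment-cosine"`` (default)
        Half-cosine rise over ``rise_fraction * T`` followed by a faster
        half-cosine fall over ``fall_fraction * T``, then zero in diastole.
        Each limb of the isovolumic pressure wave is exactly sinusoidal —
        the regime in which the single-beat sinusoid extrapolation is well
        posed — while the quicker fall reproduces the physiological timing
        in which peak elastance (end systole) comes shortly before aortic
        valve closure.
    ``"raised-cosine"``
        e(t) = (1 - cos(2 pi t / Ts)) / 2 on [0, Ts], 0 in diastole, with
        systole Ts = ``systolic_fraction`` * T: the symmetric special case
        of the above.
    ``"double-hill"``
        The product-of-Hill-functions waveform common in hemodynamic
        models; ``tau1``/``tau2`` default to 0.27 and 0.45 of the cycle
        length when left as None.  Its rise and decay are asymmetric, which
        degrades the sinusoid extrapolation — useful for robustness
        studies.
    """

    emax: float = 2.4
    emin: float = 0.08
    v0: float = 10.0
    hr: float = 70.0
    activation: str = "two-segment-cosine"
    systolic_fraction: float = 0.6
    rise_fraction: float = 0.30
    fall_fraction: float = 0.26
    tau1: float | None = None
    n1: float = 1.9
    tau2: float | None = None
    n2: float = 21.9
    valve_b: float = 1.2e-3
    valve_l: float = 8e-4
    zc: float = 0.06
    rp: float = 1.6
    c: float = 0.6
    p_la: float = 15.0
    r_mv: float = 0.06
    noise_sd: float = 1.0
    sampling_rate: float = 1000.0
    seed: int = 0
    internal_hz: float = 5000.0
    n_cycles_out: int = 8
    min_cycles: int = 10
    max_cycles: int = 50

    def __post_init__(self) -> None:
        if not (self.emax > self.emin > 0):
            raise SimulationError("need emax > emin > 0")
        if self.hr <= 0:
            raise SimulationError("heart rate must be positive")
        for name in ("valve_b", "zc", "rp", "c", "r_mv"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if self.internal_hz < 5000.0:
            raise SimulationError("internal integration rate must be >= 5 kHz")

    @property
    def period(self) -> float:
        return 60.0 / self.hr


@dataclass
class SimulatedBeat:
    """One steady-state beat plus its ground truth.

    ``trace`` holds ``n_cycles_out`` tiled copies of the steady-state cycle
    with seeded Gaussian noise on pressure; ``true_flow`` (mL/s) and
    ``true_volume`` (mL) are the noiseless aortic flow and LV volume
    co-indexed with the trace samples.  ``truth`` records per-cycle scalars:
    ``pisomax_true``, ``sv_true``, ``pes_true`` (LV pressure at the instant
    of maximal elastance, i.e. end systole), ``ea_true = pes/sv``,
    ``emax``, ``valve_open_time`` / ``valve_close_time`` / ``t_es`` (s from
    cycle start), ``edv_true``, ``lvp_max_true`` and ``cycle_duration``.
    """

    trace: PressureTrace
    true_flow: np.ndarray
    true_volume: np.ndarray
    truth: dict
    params: SimulatorParams


def _activation_grid(params: SimulatorParams, n_half: int) -> np.ndarray:
    """Normalized activation e(t) on a grid of ``n_half`` points spanning
    one period (peak exactly 1, so end-systolic elastance equals emax)."""
    T = params.period
    t = np.linspace(0.0, T, n_half)
    if params.activation == "two-segment-cosine":
        a = params.rise_fraction * T
        bseg = params.fall_fraction * T
        if not (0.1 * T <= a <= 0.6 * T) or not (0.05 * T <= bseg <= 0.6 * T):
            raise SimulationError("rise/fall fractions out of the sane range")
        if a + bseg > 0.9 * T:
            raise SimulationError("systole longer than 90% of the cycle")
        e = np.zeros_like(t)
        rise = t <= a
        e[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / a))
        fall = (t > a) & (t <= a + bseg)
        e[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - a) / bseg))
        return e
    if params.activation == "raised-cosine":
        ts = params.systolic_fraction * T
        if not (0.2 * T <= ts <= 0.8 * T):
            raise SimulationError("systolic_fraction out of the sane range")
        e = np.where(t <= ts, 0.5 * (1.0 - np.cos(2.0 * np.pi * t / ts)), 0.0)
        return e
    if params.activation == "double-hill":
        tau1 = params.tau1 if params.tau1 is not None else 0.27 * T
        tau2 = params.tau2 if params.tau2 is not None else 0.45 * T
        g1 = (t / tau1) ** params.n1
        rise = g1 / (1.0 + g1)
        decay = 1.0 / (1.0 + (t / tau2) ** params.n2)
        e = rise * decay
        peak = np.max(e)
        if peak <= 0:
            raise SimulationError("degenerate activation waveform")
        return e / peak
    raise SimulationError(f"unknown activation waveform '{params.activation}'")


def _aortic_flow(p_lv: float, p_c: float, b: float, zc: float) -> float:
    """Flow through valve + characteristic resistance for a driving
    pressure p_lv against Windkessel pressure p_c; 0 when the valve is
    closed (p_lv <= p_c)."""
    dp = p_lv - p_c
    if dp <= 0.0:
        return 0.0
    if b > 0.0:
        return (-zc + math.sqrt(zc * zc + 4.0 * b * dp)) / (2.0 * b)
    if zc > 0.0:
        return dp / zc
    raise SimulationError("valve_b and zc cannot both be zero")


def _simulate_cycles(params: SimulatorParams, sealed_valve: bool = False):
    """Integrate to steady state; return (time grid, per-step arrays of the
    emitted cycle, initial state of that cycle, step)."""
    T = params.period
    n_steps = max(int(round(T * params.internal_hz)), 100)
    h = T / n_steps
    e_half = _activation_grid(params, 2 * n_steps + 1)
    emin, emax = params.emin, params.emax
    de = emax - emin
    b, zc, rp, c = params.valve_b, params.zc, params.rp, params.c
    L = params.valve_l
    p_la, r_mv, v0 = params.p_la, params.r_mv, params.v0

    def deriv(v: float, pc: float, q: float, e_act: float, open_: bool):
        E = emin + de * e_act
        p_lv = E * (v - v0)
        if sealed_valve or not open_:
            q_av, dq = 0.0, 0.0
        elif L > 0.0:
            q_av = q
            dq = (p_lv - pc - zc * q - b * q * q) / L
        else:
            q_av = _aortic_flow(p_lv, pc, b, zc)
            dq = 0.0
        q_mv = (p_la - p_lv) / r_mv if p_la > p_lv else 0.0
        dv = q_mv - q_av
        dpc = (q_av - pc / rp) / c
        return dv, dpc, dq, p_lv, q_av

    # initial state: ventricle at a plausible filling volume, Windkessel at
    # diastolic arterial pressure, valve closed
    v, pc, q = v0 + 100.0, 80.0, 0.0

    def run_cycle(v: float, pc: float, q: float, record: bool):
        p_arr = q_arr = v_arr = None
        if record:
            p_arr = np.empty(n_steps + 1)
            q_arr = np.empty(n_steps + 1)
            v_arr = np.empty(n_steps + 1)
        peak = -math.inf
        open_ = q > 0.0
        for i in range(n_steps):
            e0, e1, e2 = e_half[2 * i], e_half[2 * i + 1], e_half[2 * i + 2]
            k1v, k1p, k1q, p_lv, q_av = deriv(v, pc, q, e0, open_)
            if not sealed_valve and not open_ and p_lv > pc:
                open_ = True
                k1v, k1p, k1q, p_lv, q_av = deriv(v, pc, q, e0, open_)
            if record:
                p_arr[i] = p_lv
                q_arr[i] = q_av
                v_arr[i] = v
            if p_lv > peak:
                peak = p_lv
            k2v, k2p, k2q, _, _ = deriv(
                v + 0.5 * h * k1v, pc + 0.5 * h * k1p, q + 0.5 * h * k1q, e1, open_
            )
            k3v, k3p, k3q, _, _ = deriv(
                v + 0.5 * h * k2v, pc + 0.5 * h * k2p, q + 0.5 * h * k2q, e1, open_
            )
            k4v, k4p, k4q, _, _ = deriv(
                v + h * k3v, pc + h * k3p, q + h * k3q, e2, open_
            )
            v += (h / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            pc += (h / 6.0) * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
            if open_ and L > 0.0:
                q += (h / 6.0) * (k1q + 2.0 * k2q + 2.0 * k3q + k4q)
                if q <= 0.0:  # flow momentum exhausted: valve closes
                    q = 0.0
                    open_ = False
            elif open_ and L == 0.0:
                # algebraic valve: closed again as soon as the gradient ends
                E_now = emin + de * e_half[2 * i + 2]
                if E_now * (v - v0) <= pc:
                    open_ = False
        if record:
            _, _, _, p_lv, q_av = deriv(v, pc, q, e_half[-1], open_)
            p_arr[n_steps] = p_lv
            q_arr[n_steps] = q_av
            v_arr[n_steps] = v
        return v, pc, q, peak, (p_arr, q_arr, v_arr)

    prev_peak = None
    for cycle in range(params.max_cycles):
        v, pc, q, peak, _ = run_cycle(v, pc, q, record=False)
        converged = (
            prev_peak is not None
            and abs(peak - prev_peak) < 1e-3 * abs(peak)
            and cycle + 1 >= params.min_cycles
        )
        prev_peak = peak
        if converged:
            break
    else:
        raise SimulationError(
            f"no periodic steady state within {params.max_cycles} cycles"
        )
    # emit the next full cycle
    state0 = (v, pc)
    _, _, _, _, arrays = run_cycle(v, pc, q, record=True)
    t = np.arange(n_steps + 1) * h
    return t, arrays, state0, h


def simulate_beat(params: SimulatorParams) -> SimulatedBeat:
    """Run the circulation to steady state and emit one beat with truth.

    The emitted :class:`PressureTrace` contains ``params.n_cycles_out``
    tiled copies of the steady-state cycle, resampled to
    ``params.sampling_rate`` with seeded Gaussian noise of SD
    ``params.noise_sd`` mmHg added to pressure last.
    """
    t_dense, (p_dense, q_dense, v_dense), state0, h = _simulate_cycles(params)
    T = params.period

    sv_true = float(np.trapezoid(q_dense, t_dense))
    open_idx = np.flatnonzero(q_dense > 0.0)
    # end systole = instant of maximal elastance (peak activation)
    n_act = len(t_dense)
    e_act = _activation_grid(params, n_act)
    i_es = int(np.argmax(e_act))
    t_es = float(t_dense[i_es])
    pes_true = float(p_dense[i_es])
    ea_true = pes_true / sv_true if sv_true > 0 else float("nan")
    if len(open_idx) == 0:
        valve_open = valve_close = float("nan")
        pes_true = ea_true = float("nan")
    else:
        valve_open = float(t_dense[open_idx[0]])
        valve_close = float(t_dense[open_idx[-1]])
    edv_true = float(v_dense[0])
    pisomax_true = _isovolumic_peak(params, state0)

    # resample the dense cycle to the output rate and tile it
    fs = params.sampling_rate
    n_per = int(round(T * fs))
    t_cycle = np.arange(n_per) / fs
    p_cycle = np.interp(t_cycle, t_dense, p_dense)
    q_cycle = np.interp(t_cycle, t_dense, q_dense)
    v_cycle = np.interp(t_cycle, t_dense, v_dense)
    k = params.n_cycles_out
    time = np.arange(k * n_per) / fs
    pressure = np.tile(p_cycle, k)
    flow = np.tile(q_cycle, k)
    volume = np.tile(v_cycle, k)
    rng = np.random.default_rng(params.seed)
    noisy = pressure + rng.normal(0.0, params.noise_sd, size=pressure.shape)

    trace = PressureTrace(
        time=time,
        pressure=noisy,
        sampling_rate=fs,
        source_id=f"sim(seed={params.seed},hr={params.hr:g})",
    )
    truth = {
        "pisomax_true": pisomax_true,
        "sv_true": sv_true,
        "pes_true": pes_true,
        "ea_true": ea_true,
        "emax": params.emax,
        "valve_open_time": valve_open,
        "valve_close_time": valve_close,
        "t_es": t_es,
        "edv_true": edv_true,
        "lvp_max_true": float(np.max(p_dense)),
        "cycle_duration": T,
        "co_true": sv_true * params.hr / 1000.0,
    }
    return SimulatedBeat(
        trace=trace, true_flow=flow, true_volume=volume, truth=truth, params=params
    )


def _isovolumic_peak(params: SimulatorParams, state0: tuple[float, float]) -> float:
    """Peak pressure of one cycle re-run from the same end-diastolic state
    with the aortic valve sealed."""
    T = params.period
    n_steps = max(int(round(T * params.internal_hz)), 100)
    h = T / n_steps
    e_half = _activation_grid(params, 2 * n_steps + 1)
    emin, de = params.emin, params.emax - params.emin
    p_la, r_mv, v0 = params.p_la, params.r_mv, params.v0
    v, _pc = state0
    peak = -math.inf
    for i in range(n_steps):

        def dv_dt(vv: float, e_act: float) -> tuple[float, float]:
            p_lv = (emin + de * e_act) * (vv - v0)
            q_mv = (p_la - p_lv) / r_mv if p_la > p_lv else 0.0
            return q_mv, p_lv

        e0, e1, e2 = e_half[2 * i], e_half[2 * i + 1], e_half[2 * i + 2]
        k1, p_lv = dv_dt(v, e0)
        peak = max(peak, p_lv)
        k2, _ = dv_dt(v + 0.5 * h * k1, e1)
        k3, _ = dv_dt(v + 0.5 * h * k2, e1)
        k4, _ = dv_dt(v + h * k3, e2)
        v += (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return float(peak)


def simulate_isovolumic_truth(params: SimulatorParams) -> float:
    """True isovolumic peak pressure (mmHg) of the steady-state beat.

    Re-runs the steady-state cycle from the same end-diastolic volume with
    the aortic valve disabled; since the mitral valve closes as soon as
    pressure rises, the ventricle contracts isovolumically and the peak is
    essentially ``emax * (EDV - V0)``.
    """
    _, _, state0, _ = _simulate_cycles(params)
    return _isovolumic_peak(params, state0)


def severe_as_params(**overrides) -> SimulatorParams:
    """Preset emulating a severe-aortic-stenosis ventricle: high valvular
    afterload, preserved contractility."""
    return replace(SimulatorParams(), **overrides)


def post_tavi_params(base: SimulatorParams | None = None, tavi_effect: float = 0.2,
                     **overrides) -> SimulatorParams:
    """Post-valve-replacement state: the valve coefficient B is multiplied
    by ``tavi_effect`` (default 5-fold reduction); all ventricular and
    arterial parameters are untouched."""
    if not (0 < tavi_effect < 1):
        raise SimulationError("tavi_effect must be in (0, 1)")
    base = base if base is not None else SimulatorParams()
    return replace(base, valve_b=base.valve_b * tavi_effect, **overrides)


PRESETS = {
    "severe-as": severe_as_params,
    "post-tavi": lambda **kw: post_tavi_params(**kw),
}


def simulate_cohort(
    n: int,
    tavi_effect: float = 0.2,
    seed: int = 0,
    emax_range: tuple[float, float] = (1.5, 3.5),
    valve_b_range: tuple[float, float] = (0.8e-3, 1.8e-3),
    hr_range: tuple[float, float] = (55.0, 95.0),
    p_la_range: tuple[float, float] = (12.0, 22.0),
    noise_sd: float = 1.0,
) -> list[dict]:
    """Simulate ``n`` paired pre/post-intervention acquisitions.

    Each subject draws contractility, valve severity, heart rate and
    filling pressure from the stated ranges (one seeded generator drives
    every draw); the post state differs only by ``valve_b`` scaled with
    ``tavi_effect``.  Returns a list of dicts with keys ``subject``,
    ``params_pre``, ``params_post``, ``pre``, ``post`` (the two
    :class:`SimulatedBeat`).
    """
    if n < 2:
        raise SimulationError("cohort needs n >= 2")
    if not (0 < tavi_effect < 1):
        raise SimulationError("tavi_effect must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        draw = {
            "emax": float(rng.uniform(*emax_range)),
            "valve_b": float(rng.uniform(*valve_b_range)),
            "hr": float(rng.uniform(*hr_range)),
            "p_la": float(rng.uniform(*p_la_range)),
            "noise_sd": noise_sd,
            "seed": int(rng.integers(0, 2**31 - 1)),
        }
        pre_params = severe_as_params(**draw)
        post_params = post_tavi_params(pre_params, tavi_effect=tavi_effect,
                                       seed=int(rng.integers(0, 2**31 - 1)))
        out.append(
            {
                "subject": i,
                "params_pre": pre_params,
                "params_post": post_params,
                "pre": simulate_beat(pre_params),
                "post": simulate_beat(post_params),
            }
        )
    return out


def write_trace_csv(beat: SimulatedBeat, path) -> None:
    """Export a simulated trace in the dialect ``read_trace`` accepts."""
    df = pd.DataFrame(
        {"time_s": beat.trace.time, "pressure_mmhg": beat.trace.pressure}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_truth_csv(cohort: list[dict], path) -> None:
    """Export per-subject truth values of a simulated cohort."""
    rows = []
    for rec in cohort:
        for arm in ("pre", "post"):
            row = {"subject": rec["subject"], "arm": arm}
            row.update(rec[arm].truth)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")
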