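"""Pressure-ejected-volume loop construction and scalar LV mechanics.

Because absolute LV volume is never measured, the loop lives in *ejected
volume* coordinates: V = 0 until the aortic valve opens, rises to the
stroke volume during ejection, and stays there through isovolumic
relaxation.  On that loop:

* **Ees** (end-systolic elastance, mmHg/mL) is the magnitude of the slope
  of the shallowest line anchored at (0, Pisomax) that still touches the
  ejection path — the discrete tangent from the isovolumic peak;
* the touching sample is the **end-systolic equilibrium point**
  (V_es, P_es), and **Ea** = P_es / V_es is the effective arterial
  elastance (stenotic valve included);
* **Veed** = Pisomax / Ees is the x-intercept of the Ees line, i.e. the
  end-diastolic volume in excess of the unstressed volume V0;
* **SW** is the area under the ejection path, **PVA** the triangle bounded
  by the Ees line and the axes, and SW/PVA the mechanical efficiency;
* **Q_load** = 4k / (1 + k)^2 with k = Ea/Ees is the fraction of the
  theoretically maximal external work actually extracted (1 at k = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DataError,
    DomainError,
    GeometryError,
    PVBeatError,
    TangencyError,
    FitError,
)
from .flow import (
    FlowLandmarks,
    build_triangular_flow,
    cumulative_ejected_volume,
    detect_flow_landmarks,
    stroke_volume_from_co,
)
from .isovolumic import fit_beat_isovolumic
from .signal import BeatSegment, PressureTrace, nth_derivative

__all__ = [
    "PVLoop",
    "EquilibriumPoint",
    "MechanicsReport",
    "PairedComparison",
    "RejectionRecord",
    "TraceReport",
    "build_pv_loop",
    "estimate_ees",
    "estimate_ea",
    "compute_veed",
    "compute_stroke_work",
    "compute_pva",
    "q_load",
    "analyze_beat",
    "analyze_trace",
    "paired_compare",
    "TABLE_VARIABLES",
]

#: Minimum ejected volume (mL) for a sample to enter the tangency scan;
#: avoids slope blow-up at the very start of ejection.
EES_VOLUME_EPS = 0.5

#: Relative slope tolerance when locating the equilibrium point: all
#: ejection samples whose anchored slope is within this fraction of the
#: minimum count as touching the tangent line, and the touching sample
#: with the largest ejected volume is reported.  The loop hugs the line
#: over a broad arc, and the slope resolution is dominated by the
#: uncertainty of the extrapolated isovolumic peak (a few per cent of
#: Pisomax maps to roughly ten per cent of the anchored slope).
EES_SLOPE_TOL = 0.10

#: Population-prior effective end-diastolic volume (mL) used to size the
#: relaxation-limb depression correction rho = Veed0 / (Veed0 - SV).
#: During isovolumic relaxation the ventricle holds its end-systolic
#: volume, so its pressures run a factor (Veed - SV)/Veed below the
#: end-diastolic isovolumic envelope that the sinusoid extrapolates.  The
#: true Veed of the beat is not identifiable from one pressure trace plus
#: stroke volume (estimating it from the fit's own output is a gain-one
#: feedback loop with no stable fixed point), so a fixed population prior
#: is used; severe-AS cohorts put the effective end-diastolic volume near
#: 130-140 mL.  The correction therefore adapts with the measured stroke
#: volume, which dominates the between-subject variation of the ratio.
VEED_PRIOR_ML = 140.0

#: Bounds on the depression correction.
RELAX_CORRECTION_MIN = 1.0
RELAX_CORRECTION_CAP = 2.5

#: The hemodynamic variables reported in pre/post comparisons.
TABLE_VARIABLES = (
    "ea",
    "ees",
    "ea_over_ees",
    "q_load",
    "veed",
    "sw",
    "pva",
    "sw_over_pva",
    "lvp_es",
    "lvp_max",
    "pisomax",
    "sv",
)


@dataclass
class PVLoop:
    """Pressure vs ejected volume for one beat.

    ``ejected_volume`` is non-decreasing in time (0 before ejection, SV
    after); ``ejection_mask`` flags the samples between flow onset and
    termination, the only part of the loop with horizontal extent.
    """

    ejected_volume: np.ndarray
    pressure: np.ndarray
    ejection_mask: np.ndarray
    beat_id: str = ""

    def __post_init__(self) -> None:
        self.ejected_volume = np.asarray(self.ejected_volume, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.ejection_mask = np.asarray(self.ejection_mask, dtype=bool)
        n = len(self.ejected_volume)
        if len(self.pressure) != n or len(self.ejection_mask) != n:
            raise DataError("loop arrays have mismatched lengths")
        if np.any(np.diff(self.ejected_volume) < -1e-9):
            raise DataError("ejected volume must be non-decreasing in time")
        if np.any(self.pressure[self.ejection_mask] < 0):
            raise DataError("negative pressure on the ejection path")

    @property
    def stroke_volume(self) -> float:
        return float(self.ejected_volume[-1])


@dataclass(frozen=True)
class EquilibriumPoint:
    """End-systolic equilibrium point (ejected volume mL, pressure mmHg)."""

    v_es: float
    p_es: float


@dataclass
class MechanicsReport:
    """Per-beat scalar mechanics.  Units: elastances mmHg/mL, volumes mL,
    pressures mmHg, work/area mmHg*mL; ``q_load`` and ``sw_over_pva`` are
    dimensionless fractions in (0, 1]."""

    ees: float
    ea: float
    ea_over_ees: float
    q_load: float
    veed: float
    sw: float
    pva: float
    sw_over_pva: float
    lvp_es: float
    lvp_max: float
    pisomax: float
    sv: float
    hr: float
    co: float
    beat_id: str = ""

    def __post_init__(self) -> None:
        if not (self.ees > 0 and self.ea > 0):
            raise DomainError("elastances must be positive")
        if not (0 < self.q_load <= 1 + 1e-12):
            raise DomainError(f"q_load out of (0, 1]: {self.q_load}")
        if not (0 < self.sw <= self.pva * (1 + 1e-9)):
            raise DomainError("stroke work must satisfy 0 < SW <= PVA")
        if abs(self.veed * self.ees - self.pisomax) > 1e-6 * self.pisomax:
            raise DomainError("Veed * Ees != Pisomax")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


@dataclass(frozen=True)
class RejectionRecord:
    """Why a beat produced no numbers.  ``stage`` names the pipeline step."""

    beat_index: int
    stage: str
    reason: str


@dataclass
class TraceReport:
    """Per-acquisition result: accepted beat reports, rejections, and the
    per-trace summary (median across accepted beats)."""

    beats: list[MechanicsReport]
    rejections: list[RejectionRecord]
    co: float
    hr: float
    source_id: str = ""
    loops: dict = field(default_factory=dict)

    @property
    def n_accepted(self) -> int:
        return len(self.beats)

    def summary(self) -> dict:
        if not self.beats:
            raise DataError("no accepted beats to summarize")
        out = {}
        for name in TABLE_VARIABLES + ("hr", "co"):
            out[name] = float(np.median([getattr(b, name) for b in self.beats]))
        out["n_beats"] = len(self.beats)
        out["n_rejected"] = len(self.rejections)
        return out


def build_pv_loop(
    pressure: np.ndarray,
    ejected_volume: np.ndarray,
    ejection_mask: np.ndarray | None = None,
    beat_id: str = "",
) -> PVLoop:
    """Assemble the pressure-ejected-volume loop from co-sampled series.

    When ``ejection_mask`` is omitted it is derived from where the volume
    series actually changes (plus the bracketing samples).
    """
    p = np.asarray(pressure, dtype=float)
    v = np.asarray(ejected_volume, dtype=float)
    if p.shape != v.shape:
        raise DataError("pressure and volume series have mismatched lengths")
    if ejection_mask is None:
        dv = np.diff(v)
        changing = np.flatnonzero(dv > 0)
        mask = np.zeros(len(v), dtype=bool)
        if len(changing):
            mask[changing[0] : changing[-1] + 2] = True
        ejection_mask = mask
    return PVLoop(ejected_volume=v, pressure=p, ejection_mask=ejection_mask, beat_id=beat_id)


def estimate_ees(loop: PVLoop, pisomax: float) -> tuple[float, EquilibriumPoint]:
    """End-systolic elastance by discrete tangency from the isovolumic peak.

    Scans every ejection sample with V > ``EES_VOLUME_EPS`` and returns the
    minimum of (Pisomax - P_i) / V_i — the shallowest line from
    (0, Pisomax) that still touches the loop.  The equilibrium point is the
    touching sample with the largest ejected volume, where "touching" means
    a slope within ``EES_SLOPE_TOL`` of the minimum (the loop typically
    hugs the tangent over an arc, and exact ties are meaningless under
    catheter noise).  The returned line lies on or above every scanned
    sample by construction.
    """
    v = loop.ejected_volume[loop.ejection_mask]
    p = loop.pressure[loop.ejection_mask]
    keep = v > EES_VOLUME_EPS
    v, p = v[keep], p[keep]
    if len(v) < 3:
        raise GeometryError("ejection path has fewer than 3 usable samples")
    if pisomax <= float(np.max(p)):
        raise TangencyError(
            f"isovolumic peak {pisomax:.1f} mmHg does not exceed the maximum "
            f"ejection pressure {np.max(p):.1f} mmHg"
        )
    slopes = (pisomax - p) / v
    m = float(np.min(slopes))
    candidates = np.flatnonzero(slopes <= m * (1.0 + EES_SLOPE_TOL))
    i = int(candidates[np.argmax(v[candidates])])
    return m, EquilibriumPoint(v_es=float(v[i]), p_es=float(p[i]))


def estimate_ea(eq: EquilibriumPoint) -> float:
    """Effective arterial elastance: slope from the origin to the
    end-systolic equilibrium point, Ea = P_es / V_es (mmHg/mL)."""
    if eq.v_es == 0:
        raise GeometryError("equilibrium point at zero ejected volume")
    return eq.p_es / eq.v_es


def compute_veed(pisomax: float, ees: float) -> float:
    """Effective end-diastolic volume: x-intercept of the Ees line,
    Veed = Pisomax / Ees (mL).  Equals LVEDV - V0; V0 itself is never
    estimated."""
    if ees <= 0:
        raise DomainError("ees must be positive")
    return pisomax / ees


def compute_stroke_work(loop: PVLoop) -> float:
    """Stroke work: trapezoidal area under pressure over the ejection path
    (mmHg*mL).  The isovolumic legs have zero width and contribute nothing;
    filling work is not measurable in ejected-volume coordinates."""
    v = loop.ejected_volume[loop.ejection_mask]
    p = loop.pressure[loop.ejection_mask]
    if len(v) < 2 or v[-1] - v[0] <= 0:
        raise GeometryError("degenerate ejection path")
    if np.any(np.diff(v) < -1e-9):
        raise DataError("ejected volume non-monotone on the ejection path")
    return float(np.trapezoid(p, v))


def compute_pva(pisomax: float, veed: float) -> float:
    """Pressure-volume area: the triangle with vertices (0, 0),
    (0, Pisomax), (Veed, 0), i.e. PVA = Pisomax * Veed / 2 = Pisomax^2 /
    (2 Ees) (mmHg*mL) — the total mechanical energy of the beat."""
    if pisomax <= 0 or veed <= 0:
        raise DomainError("pisomax and veed must be positive")
    return 0.5 * pisomax * veed


def q_load(ea_over_ees: float) -> float:
    """Load-transfer index Q_load = 4k / (1 + k)^2, k = Ea/Ees.

    The fraction of the theoretically maximal external work extracted from
    the ventricle; its ideal value is 1.0, attained exactly at k = 1, and
    it is symmetric under k <-> 1/k.
    """
    k = float(ea_over_ees)
    if k <= 0:
        raise DomainError(f"Ea/Ees must be positive, got {k}")
    return 4.0 * k / (1.0 + k) ** 2


def analyze_beat(
    trace: PressureTrace,
    beat: BeatSegment,
    co: float,
    hr: float,
    config: Mapping | None = None,
    beat_id: str = "",
    landmarks: FlowLandmarks | None = None,
    loop_sink: dict | None = None,
) -> MechanicsReport:
    """Run the full single-beat chain and return the mechanics report.

    Chain: 4th derivative -> flow landmarks -> triangular flow scaled to
    SV = 1000 CO / HR -> isovolumic sinusoid fit -> pressure-ejected-volume
    loop -> tangency (Ees, equilibrium point) -> Ea, Q_load, Veed, SW, PVA.
    Any stage failure raises a :class:`~pvbeat.errors.PVBeatError` whose
    ``stage`` attribute labels the failing step; callers convert those into
    rejection records rather than partial numbers.
    """
    cfg = dict(config or {})
    smoothing = cfg.get("smoothing")
    pisomax_ceiling = cfg.get("pisomax_ceiling", 500.0)

    sv = stroke_volume_from_co(co, hr)
    d1 = nth_derivative(trace, 1, smoothing)
    if landmarks is None:
        d4 = nth_derivative(trace, 4, smoothing)
        landmarks = detect_flow_landmarks(beat, d4, trace)

    t0 = trace.time[beat.start_index]
    beat_times = trace.time[beat.start_index : beat.end_index] - t0
    tri = build_triangular_flow(landmarks, sv, beat_times)
    volume = cumulative_ejected_volume(tri)
    mask = (beat_times >= landmarks.onset_time) & (beat_times <= landmarks.termination_time)
    loop = build_pv_loop(
        trace.pressure[beat.start_index : beat.end_index],
        volume,
        ejection_mask=mask,
        beat_id=beat_id,
    )
    if loop_sink is not None:
        loop_sink[beat_id] = loop

    # Isovolumic fit with the volume-depression correction of the
    # relaxation limb: the ventricle relaxes at its end-systolic volume,
    # so the limb is lifted by rho = Veed0 / (Veed0 - SV) back onto the
    # end-diastolic envelope, with Veed0 a population prior (see
    # VEED_PRIOR_ML).
    veed_prior = cfg.get("veed_prior_ml", VEED_PRIOR_ML)
    if sv.value < 0.8 * veed_prior:
        rho = veed_prior / (veed_prior - sv.value)
    else:
        rho = RELAX_CORRECTION_CAP
    rho = min(max(rho, RELAX_CORRECTION_MIN), RELAX_CORRECTION_CAP)
    fit = fit_beat_isovolumic(
        beat,
        landmarks,
        trace,
        d1,
        relax_scale=rho,
        pisomax_ceiling=pisomax_ceiling,
    )
    ees, eq = estimate_ees(loop, fit.pisomax)
    if not fit.converged:
        raise FitError(
            "isovolumic fit did not converge or extrapolated below the "
            "measured peak pressure"
        )
    ea = estimate_ea(eq)
    k = ea / ees
    veed = compute_veed(fit.pisomax, ees)
    sw = compute_stroke_work(loop)
    pva = compute_pva(fit.pisomax, veed)
    return MechanicsReport(
        ees=ees,
        ea=ea,
        ea_over_ees=k,
        q_load=q_load(k),
        veed=veed,
        sw=sw,
        pva=pva,
        sw_over_pva=sw / pva,
        lvp_es=eq.p_es,
        lvp_max=beat.lvp_max,
        pisomax=fit.pisomax,
        sv=sv.value,
        hr=hr,
        co=co,
        beat_id=beat_id,
    )


def analyze_trace(
    trace: PressureTrace,
    co: float,
    hr: float,
    config: Mapping | None = None,
) -> TraceReport:
    """Segment a trace into beats and analyze each one.

    Beats failing any stage are logged as rejection records; accepted beats
    are reported individually, with the per-trace value of each variable
    taken as the median across accepted beats (see :class:`TraceReport`).

    Flow landmarks are located on every beat and then *pooled*: each beat
    is analyzed with the median landmark times (as fractions of beat
    duration) across the trace.  The 4th-derivative signatures are the
    noisiest link in the chain, and on a steady recording the beats share
    their timing, so the pooled estimate is markedly more stable than any
    single beat's.
    """
    from .signal import resample_uniform, segment_beats, DEFAULT_TARGET_HZ

    cfg = dict(config or {})
    target_hz = cfg.get("target_hz", DEFAULT_TARGET_HZ)
    if trace.sampling_rate is None or abs(trace.sampling_rate - target_hz) > 1e-6:
        trace = resample_uniform(trace, target_hz)
    beats = segment_beats(trace, mode=cfg.get("segmentation_mode", "auto"),
                          smoothing=cfg.get("smoothing"))
    reports: list[MechanicsReport] = []
    rejections: list[RejectionRecord] = []
    loops: dict = {}

    d4 = nth_derivative(trace, 4, cfg.get("smoothing")) if beats else None
    fracs = []
    for beat in beats:
        try:
            lm = detect_flow_landmarks(beat, d4, trace)
        except PVBeatError:
            fracs.append(None)
            continue
        dur = beat.n_samples / trace.sampling_rate
        fracs.append((lm.onset_time / dur, lm.peak_time / dur, lm.termination_time / dur))
    good = [f for f in fracs if f is not None]
    pooled = tuple(float(np.median([g[j] for g in good])) for j in range(3)) if len(good) >= 2 else None

    for i, beat in enumerate(beats):
        lm_i = None
        if pooled is not None:
            dur = beat.n_samples / trace.sampling_rate
            try:
                lm_i = FlowLandmarks(pooled[0] * dur, pooled[1] * dur, pooled[2] * dur)
            except PVBeatError:
                lm_i = None
        try:
            reports.append(
                analyze_beat(trace, beat, co, hr, config=cfg,
                             beat_id=f"beat{i:03d}", landmarks=lm_i,
                             loop_sink=loops)
            )
        except PVBeatError as exc:
            loops.pop(f"beat{i:03d}", None)
            rejections.append(RejectionRecord(beat_index=i, stage=exc.stage, reason=str(exc)))
    return TraceReport(
        beats=reports, rejections=rejections, co=co, hr=hr,
        source_id=trace.source_id, loops=loops,
    )


@dataclass
class PairedComparison:
    """Paired pre/post statistics for one variable (post - pre differences,
    two-sided paired t test)."""

    variable: str
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    mean_difference: float
    t: float
    p: float
    n: int
    degenerate: bool = False


def _values(reports: Sequence, variable: str) -> np.ndarray:
    if len(reports) and isinstance(reports[0], (int, float, np.floating)):
        return np.asarray(reports, dtype=float)
    if len(reports) and isinstance(reports[0], Mapping):
        return np.asarray([r[variable] for r in reports], dtype=float)
    return np.asarray([getattr(r, variable) for r in reports], dtype=float)


def paired_compare(pre: Sequence, post: Sequence, variable: str) -> PairedComparison:
    """Paired t test of one variable between matched pre and post arms.

    ``pre`` and ``post`` may be sequences of :class:`MechanicsReport`,
    per-trace summary dicts, or plain numbers, in matching order.  The
    difference is taken post - pre.  When every pairwise difference is
    identical (zero variance) the result is flagged degenerate: t and p
    are undefined (NaN) unless the common difference is zero.
    """
    x = _values(pre, variable)
    y = _values(post, variable)
    if len(x) != len(y):
        raise DataError(f"unpaired lengths: {len(x)} pre vs {len(y)} post")
    n = len(x)
    if n < 2:
        raise DataError("need at least 2 pairs")
    d = y - x
    sd_d = float(np.std(d, ddof=1))
    degenerate = sd_d == 0.0
    if degenerate:
        t_stat, p_val = float("nan"), float("nan")
    else:
        res = stats.ttest_rel(y, x)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return PairedComparison(
        variable=variable,
        pre_mean=float(np.mean(x)),
        pre_sd=float(np.std(x, ddof=1)),
        post_mean=float(np.mean(y)),
        post_sd=float(np.std(y, ddof=1)),
        mean_difference=float(np.mean(d)),
        t=t_stat,
        p=p_val,
        n=n,
        degenerate=degenerate,
    )
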