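"""Loop construction, tangency, scalar mechanics and paired comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvbeat.errors import (
    DataError,
    DomainError,
    GeometryError,
    LandmarkError,
    TangencyError,
)
from pvbeat.mechanics import (
    EquilibriumPoint,
    analyze_trace,
    build_pv_loop,
    compute_pva,
    compute_stroke_work,
    compute_veed,
    estimate_ea,
    estimate_ees,
    paired_compare,
    q_load,
)


def _rect_loop(p=100.0, sv=50.0, n=60):
    v = np.concatenate([[0.0], np.linspace(0, sv, n), [sv]])
    pr = np.concatenate([[p / 2], np.full(n, p), [p / 2]])
    mask = np.zeros(len(v), bool)
    mask[1:-1] = True
    return build_pv_loop(pr, v, ejection_mask=mask)


def _linear_loop(n=201, sv=50.0):
    v = np.linspace(0, sv, n)
    pr = 180.0 - v
    return build_pv_loop(pr, v, ejection_mask=np.ones(n, bool))


# ------------------------------------------------------------------ tangency

def test_ees_rectangle_corner():
    ees, eq = estimate_ees(_rect_loop(), 200.0)
    assert ees == pytest.approx(2.0)
    assert (eq.v_es, eq.p_es) == (pytest.approx(50.0), pytest.approx(100.0))


def test_ees_linear_path():
    """P = 180 - V on V in [0, 50]: slopes (20 + V)/V are minimized at the
    far corner."""
    ees, eq = estimate_ees(_linear_loop(), 200.0)
    assert ees == pytest.approx(1.4)
    assert (eq.v_es, eq.p_es) == (pytest.approx(50.0), pytest.approx(130.0))


def test_ees_requires_peak_above_loop():
    with pytest.raises(TangencyError):
        estimate_ees(_rect_loop(p=150.0), 140.0)


def test_ea_from_equilibrium():
    assert estimate_ea(EquilibriumPoint(50.0, 100.0)) == pytest.approx(2.0)
    assert estimate_ea(EquilibriumPoint(50.0, 130.0)) == pytest.approx(2.6)
    # slope from the origin is scale invariant
    assert estimate_ea(EquilibriumPoint(100.0, 260.0)) == pytest.approx(2.6)
    with pytest.raises(GeometryError):
        estimate_ea(EquilibriumPoint(0.0, 100.0))


# ----------------------------------------------------------- scalar formulas

def test_veed_intercept():
    assert compute_veed(200.0, 2.0) == pytest.approx(100.0)
    assert compute_veed(200.0, 1.4) == pytest.approx(142.857142857, rel=1e-9)
    with pytest.raises(DomainError):
        compute_veed(200.0, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(pisomax=st.floats(50.0, 450.0), ees=st.floats(0.2, 8.0))
def test_veed_times_ees_identity(pisomax, ees):
    assert compute_veed(pisomax, ees) * ees == pytest.approx(pisomax, rel=1e-12)


def test_stroke_work_rectangle_and_linear():
    assert compute_stroke_work(_rect_loop()) == pytest.approx(5000.0)
    assert compute_stroke_work(_linear_loop()) == pytest.approx(7750.0, rel=1e-6)


def test_stroke_work_linearity():
    loop = _linear_loop()
    half = build_pv_loop(loop.pressure / 2, loop.ejected_volume,
                         ejection_mask=loop.ejection_mask)
    assert compute_stroke_work(half) == pytest.approx(
        compute_stroke_work(loop) / 2
    )


def test_zero_sv_loop_degenerate():
    v = np.zeros(50)
    p = np.linspace(10, 150, 50)
    loop = build_pv_loop(p, v)
    with pytest.raises(GeometryError):
        compute_stroke_work(loop)
    with pytest.raises(GeometryError):
        estimate_ees(loop, 300.0)


def test_pva_triangle_and_efficiency_chain():
    assert compute_pva(200.0, 100.0) == pytest.approx(10000.0)
    sw = compute_stroke_work(_rect_loop())
    assert sw / compute_pva(200.0, 100.0) == pytest.approx(0.5)
    with pytest.raises(DomainError):
        compute_pva(-1.0, 100.0)


def test_pv_loop_validation():
    with pytest.raises(DataError):
        build_pv_loop(np.ones(5), np.array([0, 1, 0.5, 2, 3.0]))  # non-monotone V
    with pytest.raises(DataError):
        build_pv_loop(np.ones(4), np.ones(5))


# -------------------------------------------------------------------- q_load

def test_q_load_ideal_value():
    assert q_load(1.0) == 1.0


def test_q_load_printed_formula():
    assert q_load(1.8) == pytest.approx(7.2 / 7.84, rel=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(k=st.floats(0.05, 20.0))
def test_q_load_reciprocal_symmetry_and_bound(k):
    assert q_load(k) == pytest.approx(q_load(1.0 / k), rel=1e-9)
    assert 0.0 < q_load(k) <= 1.0
    assert q_load(k) <= q_load(1.0)


def test_q_load_domain():
    with pytest.raises(DomainError):
        q_load(0.0)
    with pytest.raises(DomainError):
        q_load(-2.0)


# ------------------------------------------------------ end-to-end / reports

def test_analyze_trace_invariants(sim_beat):
    truth = sim_beat.truth
    rep = analyze_trace(sim_beat.trace, co=truth["co_true"], hr=sim_beat.params.hr)
    assert rep.n_accepted >= 3
    for b in rep.beats:
        assert 0 < b.q_load <= 1
        assert 0 < b.sw <= b.pva
        assert 0 < b.sw_over_pva <= 1
        assert b.veed * b.ees == pytest.approx(b.pisomax, rel=1e-6)
        assert b.sv == pytest.approx(1000 * truth["co_true"] / sim_beat.params.hr)


def test_pressure_scaling_equivariance(sim_beat_clean):
    """Scaling all pressures by c scales Ees, Ea, Pisomax, SW, PVA by c and
    leaves Ea/Ees, Q_load, SW/PVA and Veed unchanged."""
    from pvbeat.signal import PressureTrace

    truth = sim_beat_clean.truth
    c = 1.3
    tr = sim_beat_clean.trace
    scaled = PressureTrace(tr.time, c * tr.pressure, sampling_rate=tr.sampling_rate)
    r1 = analyze_trace(tr, co=truth["co_true"], hr=sim_beat_clean.params.hr).summary()
    r2 = analyze_trace(scaled, co=truth["co_true"], hr=sim_beat_clean.params.hr).summary()
    for name in ("ees", "ea", "pisomax", "sw", "pva"):
        assert r2[name] == pytest.approx(c * r1[name], rel=2e-2)
    for name in ("ea_over_ees", "q_load", "sw_over_pva", "veed"):
        assert r2[name] == pytest.approx(r1[name], rel=2e-2)


def test_rejection_record_labels_failing_stage(sim_beat, monkeypatch):
    import pvbeat.mechanics as M

    def boom(*a, **k):
        raise LandmarkError("injected failure")

    monkeypatch.setattr(M, "detect_flow_landmarks", boom)
    truth = sim_beat.truth
    rep = analyze_trace(sim_beat.trace, co=truth["co_true"], hr=sim_beat.params.hr)
    assert rep.n_accepted == 0
    assert rep.rejections
    assert all(r.stage == "flow_synthesis" for r in rep.rejections)


# ----------------------------------------------------------- paired_compare

def test_paired_t_hand_example():
    c = paired_compare([1.0, 2.0, 3.0], [2.0, 4.0, 5.0], "x")
    assert c.mean_difference == pytest.approx(5 / 3, rel=1e-9)
    assert c.t == pytest.approx(5.0, rel=1e-9)
    assert c.p == pytest.approx(0.0377, abs=1e-3)
    assert c.n == 3 and not c.degenerate


def test_paired_t_identity_is_degenerate():
    c = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "x")
    assert c.mean_difference == 0.0
    assert c.degenerate


def test_paired_t_antisymmetry():
    a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 5.0]
    c1 = paired_compare(a, b, "x")
    c2 = paired_compare(b, a, "x")
    assert c2.t == pytest.approx(-c1.t)
    assert c2.p == pytest.approx(c1.p)


def test_paired_t_unpaired_lengths():
    with pytest.raises(DataError):
        paired_compare([1.0, 2.0], [1.0, 2.0, 3.0], "x")
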