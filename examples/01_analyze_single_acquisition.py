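"""Analyze one simulated severe-aortic-stenosis acquisition end to end.

Builds a synthetic LV pressure recording with known ground truth, then
runs the full single-beat chain: beat segmentation, 4th-derivative flow
landmarks, triangular flow scaled to the thermodilution stroke volume,
isovolumic sinusoid extrapolation, pressure-ejected-volume loop, and the
scalar mechanics report.
"""

from pvbeat import analyze_trace
from pvbeat.simulator import SimulatorParams, simulate_beat

params = SimulatorParams(seed=42)          # severe-AS preset
beat = simulate_beat(params)
truth = beat.truth

report = analyze_trace(beat.trace, co=truth["co_true"], hr=params.hr)
s = report.summary()

print(f"accepted beats: {report.n_accepted}  (rejected {len(report.rejections)})")
print(f"{'quantity':<12}{'estimate':>10}{'truth':>10}")
print(f"{'Pisomax':<12}{s['pisomax']:>10.1f}{truth['pisomax_true']:>10.1f}   mmHg — peak of the would-be non-ejecting beat")
print(f"{'Ees':<12}{s['ees']:>10.2f}{params.emax:>10.2f}   mmHg/mL — end-systolic elastance (contractility)")
print(f"{'Ea':<12}{s['ea']:>10.2f}{truth['ea_true']:>10.2f}   mmHg/mL — effective arterial elastance (valve + vessels)")
print(f"{'Ea/Ees':<12}{s['ea_over_ees']:>10.2f}{'':>10}   ventriculo-arterial coupling (ideal = 1)")
print(f"{'Q_load':<12}{s['q_load']:>10.3f}{'':>10}   fraction of maximal extractable work (ideal = 1)")
print(f"{'SW':<12}{s['sw']:>10.0f}{'':>10}   mmHg*mL — external stroke work")
print(f"{'PVA':<12}{s['pva']:>10.0f}{'':>10}   mmHg*mL — total mechanical energy per beat")
print(f"{'SW/PVA':<12}{s['sw_over_pva']:>10.2f}{'':>10}   mechanical efficiency")
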