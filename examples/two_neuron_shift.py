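"""Artifactual temporal shift of a gap-coupled pair, and its cure.

Two identical neurons coupled by a 30 nS gap junction should behave
exactly like two uncoupled neurons (their gap current is zero by
symmetry), so the uncoupled pair is an exact reference. The single-step
method — partner potential frozen for one step — shifts the trace by a
couple of ms within 1 s, while the iterative waveform-relaxation method
reduces the shift by orders of magnitude at the same step size.
"""

import gapwave as gw

H = 0.05  # computation step (ms)
T = 1000.0  # biological time (ms)

ref = gw.Simulator(
    gw.build_testcase_1a(g=0.0), gw.SimulationConfig(h=H, strategy="single-step")
).run(T)
reference = gw.Trace(ref.times, ref.voltages[0])

for label, cfg in [
    ("single-step", gw.SimulationConfig(h=H, strategy="single-step")),
    ("iterative (cubic)", gw.SimulationConfig(h=H, strategy="dmin", order=3)),
]:
    res = gw.Simulator(gw.build_testcase_1a(), cfg).run(T)
    trace = gw.Trace(res.times, res.voltages[0])
    eps = gw.rmse(trace, reference)
    delta, _ = gw.temporal_displacement(trace, reference)
    print(f"{label:18s} RMSE = {eps:9.3e} mV   shift delta = {delta:9.3e} ms")

print(
    "\nThe shift is the systematic lag of the coupled trace behind the exact\n"
    "solution; the iterative method pushes it below the microsecond scale."
)
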