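"""Current-voltage relations of the peak and steady-state photocurrent.

ChR2 rectifies strongly inward: large negative current below the
zero-current potential (~+13.6 mV for this empirical G(V) form) and only
a small, near-flat outward current above it.  Both I-V curves cross zero
at the same potential because the rectification factor is shared.
"""

from optochr2 import ChR2Params, LightProtocol, extract_measures, \
    run_voltage_clamp

params = ChR2Params()
print(" V (mV)   Ip (pA/pF)   Iss (pA/pF)")
for v in (-80, -60, -40, -20, -10, 0, 20, 40):
    pulse = LightProtocol.single_pulse(10.0, 500.0, 5.5)
    m = extract_measures(run_voltage_clamp(v, pulse, params, dt_out=0.5))
    print(f"{v:7.0f} {m.i_peak:12.2f} {m.i_ss:12.2f}")
print("\nNegative (inward) below ~+13.6 mV, small outward above it.")
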