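"""Photothermal bound: is the light itself heating the preparation?

The illuminated volume is idealised as a uniformly heated sphere (radius
= beam radius) in an infinite aqueous medium; the analytic centre-point
solution of the diffusion equation gives the transient, and Q a^2/(2k)
the exact saturation.  Even at the highest irradiance used (5.5 mW/mm^2)
the rise stays in the hundredths of a degree — far too small to perturb
channel kinetics, which justifies leaving heating out of the model.
"""

from optochr2.photothermal import BeamSpec, saturation_temp_rise, temp_rise

beam = BeamSpec(irradiance=5.5)
print("time        dT at beam centre")
for t_ms in (10.0, 90.0, 1000.0, 10000.0, 60000.0):
    print(f"{t_ms / 1e3:7.2f} s   {temp_rise(beam, t_ms):.4f} C")
print(f"saturation  {saturation_temp_rise(beam):.4f} C  (< 0.04 C)")
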