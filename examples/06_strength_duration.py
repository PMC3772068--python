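"""Strength-duration curve and the IK1-swap experiment.

The optical excitation threshold (minimum irradiance that pushes V above
-20 mV within 400 ms) falls with pulse width.  Replacing the ventricular
cell's strong IK1 with the much weaker Purkinje-style rectifier slashes
the threshold — cell-type targeting by light dosing.

Runtime: a couple of minutes (each threshold is a bisection over full
cell simulations).
"""

from optochr2.cells import TenTusscher2006, optical_threshold, swap_ik1
from optochr2.io import default_params_37c
from optochr2.protocols import SolverSettings

params = default_params_37c()
solver = SolverSettings(rtol=1e-8, atol=1e-8)

native = TenTusscher2006()
purk = swap_ik1(native, "purkinje", params, solver=solver)

print("pulse width   native threshold   Purkinje-IK1 threshold   ratio")
for width in (20.0, 100.0):
    th_n = optical_threshold(native, width, params, solver=solver)
    th_p = optical_threshold(purk, width, params, solver=solver)
    print(f"{width:8.0f} ms {th_n:12.4f} {th_p:18.4f} mW/mm^2 "
          f"{100 * th_p / th_n:9.1f}%")
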