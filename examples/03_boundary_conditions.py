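"""Inlet boundary-condition helpers: pulsatile waveform, mean inlet
velocity v(t) = q(t) / (pi (d/2)^2), and the peak Reynolds number.
"""

import numpy as np

from aneumorph import InletSpec, default_waveform, inlet_mean_velocity, \
    peak_reynolds

waveform = default_waveform()            # ICA-like pulse, period 0.8 s
inlet = InletSpec(diameter=4.0)          # 4 mm inlet, blood at 1056 kg/m^3

print(f"waveform: period {waveform.period} s, mean flow "
      f"{waveform.q_mean:.0f} mm^3/s, peak at t = {waveform.t_peak:.3f} s")
for t in (0.0, waveform.t_peak, 0.6):
    v = float(inlet_mean_velocity(waveform, inlet, t))
    print(f"  t = {t:5.3f} s: q = {float(waveform.q_at(t)):7.0f} mm^3/s, "
          f"v_mean = {v:6.1f} mm/s")
re = peak_reynolds(waveform, inlet)
print(f"peak Reynolds number: {re:.0f}  (physiological range 500-750)")
print(f"outflow split MCA:ACA = {inlet.outflow_split[0]}:{inlet.outflow_split[1]}")
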