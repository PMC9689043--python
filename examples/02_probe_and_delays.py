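"""Excitation pulse, subaperture sweep plan and transmit focal delays.

The 32-element array fires 5-element subapertures, stepping one element
at a time (28 scan lines).  Each transmit applies the focal delay law
B(i) = (max_j path_j - path_i) / c so all five wavelets arrive at the
10 mm focus simultaneously.
"""

import numpy as np

from lusim import ArraySpec, PulseSpec, element_drive, focal_delays, sweep_plan

array = ArraySpec.spanning(0.050, 32)
plan = sweep_plan(32, aperture_size=5, step=1)
pulse = PulseSpec(f0=2e6)

print(f"pitch {array.pitch*1e3:.4f} mm, element width {array.element_width*1e3:.3f} mm")
print(f"sweep positions: {plan.n_positions} (scan lines per frame)")

window = plan.positions[plan.n_positions // 2]
delays = focal_delays(array.element_centers[list(window)], focus_depth=0.010, c_ref=1570.0)
print("focal delays across the center aperture (us):",
      np.round(delays * 1e6, 4))
print(f"edge-to-center delay: {(delays.max() - delays.min())*1e6:.4f} us "
      "(outer elements fire first)")

sources = element_drive(0, plan, array, pulse, dt=0.02e-6)
print(f"sweep 0 drives elements {[s.element_index for s in sources]}; "
      f"pulse window {pulse.total_duration*1e6:.2f} us, envelope sigma "
      f"{pulse.sigma*pulse.f0:.1f} cycles")
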