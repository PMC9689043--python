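"""Reproduce the A-line echo train of a healthy (no-LDZ) slab.

With homogeneous muscle under an aerated-lung pressure-release boundary,
the transmit pulse bounces between the pleura (reflection -1) and the
rigid transducer face (+1), producing echoes every 2 L / c = 12.74 us
(L = 10 mm, c = 1570 m/s).  In the image these become the horizontal
A-line bands.  Runs in ~1 minute.
"""

import numpy as np

from lusim import ExperimentConfig, detect_echoes, envelope
from lusim.probe import element_drive, sweep_plan
from lusim.runner import build_experiment_phantom
from lusim.wavesim import run_forward

cfg = ExperimentConfig.desk_scale(variant="A", G=0.0, seed=1,
                                  include_ldz=False, t_end=50e-6)
material = build_experiment_phantom(cfg)
plan = sweep_plan(cfg.n_elements, cfg.aperture_size, cfg.sweep_step)
array = cfg.array()
sweep = plan.n_positions // 2
sources = element_drive(sweep, plan, array, cfg.pulse(), cfg.dt,
                        focus_depth=cfg.focus_depth, c_ref=cfg.c_ref)
result = run_forward(material, sources, cfg.solver(), array)

center_element = plan.positions[sweep][cfg.aperture_size // 2]
env = envelope(result.traces[center_element])
dead_time = cfg.pulse().total_duration + max(s.onset_delay for s in sources) + 2e-6
train = detect_echoes(env, result.times, threshold=0.1,
                      min_separation=4e-6, t_min=dead_time)

expected = 2 * 0.010 / 1570.0
print(f"echoes detected after the transmit pulse: {len(train.arrival_times)}")
print("arrival times (us):", np.round(train.arrival_times * 1e6, 2))
print("spacings (us):     ", np.round(train.spacings * 1e6, 2),
      f"- round-trip oracle 2L/c = {expected*1e6:.2f} us")
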