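"""Biased migration: all four taxis modes at the strength that yields a
5 μm/min drift (where reachable), measured against the convection-speed
closed forms.

The three semi-mechanistic modes (orthotaxis: direction-dependent speed;
topotaxis: skewed turning distribution; klinotaxis: direction-dependent run
duration) share the same bias speed v_free*p*t_free/(3*t_run); the simple
phenomenological mode (drift during pauses) has p*v_free*t_pause/t_run and
maxes out at 3.76 μm/min here, so it is run at p = 1.
"""

import numpy as np

from beauwalk import ModelParams, TaxisSpec, convection_speed, simulate_ensemble

params = ModelParams(0.5, 2.0, 18.8)
target = 5.0  # μm/min
p_semi = 3.0 * target * params.t_run / (params.v_free * params.t_free)

print(f"{'mode':<12} {'p':>6} {'||C|| theory':>12} {'drift sim':>10} {'SE':>6}  (μm/min)")
for mode, p in [("simple", 1.0), ("orthotaxis", p_semi),
                ("topotaxis", p_semi), ("klinotaxis", p_semi)]:
    ts = simulate_ensemble(1000, params, TaxisSpec(mode, p, [1, 0, 0]),
                           duration=60.0, sample_dt=60.0, phase_mode="stationary",
                           seed=11)
    _, pos = ts.stacked()
    x = pos[:, -1, 0]
    rate, se = x.mean() / 60.0, x.std(ddof=1) / np.sqrt(len(x)) / 60.0
    print(f"{mode:<12} {p:6.3f} {convection_speed(mode, p, params):12.3f} "
          f"{rate:10.3f} {se:6.3f}")

print("\nEach simulated drift rate should sit within ~3 SE of its closed form;")
print("the three semi-mechanistic modes all reach 5 μm/min (300 μm per hour).")
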