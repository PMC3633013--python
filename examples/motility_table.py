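"""Motility coefficients of the published best-fitting parameter triplets.

The pause-and-run model's Brownian scaling limit has per-dimension motility
coefficient M = (v_free * t_free)^2 / (6 * (t_free + t_pause)).  Very
different microscopic triplets map onto nearly the same M — the first hint
that population-level statistics cannot pin down all three parameters.
"""

from beauwalk import ModelParams, motility_coefficient, msd_linear_coeffs

triplets = [
    (0.5, 2.0, 18.8),
    (0.5, 2.5, 16.6),
    (0.25, 2.0, 17.6),
    (0.75, 1.5, 23.8),
    (9.32, 2.0, 40.0),  # deliberately extreme, yet M-degenerate with the first
]

print(f"{'t_pause':>8} {'t_free':>7} {'v_free':>7} {'M':>8} {'alpha':>8} {'beta':>9}")
for tp, tf, v in triplets:
    params = ModelParams(tp, tf, v)
    alpha, beta = msd_linear_coeffs(params)
    print(f"{tp:8.2f} {tf:7.2f} {v:7.1f} {motility_coefficient(params):8.2f} "
          f"{alpha:8.2f} {beta:9.2f}")

print("\nM in μm²/min; alpha (slope 2M) and beta (intercept -2M t_free/3) describe")
print("the asymptotic per-dimension mean-square-displacement line alpha*t + beta.")
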