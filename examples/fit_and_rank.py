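"""Fit motility parameters to simulated data, and demonstrate why mean
displacement identifies the pause time while mean square displacement
cannot.

The population MSD of the model is asymptotically the line 2M t - 2M tf/3:
only two degrees of freedom.  The triplets (0.5, 2.0, 18.8) and
(9.32, 2.0, 40) share (M, t_free) and are therefore MSD-indistinguishable,
but their mean-displacement curves differ — ranking candidate triplets by
simulated SSR against a mean-displacement reference recovers the generator.
"""

from beauwalk import (
    ModelParams,
    fit_furth,
    fit_linear_msd,
    mean_displacement,
    mean_square_displacement,
    motility_coefficient,
    rank_parameter_grid,
    simulate_ensemble,
)

gen = ModelParams(0.5, 2.0, 18.8)
twin = ModelParams(9.32, 2.0, 40.0)
ts = simulate_ensemble(5000, gen, duration=30.0, sample_dt=0.5, seed=19)

msd = mean_square_displacement(ts, dims=1)
lin = fit_linear_msd(msd, fit_range=(2.0, 30.0))
fur = fit_furth(msd)
print(f"true M = {motility_coefficient(gen):.2f} μm²/min, t_free = {gen.t_free} min")
print(f"linear MSD fit: M = {lin.estimates['M']:.2f}, t_free = {lin.estimates['t_free']:.2f}")
print(f"Fürth fit:      M = {fur.estimates['M']:.2f}, P = {fur.estimates['P']:.2f} min")

ref_d = mean_displacement(ts, dims=3)
table = rank_parameter_grid(ref_d, [twin, gen], n_per_sim=5000, seed=23)
print("\nRanking against the mean-displacement reference (SSR normalized to best):")
print(table[["rank", "t_pause", "t_free", "v_free", "M", "SSR"]].to_string(index=False))
print("\nThe generating triplet ranks first: mean displacement retains the pause")
print("information that the MSD has already averaged away.")
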