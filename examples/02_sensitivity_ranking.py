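"""Rank a simulated 35-line panel by oxidant sensitivity.

Simulates the panel's latent sensitivities with the default correlation
structure (gas plasma and H2O2 concordant, HOCl independent), maps them
to IC25 values, and prints ranks, dynamic ranges and the pairwise
cross-treatment Spearman correlations.
"""

from rospanel import (
    SimulationConfig,
    cross_treatment_correlation,
    make_profile,
    rank_sum,
    simulate_ic25,
    simulate_latent,
)

cfg = SimulationConfig(seed=1)
latent = simulate_latent(cfg)
ic25 = simulate_ic25(latent, cfg)

profiles = {t: make_profile(t, ic25[t]) for t in cfg.treatment_names}
for t, prof in profiles.items():
    unit = {td.name: td.unit for td in cfg.treatments}[t]
    most = prof.ranks.idxmin()
    print(f"{t}: dynamic range {prof.dynamic_range:.0f}-fold, "
          f"most sensitive line {most} (IC25 {prof.ic25_by_line[most]:.2f} {unit})")

print()
names = cfg.treatment_names
for i, t1 in enumerate(names):
    for t2 in names[i + 1:]:
        res = cross_treatment_correlation(profiles[t1], profiles[t2])
        print(f"Spearman r({t1}, {t2}) = {res.r:+.2f}  (p = {res.p:.2g})")

sums = rank_sum(list(profiles.values()))
print(f"\nglobally most oxidant-sensitive line: {sums.idxmin()} "
      f"(rank sum {sums.min():.1f}; possible range 3..{3 * cfg.n_lines})")
# A low rank sum means the line dies early under all three oxidant
# challenges; the r values echo the configured targets (0.64 / 0.10 / 0.02).
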