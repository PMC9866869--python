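"""A miniature grid sweep with descriptive statistics and composition report.

Maximizes F_pi over rate matrices at each point of a very coarse stationary
grid for the standard code and code 22, then summarizes: per-code
min/median/max with percent changes against the standard code, the extremal
compositions, and the A+T-binned medians (the monotone relationship between
mutational A+T content and attainable codon bias).
"""

import fourfold as ff
from fourfold.reporting import binned_median_table, composition_summary

codes = [ff.get_code(1), ff.get_code(22)]
grid = ff.enumerate_stationary_grid(0.1, 0.7, 0.2)  # tiny demonstration grid
print(f"grid: {len(grid)} stationary distributions")

acceptance = ff.build_acceptance_matrix(stop_floor=0.0)
cfg = ff.ESConfig(mu=4, lambda_offspring=12, generations=25, restarts=1, seed=5)
sweep = ff.sweep_grid(codes, grid, acceptance, cfg, directions=("max",))

stats = ff.descriptive_stats(sweep, reference_code=1)
print("\nper-code summary of maximized Fpi:")
print(stats.round(4).to_string(index=False))

print("\nextremal compositions:")
print(composition_summary(sweep).round(4).to_string(index=False))

print("\nA+T-binned median of maximized Fpi:")
print(binned_median_table(sweep).round(4).to_string(index=False))
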