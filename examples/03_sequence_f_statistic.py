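"""The observed-usage statistic F on synthetic coding sequences.

Generates CDS with a controllable third-position skew in the Ala group,
counts codons, and compares the measured F with the value computed exactly
from the generating frequencies — the parameter-recovery loop for the
sequence pipeline.
"""

import fourfold as ff

code = ff.get_code(1)

for delta in (0.0, 0.15, 0.3):
    spec = ff.UsageSpec(
        code_id=1,
        group_third_position={
            "Ala": [0.25 + 0.75 * delta, 0.25 * (1 - delta),
                    0.25 * (1 - delta), 0.25 * (1 - delta)],
            "Gly": [0.25] * 4, "Pro": [0.25] * 4,
            "Thr": [0.25] * 4, "Val": [0.25] * 4,
        },
    )
    records = ff.generate_cds(spec, n_sequences=800, mean_length_codons=120, seed=11)
    usage = ff.count_codons(records, code)
    result = ff.f_statistic(usage, code)
    exact = spec.analytic_f().total
    print(
        f"delta={delta:.2f}: F={result.total:.4f} (exact {exact:.4f}) "
        f"over {usage.n_codons_counted:,} codons; "
        f"f_Ala={result.per_group['Ala']:.4f}"
    )

print()
print("F rises with the skew of the Ala group's third-position usage away")
print("from the cross-group average e; the sampled value tracks the exact")
print("value of the generating distribution.")
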