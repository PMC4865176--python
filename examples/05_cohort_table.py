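"""Cohort-characteristics table with per-row chi-square / t tests.

Reproduces the descriptive-table layout: count (%) or mean +/- SD per
exposure group with a test of the group difference per row.
"""

from methewas import SimulationConfig, characteristics_table, \
    generate_sample_sheet

sheet = generate_sample_sheet(SimulationConfig(seed=5))
table = characteristics_table(sheet)

print(f"analysed population: {table.attrs['n_not_exposed']} unexposed, "
      f"{table.attrs['n_exposed']} exposed "
      f"(total {table.attrs['n_total']})\n")
print(table.drop(columns="p_value").to_string(index=False))
print("\np-values: chi-square (counts) or pooled t-test (means); "
      "'—' marks degenerate rows.")
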