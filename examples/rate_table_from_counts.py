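"""Build the 25-marker mutation-rate table from published counts alone.

Raw pedigree genotypes from deep-pedigree studies are usually not
shareable, but the per-marker mutation counts and the total number of
meioses are printed — and they are all the rate table needs.  Each rate
is x/1576 with an exact (Clopper–Pearson) 95% interval; the Wilson score
interval is shown alongside for comparison.
"""

from ystrped import STUDY_MUTATION_COUNTS, study_counts_table

table = study_counts_table(ci_methods=("clopper_pearson", "wilson"))
print(table.to_string(index=False))
print(f"\ntotal mutations: {table['Mutations'].sum()} "
      f"across {table['Total Meioses'].iloc[0]} meioses")
print("Each row: per-meiosis mutation rate at one marker; rapidly mutating "
      "markers (DYS627, DYS576, DYS518, DYF387S1) dominate the counts.")
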