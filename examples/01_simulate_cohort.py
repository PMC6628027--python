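"""Simulate the nine-sample index patient and inspect the planted truth.

The default cohort has four primary regions (Pr1-Pr4), a vena-cava
tumour thrombus (VT) and four lung metastases (M1-M4). Pr1-Pr3 descend
from a near-diploid lineage; Pr4, VT and the metastases share a
whole-genome-doubled lineage.
"""

from metaclone import synthetic_cohort as sc

data = sc.simulate_patient(sc.index_cohort_spec(seed=1))

print(data.truth["samples"].to_string(index=False))
print()
plan = data.truth["mutation_plan"]
print(f"{len(plan)} somatic mutations; "
      f"{(plan['category'] == 'trunk').sum()} truncal (in every sample), "
      f"{plan['category'].str.startswith('private').sum()} private to one sample.")
print("Purity is the tumour-cell fraction per sample; ploidy the "
      "length-weighted mean copy number of the tumour genome.")
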