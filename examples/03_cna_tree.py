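"""Build the copy-number phylogeny of all nine samples.

Total-copy profiles are binned at 1 Mb, compared by mean absolute copy
difference, and joined into a neighbour-joining tree rooted on an
all-diploid pseudo-sample. The root split separates the near-diploid
primary regions from the genome-doubled metastatic lineage.
"""

from metaclone import pipeline as pl
from metaclone import synthetic_cohort as sc

data = sc.simulate_patient(sc.index_cohort_spec(seed=1))
res = pl.analyze_patient(data)

sides = sorted(set(res.root_split), key=len)
print("root split:", " | ".join("{" + ",".join(sorted(s)) + "}" for s in sides))
print()
print(res.neighbors.to_string(index=False))
print()
print("VT and M3 carry identical planted events (distance ~0); Pr4's "
      "nearest profile is M2 — the metastases trace back to the Pr4 region.")
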