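"""Recovery metrics of the pipeline on simulated index-patient cohorts.

These helpers run the full inference on freshly simulated patients and
score it against the planted truth: ploidy-class accuracy, recovery of
the primary/metastatic root split in the CNA tree, clonality-label
accuracy, and differential-expression counts. They are used by the test
suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import clonality as cl
from . import expression as ex
from . import phylogeny as ph
from . import pipeline as pl
from . import synthetic_cohort as sc

DIPLOID_SIDE = frozenset({"Pr1", "Pr2", "Pr3"})
WGD_SIDE = frozenset({"Pr4", "VT", "M1", "M2", "M3", "M4"})
EXPECTED_SPLIT = {DIPLOID_SIDE, WGD_SIDE}


@dataclass
class RecoveryMetrics:
    ploidy_ok: list = field(default_factory=list)      # one bool per sample-seed
    split_ok: list = field(default_factory=list)       # one bool per seed
    major_correct: int = 0
    major_total: int = 0
    de_counts: list = field(default_factory=list)      # (total, up, down) per seed

    @property
    def ploidy_accuracy(self) -> float:
        return sum(self.ploidy_ok) / len(self.ploidy_ok)

    @property
    def split_rate(self) -> float:
        return sum(self.split_ok) / len(self.split_ok)

    @property
    def major_accuracy(self) -> float:
        return self.major_correct / self.major_total

    @property
    def mean_de_counts(self) -> tuple[float, float, float]:
        n = len(self.de_counts)
        return tuple(sum(c[i] for c in self.de_counts) / n for i in range(3))


def evaluate_seed(seed: int, log2_sigma: float = 0.15, depth: int = 60,
                  run_expression: bool = True) -> RecoveryMetrics:
    """Simulate one index patient and score the pipeline against truth.

    Copy-number inference runs end to end (segmentation, BAF bands, grid
    fit, assignment, tree). Mutation labels are scored with the planted
    local copy states and purities so the clonality classifier is
    evaluated in isolation from the copy-number stage.
    """
    m = RecoveryMetrics()
    spec = sc.index_cohort_spec(seed=seed, log2_sigma=log2_sigma, depth=depth)
    data = sc.simulate_patient(spec)
    truth = data.truth["samples"].set_index("sample")
    het = dict(tuple(data.germline.groupby("sample")))

    profiles = {}
    for name in data.sample_names:
        prof = pl.analyze_sample(data.probes[name], het[name], name=name,
                                 role=data.roles[name])
        profiles[name] = prof
        m.ploidy_ok.append(prof.ploidy_class == truth.loc[name, "ploidy_class"])

    mat, mask = ph.copy_profile_matrix({n: p.segments for n, p in profiles.items()})
    mat, mask = ph.add_normal_profile(mat, mask)
    dist = ph.cna_distance_matrix(mat, mask)
    tree = ph.build_nj_tree(dist)
    m.split_ok.append(set(ph.root_split(tree)) == EXPECTED_SPLIT)

    mt = data.truth["mutations"]
    local = mt[["mutation_id", "sample", "local_total_cn", "local_major_cn"]]
    calls = cl.classify_mutations(data.somatic, data.purities, local)
    merged = calls.merge(mt[["mutation_id", "sample", "label"]],
                         on=["mutation_id", "sample"], suffixes=("", "_true"))
    majors = merged[merged["label_true"] == cl.MAJOR]
    m.major_total += len(majors)
    m.major_correct += int((majors["label"] == cl.MAJOR).sum())

    if run_expression:
        de = ex.differential_expression(data.expression, data.roles)
        m.de_counts.append((len(de.reported), de.n_up, de.n_down))
    return m


def evaluate_seeds(seeds, log2_sigma: float = 0.15, depth: int = 60,
                   run_expression: bool = True) -> RecoveryMetrics:
    total = RecoveryMetrics()
    for seed in seeds:
        m = evaluate_seed(seed, log2_sigma, depth, run_expression)
        total.ploidy_ok += m.ploidy_ok
        total.split_ok += m.split_ok
        total.major_correct += m.major_correct
        total.major_total += m.major_total
        total.de_counts += m.de_counts
    return total


def paper_count_sharing_summary() -> cl.SharingSummary:
    """Sharing summary on the published event counts of the index patient.

    Builds a presence matrix with 18 of 146 truncal rows, 51 rows confined
    to primary regions and 20 metastasis-only rows (the published
    catalogue structure) and summarises it.
    """
    import pandas as pd

    roles = {"Pr1": "primary", "Pr2": "primary", "Pr3": "primary",
             "Pr4": "primary", "VT": "thrombus",
             "M1": "metastasis", "M2": "metastasis", "M3": "metastasis",
             "M4": "metastasis"}
    prim = [s for s, r in roles.items() if r == "primary"]
    mets = [s for s, r in roles.items() if r == "metastasis"]
    rows = []
    for i in range(146):
        row = {s: cl.ABSENT for s in roles}
        if i < 18:
            row = {s: cl.MAJOR for s in roles}
        elif i < 18 + 51:
            row[prim[i % 4]] = cl.MAJOR
        elif i < 18 + 51 + 20:
            row[mets[i % 4]] = cl.MAJOR
        else:
            row["VT"] = cl.MAJOR
        rows.append(row)
    mat = pd.DataFrame(rows, index=[f"m{i}" for i in range(146)])
    return cl.summarize_sharing(mat, roles)


def paper_count_concordance() -> cl.ConcordanceReport:
    """Validation concordance on the published validation-event counts:
    243 events, 36 with insufficient re-sequencing coverage, 127/129 major
    and 7/8 minor calls validated, 69/70 absences confirmed."""
    import pandas as pd

    rows_a, rows_b = [], []

    def add(i, label_a, depth_b, present_b):
        rows_a.append({"mutation_id": f"e{i}", "sample": "s", "label": label_a})
        rows_b.append({"mutation_id": f"e{i}", "sample": "s",
                       "label": cl.MAJOR if present_b else cl.ABSENT,
                       "depth": depth_b})

    i = 0
    for k in range(129):
        add(i, cl.MAJOR, 100, k >= 2); i += 1
    for k in range(8):
        add(i, cl.MINOR, 100, k >= 1); i += 1
    for k in range(70):
        add(i, cl.ABSENT, 100, k < 1); i += 1
    for _ in range(36):
        add(i, cl.ABSENT, 5, False); i += 1
    return cl.validation_concordance(pd.DataFrame(rows_a), pd.DataFrame(rows_b),
                                     min_depth=20)
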