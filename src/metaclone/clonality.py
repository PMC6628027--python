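"""Somatic-mutation clonality: CCF estimation, major/minor classification,
presence matrices, sharing summaries and validation concordance.

The cancer cell fraction (CCF) of a mutation observed at variant allele
fraction ``vaf`` in a sample of purity rho, local total copy number cT and
mutation multiplicity m is::

    f = vaf * (rho*cT + 2*(1-rho)) / (rho*m)

Multiplicity is unobserved; it is chosen from {1..nA} (nA = local major
allele count) as the value whose implied CCF is closest to 1 — clonal
mutations are the parsimonious default. A mutation is called present when
it has at least ``min_alt`` supporting reads and the read count is
inconsistent with the sequencing error rate (one-sided binomial test);
present mutations with CCF >= 0.5 are "major clone", the rest "minor
clone". Samples with insufficient depth are flagged, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ABSENT, MINOR, MAJOR, INSUFFICIENT = "absent", "minor", "major", "insufficient"
INCONSISTENT = "inconsistent"

PRESENT_LABELS = (MINOR, MAJOR)


@dataclass
class ClonalityThresholds:
    min_depth: int = 20
    min_alt: int = 3
    error_rate: float = 0.01
    presence_p: float = 0.01
    major_ccf: float = 0.5


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def estimate_ccf(vaf: float, rho: float, cT: float, m: int) -> float:
    """Cancer cell fraction implied by a VAF at the given multiplicity."""
    if m <= 0:
        raise ValueError("multiplicity must be >= 1")
    if not (0 < rho <= 1):
        raise ValueError("purity must be in (0, 1]")
    if cT < 1:
        raise ValueError("local total copy number must be >= 1")
    return float(vaf) * (rho * cT + 2.0 * (1.0 - rho)) / (rho * m)


def classify_mutation_sample(alt: int, depth: int, rho: float, cT: float,
                             nA: int,
                             thresholds: ClonalityThresholds | None = None):
    """Classify one mutation in one sample.

    Returns ``(m_hat, ccf_hat, label)``. Depth below ``min_depth`` gives
    the "insufficient" label; a supported mutation in a zero-copy region
    is flagged "inconsistent".
    """
    t = thresholds or ClonalityThresholds()
    if depth < t.min_depth:
        return 0, float("nan"), INSUFFICIENT
    p_err = float(stats.binom.sf(alt - 1, depth, t.error_rate)) if alt > 0 else 1.0
    present = alt >= t.min_alt and p_err < t.presence_p
    if not present:
        return 0, 0.0, ABSENT
    if nA <= 0:
        return 0, float("nan"), INCONSISTENT
    vaf = alt / depth
    candidates = np.arange(1, int(nA) + 1)
    ccfs = np.array([estimate_ccf(vaf, rho, cT, int(m)) for m in candidates])
    k = int(np.argmin(np.abs(ccfs - 1.0)))
    m_hat, ccf_hat = int(candidates[k]), float(ccfs[k])
    label = MAJOR if ccf_hat >= t.major_ccf else MINOR
    return m_hat, ccf_hat, label


def classify_mutations(somatic: pd.DataFrame, purities: dict[str, float],
                       local_cn: pd.DataFrame | None = None,
                       thresholds: ClonalityThresholds | None = None) -> pd.DataFrame:
    """Classify every mutation x sample record of a long-form call table.

    ``somatic`` needs mutation_id, sample, alt_count, depth. ``local_cn``
    supplies per-(mutation, sample) local_total_cn and local_major_cn; when
    missing, a diploid heterozygous locus (cT=2, nA=1) is assumed with a
    warning column.
    """
    df = somatic.copy()
    if local_cn is not None:
        df = df.merge(local_cn[["mutation_id", "sample",
                                "local_total_cn", "local_major_cn"]],
                      on=["mutation_id", "sample"], how="left")
    if "local_total_cn" not in df.columns:
        df["local_total_cn"] = np.nan
        df["local_major_cn"] = np.nan
    df["cn_fallback"] = df["local_total_cn"].isna() | (df["local_total_cn"] < 1)
    df.loc[df["cn_fallback"], "local_total_cn"] = 2.0
    df.loc[df["cn_fallback"], "local_major_cn"] = 1

    out = []
    for row in df.itertuples(index=False):
        m_hat, ccf, label = classify_mutation_sample(
            int(row.alt_count), int(row.depth), purities[row.sample],
            float(row.local_total_cn), int(row.local_major_cn), thresholds)
        out.append((m_hat, ccf, label))
    res = pd.DataFrame(out, columns=["multiplicity_hat", "ccf_hat", "label"])
    return pd.concat([df.reset_index(drop=True), res], axis=1)


def local_copy_lookup(allelic_segments: dict[str, pd.DataFrame],
                      mutations: pd.DataFrame) -> pd.DataFrame:
    """Local (total, major) copies at each mutation position per sample.

    Looks up the assigned segment covering each mutation's position
    (1-based) in each sample's allele-specific segment table; unassigned
    regions yield NaN (the classifier then falls back to cT=2, nA=1).
    """
    rows = []
    muts = mutations.drop_duplicates("mutation_id")
    for sample, seg in allelic_segments.items():
        for chrom, sub in muts.groupby("chrom"):
            s = seg[(seg["chrom"] == chrom) & (seg["assigned"])].sort_values("start")
            pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
            if len(s) == 0:
                for mid in sub["mutation_id"]:
                    rows.append((mid, sample, np.nan, np.nan))
                continue
            starts = s["start"].to_numpy()
            ends = s["end"].to_numpy()
            idx = np.searchsorted(starts, pos0, side="right") - 1
            ok = idx >= 0
            ok &= np.where(ok, pos0 < ends[np.clip(idx, 0, None)], False)
            ct = np.where(ok, s["total_cn"].to_numpy()[np.clip(idx, 0, None)], np.nan)
            na = np.where(ok, s["major_cn"].to_numpy()[np.clip(idx, 0, None)], np.nan)
            for mid, c, a in zip(sub["mutation_id"], ct, na):
                rows.append((mid, sample, c, a))
    return pd.DataFrame(rows, columns=["mutation_id", "sample",
                                       "local_total_cn", "local_major_cn"])


def build_presence_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-form classified calls into a mutation x sample label matrix.

    Label totals are stored in ``matrix.attrs['label_totals']``.
    """
    mat = calls.pivot(index="mutation_id", columns="sample", values="label")
    mat = mat.fillna(ABSENT)
    totals = mat.stack().value_counts().to_dict()
    mat.attrs["label_totals"] = totals
    return mat


@dataclass
class SharingSummary:
    n_mutations: int
    n_trunk: int | None
    n_primary_subset: int | None
    n_metastasis_only: int | None
    n_other: int
    private_counts: dict[str, int]
    excluded_samples: list[str]

    def percent(self, count: int | None):
        """(1-decimal, integer half-up) percentage of the catalogue."""
        if count is None:
            return None, None
        x = 100.0 * count / self.n_mutations
        return round(x, 1), _round_half_up(x)

    @property
    def trunk_percent(self):
        return self.percent(self.n_trunk)

    @property
    def primary_subset_percent(self):
        return self.percent(self.n_primary_subset)


def summarize_sharing(presence_matrix: pd.DataFrame, sample_roles: dict[str, str],
                      count_minor_as_present: bool = True) -> SharingSummary:
    """Sharing pattern of the mutation catalogue across sample roles.

    Trunk mutations are present in every (evaluable) sample; the
    primary-subset category is present in at least one primary region and
    in no thrombus or metastasis sample; metastasis-only mutations occur
    only in metastases. Samples whose entire column is insufficient are
    excluded from categorisation; sporadic insufficient entries neither
    count as present nor veto trunk status. A role with no samples makes
    its dependent categories undefined (None), not zero.
    """
    present_set = set(PRESENT_LABELS) if count_minor_as_present else {MAJOR}
    mat = presence_matrix.copy()
    excluded = [s for s in mat.columns if (mat[s] == INSUFFICIENT).all()]
    mat = mat.drop(columns=excluded)
    roles = {s: sample_roles[s] for s in mat.columns}
    primaries = [s for s, r in roles.items() if r == "primary"]
    thrombi = [s for s, r in roles.items() if r == "thrombus"]
    mets = [s for s, r in roles.items() if r == "metastasis"]

    present = mat.isin(present_set)
    known = mat != INSUFFICIENT
    n = len(mat)

    trunk = (present | ~known).all(axis=1) & present.any(axis=1)
    in_primary = present[primaries].any(axis=1) if primaries else pd.Series(False, index=mat.index)
    in_thrombus = present[thrombi].any(axis=1) if thrombi else pd.Series(False, index=mat.index)
    in_met = present[mets].any(axis=1) if mets else pd.Series(False, index=mat.index)

    primary_subset = in_primary & ~in_thrombus & ~in_met & ~trunk
    met_only = in_met & ~in_primary & ~in_thrombus & ~trunk

    n_trunk = int(trunk.sum())
    # a category is undefined (None, not 0) when the roles needed to
    # assess it are absent from the cohort
    primary_defined = bool(primaries) and bool(thrombi or mets)
    met_defined = bool(mets) and bool(primaries or thrombi)
    n_primary_subset = int(primary_subset.sum()) if primary_defined else None
    n_met_only = int(met_only.sum()) if met_defined else None
    categorized = trunk | primary_subset | met_only
    n_other = int((present.any(axis=1) & ~categorized).sum())
    private = {s: int((present[s] & (present.sum(axis=1) == 1)).sum())
               for s in mat.columns}
    return SharingSummary(n, n_trunk, n_primary_subset, n_met_only,
                          n_other, private, excluded)


@dataclass
class ConcordanceReport:
    n_events: int
    n_insufficient: int
    n_evaluable: int
    n_concordant: int
    major_concordant: int
    major_total: int
    minor_concordant: int
    minor_total: int

    @property
    def percent(self) -> int:
        return _round_half_up(100.0 * self.n_concordant / self.n_evaluable)

    @property
    def major_rate(self) -> float:
        return round(100.0 * self.major_concordant / self.major_total, 1)

    @property
    def minor_rate(self) -> float:
        return round(100.0 * self.minor_concordant / self.minor_total, 1)


def validation_concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                           min_depth: int = 20) -> ConcordanceReport:
    """Concordance of presence calls between two call sets.

    Both tables carry mutation_id, sample, label (and depth in
    ``calls_b``). Events with insufficient re-sequencing depth are excluded
    as non-evaluable; concordance means the same presence status, reported
    to integer percent with a major/minor breakdown by the primary call.
    """
    key = ["mutation_id", "sample"]
    merged = calls_a.merge(calls_b, on=key, suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        raise ValueError("call sets share no (mutation, sample) events")
    n_events = len(merged)
    depth_col = "depth_b" if "depth_b" in merged.columns else (
        "depth" if "depth" in merged.columns and "depth" in calls_b.columns else None)
    if depth_col is not None:
        insufficient = merged[depth_col] < min_depth
    else:
        insufficient = merged["label_b"] == INSUFFICIENT
    insufficient |= merged["label_b"] == INSUFFICIENT
    insufficient |= merged["label_a"] == INSUFFICIENT
    ev = merged[~insufficient]
    pa = ev["label_a"].isin(PRESENT_LABELS)
    pb = ev["label_b"].isin(PRESENT_LABELS)
    concordant = pa == pb
    major = ev["label_a"] == MAJOR
    minor = ev["label_a"] == MINOR
    return ConcordanceReport(
        n_events=n_events,
        n_insufficient=int(insufficient.sum()),
        n_evaluable=len(ev),
        n_concordant=int(concordant.sum()),
        major_concordant=int((concordant & major).sum()),
        major_total=int(major.sum()),
        minor_concordant=int((concordant & minor).sum()),
        minor_total=int(minor.sum()),
    )
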