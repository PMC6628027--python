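"""End-to-end drivers tying the per-module operations together.

``analyze_sample`` runs segmentation, BAF-band summarisation, the
purity/ploidy grid fit, allele-specific assignment and ploidy
classification for one sample; ``analyze_patient`` adds the CNA tree,
mutation clonality and expression stages for a whole multi-region
patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import allelic_ploidy as ap
from . import clonality as cl
from . import cna_segmentation as cs
from . import expression as ex
from . import phylogeny as ph
from .synthetic_cohort import PatientData


@dataclass
class SampleProfile:
    """One tumour sample's inferred copy-number profile."""
    name: str
    role: str
    segments: pd.DataFrame              # allele-specific segment table
    bands: list[ap.BafBandSummary]
    fit: ap.PurityPloidyFit
    ploidy_class: str

    @property
    def purity(self) -> float:
        return self.fit.purity

    @property
    def ploidy(self) -> float:
        return self.fit.ploidy


def analyze_sample(probes: pd.DataFrame, het_sites: pd.DataFrame,
                   name: str = "sample", role: str = "primary",
                   penalty: float = 5.0, min_probes: int = 10,
                   min_sites: int = 10, max_residual: float = 0.1,
                   intermediate_tol: float = 0.1) -> SampleProfile:
    """Full single-sample inference from probe log2 ratios and het sites."""
    seg = cs.segment_log2(probes, penalty=penalty, min_probes=min_probes)
    bands = ap.bands_for_segments(seg, het_sites, min_sites=min_sites)
    fit = ap.fit_purity_ploidy(seg, bands)
    allelic = ap.assign_allele_specific_cn(seg, bands, fit, max_residual=max_residual)
    allelic = cs.flag_intermediate_segments(allelic, fit, tol=intermediate_tol)
    cls = ap.classify_ploidy(allelic)
    return SampleProfile(name, role, allelic, bands, fit, cls)


@dataclass
class PatientAnalysis:
    profiles: dict[str, SampleProfile]
    distances: pd.DataFrame
    tree: object
    root_split: tuple
    neighbors: pd.DataFrame
    calls: pd.DataFrame
    presence: pd.DataFrame
    sharing: cl.SharingSummary
    de: ex.DifferentialResult
    cluster_split: list = field(default_factory=list)


def analyze_patient(data: PatientData, n_variable_genes: int = 500,
                    fc_threshold: float = 3.0, p_threshold: float = 0.01,
                    **sample_kwargs) -> PatientAnalysis:
    """Run the whole pipeline on one simulated (or assembled) patient."""
    roles = data.roles
    het_by_sample = dict(tuple(data.germline.groupby("sample")))
    profiles = {}
    for name in data.sample_names:
        profiles[name] = analyze_sample(
            data.probes[name], het_by_sample[name],
            name=name, role=roles[name], **sample_kwargs)

    seg_by_sample = {n: p.segments for n, p in profiles.items()}
    mat, mask = ph.copy_profile_matrix(seg_by_sample)
    mat, mask = ph.add_normal_profile(mat, mask)
    dist = ph.cna_distance_matrix(mat, mask)
    tree = ph.build_nj_tree(dist, outgroup=ph.NORMAL_ID)
    split = ph.root_split(tree, outgroup=ph.NORMAL_ID)
    neighbors = ph.nearest_neighbor_report(dist.drop(index=ph.NORMAL_ID,
                                                     columns=ph.NORMAL_ID))

    purities = {n: p.fit.purity for n, p in profiles.items()}
    local = cl.local_copy_lookup(seg_by_sample, data.somatic)
    calls = cl.classify_mutations(data.somatic, purities, local)
    presence = cl.build_presence_matrix(calls)
    sharing = cl.summarize_sharing(presence, roles)

    logm = ex.log_transform(data.expression)
    top = ex.select_variable_genes(logm, n_variable_genes)
    Z, _newick, labels = ex.cluster_samples(logm, top)
    clusters = ex.cut_clusters(Z, labels, k=2)
    de = ex.differential_expression(data.expression, roles,
                                    fc_threshold=fc_threshold,
                                    p_threshold=p_threshold)
    return PatientAnalysis(profiles, dist, tree, split, neighbors,
                           calls, presence, sharing, de, clusters)


def baf_only_summary(het_sites: pd.DataFrame, min_sites: int = 10) -> pd.DataFrame:
    """Degraded chromosome-level mode for samples lacking array data.

    Summarises the mirrored BAF band, parity and LOH flag per chromosome
    from germline het sites alone — enough to match a sample to a lineage
    by band structure, but no purity or ploidy estimate.
    """
    rows = []
    for chrom, sub in het_sites.groupby("chrom", sort=False):
        depth = sub["ref_count"] + sub["alt_count"]
        baf = sub["alt_count"] / depth.replace(0, 1)
        band = ap.baf_bands(baf.to_numpy(), depth.to_numpy(), min_sites=min_sites)
        rows.append((chrom, band.band, band.n_het_sites, band.parity, band.loh_flag))
    return pd.DataFrame(rows, columns=["chrom", "band", "n_sites", "parity", "loh"])
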