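"""Seeded simulator of a multi-region renal-cancer patient.

Generates a planted clone tree for an index patient with nine tumour
samples — four primary regions (Pr1–Pr4), one vena-cava tumour thrombus
(VT) and four lung metastases (M1–M4) — plus a matched normal. The
near-diploid lineage (Pr1–Pr3) carries truncal events only (loss of one
chr3 homolog, 5q gain, focal 2q/10q losses) with region-private subclones
(chr2 gain in Pr1; 1p and chr4 loss in Pr3). A whole-genome-doubling
branch feeds Pr4/VT/M1–M4 and is followed by losses bringing 1p, chr9 and
chr13 back to two balanced copies, single-copy losses of chr8/14/15 (odd
parity), and gains of chr7, 12p and 20q; M4 carries an extra 11q loss.

Measured signals follow a simple model: per-probe log2 ratios are the
purity/ploidy-normalised expectation of the fraction-weighted copy number
plus Gaussian noise; B-allele and variant-allele read counts are binomial
at a Poisson-distributed depth. Somatic mutation sharing emulates the
index patient: 18 truncal of 146, 51 restricted to primaries (Pr1 and Pr3
with 18 and 10 private mutations), 20 metastasis-only, three Pr4-private
mutations shared with VT and all metastases.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._genome import AUTOSOMES, CHROM_LENGTHS, CHROMOSOMES, MB
from .allelic_ploidy import expected_log2

PRIMARY, THROMBUS, METASTASIS = "primary", "thrombus", "metastasis"

WGD = "WGD"  # whole-genome-doubling marker in a clone's event list


@dataclass(frozen=True)
class CNAEvent:
    """A copy-number event on one parental allele (or both) of an interval."""
    chrom: str
    start: int
    end: int
    allele: str  # "A", "B" or "both"
    delta: int


@dataclass
class CloneNode:
    """A clone in the planted tree; ``events`` apply on the incoming branch."""
    id: str
    parent: str | None
    events: list = field(default_factory=list)


@dataclass
class SampleSpec:
    name: str
    role: str
    composition: dict[str, float]  # clone id -> fraction of tumour cells
    purity: float

    def validate(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"sample {self.name}: purity must be in (0, 1]")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sample {self.name}: clone fractions sum to {total}, not 1")


@dataclass
class CohortSpec:
    """Study conditions for one simulated patient."""
    samples: list[SampleSpec]
    probe_spacing: int = 100_000       # bp between array probes (~30k genome-wide)
    het_spacing: int = 500_000         # bp between germline heterozygous sites
    depth: int = 60                    # mean sequencing depth (exome-like)
    log2_sigma: float = 0.15           # per-probe Gaussian noise on log2 ratios
    n_mutations: int = 146             # non-synonymous somatic mutations
    n_trunk: int = 18                  # shared by all tumour samples
    n_primary_subset: int = 51         # restricted to primary regions
    n_metastasis_only: int = 20        # restricted to metastases
    n_genes: int = 5000
    n_de: int = 57                     # primary-vs-metastasis DE genes (32 up, 25 down)
    n_de_up: int = 32
    de_fold_range: tuple[float, float] = (3.5, 10.0)   # linear fold change
    n_lineage_genes: int = 150         # near-diploid vs post-WGD lineage markers
    lineage_delta_range: tuple[float, float] = (2.5, 4.5)  # |log2| shift
    expression_sigma: float = 0.4      # within-group sd on log2 scale
    seed: int = 0

    def validate(self) -> None:
        for s in self.samples:
            s.validate()


@dataclass
class PatientData:
    """In-memory result of one simulation."""
    spec: CohortSpec
    clones: dict[str, CloneNode]
    probes: dict[str, pd.DataFrame]        # sample -> chrom/pos/log2
    germline: pd.DataFrame                 # long site x sample table
    somatic: pd.DataFrame                  # long mutation x sample table
    expression: pd.DataFrame               # genes x tumour samples (linear scale)
    truth: dict[str, pd.DataFrame]

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.spec.samples]

    @property
    def roles(self) -> dict[str, str]:
        return {s.name: s.role for s in self.spec.samples}

    @property
    def purities(self) -> dict[str, float]:
        return {s.name: s.purity for s in self.spec.samples}


# ---------------------------------------------------------------------------
# Planted index-patient structure

def make_index_clone_tree() -> dict[str, CloneNode]:
    """The planted clone tree of the index patient.

    Root is the normal genome (all autosomes 1+1). Truncal events are shared
    by every tumour clone; the WGD branch founds the metastatic lineage.
    """
    ev = CNAEvent
    L = CHROM_LENGTHS
    clones = {
        "normal": CloneNode("normal", None, []),
        # truncal: chr3 LOH, 5q gain, focal 2q and 10q losses
        "trunk": CloneNode("trunk", "normal", [
            ev("chr3", 0, L["chr3"], "B", -1),
            ev("chr5", 50 * MB, L["chr5"], "A", +1),
            ev("chr2", 205 * MB, 225 * MB, "B", -1),
            ev("chr10", 110 * MB, 130 * MB, "B", -1),
        ]),
        # near-diploid subclones (seen mixed within Pr1 / Pr3)
        "sub_chr2gain": CloneNode("sub_chr2gain", "trunk", [
            ev("chr2", 0, L["chr2"], "A", +1),
        ]),
        "sub_1p4loss": CloneNode("sub_1p4loss", "trunk", [
            ev("chr1", 0, 125 * MB, "B", -1),
            ev("chr4", 0, L["chr4"], "B", -1),
        ]),
        # whole-genome doubling founds the metastatic lineage
        "wgd": CloneNode("wgd", "trunk", [
            WGD,
            ev("chr1", 0, 125 * MB, "A", -1), ev("chr1", 0, 125 * MB, "B", -1),
            ev("chr9", 0, L["chr9"], "A", -1), ev("chr9", 0, L["chr9"], "B", -1),
            ev("chr13", 0, L["chr13"], "A", -1), ev("chr13", 0, L["chr13"], "B", -1),
            ev("chr8", 0, L["chr8"], "B", -1),
            ev("chr14", 0, L["chr14"], "B", -1),
            ev("chr15", 0, L["chr15"], "B", -1),
            ev("chr7", 0, L["chr7"], "A", +1),
            ev("chr12", 0, 35 * MB, "A", +1),
            ev("chr20", 28 * MB, L["chr20"], "A", +1),
        ]),
        "c_pr4": CloneNode("c_pr4", "wgd", [ev("chr16", 35 * MB, L["chr16"], "A", +1)]),
        "c_m2": CloneNode("c_m2", "c_pr4", [ev("chr22", 20 * MB, L["chr22"], "B", -1)]),
        "c_vtm3": CloneNode("c_vtm3", "wgd", [ev("chr18", 18 * MB, L["chr18"], "B", -1)]),
        "c_m1": CloneNode("c_m1", "wgd", [ev("chr21", 0, L["chr21"], "A", +1)]),
        "c_m4": CloneNode("c_m4", "wgd", [
            ev("chr11", 53 * MB, L["chr11"], "A", -1),
            ev("chr11", 53 * MB, L["chr11"], "B", -1),
            ev("chr19", 0, L["chr19"], "A", +1),
        ]),
    }
    return clones


#: Default per-sample purities (tumour-cell fractions); the source study
#: never states purity, so these are configurable stand-ins in 0.6-0.9.
INDEX_PURITIES = {
    "Pr1": 0.75, "Pr2": 0.70, "Pr3": 0.80, "Pr4": 0.85, "VT": 0.90,
    "M1": 0.80, "M2": 0.75, "M3": 0.85, "M4": 0.70,
}


def index_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Default study conditions: the nine-sample index patient."""
    p = INDEX_PURITIES
    samples = [
        SampleSpec("Pr1", PRIMARY, {"trunk": 0.5, "sub_chr2gain": 0.5}, p["Pr1"]),
        SampleSpec("Pr2", PRIMARY, {"trunk": 1.0}, p["Pr2"]),
        SampleSpec("Pr3", PRIMARY, {"trunk": 0.5, "sub_1p4loss": 0.5}, p["Pr3"]),
        SampleSpec("Pr4", PRIMARY, {"c_pr4": 1.0}, p["Pr4"]),
        SampleSpec("VT", THROMBUS, {"c_vtm3": 1.0}, p["VT"]),
        SampleSpec("M1", METASTASIS, {"c_m1": 1.0}, p["M1"]),
        SampleSpec("M2", METASTASIS, {"c_m2": 1.0}, p["M2"]),
        SampleSpec("M3", METASTASIS, {"c_vtm3": 1.0}, p["M3"]),
        SampleSpec("M4", METASTASIS, {"c_m4": 1.0}, p["M4"]),
    ]
    spec = CohortSpec(samples=samples, seed=seed)
    if overrides:
        spec = replace(spec, **overrides)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Clone genotypes on a shared elementary-interval grid

class CloneGenotypes:
    """Allele-specific copy numbers of every clone on a shared interval grid."""

    def __init__(self, clones: dict[str, CloneNode]):
        self.clones = clones
        self.boundaries: dict[str, np.ndarray] = {}
        for chrom in CHROMOSOMES:
            pts = {0, CHROM_LENGTHS[chrom]}
            for clone in clones.values():
                for e in clone.events:
                    if e is not WGD and e.chrom == chrom:
                        pts.update((e.start, e.end))
            self.boundaries[chrom] = np.array(sorted(pts), dtype=np.int64)
        # per clone: chrom -> (nA, nB) arrays over elementary intervals
        self.states: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for cid in clones:
            self.states[cid] = self._compute(cid)

    def _path(self, cid: str) -> list[CloneNode]:
        path = []
        node = self.clones[cid]
        while node is not None:
            path.append(node)
            node = self.clones[node.parent] if node.parent else None
        return path[::-1]

    def _compute(self, cid: str):
        state = {}
        for chrom in CHROMOSOMES:
            n = len(self.boundaries[chrom]) - 1
            state[chrom] = (np.ones(n, dtype=np.int64), np.ones(n, dtype=np.int64))
        for node in self._path(cid):
            for e in node.events:
                if e is WGD:
                    for chrom in CHROMOSOMES:
                        nA, nB = state[chrom]
                        state[chrom] = (nA * 2, nB * 2)
                    continue
                b = self.boundaries[e.chrom]
                lo = np.searchsorted(b, e.start)
                hi = np.searchsorted(b, e.end)
                nA, nB = state[e.chrom]
                if e.allele in ("A", "both"):
                    nA[lo:hi] += e.delta
                if e.allele in ("B", "both"):
                    nB[lo:hi] += e.delta
                if (nA[lo:hi] < 0).any() or (nB[lo:hi] < 0).any():
                    raise ValueError(f"clone {cid}: negative copy number on {e.chrom}")
        return state

    def interval_index(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.boundaries[chrom], pos, side="right") - 1

    def sample_mixture(self, composition: dict[str, float], chrom: str):
        """Fraction-weighted (nA, nB) over the interval grid of ``chrom``.

        Returns float arrays; also a boolean 'clonal' mask where every clone
        in the mixture agrees exactly.
        """
        n = len(self.boundaries[chrom]) - 1
        mA = np.zeros(n)
        mB = np.zeros(n)
        clonal = np.ones(n, dtype=bool)
        ref = None
        for cid, frac in composition.items():
            nA, nB = self.states[cid][chrom]
            mA += frac * nA
            mB += frac * nB
            if ref is None:
                ref = (nA, nB)
            else:
                clonal &= (nA == ref[0]) & (nB == ref[1])
        return mA, mB, clonal

    def tumour_ploidy(self, composition: dict[str, float],
                      chromosomes=CHROMOSOMES) -> float:
        """Length-weighted mean total copy number of the tumour cells."""
        total = 0.0
        length = 0
        for chrom in chromosomes:
            b = self.boundaries[chrom]
            widths = np.diff(b)
            mA, mB, _ = self.sample_mixture(composition, chrom)
            total += float(((mA + mB) * widths).sum())
            length += int(widths.sum())
        return total / length


# ---------------------------------------------------------------------------
# Signal realisation

def _rng(seed: int, name: str) -> np.random.Generator:
    """Named deterministic substream derived from the global seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def realize_sample_signals(genotypes: CloneGenotypes, sample: SampleSpec,
                           spec: CohortSpec, seed: int | None = None):
    """Generate probe log2 ratios and germline-het BAF counts for one sample.

    Per probe: log2 of the fraction-weighted copy number under the sample's
    purity and ploidy, plus Gaussian noise. Per het site: alt reads binomial
    at Poisson depth around the expected B-allele frequency.
    Returns ``(probes_df, het_df)``.
    """
    sample.validate()
    seed = spec.seed if seed is None else seed
    rho = sample.purity
    psi = genotypes.tumour_ploidy(sample.composition)

    rng_p = _rng(seed, f"probes:{sample.name}")
    chroms, positions, log2s = [], [], []
    for chrom in CHROMOSOMES:
        pos = np.arange(spec.probe_spacing // 2, CHROM_LENGTHS[chrom],
                        spec.probe_spacing, dtype=np.int64)
        mA, mB, _ = genotypes.sample_mixture(sample.composition, chrom)
        idx = genotypes.interval_index(chrom, pos)
        ctot = mA[idx] + mB[idx]
        exp = expected_log2(ctot, rho, psi)
        noise = rng_p.normal(0.0, spec.log2_sigma, size=len(pos)) if spec.log2_sigma > 0 else 0.0
        chroms.extend([chrom] * len(pos))
        positions.append(pos + 1)  # report 1-based
        log2s.append(exp + noise)
    probes = pd.DataFrame({
        "chrom": chroms,
        "pos": np.concatenate(positions),
        "log2": np.concatenate(log2s),
    })

    rng_b = _rng(seed, f"baf:{sample.name}")
    rows = []
    for chrom in CHROMOSOMES:
        pos = np.arange(spec.het_spacing // 2, CHROM_LENGTHS[chrom],
                        spec.het_spacing, dtype=np.int64)
        mA, mB, _ = genotypes.sample_mixture(sample.composition, chrom)
        idx = genotypes.interval_index(chrom, pos)
        # which parental haplotype carries the B allele at each site is a
        # property of the site, not the sample: derive from a site-keyed stream
        site_rng = _rng(seed, f"hetphase:{chrom}")
        b_on_A = site_rng.random(len(pos)) < 0.5
        n_b = np.where(b_on_A, mA[idx], mB[idx])
        ctot = mA[idx] + mB[idx]
        b_exp = (rho * n_b + (1 - rho)) / (rho * ctot + 2 * (1 - rho))
        depth = rng_b.poisson(spec.depth, size=len(pos))
        alt = rng_b.binomial(np.maximum(depth, 0), np.clip(b_exp, 0, 1))
        for p, d, a, be in zip(pos, depth, alt, b_exp):
            rows.append((chrom, int(p) + 1, sample.name, int(d) - int(a), int(a), float(be)))
    het = pd.DataFrame(rows, columns=["chrom", "pos", "sample",
                                      "ref_count", "alt_count", "baf_expected"])
    return probes, het


# ---------------------------------------------------------------------------
# Somatic mutations

_DIPLOID = ("Pr1", "Pr2", "Pr3")
_POSTWGD = ("Pr4", "VT", "M1", "M2", "M3", "M4")
_METS = ("M1", "M2", "M3", "M4")

#: regions carrying subclonal events in mixture samples; somatic mutations
#: are placed outside them so every sample has a clonal local copy state
_UNSAFE = {"chr2": [(0, CHROM_LENGTHS["chr2"])],
           "chr4": [(0, CHROM_LENGTHS["chr4"])],
           "chr1": [(0, 125 * MB)],
           "chrX": [(0, CHROM_LENGTHS["chrX"])]}


def _safe_position(rng: np.random.Generator) -> tuple[str, int]:
    while True:
        chrom = AUTOSOMES[rng.integers(len(AUTOSOMES))]
        pos = int(rng.integers(0, CHROM_LENGTHS[chrom]))
        bad = any(lo <= pos < hi for lo, hi in _UNSAFE.get(chrom, []))
        if not bad:
            return chrom, pos


def _draw_mutation_plan(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Plant the mutation catalogue: per mutation, member samples and CCFs.

    Category counts follow the emulated patient: ``n_trunk`` mutations in all
    samples, ``n_primary_subset`` restricted to primaries (Pr1 18, Pr3 10
    private), ``n_metastasis_only`` in metastases only, a VT-private handful,
    two VT+all-metastases mutations, three Pr4-private mutations shared with
    VT and all metastases, and the remainder on the whole metastatic lineage.
    """
    samples = ["Pr1", "Pr2", "Pr3", "Pr4", "VT", "M1", "M2", "M3", "M4"]
    entries = []  # (category, {sample: ccf}, pre_wgd)

    for _ in range(spec.n_trunk):
        entries.append(("trunk", {s: 1.0 for s in samples}, True))

    # primaries: fixed Pr1/Pr3 private loads, drawn Pr2/Pr4 loads, remainder shared
    priv = {"Pr1": 18, "Pr3": 10,
            "Pr2": int(rng.integers(3, 7)), "Pr4": int(rng.integers(3, 7))}
    for s, k in priv.items():
        for _ in range(k):
            mem = {s: 1.0}
            entries.append((f"private_{s}", mem, False))
    n_shared_primary = spec.n_primary_subset - sum(priv.values())
    if n_shared_primary < 0:
        raise ValueError("primary-subset budget smaller than private loads")
    diploid = list(_DIPLOID)
    for _ in range(n_shared_primary):
        size = int(rng.integers(2, 4))  # pairs or the full near-diploid trio
        subset = list(rng.choice(diploid, size=size, replace=False))
        mem = {s: 1.0 for s in subset}
        # occasional low-CCF presence in one more near-diploid region
        rest = [s for s in diploid if s not in subset]
        if rest and rng.random() < 0.5:
            mem[rest[int(rng.integers(len(rest)))]] = 0.3
        entries.append(("primary_shared", mem, False))

    # metastases: private loads uniform 3-6, resampled until they fit the
    # metastasis-only budget; remainder shared by metastasis pairs
    while True:
        mpriv = {m: int(rng.integers(3, 7)) for m in _METS}
        if sum(mpriv.values()) <= spec.n_metastasis_only:
            break
    for m, k in mpriv.items():
        for _ in range(k):
            mem = {m: 1.0}
            if rng.random() < 0.4:
                other = [x for x in _METS if x != m]
                mem[other[int(rng.integers(len(other)))]] = 0.3
            entries.append((f"private_{m}", mem, False))
    for _ in range(spec.n_metastasis_only - sum(mpriv.values())):
        pair = list(rng.choice(list(_METS), size=2, replace=False))
        entries.append(("metastasis_shared", {s: 1.0 for s in pair}, False))

    vt_private = int(rng.integers(3, 7))
    for _ in range(vt_private):
        entries.append(("private_VT", {"VT": 1.0}, False))
    for _ in range(2):  # VT + all metastases (ARHGAP12/CENPN-like pattern)
        entries.append(("vt_metastases", {s: 1.0 for s in ("VT",) + _METS}, False))
    # three Pr4-origin mutations shared with VT and all metastases
    for _ in range(3):
        entries.append(("pr4_vt_metastases", {s: 1.0 for s in _POSTWGD}, False))
    # fill the catalogue on the metastatic-lineage branch (pre/post WGD mixed)
    n_fill = spec.n_mutations - len(entries)
    if n_fill < 0:
        raise ValueError("mutation category counts exceed n_mutations")
    for _ in range(n_fill):
        entries.append(("metastatic_lineage", {s: 1.0 for s in _POSTWGD},
                        bool(rng.random() < 0.5)))

    rows = []
    for i, (category, members, pre_wgd) in enumerate(entries):
        chrom, pos = _safe_position(rng)
        rows.append({
            "mutation_id": f"mut{i + 1:04d}", "gene_id": f"GENE{i + 1:04d}",
            "chrom": chrom, "pos": pos + 1, "category": category,
            "pre_wgd": pre_wgd,
            **{f"ccf_{s}": members.get(s, 0.0) for s in samples},
        })
    return pd.DataFrame(rows)


def _realize_mutation_counts(plan: pd.DataFrame, genotypes: CloneGenotypes,
                             spec: CohortSpec, seed: int):
    """Turn the planted catalogue into read counts and a truth table."""
    rng = _rng(seed, "somatic")
    samples = [s for s in spec.samples]
    long_rows, truth_rows = [], []
    for _, mut in plan.iterrows():
        chrom, pos0 = mut["chrom"], int(mut["pos"]) - 1
        for s in samples:
            mA, mB, clonal = genotypes.sample_mixture(s.composition, chrom)
            idx = int(genotypes.interval_index(chrom, np.array([pos0]))[0])
            nA_raw, nB_raw = mA[idx], mB[idx]
            ctot = nA_raw + nB_raw
            n_major = int(round(max(nA_raw, nB_raw)))
            ccf = float(mut[f"ccf_{s.name}"])
            post_wgd_sample = any(c in ("wgd", "c_pr4", "c_m2", "c_vtm3", "c_m1", "c_m4")
                                  for c in s.composition)
            m_nominal = 2 if (mut["pre_wgd"] and post_wgd_sample) else 1
            m = min(m_nominal, max(n_major, 1))
            rho = s.purity
            vaf = rho * m * ccf / (rho * ctot + 2 * (1 - rho)) if ccf > 0 else 0.0
            depth = int(rng.poisson(spec.depth))
            alt = int(rng.binomial(depth, min(vaf, 1.0))) if depth > 0 else 0
            label = "absent" if ccf == 0 else ("major" if ccf >= 0.5 else "minor")
            long_rows.append((mut["mutation_id"], mut["gene_id"], chrom, pos0 + 1,
                              s.name, depth - alt, alt, depth))
            truth_rows.append((mut["mutation_id"], s.name, ccf, m if ccf > 0 else 0,
                               float(ctot), n_major, label))
    long_df = pd.DataFrame(long_rows, columns=[
        "mutation_id", "gene_id", "chrom", "pos", "sample",
        "ref_count", "alt_count", "depth"])
    truth = pd.DataFrame(truth_rows, columns=[
        "mutation_id", "sample", "ccf", "multiplicity", "local_total_cn",
        "local_major_cn", "label"])
    return long_df, truth


# ---------------------------------------------------------------------------
# Expression

def _simulate_expression(spec: CohortSpec, seed: int):
    """Gene x tumour-sample matrix (linear scale) with planted structure.

    Two planted gene sets: the primary-vs-metastasis DE set (fold change
    sampled in ``de_fold_range``; VT receives metastasis-like levels but is
    excluded from testing), and a lineage set separating the near-diploid
    from the post-WGD lineage which drives the Fig-4-style clustering split.
    """
    rng = _rng(seed, "expression")
    samples = [s.name for s in spec.samples]
    n = spec.n_genes
    genes = np.array([f"G{i + 1:05d}" for i in range(n)])
    baseline = rng.normal(6.0, 1.5, size=n)

    special = rng.choice(n, size=spec.n_de + spec.n_lineage_genes, replace=False)
    de_idx = special[:spec.n_de]
    lin_idx = special[spec.n_de:]
    de_dir = np.array([1] * spec.n_de_up + [-1] * (spec.n_de - spec.n_de_up))
    de_fc = rng.uniform(*spec.de_fold_range, size=spec.n_de)
    lin_delta = rng.uniform(*spec.lineage_delta_range, size=spec.n_lineage_genes)
    lin_sign = rng.choice([-1.0, 1.0], size=spec.n_lineage_genes)

    met_like = {"M1", "M2", "M3", "M4", "VT"}        # DE axis (VT met-like, untested)
    wgd_lineage = {"Pr4", "VT", "M1", "M2", "M3", "M4"}  # clustering axis

    levels = np.tile(baseline[:, None], (1, len(samples)))
    for j, name in enumerate(samples):
        if name in met_like:
            levels[de_idx, j] += de_dir * np.log2(de_fc)
        if name in wgd_lineage:
            levels[lin_idx, j] += lin_sign * lin_delta
    z = levels + rng.normal(0.0, spec.expression_sigma, size=levels.shape)
    linear = np.maximum(2.0 ** z - 1.0, 0.0)
    mat = pd.DataFrame(linear, index=genes, columns=samples)

    truth = pd.DataFrame({
        "gene": np.concatenate([genes[de_idx], genes[lin_idx]]),
        "set": ["de"] * spec.n_de + ["lineage"] * spec.n_lineage_genes,
        "direction": (["up_in_metastasis"] * spec.n_de_up
                      + ["down_in_metastasis"] * (spec.n_de - spec.n_de_up)
                      + ["lineage_up" if s > 0 else "lineage_down" for s in lin_sign]),
        "fold_change": np.concatenate([de_fc, 2.0 ** lin_delta]),
    })
    return mat, truth


# ---------------------------------------------------------------------------
# Whole-patient simulation

def simulate_patient(spec: CohortSpec | None = None, seed: int | None = None) -> PatientData:
    """Simulate one patient fully in memory; deterministic given the seed."""
    if spec is None:
        spec = index_cohort_spec(seed=0 if seed is None else seed)
    if seed is not None and seed != spec.seed:
        spec = replace(spec, seed=seed)
    spec.validate()
    seed = spec.seed

    clones = make_index_clone_tree()
    genotypes = CloneGenotypes(clones)

    probes, het_parts = {}, []
    for s in spec.samples:
        p, h = realize_sample_signals(genotypes, s, spec, seed)
        probes[s.name] = p
        het_parts.append(h)
    # matched normal: balanced heterozygous sites
    rngn = _rng(seed, "baf:Normal")
    normal_rows = []
    for chrom in CHROMOSOMES:
        pos = np.arange(spec.het_spacing // 2, CHROM_LENGTHS[chrom],
                        spec.het_spacing, dtype=np.int64)
        depth = rngn.poisson(spec.depth, size=len(pos))
        alt = rngn.binomial(np.maximum(depth, 0), 0.5)
        for p, d, a in zip(pos, depth, alt):
            normal_rows.append((chrom, int(p) + 1, "Normal", int(d) - int(a), int(a), 0.5))
    het_parts.append(pd.DataFrame(normal_rows, columns=het_parts[0].columns))
    germline = pd.concat(het_parts, ignore_index=True)
    germline["germline"] = True

    plan = _draw_mutation_plan(spec, _rng(seed, "mutation_plan"))
    somatic, mut_truth = _realize_mutation_counts(plan, genotypes, spec, seed)
    somatic["germline"] = False

    expression, expr_truth = _simulate_expression(spec, seed)

    # truth tables ------------------------------------------------------
    seg_rows = []
    for s in spec.samples:
        for chrom in CHROMOSOMES:
            b = genotypes.boundaries[chrom]
            mA, mB, clonal = genotypes.sample_mixture(s.composition, chrom)
            for i in range(len(b) - 1):
                nA = max(mA[i], mB[i])
                nB = min(mA[i], mB[i])
                seg_rows.append((s.name, chrom, int(b[i]), int(b[i + 1]),
                                 float(mA[i] + mB[i]),
                                 int(round(nA)) if clonal[i] else -1,
                                 int(round(nB)) if clonal[i] else -1,
                                 bool(clonal[i])))
    seg_truth = pd.DataFrame(seg_rows, columns=[
        "sample", "chrom", "start", "end", "total_cn_mean",
        "major_cn", "minor_cn", "clonal"])

    sample_rows = []
    for s in spec.samples:
        psi = genotypes.tumour_ploidy(s.composition, AUTOSOMES)
        cls = "near-diploid" if psi < 2.7 else ("near-tetraploid" if psi > 3.3 else "other")
        sample_rows.append((s.name, s.role, s.purity, psi, cls))
    sample_truth = pd.DataFrame(sample_rows, columns=[
        "sample", "role", "purity", "ploidy", "ploidy_class"])

    truth = {
        "segments": seg_truth,
        "samples": sample_truth,
        "mutations": mut_truth,
        "mutation_plan": plan,
        "expression": expr_truth,
    }
    return PatientData(spec, clones, probes, germline, somatic, expression, truth)


def simulate_cohort(spec: CohortSpec | None = None, out_dir=None,
                    seed: int | None = None) -> PatientData:
    """Simulate a patient and write the dataset to ``out_dir``.

    Writes per-sample probe tables, a germline and a somatic multi-sample
    VCF, the expression TSV, a sample/role table and all truth tables.
    """
    from . import io_formats as io

    data = simulate_patient(spec, seed)
    if out_dir is None:
        return data
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / "probes"
        probe.mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    for name, df in data.probes.items():
        io.write_probe_table(df, probe / f"{name}.tsv")
    all_samples = data.sample_names + ["Normal"]
    io.write_vcf(data.germline.assign(ref="A", alt="G"), all_samples,
                 out / "germline.vcf", germline=True)
    som = data.somatic.copy()
    normal_rows = som.drop_duplicates("mutation_id").assign(
        sample="Normal", alt_count=0, ref_count=data.spec.depth)
    som_all = pd.concat([som, normal_rows], ignore_index=True)
    io.write_vcf(som_all.assign(ref="A", alt="T"), all_samples, out / "somatic.vcf")
    io.write_expression_tsv(data.expression, out / "expression.tsv")
    data.truth["segments"].to_csv(out / "truth_segments.tsv", sep="\t", index=False)
    data.truth["samples"].to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    data.truth["mutations"].to_csv(out / "truth_mutations.tsv", sep="\t", index=False)
    data.truth["expression"].to_csv(out / "truth_expression.tsv", sep="\t", index=False)
    roles = pd.DataFrame({"sample": data.sample_names,
                          "role": [data.roles[s] for s in data.sample_names]})
    roles.to_csv(out / "roles.tsv", sep="\t", index=False)
    return data
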