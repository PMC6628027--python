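"""Absolute allele-specific copy number, purity and ploidy inference.

Combines segment-level log2 ratios with the B-allele-frequency (BAF) band
structure of germline heterozygous sites to assign integer allele-specific
copy states, detect loss of heterozygosity, and fit tumour purity (rho) and
ploidy (psi) by a joint grid search.

Measurement model
-----------------
A segment with ``cT`` total copies in a tumour of purity ``rho`` and mean
ploidy ``psi`` has expected log2 ratio::

    log2( (rho*cT + 2*(1-rho)) / (rho*psi + 2*(1-rho)) )

and a heterozygous site on a segment with major/minor copies ``(nA, nB)``
has expected mirrored BAF::

    max(b, 1-b),   b = (rho*nB + (1-rho)) / (rho*(nA+nB) + 2*(1-rho))

The grid search scores every (rho, psi) pair by the best integer state per
segment under a joint squared-residual objective; a band sitting at 0.5
forces a balanced state (nA == nB), which is what separates a two-copy
balanced segment in a tetraploid genome from a one-copy loss in a diploid
one, and a band at the mirrored extreme marks all copies as coming from a
single parental allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._genome import AUTOSOMES

LOG2_FLOOR = -8.0  # documented floor for cT=0 at full purity

NEAR_DIPLOID = "near-diploid"
NEAR_TETRAPLOID = "near-tetraploid"
OTHER = "other"


class FitError(RuntimeError):
    """Purity/ploidy fitting or classification could not proceed."""


@dataclass
class BafBandSummary:
    """Mirrored-BAF band structure of the het sites on one segment."""
    segment_id: int
    band_centers: list[float]
    n_het_sites: int
    parity: str  # "even" (balanced), "odd" (imbalanced) or "indeterminate"
    loh_flag: bool

    @property
    def band(self) -> float:
        return self.band_centers[0] if self.band_centers else float("nan")

    @property
    def determinate(self) -> bool:
        return self.parity != "indeterminate"


@dataclass
class PurityPloidyFit:
    purity: float
    ploidy: float            # length-weighted mean assigned total copies
    grid_psi: float          # normalisation ploidy selected on the grid
    score: float
    ploidy_class: str
    baf_weight: float = 4.0
    max_cn: int = 8


def _grid(rho_step: float = 0.01, psi_step: float = 0.05):
    rho = np.round(np.arange(0.10, 1.00 + 1e-9, rho_step), 10)
    psi = np.round(np.arange(1.5, 5.0 + 1e-9, psi_step), 10)
    return rho, psi


def _states(max_cn: int = 8) -> np.ndarray:
    """All integer allele states (nA, nB) with nA >= nB >= 0, nA+nB <= max_cn."""
    out = [(a, b) for t in range(max_cn + 1) for b in range(t // 2 + 1)
           for a in [t - b] if a >= b]
    return np.array(sorted(set(out)), dtype=np.int64)


def expected_log2(cT, rho, psi):
    """Expected log2 tumour/reference intensity ratio for total copies ``cT``.

    Monotone increasing in ``cT``; 0 when ``cT == psi``. ``cT = 0`` at full
    purity would be -inf and is floored at ``LOG2_FLOOR``.
    """
    cT = np.asarray(cT, dtype=float)
    if not (0 < rho <= 1):
        raise ValueError("purity must be in (0, 1]")
    if psi <= 0:
        raise ValueError("ploidy must be positive")
    num = rho * cT + 2.0 * (1.0 - rho)
    den = rho * psi + 2.0 * (1.0 - rho)
    with np.errstate(divide="ignore"):
        out = np.log2(num / den)
    out = np.maximum(out, LOG2_FLOOR)
    return out if out.ndim else float(out)


def expected_baf(nA, nB, rho):
    """Expected mirrored B-allele frequency of state (nA, nB) at purity rho.

    Lies in [0.5, 1]; equals 0.5 iff nA == nB. The empty state (0, 0) at
    full purity has no defined BAF and returns NaN.
    """
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    if np.any(nB > nA) or np.any(nB < 0):
        raise ValueError("states must satisfy nA >= nB >= 0")
    if not (0 < rho <= 1):
        raise ValueError("purity must be in (0, 1]")
    num = rho * nB + (1.0 - rho)
    den = rho * (nA + nB) + 2.0 * (1.0 - rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(den > 0, num / den, np.nan)
    out = np.where(np.isnan(b), np.nan, np.maximum(b, 1.0 - b))
    return out if out.ndim else float(out)


def baf_bands(het_site_bafs, depths=None, min_sites: int = 10,
              segment_id: int = -1, parity_tol: float = 0.05,
              loh_level: float = 0.75) -> BafBandSummary:
    """Summarise the mirrored BAF band of one segment's het sites.

    The band centre is estimated by variance decomposition: unmirrored BAFs
    of a clonal state form a symmetric two-point mixture at ``0.5 +/- d``
    blurred by binomial sampling, so ``d`` is recovered as
    ``sqrt(max(0, var(baf) - mean(binomial variance)))``. This avoids the
    upward bias of averaging mirrored values at depth-limited coverage.

    A deviation below ``parity_tol`` is called balanced ("even" parity,
    nA == nB); fewer than ``min_sites`` sites give parity "indeterminate".
    A band at or above ``loh_level`` raises the (advisory) LOH flag.
    """
    bafs = np.asarray(het_site_bafs, dtype=float)
    bafs = bafs[np.isfinite(bafs)]
    n = len(bafs)
    if n < min_sites:
        return BafBandSummary(segment_id, [], n, "indeterminate", False)
    var = float(np.var(bafs))
    if depths is not None:
        depths = np.asarray(depths, dtype=float)
        noise = float(np.mean(np.clip(bafs * (1 - bafs), 1e-6, None)
                              / np.maximum(depths, 1)))
    else:
        noise = 0.0
    d = float(np.sqrt(max(var - noise, 0.0)))
    band = 0.5 + min(d, 0.5)
    parity = "even" if d < parity_tol else "odd"
    return BafBandSummary(segment_id, [band], n, parity, band >= loh_level)


def bands_for_segments(segments: pd.DataFrame, het_sites: pd.DataFrame,
                       min_sites: int = 10, **kwargs) -> list[BafBandSummary]:
    """Assign het sites to segments by coordinate overlap and summarise each.

    ``segments`` uses 0-based half-open coordinates; ``het_sites`` carries
    1-based positions with ref/alt read counts.
    """
    out = []
    het = het_sites.copy()
    depth = het["ref_count"] + het["alt_count"]
    het["baf"] = np.where(depth > 0, het["alt_count"] / depth.replace(0, 1), np.nan)
    het["depth"] = depth
    by_chrom = dict(tuple(het.groupby("chrom")))
    for i, seg in segments.reset_index(drop=True).iterrows():
        sites = by_chrom.get(seg["chrom"])
        if sites is None:
            out.append(BafBandSummary(i, [], 0, "indeterminate", False))
            continue
        sel = sites[(sites["pos"] - 1 >= seg["start"]) & (sites["pos"] - 1 < seg["end"])]
        sel = sel[sel["depth"] > 0]
        out.append(baf_bands(sel["baf"].to_numpy(), sel["depth"].to_numpy(),
                             min_sites=min_sites, segment_id=i, **kwargs))
    return out


def _segment_arrays(segments: pd.DataFrame, bands: list[BafBandSummary]):
    seg = segments.reset_index(drop=True)
    L = seg["mean_log2"].to_numpy(dtype=float)
    lengths = (seg["end"] - seg["start"]).to_numpy(dtype=float)
    band_val = np.array([b.band if b.determinate else np.nan for b in bands])
    parity = np.array([b.parity for b in bands])
    return seg, L, lengths, band_val, parity


def fit_purity_ploidy(segments: pd.DataFrame, bands: list[BafBandSummary],
                      grid=None, baf_weight: float = 4.0, max_cn: int = 8,
                      min_determinate: int = 5, residual_cap: float = 0.1,
                      halving_margin: float = 0.5) -> PurityPloidyFit:
    """Joint grid search for purity and ploidy.

    Scores each (rho, psi) pair by the sum over autosomal segments of the
    squared log2 residual plus ``baf_weight`` times the squared BAF-band
    residual at the best integer state (parity honoured as a hard
    constraint). The log2 part of each segment's contribution is capped at
    ``residual_cap`` so that subclonal mixture segments — which sit at
    half-integer levels — cannot dominate; BAF residuals are never capped,
    because band centres are robust averages over many sites and the
    loss-of-heterozygosity band is precisely what identifies purity.

    A diploid genome read as its genome-doubled twin (all states doubled,
    purity mapped to rho/(2-rho)) fits log2 and BAF data identically, so
    after locating the global optimum an explicit halving test is applied:
    the twin solution at (2*rho/(1+rho), psi/2) is evaluated in a local
    neighbourhood and adopted — repeatedly, while possible — unless its
    score is worse by more than ``halving_margin``. Halving a genuine
    post-doubling genome misfits every odd-copy chromosome and fails the
    test, while the spurious doubled reading of a diploid genome halves at
    essentially no cost. Solutions assigning more than 1% of the genome a
    homozygous deletion (the shifted degenerate ladder) are inadmissible.
    """
    if len(bands) != len(segments):
        raise ValueError("one band summary required per segment")
    seg, L, lengths, band_val, parity = _segment_arrays(segments, bands)
    use = seg["chrom"].isin(AUTOSOMES).to_numpy()
    if int(np.sum(~np.isnan(band_val[use]))) < min_determinate:
        raise FitError("fewer than %d segments with determinate BAF bands" % min_determinate)

    rho_grid, psi_grid = grid if grid is not None else _grid()
    states = _states(max_cn)
    nA, nB = states[:, 0], states[:, 1]
    cT = nA + nB

    R, P, S = len(rho_grid), len(psi_grid), len(states)
    e_baf = np.empty((R, S))
    e_log2 = np.empty((R, P, max_cn + 1))
    for i, rho in enumerate(rho_grid):
        e_baf[i] = expected_baf(nA, nB, rho)
        for j, psi in enumerate(psi_grid):
            e_log2[i, j] = expected_log2(np.arange(max_cn + 1), rho, psi)
    e_baf = np.nan_to_num(e_baf, nan=0.5)

    even_mask = (nA == nB)
    ks = np.flatnonzero(use)
    per_seg = np.empty((len(ks), R, P))
    zero_len = np.zeros((R, P))
    for kk, k in enumerate(ks):
        resid = np.minimum((L[k] - e_log2[:, :, cT]) ** 2, residual_cap)  # (R, P, S)
        if not np.isnan(band_val[k]):
            resid = resid + baf_weight * ((band_val[k] - e_baf) ** 2)[:, None, :]
            if parity[k] == "even":
                resid = np.where(even_mask[None, None, :], resid, np.inf)
            elif parity[k] == "odd":
                resid = np.where(even_mask[None, None, :], np.inf, resid)
        per_seg[kk] = resid.min(axis=2)
        zero_len += lengths[k] * (cT[np.argmin(resid, axis=2)] == 0)
    total = per_seg.sum(axis=0)
    # a solution calling more than a sliver of the genome homozygously
    # deleted is a shifted degenerate ladder, not a tumour genome
    total = np.where(zero_len / lengths[ks].sum() > 0.01, np.inf, total)
    if not np.isfinite(total).any():
        raise FitError("no admissible purity/ploidy solution on the grid")

    i, j = np.unravel_index(int(np.argmin(total)), total.shape)
    while True:  # explicit halving test against the doubled-twin degeneracy
        rho_c = 2.0 * rho_grid[i] / (1.0 + rho_grid[i])
        psi_c = psi_grid[j] / 2.0
        if psi_c < psi_grid[0] - 1e-9:
            break
        window = (np.abs(rho_grid[:, None] - rho_c) <= 0.05 + 1e-9) \
            & (np.abs(psi_grid[None, :] - psi_c) <= 0.1 + 1e-9)
        masked = np.where(window, total, np.inf)
        if not np.isfinite(masked).any():
            break
        i2, j2 = np.unravel_index(int(np.argmin(masked)), masked.shape)
        if total[i2, j2] > total[i, j] + halving_margin:
            break
        i, j = i2, j2
    rho_hat, psi_hat = float(rho_grid[i]), float(psi_grid[j])
    score = float(total[i, j])

    assigned = _best_states(L, band_val, parity, rho_hat, psi_hat,
                            baf_weight, max_cn)
    w = lengths[use]
    mean_ct = float(np.sum(assigned[use, 0] * w) / np.sum(w))
    cls = classify_value(mean_ct)
    return PurityPloidyFit(rho_hat, mean_ct, psi_hat, score, cls,
                           baf_weight=baf_weight, max_cn=max_cn)


def _best_states(L, band_val, parity, rho, psi, baf_weight, max_cn):
    """Per segment: (cT, nA, nB, log2_residual) of the best integer state."""
    states = _states(max_cn)
    nA, nB = states[:, 0], states[:, 1]
    cT = nA + nB
    e_l = expected_log2(cT, rho, psi)
    e_b = np.nan_to_num(expected_baf(nA, nB, rho), nan=0.5)
    even_mask = (nA == nB)
    out = np.empty((len(L), 4))
    for k in range(len(L)):
        resid = (L[k] - e_l) ** 2
        if not np.isnan(band_val[k]):
            resid = resid + baf_weight * (band_val[k] - e_b) ** 2
            if parity[k] == "even":
                resid = np.where(even_mask, resid, np.inf)
            elif parity[k] == "odd":
                resid = np.where(even_mask, np.inf, resid)
        s = int(np.argmin(resid))
        out[k] = (cT[s], nA[s], nB[s], abs(L[k] - e_l[s]))
    return out


def assign_allele_specific_cn(segments: pd.DataFrame, bands: list[BafBandSummary],
                              fit: PurityPloidyFit,
                              max_residual: float = 0.1) -> pd.DataFrame:
    """Assign integer (total, major, minor) copies to every segment.

    Segments whose observed mean log2 sits further than ``max_residual``
    from every modelled level under the fit are flagged unassigned — these
    are the intermediate, intra-sample-heterogeneous states.
    """
    seg, L, lengths, band_val, parity = _segment_arrays(segments, bands)
    best = _best_states(L, band_val, parity, fit.purity, fit.grid_psi,
                        fit.baf_weight, fit.max_cn)
    out = seg.copy()
    ok = best[:, 3] <= max_residual
    out["total_cn"] = np.where(ok, best[:, 0], -1).astype(int)
    out["major_cn"] = np.where(ok, best[:, 1], -1).astype(int)
    out["minor_cn"] = np.where(ok, best[:, 2], -1).astype(int)
    out["assigned"] = ok
    out["level_residual"] = best[:, 3]
    return out


def classify_value(mean_ct: float) -> str:
    if mean_ct < 2.7:
        return NEAR_DIPLOID
    if mean_ct > 3.3:
        return NEAR_TETRAPLOID
    return OTHER


def classify_ploidy(allelic_segments: pd.DataFrame,
                    min_assigned_frac: float = 0.8) -> str:
    """Classify a sample as near-diploid / near-tetraploid / other.

    Uses the length-weighted mean assigned total copy number over autosomes;
    requires at least ``min_assigned_frac`` of the autosomal segment length
    to carry an assignment.
    """
    seg = allelic_segments[allelic_segments["chrom"].isin(AUTOSOMES)]
    lengths = (seg["end"] - seg["start"]).to_numpy(dtype=float)
    assigned = seg["assigned"].to_numpy(dtype=bool)
    if lengths.sum() == 0 or lengths[assigned].sum() / lengths.sum() < min_assigned_frac:
        raise FitError("insufficient assigned genome fraction for ploidy class")
    mean_ct = float(np.sum(seg["total_cn"].to_numpy(dtype=float)[assigned]
                           * lengths[assigned]) / lengths[assigned].sum())
    return classify_value(mean_ct)


def detect_loh(allelic_segments: pd.DataFrame) -> pd.DataFrame:
    """Intervals whose remaining copies derive from a single parental allele.

    Reports assigned segments with minor copy number 0 (and at least one
    copy), merging adjacent runs per chromosome. Copy-neutral LOH after a
    genome doubling — e.g. a (2, 0) state — is reported over the same
    interval as the pre-doubling (1, 0) loss.
    """
    seg = allelic_segments[(allelic_segments["assigned"])
                           & (allelic_segments["minor_cn"] == 0)
                           & (allelic_segments["total_cn"] >= 1)]
    rows = []
    for chrom, grp in seg.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, r in grp.iterrows():
            if cur is not None and r["start"] <= cur[2]:
                cur[2] = max(cur[2], r["end"])
            else:
                if cur is not None:
                    rows.append(cur)
                cur = [chrom, int(r["start"]), int(r["end"])]
        if cur is not None:
            rows.append(cur)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["note"] = "single parental allele"
    return df
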