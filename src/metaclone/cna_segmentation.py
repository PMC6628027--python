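"""Segmentation of probe-level log2 ratios and segment state calling.

Recursive binary segmentation: each candidate split is the least-squares
best breakpoint of the current segment and is accepted when the residual
sum-of-squares improvement, normalised by a robust per-chromosome noise
variance, exceeds ``penalty * log(n)`` (a BIC-style rule). Noise is
estimated from median absolute successive differences, so the rule adapts
to the probe noise scale and degenerates gracefully to exact changepoint
recovery on noise-free data.

Segment states are labelled relative to a fitted purity/ploidy level model
when one is available; segments sitting away from every modelled integer
level are flagged "intermediate" — the signature of intra-sample
copy-number heterogeneity (a mixture of tumour subclones).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._genome import chrom_sort_key
from .allelic_ploidy import PurityPloidyFit, expected_log2

LOSS, NEUTRAL, GAIN, INTERMEDIATE = "loss", "neutral", "gain", "intermediate"


def _robust_sigma(x: np.ndarray) -> float:
    """Noise sd from median absolute successive differences."""
    if len(x) < 2:
        return 0.0
    d = np.abs(np.diff(x))
    return float(np.median(d) / (np.sqrt(2.0) * 0.6744897501960817))


def _best_split(x: np.ndarray, lo: int, hi: int, csum: np.ndarray,
                csum2: np.ndarray, min_probes: int):
    """Best single breakpoint of x[lo:hi]; returns (split, delta_ss)."""
    n = hi - lo
    if n < 2 * min_probes:
        return None, 0.0
    total_sum = csum[hi] - csum[lo]
    total_ss = (csum2[hi] - csum2[lo]) - total_sum ** 2 / n
    ks = np.arange(lo + min_probes, hi - min_probes + 1)
    left_n = ks - lo
    right_n = hi - ks
    left_sum = csum[ks] - csum[lo]
    right_sum = csum[hi] - csum[ks]
    ss = ((csum2[ks] - csum2[lo]) - left_sum ** 2 / left_n
          + (csum2[hi] - csum2[ks]) - right_sum ** 2 / right_n)
    j = int(np.argmin(ss))
    return int(ks[j]), float(total_ss - ss[j])


def _segment_chromosome(pos: np.ndarray, x: np.ndarray, penalty: float,
                        min_probes: int) -> list[tuple[int, int]]:
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x ** 2)])
    sigma2 = max(_robust_sigma(x) ** 2, 1e-12)

    pieces = []

    def recurse(lo: int, hi: int) -> None:
        split, delta = _best_split(x, lo, hi, csum, csum2, min_probes)
        if split is not None and delta > penalty * np.log(hi - lo) * sigma2:
            recurse(lo, split)
            recurse(split, hi)
        else:
            pieces.append((lo, hi))

    recurse(0, n)
    return sorted(pieces)


def segment_log2(probes: pd.DataFrame, penalty: float = 5.0,
                 min_probes: int = 10) -> pd.DataFrame:
    """Segment a sample's probe table into constant-level pieces.

    ``probes`` has columns chrom, pos (1-based), log2. Returns a segment
    table (0-based half-open coordinates spanning the probe span of each
    chromosome, boundaries at inter-probe midpoints) with columns chrom,
    start, end, n_probes, mean_log2. Per chromosome the segments partition
    the probe set.
    """
    rows = []
    order = sorted(probes["chrom"].unique(), key=chrom_sort_key)
    for chrom in order:
        sub = probes[probes["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        x = sub["log2"].to_numpy(dtype=float)
        if len(x) == 0:
            warnings.warn(f"{chrom}: no probes, no segments", stacklevel=2)
            continue
        if len(x) < min_probes:
            pieces = [(0, len(x))]
        else:
            pieces = _segment_chromosome(pos, x, penalty, min_probes)
        # boundaries: midpoints between flanking probes, probe span at the ends
        for lo, hi in pieces:
            start = int(pos[lo]) - 1 if lo == 0 else int((pos[lo - 1] + pos[lo]) // 2)
            end = int(pos[hi - 1]) if hi == len(pos) else int((pos[hi - 1] + pos[hi]) // 2)
            rows.append((chrom, start, end, hi - lo, float(np.mean(x[lo:hi]))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes", "mean_log2"])


def _model_levels(level_model, max_cn: int = 8) -> np.ndarray:
    if isinstance(level_model, PurityPloidyFit):
        return np.asarray(expected_log2(np.arange(max_cn + 1),
                                        level_model.purity, level_model.grid_psi))
    return np.asarray(level_model, dtype=float)


def assign_state_levels(segments: pd.DataFrame, level_model=None,
                        naive_threshold: float = 0.3) -> pd.DataFrame:
    """Label each segment loss / neutral / gain against a level model.

    ``level_model`` is a :class:`PurityPloidyFit` (modelled integer-copy
    log2 levels) or an explicit array of levels indexed by total copies;
    ``None`` falls back to naive +/- ``naive_threshold`` log2 cutoffs.
    The distance to the nearest modelled level is recorded.
    """
    out = segments.copy()
    if level_model is None:
        m = out["mean_log2"].to_numpy()
        out["state"] = np.select([m < -naive_threshold, m > naive_threshold],
                                 [LOSS, GAIN], default=NEUTRAL)
        out["level_distance"] = np.minimum(np.abs(m), np.abs(np.abs(m) - naive_threshold))
        return out
    levels = _model_levels(level_model)
    if isinstance(level_model, PurityPloidyFit):
        neutral_ct = level_model.grid_psi
    else:
        neutral_ct = float(np.argmin(np.abs(levels)))
    m = out["mean_log2"].to_numpy()
    dist = np.abs(m[:, None] - levels[None, :])
    nearest = np.argmin(dist, axis=1)
    out["nearest_cn"] = nearest
    out["level_distance"] = dist[np.arange(len(m)), nearest]
    out["state"] = np.select([nearest < neutral_ct - 0.5, nearest > neutral_ct + 0.5],
                             [LOSS, GAIN], default=NEUTRAL)
    return out


def flag_intermediate_segments(segments: pd.DataFrame, level_model,
                               tol: float = 0.1) -> pd.DataFrame:
    """Flag segments lying further than ``tol`` from every modelled level.

    These do not correspond to any clonal integer copy state and indicate
    a mixture of cell populations with different copy numbers.
    """
    out = assign_state_levels(segments, level_model)
    out.loc[out["level_distance"] > tol, "state"] = INTERMEDIATE
    return out
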