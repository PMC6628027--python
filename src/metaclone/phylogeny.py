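"""Sample tree from genome-wide total copy-number profiles.

Profiles are binned onto a fixed grid (1 Mb default) so the tree does not
depend on segmentation breakpoint jitter. The distance between two samples
is the mean absolute difference in total copies over mutually assigned
bins (an L1-derived metric), and the tree is built by neighbour joining,
rooted on an all-two-copy "normal" pseudo-sample standing in for the
germline ancestor.
"""

from __future__ import annotations

import io as _io
import warnings

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from ._genome import CHROM_LENGTHS, CHROMOSOMES

NORMAL_ID = "normal"
BIN_SIZE = 1_000_000


def bin_grid(bin_size: int = BIN_SIZE, chromosomes=CHROMOSOMES) -> pd.DataFrame:
    rows = []
    for chrom in chromosomes:
        mids = np.arange(bin_size // 2, CHROM_LENGTHS[chrom], bin_size)
        for m in mids:
            rows.append((chrom, int(m)))
    return pd.DataFrame(rows, columns=["chrom", "mid"])


def copy_profile_matrix(allelic_segments: dict[str, pd.DataFrame],
                        bin_size: int = BIN_SIZE,
                        chromosomes=CHROMOSOMES):
    """Bin per-sample assigned total copies onto a shared 1 Mb grid.

    Returns ``(profiles, mask)``: integer copy matrix samples x bins and a
    boolean matrix marking bins with a valid assignment. Bins covered by an
    unassigned (intermediate) segment are masked for that sample.
    """
    grid = bin_grid(bin_size, chromosomes)
    samples = list(allelic_segments)
    values = np.zeros((len(samples), len(grid)), dtype=np.int64)
    mask = np.zeros((len(samples), len(grid)), dtype=bool)
    for si, name in enumerate(samples):
        seg = allelic_segments[name]
        for chrom, sub in seg.groupby("chrom"):
            gsel = np.flatnonzero((grid["chrom"] == chrom).to_numpy())
            if len(gsel) == 0:
                continue
            mids = grid.loc[gsel, "mid"].to_numpy()
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = np.searchsorted(starts, mids, side="right") - 1
            ok = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
            assigned = sub["assigned"].to_numpy()[np.clip(idx, 0, None)]
            cn = sub["total_cn"].to_numpy()[np.clip(idx, 0, None)]
            good = ok & assigned
            values[si, gsel[good]] = cn[good]
            mask[si, gsel[good]] = True
    profiles = pd.DataFrame(values, index=samples)
    return profiles, pd.DataFrame(mask, index=samples)


def add_normal_profile(profiles: pd.DataFrame, mask: pd.DataFrame,
                       name: str = NORMAL_ID):
    """Append the all-diploid pseudo-sample used to root the tree."""
    profiles = pd.concat([profiles, pd.DataFrame(
        [np.full(profiles.shape[1], 2, dtype=np.int64)], index=[name])])
    mask = pd.concat([mask, pd.DataFrame(
        [np.ones(mask.shape[1], dtype=bool)], index=[name])])
    return profiles, mask


def cna_distance_matrix(profiles: pd.DataFrame, mask: pd.DataFrame | None = None,
                        min_shared_bins: int = 100) -> pd.DataFrame:
    """Mean absolute total-copy difference over mutually unmasked bins.

    Symmetric with a zero diagonal; satisfies the triangle inequality.
    Pairs sharing fewer than ``min_shared_bins`` bins are listed in
    ``result.attrs['unreliable_pairs']`` and warned about.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two samples")
    X = profiles.to_numpy(dtype=float)
    M = (mask.to_numpy(dtype=bool) if mask is not None
         else np.ones_like(X, dtype=bool))
    n = len(profiles)
    D = np.zeros((n, n))
    unreliable = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = M[i] & M[j]
            k = int(shared.sum())
            if k == 0:
                raise ValueError("no shared bins for a sample pair")
            if k < min_shared_bins:
                unreliable.append((profiles.index[i], profiles.index[j]))
            D[i, j] = D[j, i] = float(np.mean(np.abs(X[i, shared] - X[j, shared])))
    if unreliable:
        warnings.warn(f"{len(unreliable)} sample pair(s) share fewer than "
                      f"{min_shared_bins} bins", stacklevel=2)
    out = pd.DataFrame(D, index=profiles.index, columns=profiles.index)
    out.attrs["unreliable_pairs"] = unreliable
    return out


def build_nj_tree(distance_matrix: pd.DataFrame,
                  outgroup: str = NORMAL_ID) -> dendropy.Tree:
    """Neighbour-joining tree rooted at ``outgroup``.

    Negative NJ branch lengths are clamped to zero with a warning. Raises
    on non-finite distances or a missing outgroup row.
    """
    if not np.all(np.isfinite(distance_matrix.to_numpy())):
        raise ValueError("non-finite distances")
    ids = [str(i) for i in distance_matrix.index]
    if outgroup not in ids:
        raise ValueError(f"outgroup {outgroup!r} not in distance matrix")
    if len(ids) == 2:
        d = float(distance_matrix.iloc[0, 1])
        newick = f"({ids[0]}:{d / 2},{ids[1]}:{d / 2});"
    else:
        sk_tree = _skbio_nj(DistanceMatrix(distance_matrix.to_numpy(), ids))
        newick = str(sk_tree.write(_io.StringIO()).getvalue())
    tree = dendropy.Tree.get(data=newick, schema="newick")
    clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative branch length(s) to 0", stacklevel=2)
    node = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == outgroup)
    if node.edge.length is None:
        node.edge.length = 0.0
    tree.reroot_at_edge(node.edge, update_bipartitions=True,
                        length1=node.edge.length / 2, length2=node.edge.length / 2)
    return tree


def root_split(tree: dendropy.Tree, outgroup: str = NORMAL_ID):
    """The two ingroup clades flanking the root, as frozensets of labels."""
    seed = tree.seed_node
    ingroup = None
    for child in seed.child_nodes():
        labels = {lf.taxon.label for lf in child.leaf_iter()}
        if outgroup not in labels:
            ingroup = child
    if ingroup is None:  # outgroup nested: take the non-outgroup side anyway
        raise ValueError("could not locate ingroup under the root")
    parts = []
    for child in ingroup.child_nodes():
        parts.append(frozenset(lf.taxon.label for lf in child.leaf_iter()))
    if len(parts) == 1:
        return parts[0], frozenset()
    return parts[0], frozenset().union(*parts[1:])


def nearest_neighbor_report(distance_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per sample: the other sample(s) at minimum distance (ties together)."""
    if len(distance_matrix) < 2:
        raise ValueError("need at least two samples")
    rows = []
    for name in distance_matrix.index:
        d = distance_matrix.loc[name].drop(name)
        dmin = float(d.min())
        ties = sorted(d.index[np.isclose(d.to_numpy(dtype=float), dmin, atol=1e-12)])
        rows.append((name, ",".join(str(t) for t in ties), dmin))
    return pd.DataFrame(rows, columns=["sample", "nearest", "distance"])
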