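"""Equal-volume tripartition of caudate and putamen.

Each caudate and putamen is split into three subregions of equal volume
(anterior, middle, posterior).  Centroids come from k-means on voxel world
coordinates; because plain k-means cannot guarantee equal cluster sizes, a
balanced greedy assignment step follows: voxels are assigned in decreasing
order of confidence (margin between best and second-best centroid distance)
to the nearest centroid that still has capacity.  Capacities are
``floor(V/3)`` per cluster, with the ``V mod 3`` leftover voxels giving one
extra slot each to the most anterior clusters, so sizes never differ by
more than one voxel.

Cluster-to-name mapping is by mean +Y (anterior) world coordinate, ties
broken by mean +Z.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .core import (
    LabelMap,
    SUBREGION_CODES,
    subregion_code,
)

__all__ = ["tripartition_nucleus", "build_subregion_map"]

_SPLIT_NUCLEI = ("caudate", "putamen")
_PASSTHROUGH = ("pallidum", "midbrain", "occipital")


def tripartition_nucleus(
    labels: LabelMap, region_code: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split one nucleus into anterior/middle/posterior equal-volume thirds.

    Returns three ``(n_i, 3)`` arrays of voxel indices ordered
    anterior -> posterior.  Sizes are ``{floor(V/3), ceil(V/3)}`` with a
    maximum pairwise difference of one voxel, and their union is exactly
    the parent region.
    """
    idx = np.argwhere(labels.grid == region_code)
    V = len(idx)
    name = labels.code_table.get(region_code, ("?", "?"))
    if V < 3:
        raise ValueError(
            f"region {name[0]}_{name[1]} (code {region_code}) has {V} voxels; "
            "at least 3 are required for tripartition"
        )
    xyz = idx @ labels.affine[:3, :3].T + labels.affine[:3, 3]

    km = KMeans(n_clusters=3, n_init=10, random_state=int(seed) % (2**32))
    km.fit(xyz)
    centroids = km.cluster_centers_

    # order centroids anterior (largest +Y) -> posterior; tie-break on +Z
    order = np.lexsort((-centroids[:, 2], -centroids[:, 1]))
    centroids = centroids[order]

    dist = np.linalg.norm(xyz[:, None, :] - centroids[None, :, :], axis=2)
    best = np.sort(dist, axis=1)
    margin = best[:, 1] - best[:, 0]  # confidence of the nearest assignment

    q, r = divmod(V, 3)
    capacity = np.array([q + (1 if k < r else 0) for k in range(3)])

    assign = np.full(V, -1, dtype=int)
    counts = np.zeros(3, dtype=int)
    # most confident voxels first; stable order for exact determinism
    for i in np.argsort(-margin, kind="stable"):
        for k in np.argsort(dist[i], kind="stable"):
            if counts[k] < capacity[k]:
                assign[i] = k
                counts[k] += 1
                break

    parts = tuple(idx[assign == k] for k in range(3))
    # reorder by realized mean anterior coordinate (assignment balancing can
    # in principle swap near-degenerate clusters); tie-break on +Z
    ys = [xyz[assign == k, 1].mean() for k in range(3)]
    zs = [xyz[assign == k, 2].mean() for k in range(3)]
    final = np.lexsort((np.negative(zs), np.negative(ys)))
    return tuple(parts[k] for k in final)  # type: ignore[return-value]


def build_subregion_map(labels: LabelMap, seed: int = 0) -> LabelMap:
    """Refine an anatomical label map into the 16+2 subregion codes.

    Caudate and putamen are tripartitioned per side; pallidum, midbrain and
    the occipital reference regions pass through unsplit.  Deterministic
    given ``seed``.
    """
    missing = []
    for nucleus in _SPLIT_NUCLEI:
        for side in ("L", "R"):
            try:
                code = labels.code_of(nucleus, side)
            except KeyError:
                missing.append(f"{nucleus}_{side}")
                continue
            if not np.any(labels.grid == code):
                missing.append(f"{nucleus}_{side}")
    if missing:
        raise ValueError(f"cannot build subregion map; missing nuclei: {missing}")

    out = np.zeros_like(labels.grid, dtype=np.int16)
    for nucleus in _SPLIT_NUCLEI:
        for side in ("L", "R"):
            code = labels.code_of(nucleus, side)
            ant, mid, post = tripartition_nucleus(labels, code, seed=seed)
            for part, prefix in zip(
                (ant, mid, post), ("anterior", "middle", "posterior")
            ):
                sub = subregion_code(f"{prefix}_{nucleus}", side)
                out[tuple(part.T)] = sub
    for region in _PASSTHROUGH:
        for side in ("L", "R"):
            try:
                code = labels.code_of(region, side)
            except KeyError:
                continue
            out[labels.grid == code] = subregion_code(region, side)

    return LabelMap(out, labels.affine, dict(SUBREGION_CODES))
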