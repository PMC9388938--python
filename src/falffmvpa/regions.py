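"""Weight-map thresholding and cluster reporting.

For visualisation and reporting, the per-voxel weight vector of the best
model is thresholded at a fraction (default 30%) of its maximum absolute
weight; surviving voxels are grouped into face-connected (6-connectivity)
components separately by weight sign, mirroring the positive/negative
sections of a cluster table: voxel count, peak weight, peak coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["WeightCluster", "threshold_weights", "weight_volume"]


@dataclass
class WeightCluster:
    sign: str  # "positive" | "negative"
    voxel_count: int
    peak_weight: float
    peak_coordinate: tuple[int, int, int]
    peak_mm: tuple[float, float, float] | None = None
    voxels: np.ndarray | None = None  # (m, 3) member coordinates


def weight_volume(weights: np.ndarray, voxel_index: np.ndarray, shape) -> np.ndarray:
    """Scatter a per-column weight vector back onto the 3D grid."""
    vol = np.zeros(shape)
    vol[tuple(voxel_index.T)] = weights
    return vol


def threshold_weights(
    weight_map: np.ndarray,
    fraction: float = 0.3,
    connectivity: int = 6,
    affine: np.ndarray | None = None,
) -> list[WeightCluster]:
    """Clusters of voxels with |weight| strictly above fraction * max |weight|.

    ``weight_map`` is a 3D volume.  Components are labelled with the given
    connectivity (6 = faces, 18 = +edges, 26 = +corners), separately for
    positive and negative weights, and returned sorted by |peak_weight|
    descending (ties broken by coordinate for determinism).  An all-zero
    map yields an empty list.
    """
    w = np.nan_to_num(np.asarray(weight_map, dtype=float), nan=0.0)
    if w.ndim != 3:
        raise ValueError("weight_map must be a 3D volume")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    wmax = np.abs(w).max()
    if wmax == 0:
        return []
    thr = fraction * wmax
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }.get(connectivity)
    if structure is None:
        raise ValueError("connectivity must be 6, 18 or 26")

    clusters: list[WeightCluster] = []
    for sign, m in (("positive", (w > thr)), ("negative", (-w > thr))):
        labels, n_lab = ndimage.label(m, structure=structure)
        for lab in range(1, n_lab + 1):
            voxels = np.argwhere(labels == lab)
            vals = w[tuple(voxels.T)]
            peak_i = int(np.argmax(np.abs(vals)))
            peak = tuple(int(c) for c in voxels[peak_i])
            peak_mm = None
            if affine is not None:
                xyz1 = affine @ np.array([*peak, 1.0])
                peak_mm = tuple(float(v) for v in xyz1[:3])
            clusters.append(
                WeightCluster(
                    sign=sign,
                    voxel_count=len(voxels),
                    peak_weight=float(vals[peak_i]),
                    peak_coordinate=peak,
                    peak_mm=peak_mm,
                    voxels=voxels,
                )
            )
    clusters.sort(key=lambda c: (-abs(c.peak_weight), c.peak_coordinate))
    return clusters
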