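"""Weighted structural connectome construction from streamlines.

Two regions are connected when a streamline's endpoints lie in both regions.
The raw edge strength is the mean FA of the connecting streamlines multiplied
by their count, then normalized by the endpoint regions' volume (mean of the
two volumes, in cm^3) to correct for region- and brain-size differences. The
result is an undirected, weighted R x R matrix (90 regions by default: an
AAL-style parcellation with 45 regions per hemisphere, cerebellum excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "Connectome",
    "BinaryConnectome",
    "assign_endpoints",
    "build_connectome",
    "binarize",
    "write_adjacency_tsv",
    "read_adjacency_tsv",
]


@dataclass
class Parcellation:
    """Integer label volume (0 = background) plus region names and volumes."""

    labels: np.ndarray            # 3-D int array, parcel ids 1..R
    voxel_size: float = 2.5       # mm, isotropic
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("parcel labels must be nonnegative")
        if not self.region_names:
            self.region_names = [f"region_{i:02d}"
                                 for i in range(1, self.n_regions + 1)]

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def region_volumes(self) -> np.ndarray:
        """Per-region volume in mm^3 (voxel count times voxel volume)."""
        counts = np.bincount(self.labels.ravel(),
                             minlength=self.n_regions + 1)[1:]
        return counts * self.voxel_size ** 3

    def label_at(self, point_mm: np.ndarray) -> int:
        """Parcel id of the voxel containing a world-space point (mm)."""
        idx = np.floor(np.asarray(point_mm) / self.voxel_size).astype(int)
        if (idx < 0).any() or (idx >= np.array(self.labels.shape)).any():
            return 0
        return int(self.labels[tuple(idx)])


@dataclass
class Connectome:
    """Symmetric nonnegative weight matrix with provenance counts."""

    weights: np.ndarray
    node_volumes: np.ndarray | None = None
    streamline_counts: np.ndarray | None = None
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if (W < 0).any():
            raise ValueError("weights must be nonnegative")
        np.fill_diagonal(W, 0.0)
        self.weights = W
        if not self.region_names:
            self.region_names = [f"region_{i:02d}"
                                 for i in range(1, W.shape[0] + 1)]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryConnectome:
    """{0,1} adjacency with zero diagonal."""

    adjacency: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if not np.isin(np.unique(A), (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        A = A.astype(np.int8)
        np.fill_diagonal(A, 0)
        self.adjacency = A
        if not self.region_names:
            self.region_names = [f"region_{i:02d}"
                                 for i in range(1, A.shape[0] + 1)]


def assign_endpoints(streamlines, parcellation: Parcellation
                     ) -> list[tuple[int, int] | None]:
    """Map each streamline to a (region_a, region_b) pair or ``None``.

    A streamline contributes only if both endpoints fall inside nonzero,
    distinct parcels; self-loops and background endpoints are unassigned.
    """
    pairs: list[tuple[int, int] | None] = []
    for sl in streamlines.streamlines:
        a = parcellation.label_at(sl.points[0])
        b = parcellation.label_at(sl.points[-1])
        if a == 0 or b == 0 or a == b:
            pairs.append(None)
        else:
            pairs.append((min(a, b), max(a, b)))
    return pairs


def build_connectome(streamlines, parcellation: Parcellation,
                     volume_norm: str = "mean") -> Connectome:
    """Aggregate streamlines into a weighted connectome.

    For region pair (i, j): ``raw = mean_fa_over_streamlines * count`` and
    ``weight = raw / norm(V_i, V_j)`` with volumes in cm^3. ``volume_norm``
    selects mean (default), sum, or the geometric mean of the two volumes.
    """
    R = parcellation.n_regions
    volumes_mm3 = parcellation.region_volumes()
    if (volumes_mm3 <= 0).any():
        raise ValueError("all regions must have positive volume")
    vol_cm3 = volumes_mm3 / 1000.0

    fa_sum = np.zeros((R, R))
    counts = np.zeros((R, R), dtype=int)
    for sl, pair in zip(streamlines.streamlines,
                        assign_endpoints(streamlines, parcellation)):
        if pair is None:
            continue
        i, j = pair[0] - 1, pair[1] - 1
        fa_sum[i, j] += sl.mean_fa
        counts[i, j] += 1
    fa_sum = fa_sum + fa_sum.T
    counts = counts + counts.T

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_fa = np.where(counts > 0, fa_sum / np.maximum(counts, 1), 0.0)
    raw = mean_fa * counts

    vi = vol_cm3[:, None]
    vj = vol_cm3[None, :]
    if volume_norm == "mean":
        norm = (vi + vj) / 2.0
    elif volume_norm == "sum":
        norm = vi + vj
    elif volume_norm == "geometric":
        norm = np.sqrt(vi * vj)
    else:
        raise ValueError(f"unknown volume_norm {volume_norm!r}")
    weights = raw / norm
    np.fill_diagonal(weights, 0.0)
    return Connectome(weights=weights, node_volumes=volumes_mm3,
                      streamline_counts=counts,
                      region_names=list(parcellation.region_names))


def binarize(connectome: Connectome) -> BinaryConnectome:
    """Presence/absence adjacency: any positive weight becomes an edge."""
    return BinaryConnectome(adjacency=(connectome.weights > 0).astype(np.int8),
                            region_names=list(connectome.region_names))


def write_adjacency_tsv(connectome, path) -> None:
    """Full (non-triangular) matrix as TSV with region-name header."""
    if isinstance(connectome, BinaryConnectome):
        M, names = connectome.adjacency, connectome.region_names
        df = pd.DataFrame(M, columns=names)
        df.to_csv(path, sep="\t", index=False)
    else:
        M, names = connectome.weights, connectome.region_names
        df = pd.DataFrame(M, columns=names)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_adjacency_tsv(path) -> Connectome:
    df = pd.read_csv(path, sep="\t")
    return Connectome(weights=df.to_numpy(dtype=float),
                      region_names=list(df.columns))
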