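"""Deterministic FACT-style streamline tractography on tensor-field phantoms.

Seeds are placed at the center of every masked voxel whose FA exceeds the
start threshold. From each seed, propagation advances a fixed step along the
current voxel's principal direction, sign-aligned with the previous step,
and a branch terminates when it leaves the brain mask, enters a voxel with
FA below the stop threshold, or the turning angle between the principal
directions of successive distinct voxels exceeds the maximum (60 degrees by
default). Tracking is bidirectional: the two branches from a seed are
concatenated into one streamline.

This is a fixed-step approximation of classical FACT (which propagates to
exact voxel boundaries); with the default step of half a voxel no voxel is
skipped along axis-aligned bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import TensorFieldPhantom

__all__ = ["TrackingParams", "Streamline", "StreamlineSet",
           "seed_voxels", "track", "track_all",
           "write_streamlines", "read_streamlines"]


@dataclass
class TrackingParams:
    fa_start_threshold: float = 0.2
    fa_stop_threshold: float = 0.2
    max_turn_angle: float = 60.0       # degrees
    step_size: float | None = None     # mm; default: half the voxel size
    max_steps: int = 2000
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.fa_start_threshold < 1.0:
            raise ValueError("fa_start_threshold must be in (0, 1)")
        if not 0.0 < self.fa_stop_threshold < 1.0:
            raise ValueError("fa_stop_threshold must be in (0, 1)")
        if not 0.0 < self.max_turn_angle <= 180.0:
            raise ValueError("max_turn_angle must be in (0, 180]")

    def resolved_step(self, voxel_size: float) -> float:
        return self.step_size if self.step_size else voxel_size / 2.0


@dataclass
class Streamline:
    points: np.ndarray       # (N, 3) positions in mm
    mean_fa: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least two points")
        if not 0.0 <= self.mean_fa <= 1.0:
            raise ValueError("mean FA must be in [0, 1]")


@dataclass
class StreamlineSet:
    streamlines: list[Streamline]
    source_phantom_id: str

    def __post_init__(self) -> None:
        if not self.source_phantom_id:
            raise ValueError("source_phantom_id must be non-empty")

    def __len__(self) -> int:
        return len(self.streamlines)


def seed_voxels(phantom: TensorFieldPhantom,
                params: TrackingParams) -> list[np.ndarray]:
    """Centers of masked voxels with FA above the start threshold."""
    seeds = []
    good = phantom.mask & (phantom.fa > params.fa_start_threshold)
    for idx in np.argwhere(good):
        seeds.append(phantom.voxel_center(idx))
    return seeds


def _canonical_direction(d: np.ndarray) -> np.ndarray:
    """Fix the axial sign: largest-magnitude component made positive."""
    k = int(np.argmax(np.abs(d)))
    return -d if d[k] < 0 else d.copy()


def _propagate(phantom: TensorFieldPhantom, start_pos: np.ndarray,
               start_voxel: tuple, init_dir: np.ndarray,
               params: TrackingParams) -> tuple[list[np.ndarray], list[tuple]]:
    """One branch: returns (points after the seed, distinct voxels entered)."""
    step = params.resolved_step(phantom.voxel_size)
    max_cos_dev = np.cos(np.deg2rad(params.max_turn_angle))
    pos = start_pos.copy()
    cur_vox = start_voxel
    prev_dir = init_dir
    points: list[np.ndarray] = []
    voxels: list[tuple] = []
    for _ in range(params.max_steps):
        d = np.asarray(phantom.directions[cur_vox], dtype=float)
        if np.linalg.norm(d) == 0:
            break
        if np.dot(d, prev_dir) < 0:
            d = -d
        new_pos = pos + step * d
        new_vox = phantom.voxel_of(new_pos)
        if new_vox is None or not phantom.mask[new_vox]:
            break                                    # left the brain mask
        if new_vox != cur_vox:
            if phantom.fa[new_vox] < params.fa_stop_threshold:
                break                                # low-anisotropy voxel
            nd = np.asarray(phantom.directions[new_vox], dtype=float)
            if np.linalg.norm(nd) > 0 and \
                    abs(np.dot(d, nd)) < max_cos_dev - 1e-12:
                break                                # turning angle exceeded
            voxels.append(new_vox)
        pos = new_pos
        points.append(pos.copy())
        cur_vox = new_vox
        prev_dir = d
    return points, voxels


def track(phantom: TensorFieldPhantom, seed: np.ndarray,
          params: TrackingParams | None = None) -> Streamline:
    """Bidirectional FACT propagation from one seed position."""
    params = params or TrackingParams()
    seed = np.asarray(seed, dtype=float)
    vox = phantom.voxel_of(seed)
    if vox is None or not phantom.mask[vox]:
        raise ValueError("seed lies outside the brain mask")
    if phantom.fa[vox] <= params.fa_start_threshold:
        raise ValueError("seed voxel FA is below the start threshold")
    d0 = _canonical_direction(np.asarray(phantom.directions[vox], dtype=float))
    fwd_pts, fwd_vox = _propagate(phantom, seed, vox, d0, params)
    if params.bidirectional:
        bwd_pts, bwd_vox = _propagate(phantom, seed, vox, -d0, params)
    else:
        bwd_pts, bwd_vox = [], []
    pts = bwd_pts[::-1] + [seed] + fwd_pts
    if len(pts) < 2:
        raise ValueError("degenerate streamline (fewer than two points)")
    visited = list(dict.fromkeys(bwd_vox[::-1] + [vox] + fwd_vox))
    mean_fa = float(np.mean([phantom.fa[v] for v in visited]))
    return Streamline(points=np.array(pts), mean_fa=mean_fa)


def track_all(phantom: TensorFieldPhantom,
              params: TrackingParams | None = None) -> StreamlineSet:
    """Track from every seed, in deterministic voxel-index order.

    Seeds that produce degenerate (< 2 point) streamlines are skipped.
    """
    params = params or TrackingParams()
    out: list[Streamline] = []
    for seed in seed_voxels(phantom, params):
        try:
            out.append(track(phantom, seed, params))
        except ValueError:
            continue
    return StreamlineSet(streamlines=out,
                         source_phantom_id=phantom.phantom_id)


# ---------------------------------------------------------------------------
# line-delimited text I/O
# ---------------------------------------------------------------------------

def write_streamlines(sset: StreamlineSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# source={sset.source_phantom_id}\n")
        for i, sl in enumerate(sset.streamlines):
            fh.write(f"> {i} {sl.mean_fa:.10g}\n")
            for p in sl.points:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_streamlines(path) -> StreamlineSet:
    source = "unknown"
    streamlines: list[Streamline] = []
    cur_pts: list[list[float]] = []
    cur_fa = 0.0
    open_record = False

    def flush():
        nonlocal open_record
        if open_record:
            streamlines.append(Streamline(points=np.array(cur_pts),
                                          mean_fa=cur_fa))
            open_record = False

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "source=" in line:
                    source = line.split("source=", 1)[1].strip()
            elif line.startswith(">"):
                flush()
                _, _, fa_s = line.split()
                cur_fa = float(fa_s)
                cur_pts = []
                open_record = True
            else:
                cur_pts.append([float(v) for v in line.split()])
    flush()
    return StreamlineSet(streamlines=streamlines, source_phantom_id=source)
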