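"""Skeleton-guided neurite diameter inference from voxel volumes.

A traced neurite is represented twice: as a skeleton (a tree of
connected nodes with µm coordinates) and as a binary voxel volume of the
filled branch.  At each skeleton node the local axis is estimated from
neighboring nodes; surface voxels lying within a small tolerance of the
orthogonal plane and within a maximum radius of the node are projected
into that plane, ordered by polar angle about their centroid, and the
enclosed polygon area is computed with the shoelace formula.  The
circular-equivalent diameter is 2·√(area/π), and profiles are smoothed
with a centered running average along the path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class Skeleton:
    """Tree of connected nodes; parent −1 marks the root (soma side)."""

    ids: np.ndarray      # (n,)
    xyz: np.ndarray      # (n, 3), µm
    parent: np.ndarray   # (n,), parent node id or −1

    def __post_init__(self):
        ids = np.asarray(self.ids)
        if np.unique(ids).size != ids.size:
            raise ValueError("node ids must be unique")
        roots = np.sum(np.asarray(self.parent) == -1)
        if roots != 1:
            raise ValueError(f"skeleton must have exactly one root, got {roots}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, node_id) -> int:
        hit = np.nonzero(self.ids == node_id)[0]
        if hit.size == 0:
            raise KeyError(f"no node {node_id}")
        return int(hit[0])

    def children_map(self) -> dict:
        out = {int(i): [] for i in self.ids}
        for nid, pid in zip(self.ids, self.parent):
            if pid != -1:
                if int(pid) not in out:
                    raise ValueError(f"orphan node {nid}: parent {pid} missing")
                out[int(pid)].append(int(nid))
        return out

    @classmethod
    def from_swc(cls, path) -> "Skeleton":
        """Read an SWC morphology (id, type, x, y, z, radius, parent)."""
        t = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                        names=["id", "type", "x", "y", "z", "r", "parent"])
        return cls(ids=t["id"].to_numpy(int),
                   xyz=t[["x", "y", "z"]].to_numpy(float),
                   parent=t["parent"].to_numpy(int))

    def to_swc(self, path, radius: Optional[np.ndarray] = None) -> None:
        r = np.ones(self.n) if radius is None else np.asarray(radius)
        t = pd.DataFrame({"id": self.ids, "type": 3,
                          "x": self.xyz[:, 0], "y": self.xyz[:, 1],
                          "z": self.xyz[:, 2], "r": r,
                          "parent": self.parent})
        with open(path, "w") as f:
            f.write("# id type x y z radius parent\n")
            t.to_csv(f, sep=" ", header=False, index=False)


@dataclass(frozen=True)
class VoxelVolume:
    """Binary mask with (x, y, z) voxel sizes in µm.  Axis order of the
    mask is (x, y, z); TIFF stacks (z, y, x pages) are transposed on IO."""

    mask: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.mask.ndim != 3 or not self.mask.any():
            raise ValueError("mask must be a non-empty 3-D array")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @classmethod
    def from_tiff(cls, path, voxel_size=(1.0, 1.0, 1.0),
                  threshold: float = 0.5) -> "VoxelVolume":
        import tifffile

        stack = tifffile.imread(path)
        mask = np.asarray(stack) > threshold
        return cls(mask=mask.transpose(2, 1, 0), voxel_size=tuple(voxel_size))

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.mask.transpose(2, 1, 0).astype(np.uint8))


@dataclass(frozen=True)
class CrossSectionConfig:
    plane_tolerance: float = 0.5   # µm, half-thickness of the section slab
    max_radius: float = 3.0        # µm; use 11 for thick branches
    smoothing_window: int = 3      # nodes, centered running average

    def __post_init__(self):
        if self.plane_tolerance <= 0 or self.max_radius <= 0:
            raise ValueError("tolerances must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd and positive")


@dataclass(frozen=True)
class CrossSection:
    node_id: int
    path_um: float
    area_um2: float        # nan when the section is flagged empty
    diameter_um: float     # 2·√(area/π); nan when flagged
    n_points: int
    valid: bool


def path_distances(skeleton: Skeleton) -> np.ndarray:
    """Cumulative Euclidean path length from the root, per node (µm)."""
    id_to_idx = {int(i): k for k, i in enumerate(skeleton.ids)}
    children = skeleton.children_map()
    dist = np.full(skeleton.n, np.nan)
    root_idx = int(np.nonzero(skeleton.parent == -1)[0][0])
    stack = [root_idx]
    dist[root_idx] = 0.0
    while stack:
        i = stack.pop()
        for cid in children[int(skeleton.ids[i])]:
            j = id_to_idx[cid]
            dist[j] = dist[i] + float(
                np.linalg.norm(skeleton.xyz[j] - skeleton.xyz[i]))
            stack.append(j)
    if np.isnan(dist).any():
        raise ValueError("skeleton contains nodes unreachable from the root")
    return dist


def surface_points(volume: VoxelVolume) -> np.ndarray:
    """Centers (µm) of foreground voxels with a background 6-neighbor.

    Voxels on the array boundary count as surface (outside is background).
    """
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(volume.mask, structure=structure,
                                      border_value=0)
    idx = np.argwhere(volume.mask & ~interior)
    return (idx + 0.5) * np.asarray(volume.voxel_size)[None, :]


def shoelace_area(xy: np.ndarray) -> float:
    """Polygon area from ordered 2-D vertices via the shoelace formula."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1))
                           - np.dot(y, np.roll(x, -1))))


def _local_axis(skeleton: Skeleton, idx: int,
                children: dict) -> np.ndarray:
    """Unit axis at a node: central difference of the neighbors along the
    path (parent ↔ first child), one-sided at root and tips."""
    nid = int(skeleton.ids[idx])
    pid = int(skeleton.parent[idx])
    kids = children[nid]
    p_here = skeleton.xyz[idx]
    p_prev = (skeleton.xyz[skeleton.index_of(pid)] if pid != -1 else p_here)
    p_next = (skeleton.xyz[skeleton.index_of(kids[0])] if kids else p_here)
    axis = p_next - p_prev
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError(f"node {nid} has no neighbor to define an axis")
    return axis / norm


def node_cross_section(node_id: int, skeleton: Skeleton,
                       points: np.ndarray,
                       cfg: CrossSectionConfig = CrossSectionConfig(),
                       path_um: float = np.nan,
                       axis: Optional[np.ndarray] = None) -> CrossSection:
    """Cross-sectional area and circular-equivalent diameter at one node.

    Surface points within ``plane_tolerance`` of the orthogonal plane and
    within ``max_radius`` of the node are projected into the plane and
    ordered by polar angle about their centroid; the polygon area comes
    from the shoelace formula.  Fewer than three candidate points flag
    the section as empty (area undefined, not zero).
    """
    idx = skeleton.index_of(node_id)
    if axis is None:
        axis = _local_axis(skeleton, idx, skeleton.children_map())
    center = skeleton.xyz[idx]
    rel = points - center[None, :]
    axial = rel @ axis
    in_slab = np.abs(axial) <= cfg.plane_tolerance
    rel = rel[in_slab]
    axial = axial[in_slab]
    planar = rel - axial[:, None] * axis[None, :]
    r = np.linalg.norm(planar, axis=1)
    keep = r <= cfg.max_radius
    planar = planar[keep]
    if planar.shape[0] < 3:
        return CrossSection(node_id=int(node_id), path_um=path_um,
                            area_um2=np.nan, diameter_um=np.nan,
                            n_points=int(planar.shape[0]), valid=False)

    # orthonormal in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    uv = np.stack([planar @ e1, planar @ e2], axis=1)
    uv0 = uv - uv.mean(axis=0)
    order = np.argsort(np.arctan2(uv0[:, 1], uv0[:, 0]))
    area = shoelace_area(uv[order])
    return CrossSection(node_id=int(node_id), path_um=path_um,
                        area_um2=float(area),
                        diameter_um=2.0 * math.sqrt(area / math.pi),
                        n_points=int(uv.shape[0]), valid=True)


def _root_to_tip_path(skeleton: Skeleton, tip_id: Optional[int]) -> list:
    dist = path_distances(skeleton)
    children = skeleton.children_map()
    if tip_id is None:
        tips = [i for i in range(skeleton.n)
                if not children[int(skeleton.ids[i])]]
        tip_idx = max(tips, key=lambda i: dist[i])
        tip_id = int(skeleton.ids[tip_idx])
    path = [tip_id]
    while True:
        pid = int(skeleton.parent[skeleton.index_of(path[-1])])
        if pid == -1:
            break
        path.append(pid)
    return path[::-1]


def diameter_profile(skeleton: Skeleton, volume: VoxelVolume,
                     cfg: CrossSectionConfig = CrossSectionConfig(),
                     tip_id: Optional[int] = None) -> pd.DataFrame:
    """Diameter vs path distance along a root-to-tip path.

    Cross sections are measured at every node of the path (the farthest
    tip by default); flagged sections are excluded from the centered
    running-average smoothing.  Returns a table ordered by path distance
    with columns node_id, path_um, area_um2, diam_um, diam_smoothed_um.
    """
    points = surface_points(volume)
    dist = path_distances(skeleton)
    children = skeleton.children_map()
    path = _root_to_tip_path(skeleton, tip_id)

    # axes via central difference of the path neighbors
    coords = np.array([skeleton.xyz[skeleton.index_of(n)] for n in path])
    sections = []
    for k, nid in enumerate(path):
        lo = max(k - 1, 0)
        hi = min(k + 1, len(path) - 1)
        axis = coords[hi] - coords[lo]
        axis = axis / np.linalg.norm(axis)
        sections.append(node_cross_section(
            nid, skeleton, points, cfg,
            path_um=float(dist[skeleton.index_of(nid)]), axis=axis))

    diam = np.array([s.diameter_um for s in sections])
    smoothed = np.full_like(diam, np.nan)
    half = cfg.smoothing_window // 2
    for k in range(diam.size):
        window = diam[max(0, k - half):k + half + 1]
        window = window[np.isfinite(window)]
        if window.size:
            smoothed[k] = window.mean()
    out = pd.DataFrame({
        "node_id": [s.node_id for s in sections],
        "path_um": [s.path_um for s in sections],
        "area_um2": [s.area_um2 for s in sections],
        "diam_um": diam,
        "diam_smoothed_um": smoothed,
        "valid": [s.valid for s in sections],
    })
    return out.sort_values("path_um").reset_index(drop=True)
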