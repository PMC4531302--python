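"""Core containers and voxel/mm geometry shared by every pipeline stage.

All geometry is carried in millimetres internally and converted through the
NIfTI affine; voxel indices are 0-based.  Affines are expected to be
axis-aligned (a diagonal scaling plus translation), which is what registered,
template-space volumes carry.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class RoifcError(Exception):
    """Base class for errors raised by this package."""


class GridError(RoifcError):
    """A coordinate or region falls outside the image grid or brain mask."""


class PeakSearchError(RoifcError):
    """A peak search region contains no in-mask voxels."""


class NoMatchError(RoifcError):
    """No ICA component matches the requested network template."""


class PipelineError(RoifcError):
    """A pipeline stage is missing an upstream artifact."""


class UndefinedResultWarning(UserWarning):
    """A statistic is undefined (flagged as NaN, distinct from a numeric value)."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the linear part)."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def voxel_to_mm(affine: np.ndarray, idx) -> np.ndarray:
    """Map voxel indices (..., 3) to mm coordinates through the affine."""
    idx = np.asarray(idx, dtype=float)
    return idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]

def mm_to_voxel(affine: np.ndarray, mm) -> np.ndarray:
    """Map mm coordinates (..., 3) to (fractional) voxel indices."""
    inv = np.linalg.inv(np.asarray(affine))
    mm = np.asarray(mm, dtype=float)
    return mm @ inv[:3, :3].T + inv[:3, 3]


def nearest_voxel(affine: np.ndarray, mm) -> np.ndarray:
    """Nearest voxel index to a mm coordinate.

    Exact mid-points between voxel centres resolve to the lower index on each
    axis (lexicographic tie-break), so the rule is deterministic.
    """
    frac = mm_to_voxel(affine, mm)
    return np.ceil(frac - 0.5).astype(int)


@dataclass
class BoldRun:
    """One subject's 4D BOLD acquisition (x, y, z, t) plus its affine and TR."""

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD run needs at least 2 timepoints")
        self.affine = _check_affine(self.affine)
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class NodeSpec:
    """A named network node: canonical template-space centre + search region."""

    network_id: str
    node_id: str
    center_mm: tuple
    search_radius_mm: float = 16.0

    def __post_init__(self):
        object.__setattr__(self, "center_mm", tuple(float(v) for v in self.center_mm))
        if len(self.center_mm) != 3:
            raise ValueError("center_mm must have 3 components")
        if not self.search_radius_mm > 0:
            raise ValueError("search_radius_mm must be > 0")

    @property
    def label(self) -> str:
        return f"{self.network_id}.{self.node_id}"


@dataclass
class RoiCube:
    """A cubic ROI: node reference, centre voxel and its in-mask voxel set."""

    node: NodeSpec
    center_voxel: np.ndarray
    edge_mm: float
    voxels: np.ndarray  # (n, 3) int, lexicographically sorted

    @property
    def label(self) -> str:
        return self.node.label


@dataclass
class RoiSet:
    """One subject's battery of cubic ROIs under one selection method."""

    subject_id: str
    method: str  # literature | group | subject_specific
    rois: list = field(default_factory=list)

    def __post_init__(self):
        allowed = {"literature", "group", "subject_specific"}
        if self.method not in allowed:
            raise ValueError(f"method must be one of {sorted(allowed)}")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)

    def roi(self, label: str) -> RoiCube:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass
class StatMap:
    """A 3D z-statistic map from a single-subject network reconstruction."""

    values: np.ndarray
    affine: np.ndarray
    subject_id: str = ""
    network_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be 3D")
        self.affine = _check_affine(self.affine)


def grid_voxel_box(shape, lo_idx, hi_idx):
    """Integer voxel grid over [lo, hi] clipped to the image shape, as (n,3).

    Rows come out in C order, i.e. lexicographically sorted by (i, j, k).
    """
    lo = np.maximum(np.asarray(lo_idx, int), 0)
    hi = np.minimum(np.asarray(hi_idx, int), np.asarray(shape) - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int)
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    return np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)


def sphere_voxels(center_mm, radius_mm, shape, affine, mask=None) -> np.ndarray:
    """In-mask voxels whose centres lie within ``radius_mm`` of ``center_mm``.

    Returned lexicographically sorted; distance uses the closed ball.
    """
    affine = _check_affine(affine)
    vs = voxel_sizes(affine)
    c_vox = mm_to_voxel(affine, center_mm)
    pad = np.ceil(radius_mm / vs).astype(int) + 1
    box = grid_voxel_box(shape, np.floor(c_vox).astype(int) - pad,
                         np.ceil(c_vox).astype(int) + pad)
    if box.size == 0:
        return box
    d = voxel_to_mm(affine, box) - np.asarray(center_mm, float)
    keep = (d ** 2).sum(axis=1) <= radius_mm ** 2 + 1e-9
    box = box[keep]
    if mask is not None:
        box = box[mask[box[:, 0], box[:, 1], box[:, 2]]]
    return box


def cube_voxels(center_voxel, edge_mm, shape, affine, mask=None) -> np.ndarray:
    """Voxels whose centres fall in the axis-aligned cube of side ``edge_mm``.

    The cube is centred on the centre voxel's mm position.  Each axis keeps
    offsets ``o`` with ``-edge/2 <= o < edge/2`` (half-open, inclusive on the
    low side) so counts are deterministic: at 2 mm voxels and a 6 mm edge an
    interior unmasked cube holds exactly 27 voxels; a one-voxel edge holds 1.
    """
    affine = _check_affine(affine)
    if not edge_mm > 0:
        raise ValueError("edge_mm must be > 0")
    vs = voxel_sizes(affine)
    half = edge_mm / 2.0
    lo = np.empty(3, int)
    hi = np.empty(3, int)
    for ax in range(3):
        ratio = half / vs[ax]
        lo[ax] = int(np.ceil(-ratio - 1e-9))
        # largest k with k*vs < half (strict); exact multiples excluded
        if abs(ratio - round(ratio)) < 1e-9:
            hi[ax] = int(round(ratio)) - 1
        else:
            hi[ax] = int(np.floor(ratio))
        hi[ax] = max(hi[ax], 0)
    c = np.asarray(center_voxel, int)
    box = grid_voxel_box(shape, c + lo, c + hi)
    if mask is not None:
        box = box[mask[box[:, 0], box[:, 1], box[:, 2]]]
    return box


def make_cube_roi(node: NodeSpec, center_voxel, edge_mm, shape, affine,
                  mask=None) -> RoiCube:
    vox = cube_voxels(center_voxel, edge_mm, shape, affine, mask)
    if vox.size == 0:
        raise GridError(f"ROI for node {node.label} has no in-mask voxels")
    return RoiCube(node=node, center_voxel=np.asarray(center_voxel, int),
                   edge_mm=float(edge_mm), voxels=vox)


def warn_undefined(message: str) -> None:
    warnings.warn(message, UndefinedResultWarning, stacklevel=3)
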