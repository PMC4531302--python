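"""Group spatial ICA on temporally concatenated subjects.

Each subject's in-mask data is variance-normalized per voxel, the runs are
concatenated in time, the concatenated matrix is PCA-reduced through its
temporal covariance, and the reduced data is unmixed by fixed-point
negentropy maximization with a logcosh contrast (FastICA).  Components are
stored as z-scored spatial maps with a deterministic sign convention (the
voxel of maximum |z| is positive), together with the concatenated mixing
time courses and per-subject segment boundaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import (NoMatchError, NodeSpec, PeakSearchError, RoiSet, RoifcError,
                   make_cube_roi, sphere_voxels)


@dataclass(frozen=True)
class Segment:
    subject_id: str
    start: int
    length: int


@dataclass
class ComponentSet:
    """Group ICA output: z-scored spatial maps + concatenated mixing courses."""

    maps: np.ndarray        # (C, V) z-scored over in-mask voxels
    mixing: np.ndarray      # (T_total, C)
    segments: list          # ordered Segment covering T_total
    mask: np.ndarray        # 3D bool, V = mask.sum()
    affine: np.ndarray

    def __post_init__(self):
        total = sum(s.length for s in self.segments)
        if total != self.mixing.shape[0]:
            raise ValueError("segment lengths do not cover the mixing matrix")
        if self.maps.shape[1] != int(self.mask.sum()):
            raise ValueError("map width does not match the mask voxel count")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def segment(self, subject_id: str) -> Segment:
        for s in self.segments:
            if s.subject_id == subject_id:
                return s
        raise KeyError(f"unknown subject {subject_id!r}")

    def map_volume(self, component: int) -> np.ndarray:
        """One component's z-map embedded in the 3D grid (zeros off-mask)."""
        vol = np.zeros(self.mask.shape, dtype=float)
        vol[self.mask] = self.maps[component]
        return vol


def variance_normalize(data: np.ndarray) -> np.ndarray:
    """Demean each row and scale to unit variance; zero-variance rows -> 0."""
    out = data - data.mean(axis=1, keepdims=True)
    sd = out.std(axis=1)
    nz = sd > 0
    out[nz] /= sd[nz, None]
    out[~nz] = 0.0
    return out


def concat_and_reduce(runs, mask, n_components: int, seed: int = 0,
                      max_iter: int = 500, tol: float = 1e-5) -> ComponentSet:
    """Group spatial ICA over temporally concatenated runs.

    All runs must share grid, affine and mask.  Each subject's in-mask data
    is variance-normalized per voxel and stacked in time; the concatenated
    (T_total, V) matrix is reduced to ``n_components`` by eigendecomposition
    of its temporal covariance, whitened, and unmixed spatially; the full
    mixing matrix is recomputed by least squares against the final z-scored
    maps.  Deterministic under a fixed seed.
    """
    if not runs:
        raise ValueError("runs must be non-empty")
    shape = runs[0].shape
    affine = runs[0].affine
    for r in runs:
        if r.shape != shape or not np.allclose(r.affine, affine):
            raise ValueError("all runs must share grid and affine")
    mask = np.asarray(mask, bool)
    total_t = sum(r.n_timepoints for r in runs)
    n_vox = int(mask.sum())
    x = np.empty((total_t, n_vox), dtype=np.float32)
    segments, start = [], 0
    for r in runs:
        x[start:start + r.n_timepoints] = variance_normalize(
            r.data[mask].astype(np.float32)).T
        segments.append(Segment(r.subject_id, start, r.n_timepoints))
        start += r.n_timepoints
    return group_ica(x, segments, mask, affine, n_components, seed=seed,
                     max_iter=max_iter, tol=tol)


def group_ica(x, segments, mask, affine, n_components: int, seed: int = 0,
              max_iter: int = 500, tol: float = 1e-5) -> ComponentSet:
    """Core group spatial ICA on an already concatenated (T_total, V) matrix.

    ``x`` holds variance-normalized in-mask voxel series stacked over the
    given segments (what :func:`concat_and_reduce` assembles from runs).
    """
    total_t = x.shape[0]
    if sum(s.length for s in segments) != total_t:
        raise ValueError("segments do not cover the concatenated matrix")
    if n_components >= total_t:
        raise RoifcError(
            f"n_components={n_components} must be below the total number of "
            f"timepoints ({total_t}); reduce n_components")
    mask = np.asarray(mask, bool)
    cov = (x @ x.T).astype(np.float64)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-6 * max(evals[0], 1.0):
        raise RoifcError(
            f"data rank is below n_components={n_components}; "
            "reduce n_components")
    # spatially whitened reduced data: rows have unit variance over voxels
    y = (evecs.T @ x) / np.sqrt(evals / x.shape[1])[:, None]

    ica = FastICA(n_components=n_components, whiten=False, fun="logcosh",
                  max_iter=max_iter, tol=tol, random_state=int(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(y.T.astype(np.float64)).T   # (C, V)

    # z-score over in-mask voxels, then fix signs: peak |z| voxel positive
    maps = sources - sources.mean(axis=1, keepdims=True)
    maps /= maps.std(axis=1, keepdims=True)
    flip = np.sign(maps[np.arange(n_components),
                        np.argmax(np.abs(maps), axis=1)])
    maps *= flip[:, None]

    # mixing by least squares of the concatenated data on the final maps
    gram = maps @ maps.T
    mixing = np.linalg.solve(gram, maps @ x.T).T      # (T_total, C)
    return ComponentSet(maps=maps, mixing=mixing, segments=segments,
                        mask=mask, affine=np.asarray(affine, float))


def match_component(cs: ComponentSet, template_map: np.ndarray,
                    floor: float = 0.2):
    """Best-matching component for a network template map.

    Returns ``(index, score)`` where score is the spatial Pearson correlation
    between each component's |z| map and the template over in-mask voxels;
    ties break toward the lower component index.  If every score falls below
    ``floor`` a :class:`NoMatchError` is raised.
    """
    t = np.asarray(template_map, dtype=float)
    if t.shape != cs.mask.shape:
        raise ValueError("template grid does not match the mask grid")
    tv = t[cs.mask]
    tv = tv - tv.mean()
    sd = tv.std()
    if sd == 0:
        raise ValueError("template map is constant inside the mask")
    tv /= sd
    a = np.abs(cs.maps)
    a = a - a.mean(axis=1, keepdims=True)
    asd = a.std(axis=1)
    scores = np.zeros(cs.n_components)
    nz = asd > 0
    scores[nz] = (a[nz] @ tv) / (a.shape[1] * asd[nz])
    idx = int(np.argmax(scores))
    if scores[idx] < floor:
        raise NoMatchError(
            f"no component matches the template (best score "
            f"{scores[idx]:.3f} < floor {floor})")
    return idx, float(scores[idx])


def match_components(cs: ComponentSet, template_maps: dict,
                     floor: float = 0.2) -> dict:
    """Map every network id to its best-matching component index."""
    return {net: match_component(cs, tmap, floor)[0]
            for net, tmap in template_maps.items()}


def peak_coordinate(values: np.ndarray, node: NodeSpec, mask: np.ndarray,
                    affine: np.ndarray) -> np.ndarray:
    """In-mask voxel maximizing the statistic within the node's search sphere.

    Ties break toward the lexicographically smallest voxel index.
    """
    vox = sphere_voxels(node.center_mm, node.search_radius_mm,
                        np.asarray(values).shape, affine, mask)
    if vox.size == 0:
        raise PeakSearchError(
            f"search region for node {node.label} contains no in-mask voxels")
    vals = np.asarray(values)[vox[:, 0], vox[:, 1], vox[:, 2]]
    return vox[int(np.argmax(vals))]


def group_roi_set(cs: ComponentSet, nodes, component_of: dict,
                  edge_mm: float = 6.0) -> RoiSet:
    """Standardized "group" ROI battery from the group component maps.

    One cubic ROI per node, centred on the peak z of that node's matched
    group component inside its search sphere.  The returned set is the same
    for every subject by construction.
    """
    rois = []
    for node in nodes:
        if node.network_id not in component_of:
            raise NoMatchError(
                f"network {node.network_id} has no matched component")
        vol = cs.map_volume(component_of[node.network_id])
        center = peak_coordinate(vol, node, cs.mask, cs.affine)
        rois.append(make_cube_roi(node, center, edge_mm, cs.mask.shape,
                                  cs.affine, cs.mask))
    return RoiSet(subject_id="group", method="group", rois=rois)
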