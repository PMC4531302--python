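"""Single-subject network reconstruction and ROI placement.

The individualized route: take the group component's mixing time course,
slice out one subject's segment, and regress it voxelwise in that subject's
own data to reconstruct the network as a z-statistic map.  Subject-specific
cubic ROIs are then centred on the per-node peak z of the subject's own map,
so the battery differs across subjects.  Standardized alternatives
("literature" coordinates fixed a priori, "group" peaks from the group maps)
share one battery across all subjects.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .core import (BoldRun, GridError, RoiCube, RoiSet, StatMap,
                   make_cube_roi, nearest_voxel)
from .ica import ComponentSet, peak_coordinate


def subject_network_timecourse(cs: ComponentSet, component: int,
                               subject_id: str) -> np.ndarray:
    """One subject's segment of a group mixing column, demeaned, unit variance."""
    try:
        seg = cs.segment(subject_id)
    except KeyError as e:
        raise KeyError(f"unknown subject {subject_id!r} in ComponentSet") from e
    series = np.asarray(cs.mixing[seg.start:seg.start + seg.length,
                                  component], dtype=float).copy()
    series -= series.mean()
    sd = series.std()
    if sd == 0:
        raise ValueError(f"mixing segment for {subject_id} is constant")
    return series / sd


def glm_zmap(run: BoldRun, regressor, mask=None, network_id: str = "",
             z_cap: float = 38.0) -> StatMap:
    """Voxelwise GLM of the run on a single regressor plus intercept, as z.

    Per in-mask voxel the least-squares slope t statistic (T-2 df) is mapped
    through the t tail probability and the standard normal quantile to a
    z score, capped at ``z_cap`` in magnitude.  Zero-variance voxels get
    z = 0; a constant regressor is an error.
    """
    reg = np.asarray(regressor, dtype=float)
    t_len = run.n_timepoints
    if reg.shape != (t_len,):
        raise ValueError("regressor length must equal the run's timepoints")
    if reg.std() == 0:
        raise ValueError("regressor is constant")
    if mask is None:
        mask = np.ones(run.shape, dtype=bool)
    data = run.data[mask].astype(float)              # (V, T)
    data = data - data.mean(axis=1, keepdims=True)
    reg_c = (reg - reg.mean()) / reg.std()
    sd = data.std(axis=1)
    r = np.zeros(data.shape[0])
    nz = sd > 0
    r[nz] = (data[nz] @ reg_c) / (t_len * sd[nz])
    r = np.clip(r, -1.0, 1.0)
    df = t_len - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r ** 2))
    z = np.zeros_like(r)
    finite = np.isfinite(tstat) & (tstat != 0)
    p_tail = stats.t.sf(np.abs(tstat[finite]), df)
    with np.errstate(divide="ignore"):
        z[finite] = np.sign(tstat[finite]) * stats.norm.isf(p_tail)
    z[~np.isfinite(tstat)] = np.sign(r[~np.isfinite(tstat)]) * z_cap
    z = np.clip(z, -z_cap, z_cap)
    z[~nz] = 0.0
    vol = np.zeros(run.shape, dtype=float)
    vol[mask] = z
    return StatMap(values=vol, affine=run.affine, subject_id=run.subject_id,
                   network_id=network_id)


def subject_roi_set(zmaps: dict, nodes, mask, edge_mm: float = 6.0) -> RoiSet:
    """Subject-specific ROI battery: per-node peak z on the subject's own maps.

    ``zmaps`` maps network id -> :class:`StatMap` for one subject.
    """
    rois = []
    subject_id = ""
    for node in nodes:
        if node.network_id not in zmaps:
            raise KeyError(f"no reconstructed map for network {node.network_id}")
        sm = zmaps[node.network_id]
        subject_id = sm.subject_id or subject_id
        center = peak_coordinate(sm.values, node, mask, sm.affine)
        rois.append(make_cube_roi(node, center, edge_mm, sm.values.shape,
                                  sm.affine, mask))
    return RoiSet(subject_id=subject_id, method="subject_specific", rois=rois)


def literature_roi_set(coords: dict, nodes, mask, affine,
                       edge_mm: float = 6.0) -> RoiSet:
    """Standardized battery of cubes at fixed a-priori mm coordinates.

    ``coords`` maps node label (``network.node``) to an (x, y, z) mm
    coordinate; each cube is centred on the nearest voxel (lexicographic
    tie-break at exact midpoints).  Identical for every subject.
    """
    mask = np.asarray(mask, bool)
    rois = []
    for node in nodes:
        if node.label not in coords:
            raise KeyError(f"no coordinate supplied for node {node.label}")
        center = nearest_voxel(affine, coords[node.label])
        if np.any(center < 0) or np.any(center >= np.asarray(mask.shape)) or \
                not mask[tuple(center)]:
            raise GridError(
                f"literature coordinate for node {node.label} falls outside "
                "the brain mask")
        rois.append(make_cube_roi(node, center, edge_mm, mask.shape, affine,
                                  mask))
    return RoiSet(subject_id="literature", method="literature", rois=rois)


def roi_mean_zstat(stat_map: StatMap, roi: RoiCube) -> float:
    """Arithmetic mean of the z statistic over the ROI's in-mask voxels."""
    if roi.voxels.size == 0:
        raise ValueError(f"ROI {roi.label} has no voxels")
    shape = np.asarray(stat_map.values.shape)
    if np.any(roi.voxels < 0) or np.any(roi.voxels >= shape):
        raise GridError(f"ROI {roi.label} has voxels outside the map grid")
    v = roi.voxels
    return float(stat_map.values[v[:, 0], v[:, 1], v[:, 2]].mean())


def roi_in_network(stat_map: StatMap, roi: RoiCube,
                   z_thresh: float = 2.3) -> float:
    """Fraction of ROI voxels above the z threshold (strict inequality).

    The "ROI falls in the network's cluster" criterion is fraction >= 0.5.
    """
    if roi.voxels.size == 0:
        raise ValueError(f"ROI {roi.label} has no voxels")
    v = roi.voxels
    vals = stat_map.values[v[:, 0], v[:, 1], v[:, 2]]
    return float(np.mean(vals > z_thresh))
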