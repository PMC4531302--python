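"""File formats: NIfTI volumes, CSV tables, motion text, Pajek graphs, JSON.

NIfTI gzip members are written with a zeroed timestamp so identical inputs
produce byte-identical files (reproducibility is checked by hashing).
"""
from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldRun, NodeSpec, RoiSet, make_cube_roi
from .connectivity import ConnMatrix
from .graphstats import BinaryGraph
from .ica import ComponentSet, Segment


# ---------------------------------------------------------------- NIfTI

def _save_nifti(img: nib.Nifti1Image, path) -> None:
    path = Path(path)
    if path.suffix == ".gz":
        raw = img.to_bytes()
        buf = _io.BytesIO()
        # fixed compresslevel + zero mtime -> byte-identical reruns
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0,
                           compresslevel=1) as gz:
            gz.write(raw)
        path.write_bytes(buf.getvalue())
    else:
        nib.save(img, str(path))


def read_bold(path, tr_s: float | None = None) -> BoldRun:
    """Load a 4D NIfTI run; TR comes from the header unless overridden.

    Plain and gzipped NIfTI are both accepted.  3D files and non-positive
    header TRs (without an override) are informative errors.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4D BOLD NIfTI, got {img.ndim}D "
            "(a 3D volume cannot carry a time series)")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr_s > 0:
            raise ValueError(
                f"{path}: header field pixdim[4] (TR) is not positive; "
                "pass tr_s explicitly")
    sid = Path(path).name
    for suf in (".gz", ".nii"):
        if sid.endswith(suf):
            sid = sid[: -len(suf)]
    sid = sid.replace("_bold", "")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    return BoldRun(data=data, affine=np.asarray(img.affine, float),
                   tr_s=float(tr_s), subject_id=sid)


def write_bold(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = run.tr_s
    img.header.set_zooms(zooms)
    _save_nifti(img, path)


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0


def write_mask(mask: np.ndarray, affine, path) -> None:
    _save_nifti(nib.Nifti1Image(mask.astype(np.uint8), np.asarray(affine)), path)


def write_stat_maps(volumes, affine, path) -> None:
    """Stack 3D maps into one 4D NIfTI (one volume per component/network)."""
    data = np.stack([np.asarray(v) for v in volumes], axis=-1).astype(np.float32)
    _save_nifti(nib.Nifti1Image(data, np.asarray(affine)), path)


# ---------------------------------------------------------------- tables

def read_node_table(path) -> list:
    """Node battery CSV/TSV: network_id,node_id,x_mm,y_mm,z_mm[,search_radius_mm]."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"network_id", "node_id", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: node table missing columns {sorted(missing)}")
    nodes = []
    for _, row in df.iterrows():
        kwargs = {}
        if "search_radius_mm" in df.columns and np.isfinite(row["search_radius_mm"]):
            kwargs["search_radius_mm"] = float(row["search_radius_mm"])
        nodes.append(NodeSpec(network_id=str(row["network_id"]),
                              node_id=str(row["node_id"]),
                              center_mm=(row["x_mm"], row["y_mm"], row["z_mm"]),
                              **kwargs))
    return nodes


def write_node_table(nodes, path) -> None:
    rows = [{"network_id": n.network_id, "node_id": n.node_id,
             "x_mm": n.center_mm[0], "y_mm": n.center_mm[1],
             "z_mm": n.center_mm[2], "search_radius_mm": n.search_radius_mm}
            for n in nodes]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_motion_params(path) -> np.ndarray:
    """Whitespace-delimited 6-column motion text (rotations in radians first)."""
    mp = np.loadtxt(path, ndmin=2)
    if mp.shape[1] != 6:
        raise ValueError(
            f"{path}: motion parameter file must have 6 columns, "
            f"got {mp.shape[1]}")
    return mp


def write_conn_matrix(cm: ConnMatrix, path) -> None:
    cm.to_dataframe().to_csv(path)


def read_conn_matrix(path, subject_id: str = "", method: str = "") -> ConnMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnMatrix(labels=list(df.columns), values=df.to_numpy(float),
                      subject_id=subject_id, method=method)


def write_roi_sets(roi_sets, affine, path) -> None:
    """Serialize ROI sets: one row per ROI with voxel and mm centre."""
    from .core import voxel_to_mm
    rows = []
    for rs in roi_sets:
        for roi in rs:
            mm = voxel_to_mm(affine, roi.center_voxel)
            rows.append({
                "subject_id": rs.subject_id, "method": rs.method,
                "network_id": roi.node.network_id, "node_id": roi.node.node_id,
                "center_i": int(roi.center_voxel[0]),
                "center_j": int(roi.center_voxel[1]),
                "center_k": int(roi.center_voxel[2]),
                "center_x_mm": mm[0], "center_y_mm": mm[1], "center_z_mm": mm[2],
                "edge_mm": roi.edge_mm,
                "search_radius_mm": roi.node.search_radius_mm,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_roi_sets(path, mask, affine) -> list:
    """Rebuild ROI sets (cube voxel membership recomputed from geometry)."""
    df = pd.read_csv(path)
    out = []
    for (sid, method), grp in df.groupby(["subject_id", "method"], sort=False):
        rois = []
        for _, row in grp.iterrows():
            node = NodeSpec(network_id=str(row["network_id"]),
                            node_id=str(row["node_id"]),
                            center_mm=(row["center_x_mm"], row["center_y_mm"],
                                       row["center_z_mm"]),
                            search_radius_mm=float(row["search_radius_mm"]))
            center = np.array([row["center_i"], row["center_j"],
                               row["center_k"]], dtype=int)
            rois.append(make_cube_roi(node, center, float(row["edge_mm"]),
                                      mask.shape, affine, mask))
        out.append(RoiSet(subject_id=str(sid), method=str(method), rois=rois))
    return out


# ---------------------------------------------------------------- ICA set

def write_component_set(cs: ComponentSet, maps_path, mixing_path,
                        segments_path) -> None:
    write_stat_maps([cs.map_volume(i) for i in range(cs.n_components)],
                    cs.affine, maps_path)
    pd.DataFrame(cs.mixing,
                 columns=[f"comp{i}" for i in range(cs.n_components)]
                 ).to_csv(mixing_path, index=False)
    pd.DataFrame([{"subject_id": s.subject_id, "start": s.start,
                   "length": s.length} for s in cs.segments]
                 ).to_csv(segments_path, index=False)


def read_component_set(maps_path, mixing_path, segments_path,
                       mask) -> ComponentSet:
    img = nib.load(str(maps_path))
    vols = np.asanyarray(img.dataobj).astype(float)
    maps = vols[mask, :].T
    mixing = pd.read_csv(mixing_path).to_numpy(float)
    seg_df = pd.read_csv(segments_path)
    segments = [Segment(str(r["subject_id"]), int(r["start"]), int(r["length"]))
                for _, r in seg_df.iterrows()]
    return ComponentSet(maps=maps, mixing=mixing, segments=segments,
                        mask=np.asarray(mask, bool),
                        affine=np.asarray(img.affine, float))


# ---------------------------------------------------------------- graphs

def write_pajek(g: BinaryGraph, path) -> None:
    """Export a binary graph in Pajek .net format."""
    import networkx as nx
    gx = g.to_networkx()
    # networkx writes node positions if present; plain topology suffices here
    nx.write_pajek(gx, str(path))


def write_edge_list(g: BinaryGraph, path) -> None:
    ii, jj = np.nonzero(np.triu(g.adjacency, k=1))
    pd.DataFrame({"node_a": [g.labels[i] for i in ii],
                  "node_b": [g.labels[j] for j in jj]}).to_csv(path, index=False)


# ---------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"cannot serialize {type(o)}")


def read_json(path):
    return json.loads(Path(path).read_text())
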