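"""ROI time-series extraction and Pearson/partial connectivity matrices.

Correlations that are undefined (a constant series) are flagged as NaN with
a warning rather than silently zeroed, and are excluded from summary means;
the diagonal is exactly 1.  By convention matrices are averaged directly
across subjects; an optional Fisher z route exists but defaults off.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BoldRun, RoiCube, warn_undefined
from .preprocess import _residualize


@dataclass
class ConnMatrix:
    """Symmetric correlation matrix over named nodes for one subject/method."""

    labels: list
    values: np.ndarray
    subject_id: str = ""
    method: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match the label count")
        if np.nanmax(np.abs(self.values - self.values.T), initial=0.0) > 1e-12:
            raise ValueError("connectivity matrix must be symmetric")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 1.0)

    @property
    def networks(self) -> list:
        seen = []
        for lab in self.labels:
            net = lab.split(".", 1)[0]
            if net not in seen:
                seen.append(net)
        return seen

    def network_of(self, label: str) -> str:
        return label.split(".", 1)[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def extract_roi_series(run: BoldRun, roi: RoiCube) -> np.ndarray:
    """Per-timepoint arithmetic mean over the ROI's voxels."""
    v = roi.voxels
    if v.size == 0:
        raise ValueError(f"ROI {roi.label} is empty")
    shape = np.asarray(run.shape)
    if np.any(v < 0) or np.any(v >= shape):
        raise ValueError(f"ROI {roi.label} has voxels outside the run grid")
    return np.asarray(run.data[v[:, 0], v[:, 1], v[:, 2], :], dtype=float).mean(axis=0)


def extract_roiset_series(run: BoldRun, roi_set) -> dict:
    return {roi.label: extract_roi_series(run, roi) for roi in roi_set}


def conn_matrix(series: dict, nuisance=None, subject_id: str = "",
                method: str = "") -> ConnMatrix:
    """Pairwise Pearson (or partial, given nuisance series) correlations.

    ``series`` maps node label -> 1D array; all must share a length >= 3.
    With nuisance regressors every series is residualized against them (plus
    an intercept) first, which with an empty set reduces bit-for-bit to the
    plain path.  Constant series yield NaN rows/columns, flagged by warning.
    """
    labels = list(series.keys())
    arrs = [np.asarray(series[k], dtype=float) for k in labels]
    n_t = arrs[0].shape[0]
    if any(a.shape != (n_t,) for a in arrs):
        raise ValueError("all node series must have the same length")
    if n_t < 3:
        raise ValueError("need at least 3 timepoints")
    x = np.stack(arrs, axis=0)
    if nuisance:
        nuis = [np.asarray(v, dtype=float) for v in nuisance]
        if any(v.shape != (n_t,) for v in nuis):
            raise ValueError("nuisance series length mismatch")
        design = np.column_stack([np.ones(n_t)] + nuis)
        x = _residualize(x.T, design).T
    xc = x - x.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1)
    bad = sd == 0
    if bad.any():
        warn_undefined(
            "constant series for node(s) "
            f"{[labels[i] for i in np.where(bad)[0]]}: correlations flagged NaN")
    sd_safe = np.where(bad, 1.0, sd)
    r = (xc @ xc.T) / (n_t * np.outer(sd_safe, sd_safe))
    r = np.clip(r, -1.0, 1.0)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnMatrix(labels=labels, values=r, subject_id=subject_id,
                      method=method)


def _network_indices(cm: ConnMatrix, network_id: str) -> np.ndarray:
    idx = [i for i, lab in enumerate(cm.labels)
           if cm.network_of(lab) == network_id]
    return np.asarray(idx, dtype=int)


def mean_within_network(cm: ConnMatrix, network_id: str) -> float:
    """Mean of the off-diagonal upper triangle over the network's nodes.

    NaN (undefined) entries are excluded with a warning.
    """
    idx = _network_indices(cm, network_id)
    if idx.size < 2:
        raise ValueError(f"network {network_id} has fewer than 2 nodes")
    sub = cm.values[np.ix_(idx, idx)]
    tri = sub[np.triu_indices(idx.size, k=1)]
    if np.isnan(tri).any():
        warn_undefined(f"{int(np.isnan(tri).sum())} undefined pair(s) excluded "
                       f"from the {network_id} mean")
        tri = tri[~np.isnan(tri)]
    if tri.size == 0:
        warn_undefined(f"network {network_id} mean undefined: no valid pairs")
        return float("nan")
    return float(tri.mean())


def node_mean_connectivity(cm: ConnMatrix, label: str,
                           scope: str = "network") -> float:
    """Mean correlation of one node to the others.

    ``scope='network'`` (default) averages over the node's own network;
    ``scope='all'`` over every other node in the battery.
    """
    if label not in cm.labels:
        raise KeyError(label)
    i = cm.labels.index(label)
    if scope == "network":
        others = [j for j in _network_indices(cm, cm.network_of(label))
                  if j != i]
    elif scope == "all":
        others = [j for j in range(len(cm.labels)) if j != i]
    else:
        raise ValueError("scope must be 'network' or 'all'")
    if not others:
        raise ValueError(f"node {label} has no partners in scope {scope!r}")
    vals = cm.values[i, others]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        warn_undefined(f"mean connectivity of {label} undefined")
        return float("nan")
    return float(vals.mean())


def zstat_connectivity_relation(mean_z_per_subject, cms,
                                scope: str = "network"):
    """Pooled relation between ROI mean z and that node's mean connectivity.

    ``mean_z_per_subject`` is a list (one entry per subject) of dicts mapping
    node label -> mean ROI z on the subject's reconstructed network;
    ``cms`` the matching list of :class:`ConnMatrix`.  Returns a DataFrame of
    (subject, node, mean_z, mean_conn) pairs and their pooled Pearson r
    (NaN + warning when degenerate).
    """
    if not cms or len(mean_z_per_subject) != len(cms):
        raise ValueError("need one z-dict per connectivity matrix, non-empty")
    rows = []
    for zdict, cm in zip(mean_z_per_subject, cms):
        for lab, z in zdict.items():
            conn = node_mean_connectivity(cm, lab, scope=scope)
            rows.append((cm.subject_id, lab, float(z), conn))
    df = pd.DataFrame(rows, columns=["subject_id", "node", "mean_z", "mean_conn"])
    ok = df[["mean_z", "mean_conn"]].dropna()
    if len(ok) < 3 or ok["mean_z"].std() == 0 or ok["mean_conn"].std() == 0:
        warn_undefined("z-vs-connectivity relation degenerate: zero variance")
        return df, float("nan")
    r = float(np.corrcoef(ok["mean_z"], ok["mean_conn"])[0, 1])
    return df, r


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Fisher z transform with clipping away from |r| = 1."""
    return np.arctanh(np.clip(values, -0.999999, 0.999999))


def average_conn_matrices(cms, fisher: bool = False) -> ConnMatrix:
    """Element-wise mean matrix across subjects (NaN entries excluded).

    With ``fisher=True`` averaging happens on Fisher z values and is mapped
    back; the default averages raw correlations.
    """
    if not cms:
        raise ValueError("no connectivity matrices given")
    labels = cms[0].labels
    for cm in cms:
        if cm.labels != labels:
            raise ValueError("node batteries differ across subjects")
    stack = np.stack([cm.values for cm in cms])
    if fisher:
        with np.errstate(invalid="ignore"):
            mean = np.tanh(np.nanmean(fisher_z(stack), axis=0))
    else:
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
    np.fill_diagonal(mean, 1.0)
    return ConnMatrix(labels=labels, values=mean, subject_id="group-mean",
                      method=cms[0].method)
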