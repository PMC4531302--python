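"""Synthetic multi-subject resting-state BOLD cohorts with planted networks.

The generator emulates the situation the individualized-ROI method targets:
a cohort shares a set of functional networks with canonical node locations,
but each subject's nodes are displaced by a random per-subject jitter, so any
ROI battery standardized across subjects mis-seeds some nodes for some
subjects.  Each node carries an isotropic Gaussian spatial footprint whose
time course is drawn from a band-limited (0.01-0.1 Hz) Gaussian process;
node signals are mixed through a Cholesky factor of a target correlation
matrix, after empirically whitening the innovations, so the *sample*
correlation of the planted node signals equals the target exactly.  White
measurement noise and optional structured nuisance fields (a CSF-like core
and a WM-like shell) are added on top.

Ground truth (realized centres, node signals, target correlations, nuisance
time courses) is recorded alongside the volumes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.fft import irfft, rfftfreq

from .core import BoldRun, GridError, NodeSpec, RoifcError

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Conventional five-network node batteries.  The printed label battery sums
#: to 29 labels although such seed batteries are conventionally counted as 30
#: seeds (and an edgewise family of C(30,2)=435 pairs); the tables here are
#: user-editable, the discrepancy is surfaced rather than resolved.
NAMED_BATTERY_LABELS = {
    "aDMN": ["PCC", "dPFC", "PLL", "PLR", "HCL", "HCR"],
    "pDMN": ["PCC", "PFC", "PLL", "PLR"],
    "FPNL": ["ACC", "PCC", "IPSL", "IPSR", "IFGL", "IFGR", "OTC"],
    "FPNR": ["ACC", "PCC", "IPSL", "IPSR", "IFGL", "IFGR", "OTC"],
    "SAL": ["ACC", "PFCL", "PFCR", "IL", "IR"],
}


@dataclass(frozen=True)
class NetworkTemplate:
    """Canonical geometry and coupling of one planted network."""

    network_id: str
    node_centers: tuple          # ((x,y,z) mm, ...) canonical template space
    node_ids: tuple = ()         # labels, defaults to n1..nK
    blob_fwhm_mm: float = 8.0    # FWHM of each node's Gaussian footprint
    within_corr: float = 0.8     # target correlation among the network's nodes

    def __post_init__(self):
        centers = tuple(tuple(float(v) for v in c) for c in self.node_centers)
        object.__setattr__(self, "node_centers", centers)
        if len(centers) < 2:
            raise ValueError(f"network {self.network_id}: needs >= 2 nodes")
        if not self.node_ids:
            object.__setattr__(
                self, "node_ids",
                tuple(f"n{i + 1}" for i in range(len(centers))))
        if len(self.node_ids) != len(centers):
            raise ValueError("node_ids/node_centers length mismatch")
        if not 0.0 <= self.within_corr <= 1.0:
            raise ValueError("within_corr must lie in [0, 1]")
        pts = np.asarray(centers)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= self.blob_fwhm_mm:
            raise ValueError(
                f"network {self.network_id}: node centres must be separated "
                f"by more than blob_fwhm_mm ({self.blob_fwhm_mm} mm)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_centers)

    @property
    def labels(self) -> list:
        return [f"{self.network_id}.{n}" for n in self.node_ids]


@dataclass
class CohortConfig:
    """All knobs of one synthetic cohort; a fixed seed gives a bit-identical cohort."""

    n_subjects: int = 20
    grid_shape: tuple = (58, 98, 58)
    voxel_mm: float = 2.0        # isotropic template resolution
    tr_s: float = 3.0            # repetition time, seconds
    n_timepoints: int = 100      # ~5 min at TR 3 s
    jitter_sd_mm: float = 6.0    # per-subject node displacement SD (per axis)
    noise_sd: float = 1.0        # additive white noise SD (signals have SD 1)
    between_corr: float = 0.1    # default between-network signal correlation
    coupling: dict = None        # {(netA,netB): r}; None -> DEFAULT_COUPLING
    nuisance: bool = False       # add WM/CSF-like structured signals
    nuisance_amp: float = 1.0
    band_hz: tuple = (0.01, 0.1)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_timepoints < 3:
            raise ValueError("counts must be positive (n_timepoints >= 3)")
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive dimensions")
        if self.jitter_sd_mm < 0 or self.noise_sd < 0 or self.voxel_mm <= 0:
            raise ValueError("jitter_sd_mm/noise_sd must be >= 0, voxel_mm > 0")
        if self.coupling is not None:
            self.coupling = {tuple(sorted(k)): float(v)
                             for k, v in dict(self.coupling).items()}

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_mm] * 3 + [1.0])
        return a

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * self.voxel_mm


@dataclass
class SyntheticTruth:
    """Everything the generator planted, keyed by subject."""

    subject_ids: list
    centers: dict                # sid -> {node label: (x,y,z) realized mm}
    signals: dict                # sid -> (T, n_nodes) node signal matrix
    node_labels: list
    target_corr: np.ndarray      # (n_nodes, n_nodes) planted correlation
    nuisance: dict               # sid -> (T, 2) [CSF, WM] or None
    config: CohortConfig = None
    aging: dict = field(default_factory=dict)

    def center_array(self, sid: str) -> np.ndarray:
        return np.asarray([self.centers[sid][lab] for lab in self.node_labels])


def ellipsoid_mask(grid_shape, voxel_mm: float = 2.0) -> np.ndarray:
    """Brain-like ellipsoid mask inscribed in the grid (95% of half-extents)."""
    shape = np.asarray(grid_shape)
    idx = np.indices(tuple(shape), dtype=float)
    center = (shape - 1) / 2.0
    semi = np.maximum((shape - 1) / 2.0 * 0.95, 0.5)
    rho2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return rho2 <= 1.0


def _lattice_points(grid_shape, voxel_mm, spacing_mm, margin_mm):
    extent = (np.asarray(grid_shape) - 1) * voxel_mm
    pts = []
    axes = []
    for ax in range(3):
        lo, hi = margin_mm, extent[ax] - margin_mm
        if hi < lo:
            raise GridError("grid too small for the requested margin")
        n = int(np.floor((hi - lo) / spacing_mm)) + 1
        axes.append(lo + spacing_mm * np.arange(n))
    for x in axes[0]:
        for y in axes[1]:
            for z in axes[2]:
                pts.append((x, y, z))
    return pts


def build_battery(sizes: dict, grid_shape=(58, 98, 58), voxel_mm=2.0,
                  spacing_mm=16.0, margin_mm=32.0, blob_fwhm_mm=8.0,
                  within_corr=0.8, node_ids: dict | None = None):
    """Place a multi-network node battery on a canonical lattice.

    ``sizes`` maps network id -> node count; consecutive lattice chunks keep
    each network spatially coherent.  The 32 mm default margin keeps every
    canonical centre at least 4 jitter SDs inside the grid for jitter SDs up
    to 8 mm.
    """
    pts = _lattice_points(grid_shape, voxel_mm, spacing_mm, margin_mm)
    total = sum(sizes.values())
    if total > len(pts):
        raise GridError(
            f"battery of {total} nodes does not fit the {len(pts)}-point lattice")
    out = []
    cursor = 0
    for net, k in sizes.items():
        ids = tuple((node_ids or {}).get(net, ())) or ()
        out.append(NetworkTemplate(
            network_id=net,
            node_centers=tuple(pts[cursor:cursor + k]),
            node_ids=ids,
            blob_fwhm_mm=blob_fwhm_mm,
            within_corr=within_corr,
        ))
        cursor += k
    return out


def default_templates(grid_shape=(58, 98, 58), voxel_mm=2.0,
                      blob_fwhm_mm=14.0, within_corr=0.8, margin_mm=32.0):
    """Default 30-node battery: five networks of six nodes each.

    Networks are stacked along the long (y) axis, each occupying a 24 mm
    slab: four nodes at the x/z corners of the interior box on the slab's
    near face and two mid-x nodes on its far face.  The construction keeps
    same-network nodes >= ~33 mm apart (so a peak-search sphere can never
    reach a sibling node and collapse node identities), uncoupled
    neighbouring networks ~20 mm apart (distinct blobs at 12 mm FWHM), and
    the two coupled default-mode sub-networks at opposite ends of the y
    axis, >= ~58 mm apart, so a subject map of one cannot capture the
    other's blobs.  The
    anterior DMN carries its conventional node labels; the aDMN-pDMN
    fractionation enters through the default coupling in
    :func:`target_correlation` (the two sub-networks couple at r=0.6).
    """
    extent = (np.asarray(grid_shape) - 1) * voxel_mm
    lo = np.full(3, float(margin_mm))
    hi = extent - margin_mm
    if np.any(hi - lo < np.array([44.0, 112.0, 44.0])):
        raise GridError("grid too small for the default five-network battery")
    xa, xb = lo[0] + 2.0, hi[0] - 2.0
    za, zb = lo[2] + 2.0, hi[2] - 2.0
    xm = (xa + xb) / 2.0
    y_centers = np.linspace(lo[1] + 12.0, hi[1] - 12.0, 5)
    # coupled aDMN/pDMN at the two ends of the y axis, others between
    order = ("aDMN", "FPNL", "SAL", "FPNR", "pDMN")
    ids = {"aDMN": ("PCC", "dPFC", "PLL", "PLR", "HCL", "HCR")}
    out = []
    for net, yc in zip(order, y_centers):
        y1, y2 = yc - 12.0, yc + 12.0
        centers = ((xa, y1, za), (xb, y1, za), (xa, y1, zb), (xb, y1, zb),
                   (xm, y2, za), (xm, y2, zb))
        out.append(NetworkTemplate(
            network_id=net, node_centers=centers, node_ids=ids.get(net, ()),
            blob_fwhm_mm=blob_fwhm_mm, within_corr=within_corr))
    return sorted(out, key=lambda t: ("aDMN pDMN FPNL FPNR SAL".split()
                                      .index(t.network_id)))


def named_battery(grid_shape=(58, 98, 58), voxel_mm=2.0, blob_fwhm_mm=8.0,
                  within_corr=0.8):
    """The conventional 29-label five-network battery (aDMN 6, pDMN 4,
    FPNL 7, FPNR 7, SAL 5) on the canonical lattice."""
    sizes = {k: len(v) for k, v in NAMED_BATTERY_LABELS.items()}
    ids = {k: tuple(v) for k, v in NAMED_BATTERY_LABELS.items()}
    return build_battery(sizes, grid_shape, voxel_mm,
                         blob_fwhm_mm=blob_fwhm_mm, within_corr=within_corr,
                         node_ids=ids)


def battery_nodes(templates, search_radius_mm: float = 16.0) -> list:
    """Flatten templates into the NodeSpec battery downstream stages consume."""
    nodes = []
    for t in templates:
        for nid, c in zip(t.node_ids, t.node_centers):
            nodes.append(NodeSpec(network_id=t.network_id, node_id=nid,
                                  center_mm=c, search_radius_mm=search_radius_mm))
    return nodes


DEFAULT_COUPLING = {("aDMN", "pDMN"): 0.6}


def target_correlation(templates, between_corr=0.1, coupling=None):
    """Planted node-pair correlation matrix over the flattened battery.

    Within-network blocks use each template's ``within_corr``; cross-network
    blocks use ``between_corr`` unless overridden per network pair.  Raises if
    the resulting matrix is not positive definite.
    """
    coupling = {tuple(sorted(k)): v
                for k, v in (DEFAULT_COUPLING if coupling is None else coupling).items()}
    labels = [lab for t in templates for lab in t.labels]
    nets = [t.network_id for t in templates for _ in t.labels]
    n = len(labels)
    r = np.full((n, n), float(between_corr))
    start = 0
    for t in templates:
        k = t.n_nodes
        r[start:start + k, start:start + k] = t.within_corr
        start += k
    for i in range(n):
        for j in range(n):
            key = tuple(sorted((nets[i], nets[j])))
            if nets[i] != nets[j] and key in coupling:
                r[i, j] = coupling[key]
    np.fill_diagonal(r, 1.0)
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError as e:
        raise RoifcError(
            "target node correlation structure is not positive definite") from e
    return labels, r


def bandlimited_series(n_timepoints, tr_s, n_series, rng, band_hz=(0.01, 0.1)):
    """Independent band-limited Gaussian processes, one per column, unit SD."""
    freqs = rfftfreq(n_timepoints, d=tr_s)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not keep.any():
        raise RoifcError(
            f"no FFT bins inside the {band_hz} Hz band at T={n_timepoints}, "
            f"TR={tr_s}s")
    spec = np.zeros((len(freqs), n_series), dtype=complex)
    nk = int(keep.sum())
    spec[keep] = rng.standard_normal((nk, n_series)) + 1j * rng.standard_normal((nk, n_series))
    x = irfft(spec, n=n_timepoints, axis=0)
    x -= x.mean(axis=0)
    x /= x.std(axis=0)
    return x


def correlated_node_signals(n_timepoints, tr_s, target_corr, rng,
                            band_hz=(0.01, 0.1)):
    """Node signals whose *sample* correlation equals ``target_corr`` exactly.

    Band-limited innovations are empirically whitened (Cholesky of their
    sample covariance) before mixing through the Cholesky factor of the
    target, so the planted correlation is exact, not just in expectation.
    Requires T > n_nodes.
    """
    n = target_corr.shape[0]
    if n_timepoints <= n:
        raise RoifcError("need more timepoints than nodes for exact mixing")
    freqs = rfftfreq(n_timepoints, d=tr_s)
    n_bins = int(((freqs >= band_hz[0]) & (freqs <= band_hz[1])).sum())
    if 2 * n_bins < n + 1:
        raise RoifcError(
            f"band-limited series span only ~{2 * n_bins} dimensions at "
            f"T={n_timepoints}, fewer than the {n} node signals; use a "
            "longer series or a wider band")
    z = bandlimited_series(n_timepoints, tr_s, n, rng, band_hz)
    cov = (z.T @ z) / n_timepoints
    z_white = z @ np.linalg.inv(np.linalg.cholesky(cov)).T
    x = z_white @ np.linalg.cholesky(target_corr).T
    x /= x.std(axis=0)
    return x


def _blob_add(vol, center_mm, sigma_mm, series, voxel_mm):
    """Add outer(gaussian blob, series) into ``vol`` over a 3-sigma support box."""
    shape = vol.shape[:3]
    c_vox = np.asarray(center_mm) / voxel_mm
    rad = int(np.ceil(3.0 * sigma_mm / voxel_mm))
    lo = np.maximum(np.floor(c_vox).astype(int) - rad, 0)
    hi = np.minimum(np.ceil(c_vox).astype(int) + rad, np.asarray(shape) - 1)
    if np.any(lo > hi):
        return
    ax = [np.arange(lo[a], hi[a] + 1) * voxel_mm - center_mm[a] for a in range(3)]
    w = np.exp(-(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                 + ax[2][None, None, :] ** 2) / (2.0 * sigma_mm ** 2))
    vol[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1, :] += (
        w[..., None] * series).astype(vol.dtype)


def _nuisance_fields(grid_shape, voxel_mm):
    shape = np.asarray(grid_shape)
    idx = np.indices(tuple(shape), dtype=float)
    center = (shape - 1) / 2.0
    semi = np.maximum((shape - 1) / 2.0 * 0.95, 0.5)
    rho = np.sqrt(sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3)))
    csf = np.exp(-rho ** 2 / (2 * 0.25 ** 2))            # ventricular core
    wm = np.exp(-(rho - 0.65) ** 2 / (2 * 0.12 ** 2))    # deep white shell
    return csf.astype(np.float32), wm.astype(np.float32)


def _draw_jitter(rng, n_nodes, sd):
    """Per-node 3D Gaussian jitter, rejection-resampled to |component| <= 4 sd."""
    j = rng.normal(0.0, sd, size=(n_nodes, 3)) if sd > 0 else np.zeros((n_nodes, 3))
    if sd > 0:
        for _ in range(100):
            bad = np.abs(j) > 4.0 * sd
            if not bad.any():
                break
            j[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
    return j


def _validate_margin(templates, config):
    extent = config.extent_mm
    margin = 4.0 * config.jitter_sd_mm
    for t in templates:
        for nid, c in zip(t.node_ids, t.node_centers):
            c = np.asarray(c)
            if np.any(c - margin < -1e-9) or np.any(c + margin > extent + 1e-9):
                raise GridError(
                    f"node {t.network_id}.{nid} at {tuple(c)} mm is closer than "
                    f"4*jitter_sd ({margin} mm) to the grid edge")


def plan_cohort(templates, config: CohortConfig) -> SyntheticTruth:
    """Draw everything light-weight about a cohort: signals, centres, nuisance.

    The returned truth record fully determines the cohort; volumes are
    materialized from it by :func:`iter_cohort` / :func:`generate_cohort`.
    Per-subject noise streams derive from the same seed tree, so the cohort
    is bit-identical however the volumes are consumed.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    _validate_margin(templates, config)
    labels, target = target_correlation(templates, config.between_corr,
                                        config.coupling)
    truth = SyntheticTruth(subject_ids=[], centers={}, signals={},
                           node_labels=labels, target_corr=target,
                           nuisance={}, config=config)
    ss = np.random.SeedSequence(config.seed)
    extent = config.extent_mm
    for s, child in enumerate(ss.spawn(config.n_subjects)):
        sid = f"sub-{s + 1:02d}"
        rng = np.random.default_rng(child.spawn(2)[0])
        signals = correlated_node_signals(config.n_timepoints, config.tr_s,
                                          target, rng, config.band_hz)
        centers = {}
        for t in templates:
            jit = _draw_jitter(rng, t.n_nodes, config.jitter_sd_mm)
            for k, (nid, c) in enumerate(zip(t.node_ids, t.node_centers)):
                realized = np.asarray(c) + jit[k]
                if np.any(realized < -1e-9) or np.any(realized > extent + 1e-9):
                    raise GridError(
                        f"subject {sid}: node {t.network_id}.{nid} jittered "
                        f"outside the grid at {tuple(np.round(realized, 1))} mm")
                centers[f"{t.network_id}.{nid}"] = tuple(realized)
        nuis = None
        if config.nuisance:
            nuis = bandlimited_series(config.n_timepoints, config.tr_s, 2,
                                      rng, config.band_hz) * config.nuisance_amp
        truth.subject_ids.append(sid)
        truth.centers[sid] = centers
        truth.signals[sid] = signals
        truth.nuisance[sid] = nuis
    return truth


def _subject_volume(templates, config, truth, index, noise_child,
                    nuisance_fields=None) -> BoldRun:
    sid = truth.subject_ids[index]
    rng = np.random.default_rng(noise_child)
    shape_t = tuple(config.grid_shape) + (config.n_timepoints,)
    if config.noise_sd > 0:
        vol = (rng.standard_normal(shape_t) * config.noise_sd).astype(np.float32)
    else:
        vol = np.zeros(shape_t, dtype=np.float32)
    signals = truth.signals[sid]
    col = 0
    for t in templates:
        sigma = t.blob_fwhm_mm * FWHM_TO_SIGMA
        for nid in t.node_ids:
            realized = np.asarray(truth.centers[sid][f"{t.network_id}.{nid}"])
            _blob_add(vol, realized, sigma, signals[:, col], config.voxel_mm)
            col += 1
    if config.nuisance:
        csf_f, wm_f = nuisance_fields or _nuisance_fields(config.grid_shape,
                                                          config.voxel_mm)
        nuis = truth.nuisance[sid]
        _field_add(vol, csf_f, nuis[:, 0])
        _field_add(vol, wm_f, nuis[:, 1])
    return BoldRun(data=vol, affine=config.affine, tr_s=config.tr_s,
                   subject_id=sid)


def iter_cohort(templates, config: CohortConfig, truth=None):
    """Yield one subject's :class:`BoldRun` at a time (bounded memory).

    Pass a truth from :func:`plan_cohort` to reuse it; otherwise one is
    planned internally and available afterwards as ``gen.truth`` — or use
    :func:`generate_cohort` for the materialized pair.
    """
    if truth is None:
        truth = plan_cohort(templates, config)
    fields = (_nuisance_fields(config.grid_shape, config.voxel_mm)
              if config.nuisance else None)
    ss = np.random.SeedSequence(config.seed)
    for index, child in enumerate(ss.spawn(config.n_subjects)):
        yield _subject_volume(templates, config, truth, index,
                              child.spawn(2)[1], fields)


def generate_cohort(templates, config: CohortConfig):
    """Generate one synthetic cohort as ``(runs, truth)``.

    Each subject's voxel series is the sum of per-node Gaussian-blob
    footprints times that subject's node signals, plus white noise and
    optional nuisance fields.  Deterministic under ``config.seed``.
    """
    truth = plan_cohort(templates, config)
    runs = list(iter_cohort(templates, config, truth))
    return runs, truth


def _field_add(vol, field3d, series):
    vol += (field3d[..., None] * series).astype(vol.dtype)


def aged_config(templates, config: CohortConfig, coupling_delta: float = 0.0,
                extra_jitter_mm: float = 0.0, delta_pairs=None) -> CohortConfig:
    """The "old group" variant of a cohort config: shifted coupling, more jitter.

    ``coupling_delta`` is added to the between-network correlation of the
    named ``delta_pairs`` (or every cross-network pair when None);
    ``extra_jitter_mm`` is added to the jitter SD to plant spatial
    reorganization.
    """
    import copy
    cfg = copy.deepcopy(config)
    cfg.jitter_sd_mm = config.jitter_sd_mm + float(extra_jitter_mm)
    if coupling_delta:
        base = dict(DEFAULT_COUPLING if config.coupling is None
                    else config.coupling)
        nets = [t.network_id for t in templates]
        pairs = (delta_pairs if delta_pairs is not None
                 else [(a, b) for i, a in enumerate(nets) for b in nets[i + 1:]])
        for pair in pairs:
            key = tuple(sorted(pair))
            base[key] = base.get(key, config.between_corr) + coupling_delta
        cfg.coupling = {tuple(sorted(k)): v for k, v in base.items()}
    return cfg


def make_aged_cohort(templates, config: CohortConfig,
                     coupling_delta: float = 0.0,
                     extra_jitter_mm: float = 0.0,
                     delta_pairs=None):
    """Generate an "old group" cohort (see :func:`aged_config`).

    With both deltas zero the cohort is bit-identical to
    :func:`generate_cohort` under the same seed.
    """
    cfg = aged_config(templates, config, coupling_delta, extra_jitter_mm,
                      delta_pairs)
    runs, truth = generate_cohort(templates, cfg)
    truth.aging = {"coupling_delta": float(coupling_delta),
                   "extra_jitter_mm": float(extra_jitter_mm),
                   "jitter_sd_mm": cfg.jitter_sd_mm}
    return runs, truth


def node_level_cohort(templates, config: CohortConfig, node_noise_sd=0.3):
    """Node-level reduction of the cohort: per-subject node series only.

    Returns ``(labels, list of (T, n_nodes) arrays)`` where each subject's
    series are the exactly-correlated planted signals plus independent node
    noise — the measurement a perfectly seeded ROI battery would deliver.
    Used for fast calibration studies that need no volumes.
    """
    labels, target = target_correlation(templates, config.between_corr,
                                        config.coupling)
    ss = np.random.SeedSequence(config.seed)
    out = []
    for child in ss.spawn(config.n_subjects):
        rng = np.random.default_rng(child)
        x = correlated_node_signals(config.n_timepoints, config.tr_s, target,
                                    rng, config.band_hz)
        x = x + rng.standard_normal(x.shape) * node_noise_sd
        out.append(x)
    return labels, out


def template_network_maps(templates, grid_shape, voxel_mm):
    """Canonical (jitter-free) spatial map per network: sum of node blobs."""
    maps = {}
    for t in templates:
        vol = np.zeros(tuple(grid_shape) + (1,), dtype=np.float32)
        sig = t.blob_fwhm_mm * FWHM_TO_SIGMA
        for c in t.node_centers:
            _blob_add(vol, np.asarray(c), sig, np.ones(1), voxel_mm)
        maps[t.network_id] = vol[..., 0]
    return maps


def truth_to_json(truth: SyntheticTruth) -> str:
    """Serialize ground truth (JSON, full precision)."""
    cfg = asdict(truth.config) if truth.config is not None else None
    if cfg is not None:
        if cfg["coupling"] is not None:
            cfg["coupling"] = {f"{a}|{b}": v
                               for (a, b), v in cfg["coupling"].items()}
        cfg["grid_shape"] = list(cfg["grid_shape"])
    doc = {
        "subject_ids": truth.subject_ids,
        "node_labels": truth.node_labels,
        "target_corr": np.asarray(truth.target_corr).tolist(),
        "centers": {sid: {k: list(v) for k, v in c.items()}
                    for sid, c in truth.centers.items()},
        "signals": {sid: np.asarray(s).tolist()
                    for sid, s in truth.signals.items()},
        "nuisance": {sid: (np.asarray(n).tolist() if n is not None else None)
                     for sid, n in truth.nuisance.items()},
        "config": cfg,
        "aging": truth.aging,
    }
    return json.dumps(doc, sort_keys=True)


def truth_from_json(text: str) -> SyntheticTruth:
    doc = json.loads(text)
    cfg = doc.get("config")
    config = None
    if cfg is not None:
        cfg = dict(cfg)
        if cfg.get("coupling") is not None:
            cfg["coupling"] = {tuple(k.split("|")): v
                               for k, v in cfg["coupling"].items()}
        cfg["grid_shape"] = tuple(cfg["grid_shape"])
        cfg["band_hz"] = tuple(cfg["band_hz"])
        config = CohortConfig(**cfg)
    return SyntheticTruth(
        subject_ids=list(doc["subject_ids"]),
        centers={sid: {k: tuple(v) for k, v in c.items()}
                 for sid, c in doc["centers"].items()},
        signals={sid: np.asarray(s) for sid, s in doc["signals"].items()},
        node_labels=list(doc["node_labels"]),
        target_corr=np.asarray(doc["target_corr"]),
        nuisance={sid: (np.asarray(n) if n is not None else None)
                  for sid, n in doc["nuisance"].items()},
        config=config,
        aging=dict(doc.get("aging", {})),
    )
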