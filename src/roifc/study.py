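"""Packaged end-to-end studies on synthetic cohorts.

Two studies bind the pipeline together and are what the acceptance script
recomputes:

* **ROI-method comparison** — one 20-subject cohort (five 6-node networks,
  6 mm node jitter SD, voxel-level SNR ~1), analyzed with literature, group
  and subject-specific ROI batteries; summarizes within-network connectivity
  per method, the paired tests between methods, and the pooled relation
  between ROI mean z and node connectivity.
* **Aging contrast** — a second cohort with purely spatial reorganization
  (jitter SD raised to 8 mm, coupling unchanged), compared edgewise against
  the first under (a) the first cohort's group ROIs and (b) subject-specific
  ROIs, with Bonferroni correction over all C(30,2)=435 node pairs; plus
  Louvain partitions of the group graphs against the planted module
  structure.

A node-level null calibration checks the edgewise test's false positive
rate against its nominal alpha.  All randomness derives from a single seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import synthetic
from .connectivity import (conn_matrix, extract_roiset_series,
                           mean_within_network, zstat_connectivity_relation)
from .core import RoiSet
from .graphstats import (binarize, compare_groups_edgewise,
                         compare_methods_paired, count_significant_edges,
                         graph_metrics, group_graph)
from .ica import group_roi_set, match_components
from .mapping import (glm_zmap, literature_roi_set, roi_in_network,
                      roi_mean_zstat, subject_network_timecourse,
                      subject_roi_set)
from .preprocess import preprocess_run
from .synthetic import (CohortConfig, battery_nodes, default_templates,
                        ellipsoid_mask, template_network_maps)

#: study-wide analysis constants (the conventional pipeline parameters)
STUDY_PARAMS = dict(
    n_components=30, edge_mm=6.0, hp_sigma_s=100.0, fwhm_mm=4.0,
    r_thresh=0.35, z_thresh=2.3, alpha=0.05,
    # 24 mm search spheres accommodate the aged cohort's 8 mm jitter SD
    # (P(|jitter| <= 24 mm) ~ 0.97 at sigma 8): clipping a subject's peak at
    # the sphere boundary would otherwise degrade aged subject-specific ROIs
    # asymmetrically and mimic an aging effect.
    search_radius_mm=24.0,
    extra_jitter_mm=2.0,        # aged cohort: reorganization-only effect
)


def derive_seeds(seed: int, n: int = 8) -> list:
    """Independent sub-seeds (< 2^31) for every random stage of the study."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


@dataclass
class CohortAnalysis:
    """Everything derived from one cohort by the common analysis path."""

    subject_ids: list
    truth: synthetic.SyntheticTruth
    component_set: object
    component_of: dict
    roi_sets: dict             # method -> {sid: RoiSet}
    conn: dict                 # method -> [ConnMatrix] in subject order
    mean_z: dict               # method -> {sid: {label: mean ROI z}}
    in_network: dict           # method -> {sid: {label: suprathreshold frac}}
    center_error_mm: dict      # sid -> {label: |ss ROI centre - planted| mm}


def _subject_zmaps(run, cs, component_of, mask):
    zmaps = {}
    for net, comp in component_of.items():
        tc = subject_network_timecourse(cs, comp, run.subject_id)
        zmaps[net] = glm_zmap(run, tc, mask, network_id=net)
    return zmaps


def analyze_cohort(run_iter, truth, mask, templates, nodes, ica_seed: int,
                   methods=("literature", "group", "subject_specific"),
                   external_group_rois: RoiSet | None = None,
                   z_networks=("aDMN",), params=STUDY_PARAMS) -> CohortAnalysis:
    """Preprocess a cohort and derive ROI sets + connectivity per method.

    ``run_iter`` yields one BoldRun per subject (e.g. from
    :func:`roifc.synthetic.iter_cohort`); volumes are preprocessed one at a
    time and only their in-mask matrices are retained, so memory stays
    bounded by one full volume plus the masked cohort.
    ``external_group_rois`` lets a standardized battery derived from another
    cohort's decomposition (e.g. the young group's) be applied here under
    the method name ``group``.
    """
    from .core import BoldRun
    from .ica import Segment, group_ica, variance_normalize
    cfg = truth.config
    affine = cfg.affine
    masked, sids = [], []
    for run in run_iter:
        pre = preprocess_run(run, mask, hp_sigma_s=params["hp_sigma_s"],
                             fwhm_mm=params["fwhm_mm"])
        masked.append(pre.data[mask].astype(np.float32))   # (V, T)
        sids.append(run.subject_id)
        del run, pre
    n_vox = int(mask.sum())
    total_t = sum(m.shape[1] for m in masked)
    x = np.empty((total_t, n_vox), dtype=np.float32)
    segments, start = [], 0
    for sid, m in zip(sids, masked):
        x[start:start + m.shape[1]] = variance_normalize(m).T
        segments.append(Segment(sid, start, m.shape[1]))
        start += m.shape[1]
    cs = group_ica(x, segments, mask, affine, params["n_components"],
                   seed=ica_seed)
    del x
    tmaps = template_network_maps(templates, mask.shape, cfg.voxel_mm)
    component_of = match_components(cs, tmaps)

    roi_sets = {m: {} for m in methods}
    lit = None
    if "literature" in methods:
        coords = {n.label: n.center_mm for n in nodes}
        lit = literature_roi_set(coords, nodes, mask, affine,
                                 edge_mm=params["edge_mm"])
    grp = external_group_rois
    if "group" in methods and grp is None:
        grp = group_roi_set(cs, nodes, component_of, edge_mm=params["edge_mm"])

    conn = {m: [] for m in methods}
    mean_z = {m: {} for m in methods}
    in_net = {m: {} for m in methods}
    center_err = {}
    shape_t = tuple(cfg.grid_shape) + (cfg.n_timepoints,)
    for sid, mdata in zip(sids, masked):
        vol = np.zeros(shape_t, dtype=np.float32)
        vol[mask] = mdata
        run = BoldRun(data=vol, affine=affine, tr_s=cfg.tr_s, subject_id=sid)
        zmaps = _subject_zmaps(run, cs, component_of, mask)
        per_method = {}
        if "literature" in methods:
            per_method["literature"] = RoiSet(sid, "literature", lit.rois)
        if "group" in methods:
            per_method["group"] = RoiSet(sid, "group", grp.rois)
        if "subject_specific" in methods:
            ss = subject_roi_set(zmaps, nodes, mask, edge_mm=params["edge_mm"])
            per_method["subject_specific"] = ss
            center_err[sid] = _center_errors(ss, truth, sid, affine)
        for m, rs in per_method.items():
            roi_sets[m][sid] = rs
            series = extract_roiset_series(run, rs)
            conn[m].append(conn_matrix(series, subject_id=sid, method=m))
            mz, frac = {}, {}
            for roi in rs:
                net = roi.node.network_id
                if net in z_networks:
                    mz[roi.label] = roi_mean_zstat(zmaps[net], roi)
                    frac[roi.label] = roi_in_network(zmaps[net], roi,
                                                     params["z_thresh"])
            mean_z[m][sid] = mz
            in_net[m][sid] = frac
        del vol, run, zmaps
    return CohortAnalysis(subject_ids=list(sids), truth=truth,
                          component_set=cs, component_of=component_of,
                          roi_sets=roi_sets, conn=conn, mean_z=mean_z,
                          in_network=in_net, center_error_mm=center_err)


def _center_errors(roi_set, truth, sid, affine):
    from .core import voxel_to_mm
    out = {}
    for roi in roi_set:
        planted = np.asarray(truth.centers[sid][roi.label])
        placed = voxel_to_mm(affine, roi.center_voxel)
        out[roi.label] = float(np.linalg.norm(placed - planted))
    return out


def planted_partition(templates, between_corr=0.1, coupling=None,
                      r_thresh=0.35):
    """Module structure implied by the planted correlations.

    Networks whose planted coupling exceeds the graph threshold merge into
    one module (connected components of the thresholded target matrix).
    """
    from .connectivity import ConnMatrix
    labels, target = synthetic.target_correlation(templates, between_corr,
                                                  coupling)
    g = binarize(ConnMatrix(labels=labels, values=target), r_thresh)
    comps = list(nx.connected_components(g.to_networkx()))
    return [set(c) for c in comps]


def partition_agreement(partition_a, partition_b, labels) -> float:
    """Adjusted Rand index between two partitions over the same labels."""
    def assign(part):
        lookup = {lab: i for i, p in enumerate(part) for lab in p}
        return [lookup[lab] for lab in labels]
    return float(adjusted_rand_score(assign(partition_a), assign(partition_b)))


def _within_summary(conn_list, networks):
    """Per-subject mean within-network connectivity, averaged over networks."""
    vals = []
    for cm in conn_list:
        vals.append(float(np.mean([mean_within_network(cm, net)
                                   for net in networks])))
    return np.asarray(vals)


def run_roi_method_study(seed: int, n_subjects: int = 20,
                         params=STUDY_PARAMS):
    """The ROI-selection comparison on one jittered synthetic cohort.

    Returns ``(summary, objects)``: plain-number summary plus the heavier
    intermediate objects (truth, analyses, connectivity matrices).
    """
    seeds = derive_seeds(seed)
    templates = default_templates()
    cfg = CohortConfig(n_subjects=n_subjects, seed=seeds[0])
    nodes = battery_nodes(templates, search_radius_mm=params["search_radius_mm"])
    mask = ellipsoid_mask(cfg.grid_shape, cfg.voxel_mm)
    truth = synthetic.plan_cohort(templates, cfg)
    ana = analyze_cohort(synthetic.iter_cohort(templates, cfg, truth), truth,
                         mask, templates, nodes, ica_seed=seeds[1],
                         params=params)
    networks = [t.network_id for t in templates]

    within = {m: _within_summary(ana.conn[m], networks)
              for m in ana.conn}
    t_grp, p_grp = compare_methods_paired(within["subject_specific"],
                                          within["group"])
    t_lit, p_lit = compare_methods_paired(within["subject_specific"],
                                          within["literature"])

    zconn = {}
    for m in ana.conn:
        zs = [ana.mean_z[m][sid] for sid in ana.subject_ids]
        _, r = zstat_connectivity_relation(zs, ana.conn[m], scope="network")
        zconn[m] = r
    mean_z_overall = {
        m: float(np.mean([z for sid in ana.subject_ids
                          for z in ana.mean_z[m][sid].values()]))
        for m in ana.mean_z}
    in_net_frac = {
        m: float(np.mean([f >= 0.5 for sid in ana.subject_ids
                          for f in ana.in_network[m][sid].values()]))
        for m in ana.in_network}
    errs = [e for sid in ana.subject_ids
            for e in ana.center_error_mm[sid].values()]

    summary = {
        "n_subjects": n_subjects,
        "networks": networks,
        "mean_within": {m: float(v.mean()) for m, v in within.items()},
        "var_within": {m: float(v.var(ddof=1)) for m, v in within.items()},
        "per_subject_within": {m: v.tolist() for m, v in within.items()},
        "paired_t": {"ss_vs_group": (t_grp, p_grp),
                     "ss_vs_literature": (t_lit, p_lit)},
        "zconn_r": zconn,
        "mean_roi_z": mean_z_overall,
        "in_network_fraction": in_net_frac,
        "median_center_error_mm": float(np.median(errs)),
        "seeds": seeds,
    }
    objects = {"analysis": ana, "templates": templates, "config": cfg,
               "mask": mask, "nodes": nodes}
    return summary, objects


def run_aging_study(seed: int, young=None, n_subjects: int = 20,
                    params=STUDY_PARAMS):
    """Reorganization-only "aging" contrast between two cohorts.

    The aged cohort keeps every coupling but moves nodes more (jitter SD
    6 -> 10 mm).  Edgewise unpaired t tests (Bonferroni alpha/m over all
    m = C(30,2) = 435 pairs) compare the cohorts under the young cohort's
    standardized group ROIs and under subject-specific ROIs; Louvain
    partitions of the subject-specific group graphs are scored against the
    planted module structure.
    """
    if young is None:
        young = run_roi_method_study(seed, n_subjects=n_subjects,
                                     params=params)
    young_summary, young_obj = young
    seeds = young_summary["seeds"]
    templates = young_obj["templates"]
    nodes = young_obj["nodes"]
    mask = young_obj["mask"]
    young_ana = young_obj["analysis"]
    young_group_rois = next(iter(young_ana.roi_sets["group"].values()))

    cfg_old = synthetic.aged_config(
        templates, CohortConfig(n_subjects=n_subjects, seed=seeds[2]),
        coupling_delta=0.0, extra_jitter_mm=params["extra_jitter_mm"])
    truth_old = synthetic.plan_cohort(templates, cfg_old)
    truth_old.aging = {"coupling_delta": 0.0,
                       "extra_jitter_mm": params["extra_jitter_mm"],
                       "jitter_sd_mm": cfg_old.jitter_sd_mm}
    old_ana = analyze_cohort(
        synthetic.iter_cohort(templates, cfg_old, truth_old), truth_old,
        mask, templates, nodes, ica_seed=seeds[3],
        methods=("group", "subject_specific"),
        external_group_rois=young_group_rois, params=params)

    ec_group = compare_groups_edgewise(young_ana.conn["group"],
                                       old_ana.conn["group"],
                                       alpha=params["alpha"])
    ec_ss = compare_groups_edgewise(young_ana.conn["subject_specific"],
                                    old_ana.conn["subject_specific"],
                                    alpha=params["alpha"])

    planted = planted_partition(templates, r_thresh=params["r_thresh"])
    labels = young_ana.conn["subject_specific"][0].labels
    graphs, parts, metrics = {}, {}, {}
    for name, conns in (("young_ss", young_ana.conn["subject_specific"]),
                        ("old_ss", old_ana.conn["subject_specific"]),
                        ("young_group", young_ana.conn["group"]),
                        ("old_group", old_ana.conn["group"])):
        g = group_graph(conns, r_thresh=params["r_thresh"])
        graphs[name] = g
        metrics[name] = graph_metrics(g, seed=seeds[4])
        parts[name] = metrics[name].partition

    summary = {
        "family_size": ec_group.m,
        "n_sig_within_decrease": {
            "group": count_significant_edges(ec_group, within_network=True,
                                             direction="decrease",
                                             corrected=True),
            "subject_specific": count_significant_edges(
                ec_ss, within_network=True, direction="decrease",
                corrected=True),
        },
        "n_sig_within_decrease_uncorrected": {
            "group": count_significant_edges(ec_group, within_network=True,
                                             direction="decrease",
                                             corrected=False),
            "subject_specific": count_significant_edges(
                ec_ss, within_network=True, direction="decrease",
                corrected=False),
        },
        "partition_ari": {name: partition_agreement(parts[name], planted,
                                                    labels)
                          for name in parts},
        "n_modules": {name: len(parts[name]) for name in parts},
        "modularity_q": {name: metrics[name].modularity_q for name in metrics},
        "aged_jitter_sd_mm": truth_old.aging["jitter_sd_mm"],
    }
    objects = {"edgewise": {"group": ec_group, "subject_specific": ec_ss},
               "graphs": graphs, "metrics": metrics, "planted": planted,
               "old_analysis": old_ana, "old_truth": truth_old}
    return summary, objects


def null_calibration(seed: int, n_networks: int = 9, nodes_per_network: int = 5,
                     n_per_group: int = 20, n_timepoints: int = 100,
                     alpha: float = 0.05):
    """Edgewise false-positive calibration on same-generator groups.

    Two groups are drawn from one node-level generator (45 nodes -> 990
    pairs); the fraction of uncorrected significant pairs estimates the
    nominal alpha.
    """
    seeds = derive_seeds(seed, n=4)
    sizes = {f"NET{i + 1}": nodes_per_network for i in range(n_networks)}
    templates = synthetic.build_battery(
        sizes, grid_shape=(101, 101, 101), voxel_mm=2.0, spacing_mm=20.0,
        margin_mm=20.0, within_corr=0.3)
    groups = []
    for s in seeds[:2]:
        cfg = CohortConfig(n_subjects=n_per_group, grid_shape=(101, 101, 101),
                           n_timepoints=n_timepoints, between_corr=0.0,
                           coupling={}, jitter_sd_mm=0.0, seed=s)
        labels, series = synthetic.node_level_cohort(templates, cfg,
                                                     node_noise_sd=1.0)
        cms = [conn_matrix({lab: x[:, k] for k, lab in enumerate(labels)},
                           subject_id=f"sub-{i + 1:02d}")
               for i, x in enumerate(series)]
        groups.append(cms)
    ec = compare_groups_edgewise(groups[0], groups[1], alpha=alpha)
    rate = float(ec.table["sig_uncorrected"].mean())
    return {"uncorrected_rate": rate, "alpha": alpha, "m": ec.m,
            "n_per_group": n_per_group}, ec
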