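"""Stage-per-subcommand pipeline over a directory layout.

Stages: ``simulate -> preprocess -> ica -> rois -> connectivity -> graph ->
compare``.  Every stage writes a manifest recording the resolved
configuration hash and seeds, and every output is reproducible from config
plus seeds alone — rerunning an unchanged configuration rewrites identical
files.  Cohorts live in groups (``young``/``old``) under the cohort
directory; each downstream stage mirrors that grouping.
"""
from __future__ import annotations

from pathlib import Path

from . import __version__, io, synthetic
from .config import PipelineConfig
from .connectivity import conn_matrix, extract_roiset_series
from .core import PipelineError, RoiSet
from .graphstats import (compare_groups_edgewise, count_significant_edges,
                         graph_metrics, group_graph)
from .ica import concat_and_reduce, group_roi_set, match_components
from .mapping import (glm_zmap, literature_roi_set, subject_network_timecourse,
                      subject_roi_set)
from .preprocess import framewise_displacement, preprocess_run
from .synthetic import (CohortConfig, battery_nodes, default_templates,
                        ellipsoid_mask, template_network_maps)

STAGES = ("simulate", "preprocess", "ica", "rois", "connectivity", "graph",
          "compare")
METHODS = ("literature", "group", "subject_specific")


def _manifest(config: PipelineConfig, stage: str, extra=None) -> dict:
    doc = {"stage": stage, "config_hash": config.hash(),
           "config": config.to_dict(), "version": __version__,
           "seeds": {"synthetic": config.seed_synthetic,
                     "ica": config.seed_ica,
                     "louvain": config.seed_louvain}}
    if extra:
        doc.update(extra)
    return doc


def _groups(config: PipelineConfig):
    return ["young", "old"] if config.aging else ["young"]


def _require(path: Path, stage_needed: str):
    if not path.exists():
        raise PipelineError(
            f"missing upstream artifact {path}; run the "
            f"'{stage_needed}' stage first")
    return path


def _templates(config: PipelineConfig):
    syn = dict(config.synthetic)
    grid = tuple(syn.get("grid_shape", CohortConfig.grid_shape))
    voxel = float(syn.get("voxel_mm", CohortConfig.voxel_mm))
    tpl = default_templates(grid_shape=grid, voxel_mm=voxel)
    return tpl, grid, voxel


def stage_simulate(config: PipelineConfig) -> dict:
    templates, grid, voxel = _templates(config)
    cohort = Path(config.cohort_dir)
    syn = dict(config.synthetic)
    syn.setdefault("seed", config.seed_synthetic)
    syn["grid_shape"] = grid
    syn["voxel_mm"] = voxel
    mask = ellipsoid_mask(grid, voxel)
    written = []
    for group in _groups(config):
        gdir = cohort / group
        gdir.mkdir(parents=True, exist_ok=True)
        if group == "young":
            cfg = CohortConfig(**syn)
            truth = synthetic.plan_cohort(templates, cfg)
        else:
            aged = dict(syn)
            aged["seed"] = int(config.aging.get("seed", syn["seed"] + 1))
            delta = float(config.aging.get("coupling_delta", 0.0))
            extra = float(config.aging.get("extra_jitter_mm", 0.0))
            cfg = synthetic.aged_config(templates, CohortConfig(**aged),
                                        coupling_delta=delta,
                                        extra_jitter_mm=extra)
            truth = synthetic.plan_cohort(templates, cfg)
            truth.aging = {"coupling_delta": delta, "extra_jitter_mm": extra,
                           "jitter_sd_mm": cfg.jitter_sd_mm}
        for run in synthetic.iter_cohort(templates, cfg, truth):
            p = gdir / f"{run.subject_id}_bold.nii.gz"
            io.write_bold(run, p)
            written.append(str(p))
        (gdir / "truth.json").write_text(synthetic.truth_to_json(truth))
        io.write_mask(mask, cfg.affine, gdir / "mask.nii.gz")
    nodes = battery_nodes(templates,
                          search_radius_mm=config.search_radius_mm)
    io.write_node_table(nodes, cohort / "nodes.csv")
    man = _manifest(config, "simulate", {"outputs": written})
    io.write_json(man, cohort / "manifest_simulate.json")
    return man


def _load_group_runs(gdir: Path, stage_needed: str):
    paths = sorted(gdir.glob("*_bold.nii.gz")) + sorted(gdir.glob("*_bold.nii"))
    if not paths:
        raise PipelineError(
            f"no BOLD runs under {gdir}; run the '{stage_needed}' stage first")
    return [io.read_bold(p) for p in paths]


def stage_preprocess(config: PipelineConfig) -> dict:
    cohort = Path(config.cohort_dir)
    out = Path(config.output_dir) / "preproc"
    written = []
    for group in _groups(config):
        gdir = cohort / group
        mask = io.read_mask(_require(gdir / "mask.nii.gz", "simulate"))
        odir = out / group
        odir.mkdir(parents=True, exist_ok=True)
        fd = {}
        for run in _load_group_runs(gdir, "simulate"):
            pre = preprocess_run(run, mask, hp_sigma_s=config.hp_sigma_s,
                                 fwhm_mm=config.fwhm_mm)
            p = odir / f"{run.subject_id}_bold.nii.gz"
            io.write_bold(pre, p)
            written.append(str(p))
            mp_path = gdir / f"{run.subject_id}_motion.txt"
            if mp_path.exists():
                mp = io.read_motion_params(mp_path)
                fd[run.subject_id] = framewise_displacement(
                    mp, config.head_radius_mm).tolist()
        if fd:
            io.write_json(fd, odir / "fd.json")
    man = _manifest(config, "preprocess", {"outputs": written})
    io.write_json(man, out / "manifest_preprocess.json")
    return man


def stage_ica(config: PipelineConfig) -> dict:
    cohort = Path(config.cohort_dir)
    pre = Path(config.output_dir) / "preproc"
    out = Path(config.output_dir) / "ica"
    templates, grid, voxel = _templates(config)
    for group in _groups(config):
        mask = io.read_mask(_require(cohort / group / "mask.nii.gz",
                                     "simulate"))
        runs = _load_group_runs(_require(pre / group, "preprocess"),
                                "preprocess")
        cs = concat_and_reduce(runs, mask, config.n_components,
                               seed=config.seed_ica)
        odir = out / group
        odir.mkdir(parents=True, exist_ok=True)
        io.write_component_set(cs, odir / "maps.nii.gz",
                               odir / "mixing.csv", odir / "segments.csv")
        tmaps = template_network_maps(templates, grid, voxel)
        comp_of = match_components(cs, tmaps, floor=config.match_floor)
        io.write_json(comp_of, odir / "matched_components.json")
    man = _manifest(config, "ica")
    io.write_json(man, out / "manifest_ica.json")
    return man


def _load_ica(config: PipelineConfig, group: str):
    cohort = Path(config.cohort_dir)
    idir = Path(config.output_dir) / "ica" / group
    mask = io.read_mask(_require(cohort / group / "mask.nii.gz", "simulate"))
    cs = io.read_component_set(_require(idir / "maps.nii.gz", "ica"),
                               idir / "mixing.csv", idir / "segments.csv",
                               mask)
    comp_of = {k: int(v)
               for k, v in io.read_json(idir / "matched_components.json").items()}
    return cs, comp_of, mask


def stage_rois(config: PipelineConfig, methods=METHODS) -> dict:
    cohort = Path(config.cohort_dir)
    pre = Path(config.output_dir) / "preproc"
    out = Path(config.output_dir) / "rois"
    out.mkdir(parents=True, exist_ok=True)
    nodes = io.read_node_table(_require(cohort / "nodes.csv", "simulate"))
    if config.node_table:
        lit_nodes = io.read_node_table(config.node_table)
    else:
        lit_nodes = nodes
    for group in _groups(config):
        cs, comp_of, mask = _load_ica(config, group)
        runs = _load_group_runs(_require(pre / group, "preprocess"),
                                "preprocess")
        sets = []
        if "literature" in methods:
            coords = {n.label: n.center_mm for n in lit_nodes}
            lit = literature_roi_set(coords, nodes, mask, cs.affine,
                                     edge_mm=config.edge_mm)
            sets.extend(RoiSet(r.subject_id, "literature", lit.rois)
                        for r in runs)
        if "group" in methods:
            grp = group_roi_set(cs, nodes, comp_of, edge_mm=config.edge_mm)
            sets.extend(RoiSet(r.subject_id, "group", grp.rois) for r in runs)
        z_rows = []
        if "subject_specific" in methods:
            from .mapping import roi_mean_zstat
            for run in runs:
                zmaps = {net: glm_zmap(run, subject_network_timecourse(
                    cs, comp, run.subject_id), mask, network_id=net)
                    for net, comp in comp_of.items()}
                ss = subject_roi_set(zmaps, nodes, mask,
                                     edge_mm=config.edge_mm)
                sets.append(ss)
                # provenance: every ROI's mean z on the subject's own map
                for rs in sets:
                    if rs.subject_id != run.subject_id:
                        continue
                    for roi in rs:
                        z_rows.append({
                            "subject_id": run.subject_id,
                            "method": rs.method, "node": roi.label,
                            "mean_z": roi_mean_zstat(
                                zmaps[roi.node.network_id], roi)})
        io.write_roi_sets(sets, cs.affine, out / f"rois_{group}.csv")
        if z_rows:
            import pandas as pd
            pd.DataFrame(z_rows).to_csv(out / f"roi_zstats_{group}.csv",
                                        index=False)
    man = _manifest(config, "rois", {"methods": list(methods)})
    io.write_json(man, out / "manifest_rois.json")
    return man


def stage_connectivity(config: PipelineConfig) -> dict:
    pre = Path(config.output_dir) / "preproc"
    rdir = Path(config.output_dir) / "rois"
    out = Path(config.output_dir) / "conn"
    for group in _groups(config):
        cs, comp_of, mask = _load_ica(config, group)
        roi_sets = io.read_roi_sets(_require(rdir / f"rois_{group}.csv",
                                             "rois"), mask, cs.affine)
        runs = {r.subject_id: r
                for r in _load_group_runs(_require(pre / group, "preprocess"),
                                          "preprocess")}
        manifest_rows = []
        for rs in roi_sets:
            run = runs[rs.subject_id]
            series = extract_roiset_series(run, rs)
            cm = conn_matrix(series, subject_id=rs.subject_id,
                             method=rs.method)
            odir = out / group / rs.method
            odir.mkdir(parents=True, exist_ok=True)
            p = odir / f"{rs.subject_id}.csv"
            io.write_conn_matrix(cm, p)
            manifest_rows.append({"subject_id": rs.subject_id,
                                  "method": rs.method, "path": str(p)})
        io.write_json(manifest_rows, out / group / "manifest.json")
    man = _manifest(config, "connectivity")
    io.write_json(man, out / "manifest_connectivity.json")
    return man


def _load_conns(config: PipelineConfig, group: str, method: str):
    out = Path(config.output_dir) / "conn" / group / method
    _require(out, "connectivity")
    return [io.read_conn_matrix(p, subject_id=p.stem, method=method)
            for p in sorted(out.glob("*.csv"))]


def stage_graph(config: PipelineConfig) -> dict:
    out = Path(config.output_dir) / "graph"
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    for group in _groups(config):
        for method in METHODS:
            cdir = Path(config.output_dir) / "conn" / group / method
            if not cdir.exists():
                continue
            cms = _load_conns(config, group, method)
            g = group_graph(cms, r_thresh=config.r_thresh,
                            fisher=config.fisher_z)
            gm = graph_metrics(g, seed=config.seed_louvain)
            io.write_pajek(g, out / f"{group}_{method}.net")
            io.write_edge_list(g, out / f"{group}_{method}_edges.csv")
            results[f"{group}/{method}"] = {
                "n_edges": g.n_edges,
                "clustering_mean": gm.clustering_mean,
                "modularity_q": gm.modularity_q,
                "n_modules": len(gm.partition),
                "assortativity": gm.assortativity,
                "global_efficiency": gm.global_efficiency,
                "partition": [sorted(p) for p in gm.partition],
            }
    io.write_json(results, out / "metrics.json")
    man = _manifest(config, "graph")
    io.write_json(man, out / "manifest_graph.json")
    return man


def stage_compare(config: PipelineConfig) -> dict:
    if not config.aging:
        raise PipelineError(
            "the 'compare' stage needs two groups; enable the aging block "
            "in the config and rerun from 'simulate'")
    out = Path(config.output_dir) / "compare"
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for method in METHODS:
        young_dir = Path(config.output_dir) / "conn" / "young" / method
        old_dir = Path(config.output_dir) / "conn" / "old" / method
        if not (young_dir.exists() and old_dir.exists()):
            continue
        ec = compare_groups_edgewise(_load_conns(config, "young", method),
                                     _load_conns(config, "old", method),
                                     alpha=config.alpha)
        ec.table.to_csv(out / f"edgewise_{method}.csv", index=False)
        summary[method] = {
            "family_size": ec.m,
            "n_sig_uncorrected": int(ec.table["sig_uncorrected"].sum()),
            "n_sig_bonferroni": int(ec.table["sig_bonferroni"].sum()),
            "n_within_decrease_bonferroni": count_significant_edges(
                ec, within_network=True, direction="decrease"),
        }
    if not summary:
        raise PipelineError("no connectivity matrices found; run "
                            "'connectivity' first")
    io.write_json(summary, out / "summary.json")
    man = _manifest(config, "compare")
    io.write_json(man, out / "manifest_compare.json")
    return man


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "ica": stage_ica,
    "rois": stage_rois,
    "connectivity": stage_connectivity,
    "graph": stage_graph,
    "compare": stage_compare,
}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in order; returns {stage: manifest}."""
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    manifests = {}
    for stage in STAGES:
        if stage in stages:
            manifests[stage] = _STAGE_FUNCS[stage](config)
    return manifests
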