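"""End-to-end orchestration: simulate -> preprocess -> CTPA -> networks ->
metrics -> inference -> report, with per-stage checkpoints, an append-only
manifest, and reproducible seed derivation from a single master seed."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ctpa, inference, metrics, networks, preprocess
from .config import STAGES, PipelineConfig
from .synthetic import SyntheticSceneConfig, generate_cohort

logger = logging.getLogger(__name__)

CONDITIONS = ("ctp", "rtp", "creative", "control")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def subject_seed(master_seed: int, subject: int, stage: str) -> int:
    """Deterministic per-subject, per-stage seed below 2**31."""
    h = np.random.SeedSequence((master_seed, subject, STAGES.index(stage)))
    return int(h.generate_state(1)[0] % (2 ** 31))


class Manifest:
    """Append-only record of every artifact a stage produces."""

    def __init__(self, path: Path):
        self.path = Path(path)

    def record(self, file: Path, stage: str, **params) -> None:
        entry = {"file": str(Path(file).name), "stage": stage,
                 "params": _jsonable(params)}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    def entries(self) -> list:
        if not self.path.exists():
            return []
        return [json.loads(line) for line in self.path.read_text().splitlines()
                if line.strip()]


def _scene_from_config(config: PipelineConfig) -> SyntheticSceneConfig:
    scene = SyntheticSceneConfig(**config.scene)
    return replace(scene, n_discard_rest=config.n_discard_rest,
                   n_discard_task=config.n_discard_task)


def _grid_from_config(config: PipelineConfig) -> metrics.SparsityGrid:
    n = len(config.sparsity_levels)
    return metrics.SparsityGrid(delta_s=config.sparsity_step, k_max=n)


# ---------------------------------------------------------------- stages

def stage_simulate(config: PipelineConfig, run_dir: Path, state: dict,
                   manifest: Manifest) -> None:
    scene = _scene_from_config(config)
    datasets, covs = generate_cohort(config.n_subjects, scene,
                                     seed=config.master_seed)
    d = run_dir / "simulate"
    d.mkdir(exist_ok=True)
    covs.to_csv(d / "covariates.tsv", sep="\t", index=False)
    manifest.record(d / "covariates.tsv", "simulate", seed=config.master_seed)
    for i, ds in enumerate(datasets):
        sid = ds.covariates["subject_id"]
        ds.motion_table.to_csv(d / f"{sid}_rest_motion.tsv", sep="\t", index=False)
        (d / f"{sid}_ground_truth.json").write_text(ds.ground_truth_json())
        if ds.task is not None:
            ds.task.events.to_csv(d / f"{sid}_task_events.tsv", sep="\t",
                                  index=False)
        if config.write_volumes:
            ds.bold.save(d / f"{sid}_rest.nii.gz")
            if ds.task is not None:
                ds.task.bold.save(d / f"{sid}_task.nii.gz")
    ds0 = datasets[0]
    ds0.roi_mask.save(d / "roi_mask.nii.gz")
    ds0.brain_mask.save(d / "brain_mask.nii.gz")
    manifest.record(d / "roi_mask.nii.gz", "simulate")
    state["datasets"] = datasets
    state["covariates"] = covs


def stage_preprocess(config: PipelineConfig, run_dir: Path, state: dict,
                     manifest: Manifest) -> None:
    d = run_dir / "preprocess"
    d.mkdir(exist_ok=True)
    rows = []
    rest_pre, task_pre, motion_ok = [], [], []
    for i, ds in enumerate(state["datasets"]):
        sid = ds.covariates.get("subject_id", f"sub-{i + 1:02d}")
        qc = preprocess.motion_qc(ds.motion_table, config.motion_threshold_mm,
                                  config.motion_threshold_deg)
        motion_ok.append(not qc.excluded)
        run = preprocess.discard_initial_volumes(ds.bold, config.n_discard_rest)
        run = preprocess.smooth_run(run, config.smooth_fwhm_mm)
        regs = qc.friston24[config.n_discard_rest:]
        if config.filter_before_regression:
            run = preprocess.detrend_bandpass(run, config.bandpass_low_hz,
                                              config.bandpass_high_hz)
        wm = preprocess.extract_mask_mean(run, ds.wm_mask)
        csf = preprocess.extract_mask_mean(run, ds.csf_mask)
        run = preprocess.nuisance_regress(run, np.column_stack([regs, wm, csf]))
        if not config.filter_before_regression:
            run = preprocess.detrend_bandpass(run, config.bandpass_low_hz,
                                              config.bandpass_high_hz)
        rest_pre.append(run)
        task_run = None
        if ds.task is not None:
            task_run = preprocess.discard_initial_volumes(ds.task.bold,
                                                          config.n_discard_task)
            task_run = preprocess.smooth_run(task_run, config.smooth_fwhm_mm)
        task_pre.append(task_run)
        rows.append({"subject_id": sid, "motion_excluded": qc.excluded,
                     "max_trans_mm": qc.max_abs_translation_mm.max(),
                     "max_rot_deg": qc.max_abs_rotation_deg.max(),
                     "n_volumes_rest": run.n_volumes})
        logger.info("preprocess %s: motion_excluded=%s, %d retained volumes",
                    sid, qc.excluded, run.n_volumes)
    qc_table = pd.DataFrame(rows)
    qc_table.to_csv(d / "motion_qc.tsv", sep="\t", index=False)
    manifest.record(d / "motion_qc.tsv", "preprocess")
    state["rest_pre"] = rest_pre
    state["task_pre"] = task_pre
    state["motion_ok"] = motion_ok


def stage_ctpa(config: PipelineConfig, run_dir: Path, state: dict,
               manifest: Manifest) -> None:
    d = run_dir / "ctpa"
    d.mkdir(exist_ok=True)
    classifications, contrasts, usable = [], [], []
    datasets = state["datasets"]
    for i, run in enumerate(state["rest_pre"]):
        ds = datasets[i]
        sid = ds.covariates.get("subject_id", f"sub-{i + 1:02d}")
        sampled = ctpa.select_sampled_timepoints(run.n_volumes, config.stride)
        z = ctpa.zscore_roi(run, ds.roi_mask, sampled, mode=config.zscore_mode)
        cls = ctpa.classify_timepoints(z, config.frac_threshold,
                                       config.overlap_threshold,
                                       config.z_threshold)
        classifications.append(cls)
        table = pd.DataFrame({
            "sampled_index": cls.sampled_indices,
            "supra_count": cls.counts,
            "label": ["CTP" if s in set(cls.ctp_indices) else "RTP"
                      for s in cls.sampled_indices]})
        table.to_csv(d / f"{sid}_timepoints.tsv", sep="\t", index=False)
        record = {"subject_id": sid, "ctp_indices": cls.ctp_indices,
                  "rtp_indices": cls.rtp_indices, "n_ctp": cls.n_ctp,
                  "top2_failed": cls.top2_failed,
                  "roi_n_voxels": cls.roi_n_voxels}
        (d / f"{sid}_classification.json").write_text(
            json.dumps(_jsonable(record), indent=2))
        manifest.record(d / f"{sid}_timepoints.tsv", "ctpa",
                        stride=config.stride, z=config.z_threshold)
        try:
            contrasts.append(ctpa.subject_contrast_map(run, cls).t_map)
            usable.append(state["motion_ok"][i])
        except ctpa.SubjectExcludedError as exc:
            contrasts.append(None)
            usable.append(False)
            logger.warning("subject %s excluded from group map: %s", sid, exc)
    group_input = [c for c, ok in zip(contrasts, usable) if c is not None and ok]
    if len(group_input) >= 2:
        gmap = ctpa.group_ctp_map(group_input, datasets[0].brain_mask,
                                  q=config.fdr_q,
                                  cluster_min=config.cluster_min_voxels,
                                  connectivity=config.cluster_connectivity)
        np.save(d / "group_t_map.npy", gmap.stat_volume)
        cluster_rows = [{"cluster": k + 1, "n_voxels": len(c[0]),
                         "peak_x": c[1][0], "peak_y": c[1][1], "peak_z": c[1][2],
                         "peak_t": c[2]}
                        for k, c in enumerate(gmap.surviving_clusters)]
        pd.DataFrame(cluster_rows, columns=["cluster", "n_voxels", "peak_x",
                                            "peak_y", "peak_z", "peak_t"]) \
            .to_csv(d / "group_clusters.tsv", sep="\t", index=False)
        manifest.record(d / "group_clusters.tsv", "ctpa", q=config.fdr_q,
                        cluster_min=config.cluster_min_voxels)
        state["group_map"] = gmap
    state["classifications"] = classifications
    state["subject_usable"] = usable


def stage_netbuild(config: PipelineConfig, run_dir: Path, state: dict,
                   manifest: Manifest) -> None:
    d = run_dir / "networks"
    d.mkdir(exist_ok=True)
    datasets = state["datasets"]
    parc = networks.build_cube_parcellation(datasets[0].brain_mask,
                                            config.cube_edge,
                                            datasets[0].parcellation)
    state["parcellation"] = parc
    nets_per_subject = []
    for i, (run, cls) in enumerate(zip(state["rest_pre"],
                                       state["classifications"])):
        ds = datasets[i]
        sid = ds.covariates.get("subject_id", f"sub-{i + 1:02d}")
        subj_nets = {}
        if cls.n_ctp >= 1 and len(cls.rtp_indices) >= 1:
            ctp_nets = [networks.cube_similarity_network(run.data[..., e - 1],
                                                         parc, "ctp", int(e))
                        for e in cls.ctp_indices]
            rtp_nets = [networks.cube_similarity_network(run.data[..., e - 1],
                                                         parc, "rtp", int(e))
                        for e in cls.rtp_indices]
            subj_nets["ctp"] = networks.average_condition_network(ctp_nets, "ctp")
            subj_nets["rtp"] = networks.average_condition_network(rtp_nets, "rtp")
        if state["task_pre"][i] is not None:
            betas = networks.glm_beta_series(state["task_pre"][i],
                                             ds.task.events,
                                             drift_cutoff_s=config.task_highpass_s)
            creative, control = networks.task_condition_network(betas, parc)
            subj_nets["creative"] = creative
            subj_nets["control"] = control
        for cond, net in subj_nets.items():
            net.edge_list().to_csv(d / f"{sid}_{cond}_edges.tsv", sep="\t",
                                   index=False)
        nets_per_subject.append(subj_nets)
        logger.info("netbuild %s: %d cubes, conditions %s", sid, parc.n_cubes,
                    sorted(subj_nets))
    manifest.record(d, "netbuild", n_cubes=parc.n_cubes,
                    cube_edge=config.cube_edge)
    state["networks"] = nets_per_subject


def stage_metrics(config: PipelineConfig, run_dir: Path, state: dict,
                  manifest: Manifest) -> None:
    d = run_dir / "metrics"
    d.mkdir(exist_ok=True)
    grid = _grid_from_config(config)
    datasets = state["datasets"]
    global_rows, nodal_frames = [], {c: [] for c in CONDITIONS}
    profiles = []
    for i, subj_nets in enumerate(state["networks"]):
        sid = datasets[i].covariates.get("subject_id", f"sub-{i + 1:02d}")
        subj_prof = {}
        for cond, net in subj_nets.items():
            prof = metrics.metric_profile(net, grid, compute_small_world=False)
            subj_prof[cond] = prof
            for k, s in enumerate(grid.levels):
                global_rows.append({"subject_id": sid, "condition": cond,
                                    "sparsity": s, "e_glob": prof.e_glob[k],
                                    "e_loc": prof.e_loc[k]})
            global_rows.append({"subject_id": sid, "condition": cond,
                                "sparsity": "integrated",
                                "e_glob": prof.integrated_e_glob,
                                "e_loc": prof.integrated_e_loc})
            row_g = {"subject_id": sid}
            row_l = {"subject_id": sid}
            for node, vg, vl in zip(prof.node_ids,
                                    prof.integrated_e_glob_nodal,
                                    prof.integrated_e_loc_nodal):
                row_g[f"node_{node}"] = vg
                row_l[f"node_{node}"] = vl
            nodal_frames[cond].append({"e_glob_nodal": row_g,
                                       "e_loc_nodal": row_l})
        profiles.append(subj_prof)
    pd.DataFrame(global_rows).to_csv(d / "global_metrics.tsv", sep="\t",
                                     index=False)
    manifest.record(d / "global_metrics.tsv", "metrics",
                    levels=config.sparsity_levels)
    for cond in CONDITIONS:
        for which in ("e_glob_nodal", "e_loc_nodal"):
            rows = [fr[which] for fr in nodal_frames[cond]]
            if rows:
                pd.DataFrame(rows).to_csv(
                    d / f"integrated_{which}_{cond}.tsv", sep="\t", index=False)
    # small-world verdicts on the cohort-mean network per condition
    sw_rows = []
    group_profiles = {}
    for cond in CONDITIONS:
        member = [sn[cond] for sn in state["networks"] if cond in sn]
        if not member:
            continue
        mean_net = networks.average_condition_network(member, cond)
        prof = metrics.metric_profile(
            mean_net, grid, n_null=config.n_null,
            seed=subject_seed(config.master_seed, 10000 + CONDITIONS.index(cond),
                              "metrics"),
            compute_small_world=True)
        group_profiles[cond] = prof
        for k, s in enumerate(grid.levels):
            r = prof.small_world[k]
            sw_rows.append({"condition": cond, "sparsity": s, "gamma": r.gamma,
                            "lambda": r.lam, "sigma": r.sigma,
                            "small_world": r.is_small_world})
    pd.DataFrame(sw_rows).to_csv(d / "small_world.tsv", sep="\t", index=False)
    manifest.record(d / "small_world.tsv", "metrics", n_null=config.n_null)
    state["profiles"] = profiles
    state["group_profiles"] = group_profiles


def _metric_vector(profiles: list, usable: list, cond: str, attr: str
                   ) -> tuple[np.ndarray, list]:
    vals, idx = [], []
    for i, subj in enumerate(profiles):
        if usable[i] and cond in subj:
            vals.append(getattr(subj[cond], attr))
            idx.append(i)
    return np.array(vals), idx


def stage_infer(config: PipelineConfig, run_dir: Path, state: dict,
                manifest: Manifest) -> None:
    d = run_dir / "inference"
    d.mkdir(exist_ok=True)
    profiles = state["profiles"]
    usable = state.get("subject_usable", [True] * len(profiles))
    covs = state["covariates"]
    report: dict = {"permutation_tests": [], "regressions": [],
                    "n_perm": config.n_perm, "alpha": config.alpha}
    # --- permutation tests on integrated global metrics
    for pi, pair in enumerate((("ctp", "rtp"), ("creative", "control"))):
        for ai, attr in enumerate(("integrated_e_glob", "integrated_e_loc")):
            x_a, idx_a = _metric_vector(profiles, usable, pair[0], attr)
            x_b, idx_b = _metric_vector(profiles, usable, pair[1], attr)
            common = sorted(set(idx_a) & set(idx_b))
            if len(common) < 4:
                logger.warning("skipping %s vs %s on %s: only %d usable subjects",
                               *pair, attr, len(common))
                continue
            a = np.array([getattr(profiles[i][pair[0]], attr) for i in common])
            b = np.array([getattr(profiles[i][pair[1]], attr) for i in common])
            cv = covs.iloc[common][["age", "sex"]].reset_index(drop=True)
            seed = subject_seed(config.master_seed, 2000 + 10 * pi + ai, "infer")
            res = inference.paired_permutation_test(
                a, b, cv, n_perm=config.n_perm, seed=seed, alpha=config.alpha,
                method=config.permutation_method)
            report["permutation_tests"].append({
                "comparison": f"{pair[0]}_vs_{pair[1]}", "metric": attr,
                "observed_diff": res.observed_diff,
                "p_two_tailed": res.p_two_tailed, "reject": res.reject,
                "critical_value": res.critical_value, "n_subjects": len(common),
                "seed": seed})
    # --- screened regression: task global <- rest nodal (CTP), cross-applied
    for attr_dep, attr_pred in (("integrated_e_loc", "integrated_e_loc_nodal"),
                                ("integrated_e_glob", "integrated_e_glob_nodal")):
        entry = {"dependent": f"creative_{attr_dep}", "status": "undefined"}
        y, idx_y = _metric_vector(profiles, usable, "creative", attr_dep)
        common = [i for i in idx_y if "ctp" in profiles[i]]
        if len(common) >= 5:
            y = np.array([getattr(profiles[i]["creative"], attr_dep)
                          for i in common])
            pred = _nodal_table(profiles, common, "ctp", attr_pred)
            retained, screen_table = inference.screen_predictors(
                y, pred, alpha=config.screen_alpha)
            entry["n_candidates"] = int(pred.shape[1])
            entry["screened"] = retained
            max_p = len(common) - 2
            if retained and len(retained) > max_p:
                keep = screen_table.set_index("predictor").loc[retained, "p"] \
                    .sort_values().index[:max_p]
                logger.warning("screen retained %d predictors for n=%d; "
                               "keeping the %d smallest-p", len(retained),
                               len(common), max_p)
                retained = list(keep)
            if retained:
                model = inference.fit_mlra(y, pred[retained],
                                           dependent_name=entry["dependent"],
                                           screen_alpha=config.screen_alpha)
                entry.update(status="fitted",
                             predictors=model.predictors,
                             adjusted_r_squared=model.adjusted_r_squared,
                             r_squared=model.r_squared, model_p=model.model_p,
                             variance_explained=model.per_predictor_variance_explained)
                # cross-application 1: same predictors, control-network dependent
                yc = np.array([getattr(profiles[i]["control"], attr_dep)
                               for i in common if "control" in profiles[i]])
                if len(yc) == len(common):
                    tr = inference.cross_apply_model(
                        model, yc, pred, dependent_name=f"control_{attr_dep}")
                    entry["transfer_to_control"] = {
                        "adjusted_r_squared": tr.adjusted_r_squared,
                        "model_p": tr.model_p, "transfers": tr.transfers}
                # cross-application 2: RTP-network nodal values, creative dependent
                pred_rtp = _nodal_table(profiles, common, "rtp", attr_pred)
                if all(c in pred_rtp.columns for c in model.predictors):
                    tr = inference.cross_apply_model(
                        model, y, pred_rtp, dependent_name=entry["dependent"])
                    entry["transfer_from_rtp"] = {
                        "adjusted_r_squared": tr.adjusted_r_squared,
                        "model_p": tr.model_p, "transfers": tr.transfers}
        report["regressions"].append(entry)
    (d / "inference.json").write_text(json.dumps(_jsonable(report), indent=2))
    manifest.record(d / "inference.json", "infer", n_perm=config.n_perm)
    _write_inference_summary(d / "summary.txt", report)
    state["inference"] = report


def _nodal_table(profiles, subject_idx, cond, attr) -> pd.DataFrame:
    rows = []
    for i in subject_idx:
        prof = profiles[i][cond]
        rows.append({f"node_{n}": v for n, v in zip(prof.node_ids,
                                                    getattr(prof, attr))})
    return pd.DataFrame(rows)


def _write_inference_summary(path: Path, report: dict) -> None:
    lines = ["Inference summary", "=" * 40]
    for t in report["permutation_tests"]:
        lines.append(f"{t['comparison']:24s} {t['metric']:20s} "
                     f"diff={t['observed_diff']:+.4f} p={t['p_two_tailed']:.4f}"
                     f"{' *' if t['reject'] else ''}")
    for r in report["regressions"]:
        lines.append(f"{r['dependent']}: {r['status']}")
        if r["status"] == "fitted":
            lines.append(f"  adj R2={r['adjusted_r_squared']:.3f} "
                         f"p={r['model_p']:.4f} "
                         f"predictors={len(r['predictors'])}")
    Path(path).write_text("\n".join(lines) + "\n")


def stage_report(config: PipelineConfig, run_dir: Path, state: dict,
                 manifest: Manifest) -> None:
    path = run_dir / "report.md"
    lines = ["# Pipeline report", ""]
    ctpa_dir = run_dir / "ctpa"
    n_ctps = []
    for f in sorted(ctpa_dir.glob("*_classification.json")):
        n_ctps.append(json.loads(f.read_text())["n_ctp"])
    if n_ctps:
        lines += ["## Critical time points",
                  f"CTP count across {len(n_ctps)} subjects: "
                  f"{np.mean(n_ctps):.2f} +/- {np.std(n_ctps, ddof=1):.2f}", ""]
    gm = run_dir / "metrics" / "global_metrics.tsv"
    if gm.exists():
        table = pd.read_csv(gm, sep="\t")
        integ = table[table["sparsity"] == "integrated"]
        lines += ["## Integrated global metrics (mean across subjects)", "",
                  "| condition | E_glob | E_loc |", "|---|---|---|"]
        for cond, grp in integ.groupby("condition"):
            lines.append(f"| {cond} | {grp['e_glob'].mean():.4f} | "
                         f"{grp['e_loc'].mean():.4f} |")
        lines.append("")
    sw = run_dir / "metrics" / "small_world.tsv"
    if sw.exists():
        swt = pd.read_csv(sw, sep="\t")
        lines += ["## Small-world verdicts (cohort-mean networks)", "",
                  "| condition | min sigma | small world |", "|---|---|---|"]
        for cond, grp in swt.groupby("condition"):
            lines.append(f"| {cond} | {grp['sigma'].min():.3f} | "
                         f"{bool(grp['small_world'].all())} |")
        lines.append("")
    inf = run_dir / "inference" / "inference.json"
    if inf.exists():
        rep = json.loads(inf.read_text())
        lines.append("## Permutation tests")
        lines += ["", "| comparison | metric | diff | p |", "|---|---|---|---|"]
        for t in rep["permutation_tests"]:
            lines.append(f"| {t['comparison']} | {t['metric']} | "
                         f"{t['observed_diff']:+.4f} | {t['p_two_tailed']:.4f} |")
        lines.append("")
        lines.append("## Regression models")
        for r in rep["regressions"]:
            if r["status"] == "fitted":
                lines.append(f"- {r['dependent']}: adj R2 = "
                             f"{r['adjusted_r_squared']:.3f}, "
                             f"p = {r['model_p']:.4g}, "
                             f"{len(r['predictors'])} predictors")
            else:
                lines.append(f"- {r['dependent']}: no model "
                             f"(screen retained nothing or too few subjects)")
    else:
        lines.append("_Inference stage not run; regression section omitted._")
    path.write_text("\n".join(lines) + "\n")
    manifest.record(path, "report")


STAGE_FUNCS = {"simulate": stage_simulate, "preprocess": stage_preprocess,
               "ctpa": stage_ctpa, "netbuild": stage_netbuild,
               "metrics": stage_metrics, "infer": stage_infer,
               "report": stage_report}

# stages whose outputs the next stages consume from memory
_DEPENDENCIES = {"preprocess": ("simulate",), "ctpa": ("preprocess",),
                 "netbuild": ("ctpa",), "metrics": ("netbuild",),
                 "infer": ("metrics",), "report": ()}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Upstream stages a requested stage depends on are executed automatically
    (deterministically, from the master seed) when they are not in the
    requested set. Reruns with the same config and seed reproduce all
    deterministic artifacts.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_file(run_dir / "config.json")
    manifest = Manifest(run_dir / "manifest.jsonl")
    requested = [s for s in STAGES if s in config.stages]
    needed: set = set()

    def _expand(stage: str) -> None:
        for dep in _DEPENDENCIES.get(stage, ()):
            if dep not in needed:
                needed.add(dep)
                _expand(dep)

    for s in requested:
        needed.add(s)
        _expand(s)
    state: dict = {}
    for stage in STAGES:
        if stage not in needed:
            continue
        t0 = time.time()
        try:
            STAGE_FUNCS[stage](config, run_dir, state, manifest)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        logger.info("stage %s finished in %.1f s", stage, time.time() - t0)
    return run_dir
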