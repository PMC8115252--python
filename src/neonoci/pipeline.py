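"""End-to-end simulated-cohort pipeline.

Stages mirror the analysis chain: ``simulate`` writes a synthetic
event-related cohort (4D runs + tables) and a larger tabular resting +
diffusion cohort; ``evoked`` estimates subject GLMs, the group map,
overall amplitudes, template expression and task confounds; ``rsn``
extracts network amplitudes and resting confounds; ``predict`` runs the
LOO-CV SVR with cross-validated confound regression and transfers the
trained model to the larger cohort; ``structfun`` runs the exploratory
screen on the transfer cohort and the confirmatory analyses on the
event-related cohort; ``report`` merges every stage summary into one JSON
keyed by the configuration hash.

Each stage reads only the previous stages' on-disk outputs, so stages can
be rerun individually; missing prerequisites raise
:class:`MissingPrerequisiteError`.  Every stochastic output records the
seed it was generated from.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import confounds as conf_mod
from . import evoked, prediction, resting, simulate, structfun
from .hrf import Hrf
from .images import VoxelMap, read_volume, write_volume
from .tables import read_events, read_motion, read_table, write_table

__all__ = ["RunConfig", "MissingPrerequisiteError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "evoked", "rsn", "predict", "structfun", "report")

TASK_CONFOUNDS = ("mean_fd", "stim_corr_motion", "csf_amp")
REST_CONFOUNDS = ("mean_fd_rest", "csf_amp_rest", "wm_amp_rest")
DMRI_CONFOUNDS = ("dmri_motion", "noisy_voxels", "tbv")


class MissingPrerequisiteError(RuntimeError):
    """A stage was requested before its inputs were produced."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "neonoci_out"
    # phantom geometry
    grid_shape: tuple = (24, 24, 16)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    # cohorts
    n_local: int = 18
    n_dhcp: int = 215
    cohort_overrides: dict = field(default_factory=dict)
    # acquisition
    task_tr: float = 1.3
    task_n_vols: int = 277
    rest_tr: float = 1.3
    rest_n_vols: int = 500
    n_events: int = 10
    # template construction: adult template name -> target spatial r
    adult_templates: dict = field(default_factory=lambda: {
        "pain": 0.6, "nociceptive": 0.55, "nps": 0.5,
        "visual": 0.0, "social": 0.05,
    })
    rsn_replica_noise: float = 0.7
    # analysis parameters
    drift_order: int = 1
    cluster_forming_p: float = 0.001
    variance_fwhm_mm: float = 6.0
    n_perm_cluster: int = 10000
    n_perm_expression: int = 10000
    epsilon: float = 0.1
    c_grid: tuple = (0.001, 0.01, 0.1, 1.0)
    n_perm_prediction: int = 10000
    screen_alpha: float = 0.05
    n_perm_screen: int = 10000
    n_perm_confirmatory: int = 10000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("grid_shape", "voxel_size_mm", "c_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["c_grid"] = list(self.c_grid)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def prediction_config(self) -> prediction.PredictionConfig:
        return prediction.PredictionConfig(epsilon=self.epsilon,
                                           c_grid=tuple(self.c_grid))


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _roi_masks(geometry: simulate.PhantomGeometry) -> dict:
    """Small reference-region boxes (CSF-like, WM-like) inside the mask."""
    nx, ny, nz = geometry.grid_shape
    csf = np.zeros(geometry.grid_shape, dtype=bool)
    wm = np.zeros(geometry.grid_shape, dtype=bool)
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    csf[cx - 1:cx + 1, cy - 1:cy + 1, cz - 1:cz + 1] = True
    wm[cx + 2:cx + 4, cy - 3:cy - 1, cz - 1:cz + 1] = True
    return {"csf": csf & geometry.mask, "wm": wm & geometry.mask}


def _zero_in_rois(vmap: VoxelMap, rois: dict) -> VoxelMap:
    data = vmap.data.copy()
    for roi in rois.values():
        data[roi] = 0.0
    return vmap.with_data(data)


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_report(out: Path, stage: str, payload: dict) -> None:
    (out / "reports").mkdir(parents=True, exist_ok=True)
    (out / "reports" / f"{stage}.json").write_text(
        json.dumps(_json_ready(payload), indent=1, sort_keys=True))


def _load_report(out: Path, stage: str) -> dict:
    path = out / "reports" / f"{stage}.json"
    if not path.exists():
        raise MissingPrerequisiteError(
            f"stage {stage!r} output missing; run it first")
    return json.loads(path.read_text())


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingPrerequisiteError(
            f"missing {path.name}: run the {stage!r} stage first")
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path) -> dict:
    geometry = simulate.PhantomGeometry(tuple(config.grid_shape),
                                        tuple(config.voxel_size_mm))
    rois = _roi_masks(geometry)
    names = list(config.adult_templates)
    templates = simulate.gen_templates(
        geometry, k_rsn=len(simulate.RSN_LABELS),
        adult_target_corrs=[config.adult_templates[n] for n in names],
        seed=config.seed, rsn_replica_noise=config.rsn_replica_noise)
    # reference regions carry no neural signal
    templates["group_map"] = _zero_in_rois(templates["group_map"], rois)
    templates["rsn_maps"] = [_zero_in_rois(m, rois) for m in templates["rsn_maps"]]

    local_spec = simulate.CohortSpec(
        n_subjects=config.n_local, seed=config.seed + 1,
        **config.cohort_overrides)
    dhcp_spec = simulate.CohortSpec(
        n_subjects=config.n_dhcp, seed=config.seed + 2,
        n_dmri_incomplete=0, **config.cohort_overrides)
    local = simulate.gen_cohort(local_spec)
    dhcp = simulate.gen_cohort(dhcp_spec)

    events = simulate.default_event_schedule(n_events=config.n_events)
    runs = {}
    rng = np.random.default_rng(config.seed + 3)
    for i, sid in enumerate(local.subject_ids):
        a_true = float(local.amplitudes["amplitude"].iloc[i])
        rsn_true = local.rsn.iloc[i][list(local_spec.rsn_labels)].to_numpy(float)
        task = simulate.gen_task_run(
            a_true, templates["group_map"], events,
            tr=config.task_tr, n_vols=config.task_n_vols,
            thermal_sd=local_spec.thermal_sd, ar1=local_spec.ar1,
            drift_sd=local_spec.drift_sd, seed=int(rng.integers(2 ** 31)))
        task.motion = simulate.gen_motion_table(config.task_n_vols,
                                                seed=int(rng.integers(2 ** 31)))
        rest = simulate.gen_rest_run(
            rsn_true, templates["rsn_maps"],
            tr=config.rest_tr, n_vols=config.rest_n_vols,
            thermal_sd=local_spec.thermal_sd, ar1=local_spec.ar1,
            seed=int(rng.integers(2 ** 31)))
        rest.motion = simulate.gen_motion_table(config.rest_n_vols,
                                                seed=int(rng.integers(2 ** 31)))
        runs[sid] = {"task": task, "rest": rest}

    local_dir = out / "local"
    manifest = simulate.write_dataset(local, templates, runs, local_dir)
    for name, roi in rois.items():
        write_volume(VoxelMap(roi.astype(float), geometry.mask,
                              tuple(geometry.voxel_size_mm)),
                     local_dir / "maps" / f"roi_{name}.nii")
    for k, m in enumerate(templates.get("rsn_replica", [])):
        write_volume(m, local_dir / "maps" / f"rsn_replica_{k:02d}.nii")
    write_volume(VoxelMap(geometry.mask.astype(float), geometry.mask,
                          tuple(geometry.voxel_size_mm)),
                 local_dir / "maps" / "brain_mask.nii")

    dhcp_dir = out / "dhcp" / "tables"
    for name in ("amplitudes", "rsn", "tracts", "confounds", "clinical"):
        write_table(getattr(dhcp, name), dhcp_dir / f"{name}.tsv")

    return {
        "seed": config.seed,
        "n_local": config.n_local,
        "n_dhcp": config.n_dhcp,
        "n_files_local": int(len(manifest)),
        "adult_templates": names,
        "rsn_labels": list(local_spec.rsn_labels),
        "tract_labels": list(local_spec.tract_labels),
    }


def _load_local_subjects(out: Path) -> list:
    func = _require(out / "local" / "func", "simulate")
    return sorted({p.name.split("_")[0] for p in func.glob("*_bold.nii")})


def _stage_evoked(config: RunConfig, out: Path) -> dict:
    local = out / "local"
    _require(local / "maps" / "group_map.nii", "simulate")
    subjects = _load_local_subjects(out)
    mask = read_volume(local / "maps" / "brain_mask.nii").data > 0.5
    roi_csf = read_volume(local / "maps" / "roi_csf.nii").data > 0.5
    hrf = Hrf()

    beta_maps, confound_rows = [], []
    for sid in subjects:
        bold = read_volume(local / "func" / f"{sid}_task_bold.nii")
        bold.mask = mask
        events = read_events(local / "func" / f"{sid}_task_events.tsv")
        motion = read_motion(local / "func" / f"{sid}_task_motion.tsv")
        design = evoked.build_design(events, bold.n_vols, bold.tr, hrf,
                                     drift_order=config.drift_order)
        fit = evoked.glm_fit(bold, design)
        beta_maps.append(fit.stimulus_beta)
        fd = conf_mod.framewise_displacement(motion)
        scm = conf_mod.stimulus_correlated_motion(
            design[:, 0], conf_mod.motion_expansion(motion))
        confound_rows.append({
            "subject_id": sid,
            "mean_fd": fd["mean_fd"],
            "stim_corr_motion": scm,
            "csf_amp": conf_mod.roi_amplitude(fit.stimulus_beta, roi_csf,
                                              mode="mean_beta"),
        })
    confound_table = pd.DataFrame(confound_rows)
    write_table(confound_table, local / "tables" / "confounds_task_measured.tsv")

    group = evoked.group_tmap(beta_maps)
    write_volume(group, local / "maps" / "group_tmap.nii")

    cluster = evoked.cluster_inference(
        beta_maps, cluster_forming_p=config.cluster_forming_p,
        n_perm=config.n_perm_cluster,
        variance_fwhm_mm=config.variance_fwhm_mm, seed=config.seed + 10)
    write_volume(cluster.thresholded, local / "maps" / "group_thresholded.nii")
    write_table(cluster.clusters, local / "tables" / "clusters.tsv")

    amplitudes = pd.DataFrame({
        "subject_id": subjects,
        "amplitude": [evoked.overall_amplitude(b, group) for b in beta_maps],
    })
    write_table(amplitudes, local / "tables" / "amplitudes_measured.tsv")

    adult_paths = sorted((local / "maps").glob("adult_*.nii"))
    sim_report = _load_report(out, "simulate")
    names = sim_report["adult_templates"]
    expr_rows, tests = [], {}
    for path, name in zip(adult_paths, names):
        template = read_volume(path)
        template.mask = mask
        vals = [evoked.template_expression(b, template, method="pearson")
                for b in beta_maps]
        for sid, v in zip(subjects, vals):
            expr_rows.append({"subject_id": sid, "template": name,
                              "method": "pearson", "value": v})
        ttest = evoked.group_expression_test(vals, config.n_perm_expression,
                                             seed=config.seed + 11)
        corr = evoked.perm_correlation(
            amplitudes["amplitude"].to_numpy(), np.asarray(vals),
            tails="two", n_perm=config.n_perm_expression, seed=config.seed + 12)
        tests[name] = {"t_test": ttest.to_dict(), "amplitude_corr": corr.to_dict()}
    expr = pd.DataFrame(expr_rows)
    write_table(expr, local / "tables" / "template_expression.tsv")

    wide = expr.pivot(index="subject_id", columns="template", values="value")
    m_eff = evoked.effective_tests(wide.corr().to_numpy(), method="liji")

    return {
        "seed": config.seed,
        "n_subjects": len(subjects),
        "clusters": cluster.clusters.to_dict("records"),
        "cluster_convention": cluster.convention,
        "template_tests": tests,
        "effective_tests": m_eff,
        "amplitude_range": [float(amplitudes["amplitude"].min()),
                            float(amplitudes["amplitude"].max())],
    }


def _stage_rsn(config: RunConfig, out: Path) -> dict:
    local = out / "local"
    subjects = _load_local_subjects(out)
    mask = read_volume(_require(local / "maps" / "brain_mask.nii", "simulate")).data > 0.5
    rsn_paths = sorted((local / "maps").glob("rsn_??.nii"))
    templates = []
    for p in rsn_paths:
        m = read_volume(p)
        m.mask = mask
        templates.append(m)
    labels = _load_report(out, "simulate")["rsn_labels"]
    roi_csf = read_volume(local / "maps" / "roi_csf.nii").data > 0.5
    roi_wm = read_volume(local / "maps" / "roi_wm.nii").data > 0.5

    amp_rows, conf_rows = [], []
    for sid in subjects:
        bold = read_volume(local / "func" / f"{sid}_rest_bold.nii")
        bold.mask = mask
        motion = read_motion(local / "func" / f"{sid}_rest_motion.tsv")
        ts = resting.spatial_regression_timeseries(bold, templates, labels=labels)
        ts_frame = pd.DataFrame(ts.series.T, columns=labels)
        ts_frame.insert(0, "frame", np.arange(ts.n_frames))
        write_table(ts_frame, local / "tables" / f"{sid}_network_timeseries.tsv")
        row = {"subject_id": sid}
        for k, label in enumerate(labels):
            row[label] = resting.mad_amplitude(ts.series[k])
            row[f"{label}_outlier_fraction"] = resting.outlier_fraction(ts.series[k])
        amp_rows.append(row)
        conf_rows.append({
            "subject_id": sid,
            "mean_fd_rest": conf_mod.framewise_displacement(motion)["mean_fd"],
            "csf_amp_rest": conf_mod.roi_amplitude(bold, roi_csf, "mad_timeseries"),
            "wm_amp_rest": conf_mod.roi_amplitude(bold, roi_wm, "mad_timeseries"),
        })
    write_table(pd.DataFrame(amp_rows), local / "tables" / "rsn_amplitudes_measured.tsv")
    write_table(pd.DataFrame(conf_rows), local / "tables" / "confounds_rest_measured.tsv")

    report = {"seed": config.seed, "n_subjects": len(subjects),
              "networks": labels}
    replica_paths = sorted((local / "maps").glob("rsn_replica_*.nii"))
    if replica_paths:
        replicas = []
        for p in replica_paths:
            m = read_volume(p)
            m.mask = mask
            replicas.append(m)
        match = resting.match_templates(templates, replicas)
        report["template_matching"] = {
            "pairs": match["pairs"],
            "unmatched_a": match["unmatched_a"],
            "mean_abs_r": float(np.mean([abs(p["r"]) for p in match["pairs"]]))
            if match["pairs"] else None,
        }
    return report


def _stage_predict(config: RunConfig, out: Path) -> dict:
    local = out / "local" / "tables"
    labels = _load_report(out, "simulate")["rsn_labels"]
    amps = read_table(_require(local / "amplitudes_measured.tsv", "evoked"),
                      required=("subject_id", "amplitude"), index="subject_id")
    rsn_amp = read_table(_require(local / "rsn_amplitudes_measured.tsv", "rsn"),
                         index="subject_id")
    conf_task = read_table(local / "confounds_task_measured.tsv", index="subject_id")
    conf_rest = read_table(local / "confounds_rest_measured.tsv", index="subject_id")
    df = amps.merge(rsn_amp, on="subject_id").merge(conf_task, on="subject_id")
    df = df.merge(conf_rest, on="subject_id")

    model = prediction.AmplitudePredictionModel.from_dataframe(
        df, response="amplitude", features=labels,
        feature_confounds=REST_CONFOUNDS, response_confounds=TASK_CONFOUNDS,
        config=config.prediction_config())
    results = model.fit()
    perm = results.permutation_test(n_perm=config.n_perm_prediction,
                                    seed=config.seed + 20)
    write_table(results.to_frame(), local / "predictions.tsv")

    screens = prediction.univariate_screens(
        model.X, model.y, model.conf_X, model.conf_y,
        config=config.prediction_config(), feature_names=labels)
    write_table(screens, local / "univariate_screens.tsv")

    dhcp_tables = out / "dhcp" / "tables"
    dhcp_rsn = read_table(_require(dhcp_tables / "rsn.tsv", "simulate"),
                          index="subject_id")
    dhcp_conf = read_table(dhcp_tables / "confounds.tsv", index="subject_id")
    predicted = prediction.apply_model(
        {"X": model.X, "y": model.y, "conf_X": model.conf_X,
         "conf_y": model.conf_y},
        dhcp_rsn[labels].to_numpy(float),
        dhcp_conf[list(REST_CONFOUNDS)].to_numpy(float),
        config=config.prediction_config(), adjust_mode="within_target")
    write_table(pd.DataFrame({"subject_id": dhcp_rsn["subject_id"],
                              "predicted_amplitude": predicted}),
                dhcp_tables / "predicted_amplitudes.tsv")

    return {
        "seed": config.seed,
        "metrics": results.metrics,
        "p_values": {k: v.to_dict() for k, v in perm.items()},
        "chosen_c": results.chosen_c.tolist(),
        "univariate": screens.to_dict("records"),
        "n_transfer": int(len(predicted)),
        "summary": results.summary(),
    }


def _stage_structfun(config: RunConfig, out: Path) -> dict:
    dhcp_tables = out / "dhcp" / "tables"
    local_tables = out / "local" / "tables"
    tract_labels = _load_report(out, "simulate")["tract_labels"]
    feature_cols = [f"{t}_{p}" for t in tract_labels
                    for p in structfun.DTI_PARAMS]

    pred = read_table(_require(dhcp_tables / "predicted_amplitudes.tsv", "predict"),
                      index="subject_id")
    dhcp_tracts = read_table(dhcp_tables / "tracts.tsv", index="subject_id")
    dhcp_conf = read_table(dhcp_tables / "confounds.tsv", index="subject_id")
    merged = pred.merge(dhcp_tracts, on="subject_id").merge(dhcp_conf, on="subject_id")

    screen = structfun.exploratory_screen(
        merged["predicted_amplitude"].to_numpy(float),
        merged[feature_cols],
        merged[list(DMRI_CONFOUNDS)].to_numpy(float),
        alpha=config.screen_alpha, n_perm=config.n_perm_screen,
        seed=config.seed + 30)
    write_table(screen.table, dhcp_tables / "exploratory_screen.tsv")

    sig_md = screen.table[(screen.table["parameter"] == "MD")
                          & screen.table["significant"]]["tract"].tolist()
    confirmed = sig_md if sig_md else list(structfun.CONFIRMED_TRACTS)
    md_cols = [f"{t}_MD" for t in confirmed]

    dhcp_pca = structfun.md_pc1(
        structfun._residuals(merged[md_cols].to_numpy(float),
                             merged[list(DMRI_CONFOUNDS)].to_numpy(float)))
    dhcp_pc1_r = structfun.adjusted_correlation(
        dhcp_pca["scores"], merged["predicted_amplitude"].to_numpy(float),
        merged[list(DMRI_CONFOUNDS)].to_numpy(float))

    amps = read_table(_require(local_tables / "amplitudes_measured.tsv", "evoked"),
                      index="subject_id")
    local_tracts = read_table(local_tables / "tracts.tsv", index="subject_id")
    local_conf = read_table(local_tables / "confounds.tsv", index="subject_id")
    lmerged = amps.merge(local_tracts, on="subject_id").merge(local_conf,
                                                             on="subject_id")
    confirm = structfun.confirmatory_test(
        lmerged["amplitude"].to_numpy(float), lmerged[md_cols],
        lmerged[list(DMRI_CONFOUNDS)].to_numpy(float),
        direction="negative", n_perm=config.n_perm_confirmatory,
        seed=config.seed + 31)
    pd.DataFrame({"subject_id": lmerged.loc[
        ~lmerged[md_cols].isna().any(axis=1), "subject_id"],
        "pc1_score": confirm["pc1_scores"]}).pipe(
        write_table, local_tables / "md_pc1_scores.tsv")

    all_md = [f"{t}_MD" for t in tract_labels]
    subsets = structfun.subset_combination_analysis(
        lmerged["amplitude"].to_numpy(float), lmerged[all_md].rename(
            columns=dict(zip(all_md, tract_labels))),
        lmerged[list(DMRI_CONFOUNDS)].to_numpy(float),
        target_subset=confirmed)
    write_table(subsets["r2"], local_tables / "subset_analysis.tsv")
    global_r2 = float(subsets["r2"]["r2"].iloc[-1])   # full 16-tract subset

    # tract-to-tract MD association profiles in both datasets
    dhcp_profile = screen.table[screen.table["parameter"] == "MD"]["r"].to_numpy()
    local_profile = np.array([
        structfun.adjusted_correlation(
            lmerged.loc[~lmerged[all_md].isna().any(axis=1), f"{t}_MD"],
            lmerged.loc[~lmerged[all_md].isna().any(axis=1), "amplitude"],
            lmerged.loc[~lmerged[all_md].isna().any(axis=1),
                        list(DMRI_CONFOUNDS)].to_numpy(float))
        for t in tract_labels])
    profile_r = structfun.compare_tract_profiles(dhcp_profile, local_profile)

    return {
        "seed": config.seed,
        "n_tests": int(len(screen.table)),
        "n_significant": int(screen.table["significant"].sum()),
        "significant_md_tracts": sig_md,
        "confirmed_tracts": confirmed,
        "exploratory_pc1_r": float(dhcp_pc1_r),
        "exploratory_variance_fraction": float(dhcp_pca["variance_fraction"]),
        "confirmatory": {
            "pc1_r": confirm["pc1_r"],
            "p": confirm["p"].to_dict(),
            "variance_fraction": confirm["variance_fraction"],
            "n": confirm["n"],
            "polarity": confirm["polarity"].to_dict("records"),
        },
        "subset_percentile": subsets["percentile"],
        "target_r2": subsets["target_r2"],
        "global_r2": global_r2,
        "n_subsets": subsets["n_subsets"],
        "md_profile_similarity": float(profile_r),
    }


def validate_report(report: dict) -> None:
    """Structural validation against the shipped report schema.

    Checks the required-key structure declared in ``report_schema.json``
    (a dependency-free subset of JSON-Schema validation).
    """
    schema = json.loads(
        (Path(__file__).parent / "report_schema.json").read_text())

    def check(node, spec, path="$"):
        if spec.get("type") == "object":
            if not isinstance(node, dict):
                raise ValueError(f"report{path}: expected object")
            for key in spec.get("required", []):
                if key not in node:
                    raise ValueError(f"report{path}: missing key {key!r}")
            for key, sub in spec.get("properties", {}).items():
                if key in node:
                    check(node[key], sub, f"{path}.{key}")
        elif spec.get("type") == "string" and not isinstance(node, str):
            raise ValueError(f"report{path}: expected string")

    check(report, schema)


def _stage_report(config: RunConfig, out: Path) -> dict:
    merged = {"config": config.to_dict(), "config_hash": config.config_hash(),
              "stages": {}}
    for stage in STAGES[:-1]:
        merged["stages"][stage] = _load_report(out, stage)
    merged = _json_ready(merged)
    validate_report(merged)
    (out / "report.json").write_text(json.dumps(merged, indent=1,
                                                sort_keys=True))
    return merged


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "evoked": _stage_evoked,
    "rsn": _stage_rsn,
    "predict": _stage_predict,
    "structfun": _stage_structfun,
    "report": _stage_report,
}


def run_pipeline(config: RunConfig, stage: str = "all") -> dict:
    """Run one stage (or ``all``) and return the merged report dict."""
    if stage != "all" and stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stage == "all" else [stage]
    timings = {}
    for st in stages:
        t0 = time.perf_counter()
        payload = _STAGE_FUNCS[st](config, out)
        timings[st] = round(time.perf_counter() - t0, 3)
        if st != "report":
            _write_report(out, st, payload)
    (out / "reports" / "timings.json").write_text(json.dumps(timings, indent=1))
    if stage in ("all", "report"):
        return json.loads((out / "report.json").read_text())
    return payload
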