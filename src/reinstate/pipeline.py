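"""End-to-end study pipeline: simulate -> (GLM) -> within-subject RSAs ->
inter-subject RSAs -> group inference -> behavior statistics.

Every stage writes its products under the output directory and records them
in ``manifest.json`` with content hashes; re-running with an unchanged
configuration skips stages whose outputs already exist (searchlights dominate
runtime).  All randomness flows from the single configuration seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .data_model import Mask, read_stat_map, write_stat_map
from .group import ClusterConfig, cluster_fwe, interaction_anova_2x3, paired_t_map
from .intersubject import SmoothingSpec, intersubject_searchlight
from .rsa import (SearchlightSpec, build_same_vs_different,
                  build_weighted_diagonal, neighborhood_matrix, roi_rsa,
                  searchlight_rsa)
from .synth import EffectSpec, GeneratorConfig, StudyData, generate_pattern_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_full_study", "default_config"]

PHASE_PAIRS = (("Enc", "ImRet"), ("Enc", "DelRet"), ("ImRet", "DelRet"))


@dataclass
class PipelineConfig:
    """Everything one full synthetic-study analysis needs."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    phase_pairs: tuple = PHASE_PAIRS
    weight_kinds: tuple = ("same_vs_different", "weighted")
    searchlight: SearchlightSpec = field(default_factory=SearchlightSpec)
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    cluster: ClusterConfig = field(default_factory=lambda: ClusterConfig(
        n_permutations=1000))
    rois: dict = field(default_factory=dict)   # name -> Mask
    run_intersubject: bool = True
    mode: str = "patterns"                     # or "timeseries" (adds a GLM stage)
    exclude_first12_control: bool = False      # cue-control RSA variant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed != self.generator.seed:
            self.generator.seed = self.seed
        if not self.rois and self.generator.effects:
            self.rois = {"effect_region": self.generator.effects[0].region}

    def content_hash(self) -> str:
        def enc(o):
            if isinstance(o, Mask):
                return {"mask_voxels": int(o.n_voxels),
                        "digest": hashlib.sha256(o.voxels.tobytes()).hexdigest()}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dataclass_fields__"):
                return {k: enc(v) for k, v in asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def default_config(seed: int = 0, n_subjects: int = 21) -> PipelineConfig:
    """The emulated study at its reported design parameters: one effect
    region of posterior-midline-like magnitude (same-video z ~ 0.136 vs
    different-video z ~ 0.103), behavior-coupled reinstatement and a shared
    across-subject component."""
    from .synth import ellipsoid_mask, VolumeGrid
    grid = VolumeGrid((24, 28, 24), (3.0, 3.0, 3.0), space_label="common")
    region = ellipsoid_mask(grid, center=(11.5, 17.0, 13.0),
                            semi_axes=(5.0, 6.0, 5.0))
    gen = GeneratorConfig(
        n_subjects=n_subjects, grid=grid, seed=seed,
        effects=[EffectSpec(region=region, delta_z_same=0.033,
                            base_z_diff=0.103, behavior_coupling=0.01,
                            shared_fraction=0.4)])
    return PipelineConfig(generator=gen, seed=seed,
                          rois={"pmc_like": region})


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    roi_stats: pd.DataFrame
    cluster_tables: dict
    behavior_stats: dict
    interaction: tuple


def _pair_name(pair) -> str:
    return f"{pair[0]}_{pair[1]}"


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _patterns_from_timeseries(study: StudyData, runs, variant) -> dict:
    """Fit per-trial t-maps for every run and regroup them per (subject,
    phase), replacing the generator's direct patterns with GLM estimates."""
    from .data_model import PatternSet
    from .first_level import fit_run
    per_sub: dict[str, list] = {}
    for run in runs:
        per_sub.setdefault(run.subject_id, []).append(fit_run(run, variant))
    out = {}
    for sub, fitted in per_sub.items():
        trials = pd.concat([f.trials for f in fitted], ignore_index=True)
        values = np.vstack([f.values for f in fitted])
        for ph in ("Enc", "ImRet", "DelRet"):
            sel = (trials["phase"] == ph).to_numpy()
            if not sel.any():
                continue
            ref = fitted[0]
            out[(sub, ph)] = PatternSet(ref.grid, ref.mask,
                                        trials[sel].reset_index(drop=True),
                                        values[sel])
    return out


def run_full_study(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run the whole analysis and return collected statistics.

    Products per phase pair: per-subject same-vs-different and behavior-
    weighted searchlight maps, group cluster tables (sign-flip FWE), ROI
    same/different Fisher-z statistics, inter-subject maps, pairwise paired-t
    comparisons between phase pairs, behavior statistics, and a manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.content_hash()
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": cfg_hash, "seed": config.seed,
                "stages": {}, "files": {}}
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == cfg_hash:
                manifest = old
        except json.JSONDecodeError:
            pass

    def stage_done(name: str) -> bool:
        info = manifest["stages"].get(name)
        if not info:
            return False
        return all((out / f).exists() for f in info["outputs"])

    def record(name: str, outputs: list[Path], t0: float) -> None:
        rel = [str(p.relative_to(out)) for p in outputs]
        manifest["stages"][name] = {"outputs": rel,
                                    "seconds": round(time.time() - t0, 2)}
        for p, r in zip(outputs, rel):
            manifest["files"][r] = _sha(p)
        manifest_path.write_text(json.dumps(manifest, indent=1))

    t0 = time.time()
    logger.info("simulate: generating %s study (seed %d)", config.mode,
                config.seed)
    control_sets = None
    if config.mode == "timeseries":
        from .first_level import RetrievalModelVariant
        from .synth import generate_timeseries_study
        runs, study = generate_timeseries_study(config.generator)
        study.pattern_sets = _patterns_from_timeseries(
            study, runs, RetrievalModelVariant("full_trial"))
        if config.exclude_first12_control:
            control_sets = _patterns_from_timeseries(
                study, runs, RetrievalModelVariant("exclude_first_12s"))
    else:
        study = generate_pattern_study(config.generator)
    subjects = config.generator.subjects
    beh_table = study.behavior
    beh_path = out / "behavior.tsv"
    beh_table.to_csv(beh_path, sep="\t", index=False)
    record("simulate", [beh_path], t0)

    # --- within-subject searchlights -------------------------------------
    nbm = neighborhood_matrix(config.generator.brain_mask, config.searchlight)
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    map_files: dict[tuple, list[Path]] = {}
    rel_scores = beh_table.pivot(index="subject_id", columns="video_id",
                                 values="relative_score")
    t0 = time.time()
    for pair in config.phase_pairs:
        for kind in config.weight_kinds:
            key = (_pair_name(pair), kind)
            paths = []
            for sub in subjects:
                p = maps_dir / f"{key[0]}_{kind}_{sub}.nii.gz"
                paths.append(p)
            map_files[key] = paths
            if all(p.exists() for p in paths) and stage_done(f"rsa_{key[0]}_{kind}"):
                continue
            tstage = time.time()
            for sub, p in zip(subjects, paths):
                pa = study.phase(sub, pair[0])
                pb = study.phase(sub, pair[1])
                if kind == "same_vs_different":
                    w = build_same_vs_different(pa.trials, pb.trials)
                else:
                    w = build_weighted_diagonal(
                        pa.trials, pb.trials, rel_scores.loc[sub].to_dict())
                sm = searchlight_rsa(pa, pb, w, config.searchlight, nbm=nbm)
                write_stat_map(sm, p)
            record(f"rsa_{key[0]}_{kind}", paths, tstage)
    logger.info("rsa searchlights done in %.1fs", time.time() - t0)

    # cue-control variant: same analyses on patterns fit without the first
    # 12 s of each retrieval trial, written alongside the main outputs
    if control_sets is not None:
        for pair in config.phase_pairs:
            key = (f"{_pair_name(pair)}_exclude12", "same_vs_different")
            paths = [maps_dir / f"{key[0]}_{sub}.nii.gz" for sub in subjects]
            map_files[key] = paths
            tstage = time.time()
            for sub, p in zip(subjects, paths):
                pa = control_sets[(sub, pair[0])]
                pb = control_sets[(sub, pair[1])]
                w = build_same_vs_different(pa.trials, pb.trials)
                write_stat_map(searchlight_rsa(pa, pb, w, config.searchlight,
                                               nbm=nbm), p)
            record(f"rsa_{key[0]}", paths, tstage)

    # --- ROI statistics ----------------------------------------------------
    roi_rows = []
    interaction_cells = {}
    for roi_name, roi in config.rois.items():
        for pair in config.phase_pairs:
            same_z, diff_z, weighted = [], [], []
            for sub in subjects:
                pa, pb = study.phase(sub, pair[0]), study.phase(sub, pair[1])
                w = build_same_vs_different(pa.trials, pb.trials)
                res = roi_rsa(pa, pb, roi, w)
                same_z.append(res.mean_same_z)
                diff_z.append(res.mean_diff_z)
                ww = build_weighted_diagonal(pa.trials, pb.trials,
                                             rel_scores.loc[sub].to_dict())
                weighted.append(roi_rsa(pa, pb, roi, ww).weighted_sum)
            same_z, diff_z = np.array(same_z), np.array(diff_z)
            from scipy import stats as sps
            t_sd, p_sd = sps.ttest_rel(same_z, diff_z)
            t_w, p_w = sps.ttest_1samp(np.array(weighted), 0.0)
            roi_rows.append(dict(
                roi=roi_name, pair=_pair_name(pair),
                mean_same_z=same_z.mean(), mean_diff_z=diff_z.mean(),
                sem_same=same_z.std(ddof=1) / np.sqrt(len(same_z)),
                sem_diff=diff_z.std(ddof=1) / np.sqrt(len(diff_z)),
                t_same_vs_diff=float(t_sd), p_same_vs_diff=float(p_sd),
                t_weighted=float(t_w), p_weighted=float(p_w)))
            interaction_cells[(roi_name, _pair_name(pair))] = (same_z, diff_z)
    roi_stats = pd.DataFrame(roi_rows)
    roi_path = out / "roi_stats.tsv"
    roi_stats.to_csv(roi_path, sep="\t", index=False, float_format="%.6g")
    record("roi", [roi_path], t0)

    # 2x3 repeated-measures interaction (type x phase pair) per ROI
    interaction = None
    if config.rois and len(config.phase_pairs) == 3:
        roi_name = next(iter(config.rois))
        cells = np.stack([
            np.stack([interaction_cells[(roi_name, _pair_name(p))][0]
                      for p in config.phase_pairs], axis=-1),
            np.stack([interaction_cells[(roi_name, _pair_name(p))][1]
                      for p in config.phase_pairs], axis=-1),
        ], axis=1)  # (n, 2, 3)
        interaction = interaction_anova_2x3(cells)

    # --- group cluster inference ------------------------------------------
    cluster_tables = {}
    t0 = time.time()
    for key, paths in map_files.items():
        maps = [read_stat_map(p) for p in paths]
        res = cluster_fwe(maps, config.cluster)
        tab = res.table()
        tab_path = out / f"clusters_{key[0]}_{key[1]}.tsv"
        tab.to_csv(tab_path, sep="\t", index=False, float_format="%.6g")
        cluster_tables[key] = tab
        record(f"group_{key[0]}_{key[1]}", [tab_path], t0)

    # paired comparisons of the retrieval-pair RSA against the encoding pairs
    sd_keys = [k for k in map_files if k[1] == "same_vs_different"
               and not k[0].endswith("_exclude12")]
    if ("ImRet_DelRet", "same_vs_different") in map_files:
        target = [read_stat_map(p)
                  for p in map_files[("ImRet_DelRet", "same_vs_different")]]
        for key in sd_keys:
            if key[0] == "ImRet_DelRet":
                continue
            other = [read_stat_map(p) for p in map_files[key]]
            diff_t = paired_t_map(target, other)
            write_stat_map(diff_t, out / f"paired_t_ImRet_DelRet_vs_{key[0]}.nii.gz")

    # --- inter-subject RSAs -------------------------------------------------
    if config.run_intersubject:
        t0 = time.time()
        for pair in config.phase_pairs:
            name = _pair_name(pair)
            paths = [maps_dir / f"isrsa_{name}_{sub}.nii.gz" for sub in subjects]
            if not all(p.exists() for p in paths) or not stage_done(f"isrsa_{name}"):
                sets_a = {s: study.phase(s, pair[0]) for s in subjects}
                sets_b = {s: study.phase(s, pair[1]) for s in subjects}
                maps = intersubject_searchlight(
                    sets_a, sets_b, build_same_vs_different,
                    spec=config.searchlight, smoothing=config.smoothing)
                for sub, p in zip(subjects, paths):
                    write_stat_map(maps[sub], p)
                record(f"isrsa_{name}", paths, t0)
            res = cluster_fwe([read_stat_map(p) for p in paths], config.cluster)
            tab_path = out / f"clusters_isrsa_{name}.tsv"
            res.table().to_csv(tab_path, sep="\t", index=False,
                               float_format="%.6g")
            cluster_tables[(name, "intersubject")] = res.table()
            record(f"group_isrsa_{name}", [tab_path], t0)

    # --- behavior -----------------------------------------------------------
    behavior_stats = {
        "paired": beh.paired_comparisons(beh_table),
        "vividness_association_imret":
            {k: v for k, v in beh.vividness_performance_association(
                beh_table, "ImRet").items() if np.isscalar(v)},
        "mean_details": float(beh_table["detail_score"].mean()),
        "sd_details": float(beh_table["detail_score"].std(ddof=1)),
    }
    if interaction is not None:
        behavior_stats["interaction_F_df_p"] = [interaction[0], interaction[1],
                                                interaction[2], interaction[3]]
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(behavior_stats, indent=1, default=float))
    record("behavior", [stats_path], t0)
    return PipelineResult(out, manifest, roi_stats, cluster_tables,
                          behavior_stats, interaction)
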