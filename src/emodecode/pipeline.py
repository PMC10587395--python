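"""End-to-end orchestration: simulate -> GLM -> decoding -> group -> ROI.

A pipeline run is fully reproducible from (config, master seed): every
stochastic stage draws its seed from the master seed via a fixed
SeedSequence spawn order, and a manifest records the sha256 of every
output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmodecodeError
from .glm import TrialBetaSet, fit_trial_betas
from .inference import (
    PermutationScheme,
    cluster_threshold,
    fwe_correct,
    permutation_group_test,
    ttest_vs_chance,
)
from .io import dataset_config_from_dict, write_events, write_nifti
from .roi import build_rois, compute_rdm, condition_patterns, roi_decode
from .searchlight import (
    CROSSMODAL_PAIRS,
    SearchlightSpec,
    crossmodal_decode,
    crossmodal_task,
    emotion_all_task,
    emotion_within_task,
    mask_adjacency,
    modality_searchlight,
    searchlight_decode,
)
from .simulate import Dataset, DatasetConfig, generate_dataset

log = logging.getLogger("emodecode")

ALL_STAGES = ("simulate", "glm", "decode", "group", "roi")


@dataclass
class AnalysisOptions:
    radius_voxels: int = 5
    min_voxels: int = 1
    alpha: float = 0.05
    q: float = 0.05
    voxel_p: float = 0.001
    cluster_k: int = 25
    connectivity: int = 26
    t_threshold: float = 3.9
    n_permutations: int = 100
    run_permutation_test: bool = False
    tasks: tuple[str, ...] = ("modality", "emotion_all")
    crossmodal: bool = False
    roi_source: str = "regions"  # "regions" (ground truth) or "table1"
    roi_radius: float = 5.0


@dataclass
class PipelineConfig:
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    analysis_data = data.pop("analysis", {})
    valid = set(AnalysisOptions.__dataclass_fields__)
    unknown = set(analysis_data) - valid
    if unknown:
        warnings.warn(f"unknown analysis key(s): {sorted(unknown)}")
    kwargs = {k: v for k, v in analysis_data.items() if k in valid}
    if "tasks" in kwargs:
        kwargs["tasks"] = tuple(kwargs["tasks"])
    return PipelineConfig(
        dataset=dataset_config_from_dict(data),
        analysis=AnalysisOptions(**kwargs),
    )


def read_pipeline_config(path) -> PipelineConfig:
    import yaml

    from .exceptions import ValidationError

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such config file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return pipeline_config_from_dict(data)


def _named_task(name: str):
    if name == "emotion_all":
        return emotion_all_task()
    if name == "emotion_voice":
        return emotion_within_task(["voice"], name="emotion_voice")
    if name == "emotion_visual":
        return emotion_within_task(["face", "body"], name="emotion_visual")
    if name == "emotion_face":
        return emotion_within_task(["face"], name="emotion_face")
    if name == "emotion_body":
        return emotion_within_task(["body"], name="emotion_body")
    raise ConfigurationError(f"unknown task {name!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineResult:
    """Outputs of a pipeline run, kept in memory plus a file manifest."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.dataset: Dataset | None = None
        self.betas: list[TrialBetaSet] = []
        self.accuracy_maps: dict[str, list] = {}
        self.group_maps: dict[str, object] = {}
        self.cluster_tables: dict[str, object] = {}
        self.roi_report = None
        self.rdms: dict[str, object] = {}
        self.manifest: dict = {"stages": [], "outputs": {}, "skipped_stages": []}

    def record(self, stage: str, path: Path) -> None:
        rel = str(path.relative_to(self.out_dir))
        self.manifest["outputs"][rel] = _sha256(path)

    def write_manifest(self) -> Path:
        path = self.out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return path


def run_pipeline(
    config: PipelineConfig,
    seed: int,
    out_dir,
    stages: tuple[str, ...] = ALL_STAGES,
) -> PipelineResult:
    """Execute the requested stages and write a manifest.

    Stage failures are re-raised annotated with the failing stage.
    """
    for st in stages:
        if st not in ALL_STAGES:
            raise ConfigurationError(f"unknown stage {st!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir)
    result.manifest["seed"] = seed
    result.manifest["skipped_stages"] = [s for s in ALL_STAGES if s not in stages]
    opts = config.analysis
    stage = "simulate"
    try:
        dataset = generate_dataset(config.dataset, seed)
        result.dataset = dataset
        if "simulate" in stages:
            from .io import write_dataset

            write_dataset(dataset, out_dir / "data")
            for p in sorted((out_dir / "data").rglob("*")):
                if p.is_file():
                    result.record("simulate", p)
            result.manifest["stages"].append("simulate")
        if not ({"glm", "decode", "group", "roi"} & set(stages)):
            result.write_manifest()
            return result

        stage = "glm"
        mask = dataset.truth.brain_mask
        betas = [fit_trial_betas(s, mask, config.dataset.hrf) for s in dataset.subjects]
        result.betas = betas
        if "glm" in stages:
            bdir = out_dir / "betas"
            for b in betas:
                vol = np.full(b.mask.shape + (b.betas.shape[0],), np.nan)
                vol[b.mask] = b.betas.T
                result.record("glm", write_nifti(vol, b.affine, bdir / f"sub-{b.subject:02d}_betas.nii.gz"))
                result.record("glm", write_events(b.labels, bdir / f"sub-{b.subject:02d}_labels.tsv"))
            result.manifest["stages"].append("glm")
        if not ({"decode", "group", "roi"} & set(stages)):
            result.write_manifest()
            return result

        stage = "decode"
        spec = SearchlightSpec(opts.radius_voxels, opts.min_voxels)
        adjacency = mask_adjacency(mask, spec.radius_voxels)
        if "decode" in stages or "group" in stages:
            for name in opts.tasks:
                if name == "modality":
                    maps = [modality_searchlight(b, spec, adjacency) for b in betas]
                else:
                    task = _named_task(name)
                    maps = [searchlight_decode(b, task, spec, adjacency) for b in betas]
                result.accuracy_maps[name] = maps
                log.info("task %s: %d subjects, %d folds, %d undefined centers",
                         name, len(maps), maps[0].n_folds,
                         int(mask.sum() - maps[0].defined.sum()))
            if opts.crossmodal:
                for train, test in CROSSMODAL_PAIRS:
                    task = crossmodal_task(train, test)
                    result.accuracy_maps[task.name] = [
                        crossmodal_decode(b, task, spec, adjacency) for b in betas
                    ]
            if "decode" in stages:
                ddir = out_dir / "decode"
                for name, maps in result.accuracy_maps.items():
                    for m in maps:
                        p = write_nifti(m.values, m.affine, ddir / f"sub-{m.subject:02d}_{name}_accuracy.nii.gz")
                        result.record("decode", p)
                    side = ddir / f"{name}.json"
                    with open(side, "w") as fh:
                        json.dump(
                            {"task": name, "chance_level": maps[0].chance_level,
                             "n_folds": maps[0].n_folds,
                             "radius_voxels": spec.radius_voxels,
                             "min_voxels": spec.min_voxels}, fh)
                    result.record("decode", side)
                result.manifest["stages"].append("decode")

        if "group" in stages:
            stage = "group"
            gdir = out_dir / "group"
            for name, maps in result.accuracy_maps.items():
                stat = ttest_vs_chance(maps, maps[0].chance_level)
                result.group_maps[name] = stat
                reject = fwe_correct(stat, opts.alpha, "bonferroni")
                clusters = cluster_threshold(stat, opts.voxel_p, opts.cluster_k, opts.connectivity)
                result.cluster_tables[name] = clusters
                result.record("group", write_nifti(stat.t_values, stat.affine, gdir / f"{name}_tmap.nii.gz"))
                result.record("group", write_nifti(reject.astype(np.uint8), stat.affine, gdir / f"{name}_fwe_reject.nii.gz"))
                ct = gdir / f"{name}_clusters.tsv"
                clusters.table.to_csv(ct, sep="\t", index=False)
                result.record("group", ct)
            if opts.run_permutation_test and "emotion_all" in opts.tasks:
                scheme = PermutationScheme(
                    n_permutations=opts.n_permutations,
                    seed=int(np.random.SeedSequence(seed).spawn(4)[3].generate_state(1)[0] % (2**31)),
                )
                perm = permutation_group_test(betas, emotion_all_task(), spec, scheme, opts.t_threshold)
                result.group_maps["emotion_all_permutation"] = perm
                result.record("group", write_nifti(perm.averaged_t, betas[0].affine, gdir / "emotion_all_perm_avg_t.nii.gz"))
            result.manifest["stages"].append("group")

        if "roi" in stages:
            stage = "roi"
            rdir = out_dir / "roi"
            rdir.mkdir(parents=True, exist_ok=True)
            if opts.roi_source == "table1":
                rois = build_rois(dataset.truth.grid_shape, dataset.truth.affine, mask, opts.roi_radius)
            else:
                rois = {
                    name: rmask for name, rmask in dataset.truth.region_masks.items()
                } or {"center": _center_roi(dataset.truth, opts.roi_radius)}
            report = roi_decode(betas, rois)
            result.roi_report = report
            rp = rdir / "roi_decoding_pfdr.tsv"
            report.to_tsv(rp)
            result.record("roi", rp)
            ra = rdir / "roi_decoding_accuracy.tsv"
            report.accuracies.to_csv(ra, sep="\t", float_format="%.4f")
            result.record("roi", ra)
            for name, rmask in rois.items():
                pats = np.mean([condition_patterns(b, rmask) for b in betas], axis=0)
                rdm = compute_rdm(pats)
                result.rdms[name] = rdm
                rt = rdir / f"rdm_{name}.tsv"
                pd.DataFrame(rdm.values).to_csv(rt, sep="\t", index=False, header=False, float_format="%.5f")
                result.record("roi", rt)
            result.manifest["stages"].append("roi")
    except EmodecodeError as err:
        raise type(err)(f"stage {stage!r} failed: {err}") from err
    result.write_manifest()
    return result


def _center_roi(truth, radius: float) -> np.ndarray:
    from .patterns import spherical_mask

    center = tuple((s - 1) / 2.0 for s in truth.grid_shape)
    return spherical_mask(truth.grid_shape, center, radius) & truth.brain_mask
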