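"""File I/O: NIfTI volumes, BIDS-style event tables, YAML configs."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import ExperimentDesign, validate_events
from .exceptions import ValidationError
from .hrf import HRFSpec
from .patterns import NoiseModel, RegionSpec, TruthConfig
from .simulate import BoldRun, Dataset, DatasetConfig


def write_nifti(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    return path


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such events file: {path}")
    events = pd.read_csv(path, sep="\t")
    validate_events(events)
    return events


_CONFIG_SECTIONS = {"design", "truth", "noise", "hrf", "n_subjects"}


def _build_section(cls, data: dict, context: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        warnings.warn(f"unknown key(s) in {context}: {sorted(unknown)}", stacklevel=3)
    kwargs = {k: v for k, v in data.items() if k in valid}
    # YAML lists -> tuples for fields that expect them
    for key in ("isi_range", "emotions", "stimulus_types", "grid_shape"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def dataset_config_from_dict(data: dict) -> DatasetConfig:
    """Build a :class:`DatasetConfig` from a plain dict, warning on
    unknown keys instead of silently ignoring them."""
    unknown = set(data) - _CONFIG_SECTIONS
    if unknown:
        warnings.warn(f"unknown config key(s): {sorted(unknown)}", stacklevel=2)
    design = _build_section(ExperimentDesign, data.get("design", {}), "design")
    truth_data = dict(data.get("truth", {}))
    regions = {
        name: RegionSpec(center=tuple(spec["center"]), radius=spec["radius"], amplitude=spec["amplitude"])
        for name, spec in truth_data.pop("regions", {}).items()
    }
    truth = _build_section(TruthConfig, truth_data, "truth")
    truth.regions = regions
    noise = _build_section(NoiseModel, data.get("noise", {}), "noise")
    hrf = _build_section(HRFSpec, data.get("hrf", {}), "hrf")
    return DatasetConfig(
        design=design, truth=truth, noise=noise, hrf=hrf,
        n_subjects=int(data.get("n_subjects", 8)),
    )


def read_config(path) -> DatasetConfig:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such config file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError("config must be a YAML mapping")
    return dataset_config_from_dict(data)


def write_dataset(dataset: Dataset, out_dir) -> Path:
    """Write NIfTI runs, event TSVs and the ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_events(dataset.events, out / "events.tsv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(dataset.truth.to_json_dict(), fh)
    for subj in dataset.subjects:
        sdir = out / f"sub-{subj.subject:02d}"
        for run in subj.runs:
            write_nifti(run.data, run.affine, sdir / f"run-{run.run:02d}_bold.nii.gz")
    return out


def read_dataset_runs(out_dir, subject: int, design: ExperimentDesign) -> list[BoldRun]:
    """Reload one subject's runs written by :func:`write_dataset`."""
    out = Path(out_dir)
    sdir = out / f"sub-{subject:02d}"
    runs = []
    for run in range(1, design.n_runs + 1):
        data, affine = read_nifti(sdir / f"run-{run:02d}_bold.nii.gz")
        session = 1 if run <= design.runs_per_session else 2
        runs.append(BoldRun(data=data, tr=design.tr, affine=affine, run=run, session=session))
    return runs
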