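"""Cohort file layout, subject round-tripping and run manifests.

One directory per subject with fixed filenames: ``fat.nii.gz``,
``water.nii.gz``, ``body.nii.gz``, ``bone.nii.gz``, ``bodyparts.nii.gz``,
``landmarks.json`` (+ optional covariates in the cohort-level
``covariates.csv``).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imagecore import BinaryMask, LabelVolume, ScalarVolume, read_nifti, write_nifti
from .subject import SubjectRecord
from .transforms import LANDMARK_NAMES, LandmarkSet

_FILES = {
    "fat": ("fat.nii.gz", ScalarVolume),
    "water": ("water.nii.gz", ScalarVolume),
    "body": ("body.nii.gz", BinaryMask),
    "bone": ("bone.nii.gz", BinaryMask),
    "bodyparts": ("bodyparts.nii.gz", LabelVolume),
}


def save_subject(record: SubjectRecord, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for attr, (fname, _) in _FILES.items():
        write_nifti(getattr(record, attr), d / fname)
    (d / "landmarks.json").write_text(json.dumps(record.landmarks.to_dict(), indent=1))
    if record.covariates:
        (d / "covariates.json").write_text(
            json.dumps(record.covariates, indent=1, default=str)
        )
    return d


def load_subject(directory) -> SubjectRecord:
    """Load and validate one subject directory; errors name the missing or
    inconsistent piece explicitly."""
    d = Path(directory)
    vols = {}
    for attr, (fname, kind) in _FILES.items():
        path = d / fname
        if not path.exists():
            raise FileNotFoundError(f"{d}: missing {attr} volume ({fname})")
        vols[attr] = read_nifti(path, kind)
    ref = vols["fat"]
    for attr, vol in vols.items():
        if vol.shape != ref.shape:
            raise ValueError(f"{d}: {attr} shape {vol.shape} != fat shape {ref.shape}")
        for ax in range(3):
            if abs(vol.spacing[ax] - ref.spacing[ax]) > 1e-4:
                raise ValueError(
                    f"{d}: {attr} spacing mismatch on axis {ax}: "
                    f"{vol.spacing[ax]} vs {ref.spacing[ax]}"
                )
    lm_path = d / "landmarks.json"
    if not lm_path.exists():
        raise FileNotFoundError(f"{d}: missing landmarks.json")
    raw = json.loads(lm_path.read_text())
    missing = [n for n in LANDMARK_NAMES if n not in raw]
    if missing:
        raise ValueError(f"{d}: landmarks.json lacks {', '.join(missing)}")
    covs = {}
    cov_path = d / "covariates.json"
    if cov_path.exists():
        covs = json.loads(cov_path.read_text())
    return SubjectRecord(
        subject_id=d.name,
        **vols,
        landmarks=LandmarkSet({n: np.array(raw[n], dtype=float) for n in LANDMARK_NAMES}),
        covariates=covs,
    )


def load_cohort(directory) -> tuple[list, pd.DataFrame | None]:
    d = Path(directory)
    subjects = [
        load_subject(p) for p in sorted(d.iterdir()) if (p / "fat.nii.gz").exists()
    ]
    if not subjects:
        raise FileNotFoundError(f"{d}: no subject directories found")
    table = None
    if (d / "covariates.csv").exists():
        table = pd.read_csv(d / "covariates.csv", index_col=0)
    return subjects, table


def write_manifest(out_dir, command: str, seed: int, inputs: dict, outputs: dict, config=None):
    """One manifest per CLI run; re-running with the same manifest reproduces
    stochastic outputs bit-for-bit (all randomness flows from the seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_repr = json.dumps(config, sort_keys=True, default=str) if config is not None else ""
    manifest = {
        "command": command,
        "seed": int(seed),
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
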