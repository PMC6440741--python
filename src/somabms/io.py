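"""File formats, configuration, and provenance.

Trial tables travel as BIDS-style events files (tab-separated, ``n/a`` for
missing values); volumes as NIfTI-1; configuration as YAML validated through
a pydantic schema.  Every artefact-writing stage records provenance (config
hash, seed, package version) in a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .synth import SimulationConfig

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "read_events",
    "write_events",
    "save_volume",
    "load_volume",
    "provenance",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type", "level", "intensity_mA",
                 "cue", "detected", "report", "response_time"]


class MalformedEventsError(ValueError):
    pass


class PipelineConfig(BaseModel):
    """Resolved settings for a full pipeline run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    simulation: SimulationConfig = SimulationConfig()
    glm_prior_g: float | None = None       # None -> unit information (n scans)
    glm_prior_a0: float = 0.1
    glm_prior_b0: float = 0.1
    prewhiten: bool = True
    evidence_fwhm_mm: float = 8.0
    resample_mm: float | None = None
    alpha0: float = 1.0
    ep_samples_scalar: int = 1_000_000
    ep_samples_map: int = 20_000
    ep_min: float = 0.99
    k_min: int = 50
    connectivity: int = 26
    srp_radius_mm: float = 4.0
    jzs_scale: float = 0.707

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config; schema errors name the offending key."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as e:
        keys = ", ".join(".".join(str(p) for p in err["loc"]) for err in e.errors())
        raise ValueError(f"invalid configuration key(s): {keys}") from e


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def write_events(trials: pd.DataFrame, path: str | Path) -> None:
    """BIDS-style events file: tab-separated, header row, 'n/a' for missing."""
    df = trials.loc[:, EVENT_COLUMNS].copy()
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.6f")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate an events file (onset monotonicity, row integrity)."""
    path = Path(path)
    header = path.read_text().splitlines()
    if not header:
        raise MalformedEventsError(f"{path}: empty events file")
    n_cols = len(header[0].split("\t"))
    for ln, line in enumerate(header[1:], start=2):
        if line and len(line.split("\t")) != n_cols:
            raise MalformedEventsError(f"{path}: malformed row at line {ln}")
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedEventsError(f"{path}: missing columns {missing}")
    # numeric columns: 'n/a' -> NaN; string columns keep the literal marker
    for col in ("onset", "duration", "intensity_mA", "detected", "response_time"):
        df[col] = pd.to_numeric(df[col].replace("n/a", np.nan), errors="raise")
    df["level"] = pd.to_numeric(df["level"].replace("n/a", 0)).astype(int)
    onsets = df["onset"].to_numpy(float)
    if np.any(np.diff(onsets) <= 0):
        bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 3  # 1-based + header
        raise MalformedEventsError(f"{path}: onsets not strictly increasing at line {bad}")
    df["is_null"] = df["trial_type"] == "null"
    return df


def save_volume(data: np.ndarray, path: str | Path, voxel_size: float = 3.0,
                sidecar: dict | None = None) -> None:
    """Write a 3-D/4-D array as NIfTI-1 with an isotropic affine."""
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    if sidecar is not None:
        Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json").write_text(
            json.dumps(sidecar, indent=2, default=str) + "\n")


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def provenance(config: PipelineConfig, seed: int) -> dict:
    from . import __version__
    return {"config_sha256": config.digest(), "seed": seed,
            "software": f"somabms {__version__}"}
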