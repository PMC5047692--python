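"""File formats: TIFF stacks with JSON sidecars, cohort CSVs, manifests.

Stacks travel as multi-page TIFF (axes C, Z, Y, X) with a JSON sidecar next
to the image carrying the voxel sizes, channel names and — for simulated
data — the ground truth.  The sidecar was chosen over OME-XML embedding for
transparency; externally produced OME-TIFFs are accepted as plain TIFF as
long as a sidecar is supplied.  Cohort tables are comma-separated UTF-8 CSV
with a mandatory header row and decimal points.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .stacks import ImageStack
from .synthetic import BranchGroundTruth

SIDECAR_KEYS = ("pixel_size_um", "z_step_um", "channel_names")


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(".json")


def _truth_to_jsonable(truth) -> dict | None:
    if truth is None:
        return None
    if isinstance(truth, BranchGroundTruth):
        return truth.to_dict()
    if isinstance(truth, dict) and truth.get("kind") == "muscle_field":
        return {
            "kind": "muscle_field",
            "puncta": truth["puncta"].to_dict(orient="list"),
            "nuclei": truth["nuclei"].to_dict(orient="list"),
            "d_max_um": truth["d_max_um"],
        }
    raise FormatError(f"unsupported ground-truth object: {type(truth)!r}")


def _truth_from_jsonable(d: dict | None):
    if d is None:
        return None
    if d.get("kind") == "branch":
        return BranchGroundTruth.from_dict(d)
    if d.get("kind") == "muscle_field":
        return {"kind": "muscle_field",
                "puncta": pd.DataFrame(d["puncta"]),
                "nuclei": pd.DataFrame(d["nuclei"]),
                "d_max_um": float(d["d_max_um"])}
    raise FormatError(f"unknown ground-truth kind {d.get('kind')!r}")


def write_stack(path: str | Path, stack: ImageStack, ground_truth=None) -> Path:
    """Write a stack as multi-page TIFF plus its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels.astype(np.float32),
                     photometric="minisblack",
                     metadata={"axes": "CZYX"})
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "channel_names": list(stack.channel_names),
        "ground_truth": _truth_to_jsonable(ground_truth),
    }
    sidecar_path(path).write_text(json.dumps(meta, sort_keys=True))
    return path


def read_stack(path: str | Path):
    """Read a TIFF stack and its sidecar; returns (ImageStack, ground_truth).

    The sidecar must provide pixel_size_um, z_step_um and channel_names;
    a missing sidecar or missing keys raise :class:`FormatError` naming what
    is required.  ``ground_truth`` is ``None`` for non-simulated data.
    """
    path = Path(path)
    try:
        voxels = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"{path} is not a readable TIFF stack: {exc}") from exc
    sc = sidecar_path(path)
    if not sc.exists():
        raise FormatError(
            f"missing sidecar {sc}; required keys: {', '.join(SIDECAR_KEYS)}")
    meta = json.loads(sc.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise FormatError(f"sidecar {sc} missing keys: {', '.join(missing)}")
    names = list(meta["channel_names"])
    if voxels.ndim == 3:
        if len(names) == 1:
            voxels = voxels[np.newaxis]
        elif voxels.shape[0] == len(names):  # single z plane per channel
            voxels = voxels[:, np.newaxis]
        else:
            raise FormatError(
                f"cannot map TIFF shape {voxels.shape} onto "
                f"{len(names)} channels")
    if voxels.ndim != 4 or voxels.shape[0] != len(names):
        raise FormatError(
            f"TIFF shape {voxels.shape} inconsistent with channel names "
            f"{names}")
    stack = ImageStack(voxels, names, float(meta["pixel_size_um"]),
                       float(meta["z_step_um"]))
    return stack, _truth_from_jsonable(meta.get("ground_truth"))


COHORT_COLUMNS = {"condition", "test_id", "value"}


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path} is not a readable CSV table: {exc}") from exc
    missing = COHORT_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(
            f"cohort CSV {path} missing columns: {', '.join(sorted(missing))}")
    return df


def write_json(path: str | Path, obj) -> Path:
    """Deterministic JSON writer (sorted keys, fixed layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
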