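"""File formats: NIfTI / plain-text images, feature tables, model dumps.

Images are accepted either as NIfTI volumes (via nibabel) or as
whitespace-delimited numeric matrices (one file per slice, or a 2-D file for
a single slice).  Feature stacks travel as tab-separated tables with a
header row; the standard scale and the ensemble manifest as flat key-value
text files.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ensemble import EnsembleModel, PlattCalibration, WeakHypothesis
from .standardize import StandardScale
from .texture import FeatureStack

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_feature_stack",
    "read_feature_stack",
    "write_standard_scale",
    "read_standard_scale",
    "write_selection_result",
    "save_model",
    "load_model",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D or 3-D image from NIfTI or a plain-text matrix."""
    path = Path(path)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        data = np.asarray(nib.load(str(path)).get_fdata())
        if data.ndim == 3:
            # store as (slices, rows, cols)
            return np.transpose(data, (2, 0, 1))
        return data
    return np.loadtxt(path)


def write_image(path: str | Path, data: np.ndarray) -> None:
    """Write an array as NIfTI (.nii/.nii.gz) or a plain-text matrix."""
    path = Path(path)
    data = np.asarray(data)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        vol = np.transpose(data, (1, 2, 0)) if data.ndim == 3 else data
        nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), str(path))
    else:
        if data.ndim == 3 and data.shape[0] == 1:
            data = data[0]
        np.savetxt(path, data, fmt="%.8g")


def read_stack(paths: list[str | Path]) -> np.ndarray:
    """Stack one or more 2-D slice files (or a single 3-D file) to 3-D."""
    if len(paths) == 1:
        arr = read_image(paths[0])
        return arr[None] if arr.ndim == 2 else arr
    return np.stack([np.atleast_2d(read_image(p)) for p in paths])


def write_feature_stack(path: str | Path, stack: FeatureStack) -> None:
    """Tab-separated table: slice,row,col[,label], then feature columns."""
    cols = {
        "slice": stack.pixel_index[:, 0],
        "row": stack.pixel_index[:, 1],
        "col": stack.pixel_index[:, 2],
    }
    if stack.y is not None:
        cols["label"] = stack.y
    for j, name in enumerate(stack.feature_names):
        cols[name] = stack.X[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_feature_stack(path: str | Path) -> FeatureStack:
    df = pd.read_csv(path, sep="\t")
    meta = ["slice", "row", "col"]
    y = None
    if "label" in df.columns:
        y = df["label"].to_numpy(dtype=int)
        meta.append("label")
    names = [c for c in df.columns if c not in meta]
    return FeatureStack(
        X=df[names].to_numpy(dtype=float),
        feature_names=names,
        pixel_index=df[["slice", "row", "col"]].to_numpy(dtype=int),
        y=y,
    )


def write_standard_scale(path: str | Path, scale: StandardScale) -> None:
    lines = [
        f"s1 = {scale.s1!r}",
        f"s2 = {scale.s2!r}",
        f"mu_s = {scale.mu_s!r}",
        f"p_low_percentile = {scale.p_percentiles[0]!r}",
        f"p_high_percentile = {scale.p_percentiles[1]!r}",
        f"n_slices_trained = {scale.n_slices_trained}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_standard_scale(path: str | Path) -> StandardScale:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = float(v.strip())
    return StandardScale(
        s1=kv["s1"],
        s2=kv["s2"],
        mu_s=kv["mu_s"],
        p_percentiles=(kv["p_low_percentile"], kv["p_high_percentile"]),
        n_slices_trained=int(kv["n_slices_trained"]),
    )


def write_selection_result(path: str | Path, result) -> None:
    payload = {
        "kept_indices": list(map(int, result.kept_indices)),
        "dropped_pairs": [
            [int(a), int(b), float(r)] for a, b, r in result.dropped_pairs
        ],
        "forward_path": [[int(j), float(s)] for j, s in result.forward_path],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def save_model(directory: str | Path, model: EnsembleModel) -> None:
    """Serialize the ensemble: one solver dump + manifest line per hypothesis."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, inc in enumerate(model.increments):
        for j, h in enumerate(inc):
            dump = directory / f"hypothesis_{i:03d}_{j:03d}.pkl"
            with open(dump, "wb") as fh:
                pickle.dump(h.model, fh)
        manifest.append(
            [
                {
                    "C": h.C,
                    "gamma": h.gamma,
                    "subspace": list(map(int, h.subspace)),
                    "epsilon": h.epsilon,
                    "beta": h.beta,
                    "platt_A": None if h.calibration is None else h.calibration.A,
                    "platt_B": None if h.calibration is None else h.calibration.B,
                    "scale_mean": None
                    if h.scale_mean is None
                    else list(map(float, h.scale_mean)),
                    "scale_sd": None
                    if h.scale_sd is None
                    else list(map(float, h.scale_sd)),
                }
                for h in inc
            ]
        )
    payload = {
        "increments": manifest,
        "history": model.history,
        "calibration": None
        if model.calibration is None
        else {"A": model.calibration.A, "B": model.calibration.B},
    }
    (directory / "manifest.json").write_text(json.dumps(payload, indent=2))


def load_model(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    payload = json.loads((directory / "manifest.json").read_text())
    model = EnsembleModel(history=payload["history"])
    for i, inc in enumerate(payload["increments"]):
        hyps = []
        for j, rec in enumerate(inc):
            with open(directory / f"hypothesis_{i:03d}_{j:03d}.pkl", "rb") as fh:
                svm = pickle.load(fh)
            cal = (
                None
                if rec["platt_A"] is None
                else PlattCalibration(A=rec["platt_A"], B=rec["platt_B"])
            )
            hyps.append(
                WeakHypothesis(
                    model=svm,
                    C=rec["C"],
                    gamma=rec["gamma"],
                    subspace=np.asarray(rec["subspace"], dtype=int),
                    epsilon=rec["epsilon"],
                    beta=rec["beta"],
                    calibration=cal,
                    scale_mean=None
                    if rec.get("scale_mean") is None
                    else np.asarray(rec["scale_mean"]),
                    scale_sd=None
                    if rec.get("scale_sd") is None
                    else np.asarray(rec["scale_sd"]),
                )
            )
        model.increments.append(hyps)
    if payload["calibration"] is not None:
        model.calibration = PlattCalibration(**payload["calibration"])
    return model
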