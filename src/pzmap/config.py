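"""Flat key-value run configuration shared by the CLI subcommands.

Every tunable of the pipeline lives in one flat (non-nested) document so
that two runs can be diffed line by line.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run.

    Defaults are desk-scale: a small six-slice phantom, a stratified pixel
    subsample per slice and a short ensemble schedule, so a complete run
    finishes in minutes on one CPU.  Every stochastic step derives its
    stream from ``seed``.
    """

    seed: int = 0
    out_dir: str = "pzmap_run"

    # phantom
    n_slices: int = 6
    height: int = 64
    width: int = 64
    n_lesions_per_slice: int = 2
    lesion_radius_min: float = 4.0
    lesion_radius_max: float = 7.0
    background_mean: float = 100.0
    lesion_mean: float = 130.0
    background_sigma: float = 20.0
    lesion_sigma: float = 20.0
    background_smoothing_sigma: float = 0.6
    lesion_smoothing_sigma: float = 1.8
    bias_amplitude: float = 0.1
    slice_gain_sigma: float = 0.05
    slice_offset_sigma: float = 5.0
    label_noise_fraction: float = 0.0
    min_lesion_area: int = 25

    # standardization
    s1: float = 1.0
    s2: float = 4095.0

    # features
    n_levels: int = 32
    first_order_window: int = 5
    ngtdm_window: int = 9
    ngtdm_nbhd: int = 3
    ngldm_window: int = 9
    ngldm_d: int = 1
    ngldm_a: float = 10.0
    lpq_k: int = 3
    lpq_n_angles: int = 36
    lpq_hist_window: int = 7
    include_functional: bool = True
    include_texture: bool = True

    # selection
    spearman_threshold: float = 0.60
    run_forward_selection: bool = False
    sfs_delta: float = 0.005
    sfs_patience: int = 1

    # training
    clean_outliers: bool = False
    balance_classes: bool = True
    oneclass_nu: float = 0.05
    T: int = 5
    max_retries: int = 10
    inner_cv_folds: int = 3
    optimize_every: str = "increment"
    max_pixels_per_slice: int = 400

    # evaluation
    outer_k: int = 3
    threshold_step: float = 0.05

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {ln}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
        return cls.from_dict(kv)

    @classmethod
    def from_dict(cls, kv: dict) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(kv) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        parsed = {}
        for k, v in kv.items():
            if isinstance(v, str):
                ftype = fields[k].type
                if ftype == "bool":
                    parsed[k] = v.lower() in {"1", "true", "yes"}
                elif ftype == "int":
                    parsed[k] = int(v)
                elif ftype == "float":
                    parsed[k] = float(v)
                else:
                    parsed[k] = v
            else:
                parsed[k] = v
        return cls(**parsed)
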