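"""File I/O: TIFF stacks with voxel metadata, trace CSVs, configuration.

Stacks are multi-page TIFFs in ImageJ layout with the in-plane resolution
in the TIFF resolution tags and the z spacing in the ImageJ metadata;
phantom ground truth travels in a JSON sidecar.  Traces are plain CSVs
with one row per sample (time_s, force_uN, position_um, annotation), the
annotation column carrying the step windows as contiguous runs of
"kind:value" labels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import ForceTrace, ImageStack, StepAnnotation
from .phantom import GroundTruth

__all__ = [
    "write_stack",
    "read_stack",
    "read_ground_truth",
    "write_trace",
    "read_trace",
    "PipelineConfig",
]


def _truth_path(path: Path) -> Path:
    return path.with_suffix(".truth.json")


def write_stack(
    stack: ImageStack, path: str | Path, ground_truth: Optional[GroundTruth] = None
) -> Path:
    """Write a stack as an ImageJ-layout multi-page TIFF (float32).

    Voxel sizes go into the resolution tags (pixels per micrometre) and
    the ImageJ ``spacing`` field; ground truth, when given, is written to
    a ``.truth.json`` sidecar next to the TIFF.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        imagej=True,
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata={"spacing": stack.z_step_um, "unit": "um", "axes": "ZYX"},
    )
    if ground_truth is not None:
        _truth_path(path).write_text(
            json.dumps(ground_truth.to_dict(), indent=2, sort_keys=True)
        )
    return path


def read_stack(
    path: str | Path,
    pixel_size_um: Optional[float] = None,
    z_step_um: Optional[float] = None,
) -> ImageStack:
    """Read a multi-page TIFF; explicit voxel sizes override the metadata.

    Voxel sizes come from the TIFF resolution tags / ImageJ metadata when
    present; arguments take precedence.  If a size is available from
    neither source, an error is raised — never a silent default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        meta_px = meta_dz = None
        page = tf.pages[0]
        if "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if num:
                meta_px = den / num
        ij = tf.imagej_metadata or {}
        if "spacing" in ij:
            meta_dz = float(ij["spacing"])
    if data.ndim == 2:
        data = data[None]
    px = pixel_size_um if pixel_size_um is not None else meta_px
    dz = z_step_um if z_step_um is not None else meta_dz
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata and none given")
    if dz is None:
        raise ValueError(f"{path}: no z step in metadata and none given")
    return ImageStack(data, pixel_size_um=float(px), z_step_um=float(dz))


def read_ground_truth(stack_path: str | Path) -> GroundTruth:
    """Load the ground-truth sidecar written next to a phantom TIFF."""
    d = json.loads(_truth_path(Path(stack_path)).read_text())
    d["dislocation_coords"] = [tuple(c) for c in d["dislocation_coords"]]
    return GroundTruth(**d)


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def write_trace(trace: ForceTrace, path: str | Path) -> Path:
    """Write a force trace as CSV (time_s, force_uN, position_um, annotation)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    label = np.full(len(trace.time_s), "", dtype=object)
    for i, a in enumerate(trace.annotations):
        sel = (trace.time_s >= a.start_s) & (trace.time_s < a.end_s)
        # the index keeps consecutive steps of equal value distinguishable
        label[sel] = f"{a.kind}:{a.value:g}:{i}"
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "force_uN": trace.force_un,
            "position_um": trace.position_um
            if trace.position_um is not None
            else np.full(len(trace.time_s), np.nan),
            "annotation": label,
        }
    )
    df.to_csv(path, index=False, float_format="%.8g", na_rep="nan")
    return path


def read_trace(path: str | Path) -> ForceTrace:
    """Read a trace CSV, rebuilding step annotations from the label runs."""
    df = pd.read_csv(path, keep_default_na=False, na_values=["nan"])
    t = df["time_s"].to_numpy(dtype=float)
    f = df["force_uN"].to_numpy(dtype=float)
    pos = df["position_um"].to_numpy(dtype=float) if "position_um" in df else None
    if pos is not None and np.all(np.isnan(pos)):
        pos = None
    annotations: list[StepAnnotation] = []
    if "annotation" in df:
        labels = df["annotation"].astype(str).to_numpy()
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                lab = labels[start]
                if lab and lab != "nan":
                    kind, val = lab.split(":")[:2]
                    annotations.append(
                        StepAnnotation(kind, float(val), t[start], t[i - 1] + dt)
                    )
                start = i
    return ForceTrace(t, f, position_um=pos, annotations=annotations)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; defaults match the analysis defaults."""

    stacks: list[str] = field(default_factory=list)
    traces: list[str] = field(default_factory=list)
    output_dir: str = "results"
    # morphometry
    scale_um: Optional[float] = None  # default: SL/4, decided per fiber
    energy_quantile: float = 0.10
    wavelet_denoise: bool = False
    n_scales: int = 4
    threshold_k: float = 3.0
    # geometry
    threshold_frac: float = 0.10
    # mechanics
    spike_gate_sigmas: float = 5.0
    quiet_fraction: float = 0.20
    selection_margin: float = 0.05
    # calibration
    calibration_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("cas", "pca50"), ("vd", "pca50")]
    )
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.energy_quantile < 1:
            raise ValueError("energy_quantile must be in [0, 1)")
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in (0, 1)")
        if self.scale_um is not None and self.scale_um <= 0:
            raise ValueError("scale_um must be positive")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if not 0 < self.quiet_fraction <= 1:
            raise ValueError("quiet_fraction must be in (0, 1]")
        for p in self.stacks + self.traces:
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "calibration_pairs" in data:
            data["calibration_pairs"] = [tuple(p) for p in data["calibration_pairs"]]
        return cls(**data)

    def config_hash(self) -> str:
        """Stable hash of the analysis parameters, embedded in every output.

        Path fields are excluded so the hash identifies the analysis, not
        where its inputs happen to live; file names still appear in the
        per-fiber table.
        """
        params = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("stacks", "traces", "output_dir")
        }
        canon = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
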