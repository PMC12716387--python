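"""Readers, writers, configuration and QC artifacts.

Slice stacks live on disk as folders of numbered grayscale TIFF or PNG
images (the order is taken from the numeric part of the filename, not the
lexicographic order). Results are written as plain CSV — per-slice counts
and per-specimen volume summaries — plus optional color QC overlays and a
JSON run manifest recording the configuration, seed and package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .slice_seg import SegConfig
from .stack_proc import SliceSeries, VolumeSummary

__all__ = [
    "RunConfig",
    "read_slice_stack",
    "write_slice_stack",
    "write_truth_csv",
    "write_series_csv",
    "read_series_csv",
    "write_outputs",
]

_NUM_RE = re.compile(r"(\d+)(?!.*\d)")  # last run of digits in the stem

# Overlay colors (RGB): cuticle amber, interior teal.
_CUTICLE_RGB = (230, 159, 0)
_INTERIOR_RGB = (0, 158, 115)


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs, mirroring the CLI flags."""

    input_dirs: list[str] = dataclasses.field(default_factory=list)
    output_dir: str = "."
    seg: SegConfig = dataclasses.field(default_factory=SegConfig)
    specimen_id: str = "specimen"
    caste: str | None = None
    magnification: int | None = None
    pixel_size_um: float | None = None
    median_window: int = 5
    stitch_min_overlap: int = 3
    overlay_every: int = 50
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg_fields = {f.name for f in dataclasses.fields(SegConfig)}
        seg_kwargs = {k: raw.pop(k) for k in list(raw) if k in seg_fields}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(seg=SegConfig(**seg_kwargs), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _numeric_key(path: Path) -> int:
    m = _NUM_RE.search(path.stem)
    if not m:
        raise ValueError(f"slice filename {path.name!r} has no numeric index")
    return int(m.group(1))


def read_slice_stack(folder: str | Path) -> tuple[np.ndarray, dict]:
    """Read a folder of numbered TIFF/PNG slices into a (nz, ny, nx) array.

    Slices are ordered by the last number in the filename. All slices must
    share dimensions and bit depth. Returns the stack and inferred metadata
    (n_slices, shape, dtype).
    """
    import imageio.v3 as iio
    import tifffile

    folder = Path(folder)
    paths = sorted(
        [p for p in folder.iterdir()
         if p.suffix.lower() in (".tif", ".tiff", ".png")],
        key=_numeric_key,
    ) if folder.is_dir() else []
    if not folder.is_dir():
        raise FileNotFoundError(f"{folder} is not a directory")
    if not paths:
        raise ValueError(f"no TIFF/PNG slices found in {folder}")
    slices = []
    for p in paths:
        if p.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(p)
        else:
            arr = iio.imread(p)
        if arr.ndim == 3:  # RGB(A) PNG: accept if gray-encoded
            if not np.all(arr[..., 0] == arr[..., 1]):
                raise ValueError(f"{p.name} is not grayscale")
            arr = arr[..., 0]
        slices.append(arr)
    shapes = {s.shape for s in slices}
    dtypes = {s.dtype for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"mixed slice dimensions: {sorted(map(str, shapes))}")
    if len(dtypes) > 1:
        raise ValueError(f"mixed bit depths: {sorted(map(str, dtypes))}")
    stack = np.stack(slices)
    meta = {"n_slices": stack.shape[0], "shape": stack.shape,
            "dtype": str(stack.dtype)}
    return stack, meta


def write_slice_stack(stack: np.ndarray, folder: str | Path,
                      prefix: str = "slice") -> list[Path]:
    """Write a stack as numbered 16-bit grayscale TIFF slices."""
    import tifffile

    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    out = []
    data = stack.astype(np.uint16, copy=False)
    width = max(4, len(str(len(stack))))
    for i, sl in enumerate(data):
        p = folder / f"{prefix}{i:0{width}d}.tif"
        tifffile.imwrite(p, sl)
        out.append(p)
    return out


def write_truth_csv(truth, path: str | Path) -> Path:
    """Write per-slice ground-truth counts of a phantom as CSV."""
    path = Path(path)
    pd.DataFrame(
        {
            "slice_index": np.arange(len(truth.cuticle_counts)),
            "cuticle_px": truth.cuticle_counts,
            "body_px": truth.body_counts,
        }
    ).to_csv(path, index=False)
    return path


def write_series_csv(series: SliceSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "slice_index": np.arange(len(series)),
            "cuticle_px": series.cuticle_px,
            "body_px": series.body_px,
            "flags": series.flags,
        }
    ).to_csv(path, index=False, float_format="%.12g")
    return path


def read_series_csv(path: str | Path) -> SliceSeries:
    df = pd.read_csv(path, keep_default_na=False)
    return SliceSeries(
        cuticle_px=df["cuticle_px"].to_numpy(dtype=float),
        body_px=df["body_px"].to_numpy(dtype=float),
        flags=[str(f) for f in df["flags"]],
    )


def _overlay_png(label_mask: np.ndarray, path: Path) -> None:
    import imageio.v3 as iio

    rgb = np.zeros(label_mask.shape + (3,), dtype=np.uint8)
    rgb[label_mask == 1] = _CUTICLE_RGB
    rgb[label_mask == 2] = _INTERIOR_RGB
    iio.imwrite(path, rgb)


def write_outputs(
    series: SliceSeries,
    summary: VolumeSummary,
    cfg: RunConfig,
    stack: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write counts CSV, summary CSV, QC overlays and a JSON run manifest.

    Overlays are re-segmented label masks of every ``cfg.overlay_every``-th
    slice (requires ``stack``). Volumes are serialized with 15 significant
    digits so the CSV round-trips.
    """
    from . import __version__
    from .slice_seg import SliceImage, segment_slice

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["counts"] = write_series_csv(series, outdir / "counts.csv")
    sdf = pd.DataFrame(
        [
            {
                "specimen_id": summary.specimen_id,
                "caste": summary.caste or "",
                "pixel_size_um": summary.pixel_size_um,
                "cuticle_volume_um3": summary.cuticle_volume_um3,
                "body_volume_um3": summary.body_volume_um3,
                "ratio": summary.ratio,
                "n_slices": summary.n_slices,
            }
        ]
    )
    paths["summary"] = outdir / "summary.csv"
    sdf.to_csv(paths["summary"], index=False, float_format="%.15g")
    if stack is not None and cfg.overlay_every > 0:
        qc = outdir / "qc"
        qc.mkdir(exist_ok=True)
        for i in range(0, len(stack), cfg.overlay_every):
            res = segment_slice(
                SliceImage(stack[i], summary.pixel_size_um), cfg.seg, keep_mask=True
            )
            _overlay_png(res.label_mask, qc / f"overlay{i:05d}.png")
            paths[f"overlay{i}"] = qc / f"overlay{i:05d}.png"
    manifest = {
        "config": _jsonable(cfg.to_dict()),
        "seed": cfg.seed,
        "versions": {"cuticlevol": __version__, "numpy": np.__version__},
        "summary_sha256": hashlib.sha256(
            sdf.to_csv(index=False, float_format="%.15g").encode()
        ).hexdigest(),
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.dtype):
        return str(obj)
    return obj
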