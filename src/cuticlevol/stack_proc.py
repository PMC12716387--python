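"""Stack-level processing: serial slice segmentation, rolling-median error
correction, and voxel volume integration.

A tomogram is processed as an ordered series of independent 2D slices; the
per-slice cuticle/body pixel counts form two lists that vary smoothly along
the body axis. Punctual segmentation failures show up as isolated spikes in
those lists and are removed by a centered rolling median. Total volumes are
the summed counts times the cubed pixel size (voxels are isotropic: slice
thickness equals pixel size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .slice_seg import SegConfig, SliceImage, segment_slice

__all__ = [
    "MAGNIFICATION_PIXEL_SIZE_UM",
    "ScanMeta",
    "SliceSeries",
    "VolumeSummary",
    "pixel_size_from_magnification",
    "segment_stack",
    "rolling_median_correct",
    "integrate_volumes",
]

logger = logging.getLogger("cuticlevol")

# Effective detector pixel size by scan magnification.
MAGNIFICATION_PIXEL_SIZE_UM = {10: 1.22, 5: 2.44, 2: 6.11}


def pixel_size_from_magnification(mag: int | float) -> float:
    """Map a scan magnification (10x, 5x or 2x) to its pixel size in um."""
    try:
        return MAGNIFICATION_PIXEL_SIZE_UM[int(mag)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(
            f"unknown magnification {mag!r}; known values are "
            f"{sorted(MAGNIFICATION_PIXEL_SIZE_UM)} - pass an explicit pixel size instead"
        ) from None


@dataclass
class ScanMeta:
    """Scan-level metadata resolving the physical pixel size.

    Exactly one of ``magnification`` / ``pixel_size_um`` must be given.
    """

    specimen_id: str = "specimen"
    caste: str | None = None
    magnification: int | None = None
    pixel_size_um: float | None = None
    n_slices: int | None = None

    def __post_init__(self) -> None:
        if (self.magnification is None) == (self.pixel_size_um is None):
            raise ValueError("give exactly one of magnification or pixel_size_um")
        if self.pixel_size_um is None:
            self.pixel_size_um = pixel_size_from_magnification(self.magnification)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")


@dataclass
class SliceSeries:
    """Ordered per-slice (cuticle_px, body_px) counts with QC flags.

    Counts may be non-integral after rolling-median correction.
    """

    cuticle_px: np.ndarray
    body_px: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cuticle_px = np.asarray(self.cuticle_px, dtype=float)
        self.body_px = np.asarray(self.body_px, dtype=float)
        if self.cuticle_px.shape != self.body_px.shape or self.cuticle_px.ndim != 1:
            raise ValueError("cuticle and body count lists must be equal-length 1D")
        if not self.flags:
            self.flags = [""] * len(self.cuticle_px)
        if len(self.flags) != len(self.cuticle_px):
            raise ValueError("one flag string per slice required")
        if np.any(self.cuticle_px < 0) or np.any(self.body_px < 0):
            raise ValueError("counts must be >= 0")
        if np.any(self.cuticle_px > self.body_px + 1e-9):
            raise ValueError("invariant violated: cuticle_px > body_px on some slice")

    def __len__(self) -> int:
        return len(self.cuticle_px)

    def copy(self) -> "SliceSeries":
        return SliceSeries(
            cuticle_px=self.cuticle_px.copy(),
            body_px=self.body_px.copy(),
            flags=list(self.flags),
        )

    def slice(self, start: int, stop: int) -> "SliceSeries":
        return SliceSeries(
            cuticle_px=self.cuticle_px[start:stop],
            body_px=self.body_px[start:stop],
            flags=self.flags[start:stop],
        )


@dataclass
class VolumeSummary:
    """Total cuticle and body volume of one specimen, in cubic micrometres."""

    cuticle_volume_um3: float
    body_volume_um3: float
    n_slices: int
    pixel_size_um: float
    specimen_id: str = "specimen"
    caste: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.cuticle_volume_um3 <= self.body_volume_um3 + 1e-9):
            raise ValueError("invariant violated: need 0 <= V_cuticle <= V_body")

    @property
    def ratio(self) -> float:
        """Cuticle fraction of total body volume, in [0, 1]."""
        if self.body_volume_um3 == 0:
            return 0.0
        return self.cuticle_volume_um3 / self.body_volume_um3


def segment_stack(
    stack: np.ndarray | list[np.ndarray],
    cfg: SegConfig = SegConfig(),
    pixel_size_um: float = 1.0,
) -> SliceSeries:
    """Segment every slice of a stack in order.

    ``stack`` is a (nz, ny, nx) array or list of 2D arrays. Slices that
    fail to segment are recorded as zero counts with an ``error`` flag and
    are expected to be repaired by :func:`rolling_median_correct`.

    All slices of one tomogram share a gray scale, so the contrast stretch
    uses the stack-wide intensity range, and when no explicit ``t_lo`` is
    configured the band threshold is resolved once from a stack-wide sample
    rather than per slice (single slices near the specimen's poles lack the
    soft-tissue class and would threshold inconsistently).
    """
    from dataclasses import replace

    from .slice_seg import band_lower_threshold, detect_and_crop_vial, enhance_slice

    n = len(stack)
    if n == 0:
        raise ValueError("empty stack")
    arr = stack if isinstance(stack, np.ndarray) else np.stack(stack)
    stretch = (float(arr.min()), float(arr.max()))
    sample_indices = np.linspace(0, n - 1, num=min(n, 9), dtype=int)
    cropped_samples: list[np.ndarray] = []
    if cfg.vial_detect:
        # The container rim is not specimen: the shared contrast stretch must
        # span specimen intensities only, or a bright rim compresses the
        # tissue/cuticle contrast and biases the resolved threshold.
        lo, hi = np.inf, -np.inf
        for i in sample_indices:
            si, _ = detect_and_crop_vial(SliceImage(arr[i], pixel_size_um), cfg)
            cropped_samples.append(si.data)
            lo = min(lo, float(si.data.min()))
            hi = max(hi, float(si.data.max()))
        if lo < hi:
            stretch = (lo, hi)
    else:
        cropped_samples = [arr[i] for i in sample_indices]
    if cfg.t_lo is None and stretch[0] < stretch[1]:
        bit_max = SliceImage(arr[0], pixel_size_um).bit_max
        t_hi = cfg.t_hi if cfg.t_hi is not None else float(bit_max)
        # Resolve the band once for the whole scan, from representative
        # slices prepared with the shared stretch and the vial cropped so
        # the rim class cannot skew the intensity clustering.
        sample_parts = []
        for data in cropped_samples:
            si = SliceImage(data, pixel_size_um)
            if cfg.enhance:
                si = enhance_slice(si, cfg, stretch_range=stretch)
            sample_parts.append(si.data.ravel())
        sample = np.concatenate(sample_parts)
        if sample.size > 2_000_000:
            sample = sample[:: sample.size // 2_000_000 + 1]
        cfg = replace(cfg, t_lo=band_lower_threshold(sample, t_hi))
    cut = np.zeros(n, dtype=float)
    body = np.zeros(n, dtype=float)
    flags: list[str] = []
    for i in range(n):
        try:
            res = segment_slice(
                SliceImage(stack[i], pixel_size_um),
                cfg,
                keep_mask=False,
                stretch_range=stretch,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("slice %d failed to segment: %s", i, exc)
            flags.append("error")
            continue
        cut[i], body[i] = res.cuticle_px, res.body_px
        f = []
        if res.vial_detected:
            f.append("vial")
        if res.linking_used:
            f.append("linked")
        if res.orphans_closed:
            f.append("orphan_closed")
        if res.hull_fallback:
            f.append("hull_fallback")
        if res.body_px == 0:
            f.append("empty")
            logger.debug("slice %d segmented to zero counts", i)
        flags.append("+".join(f))
    return SliceSeries(cuticle_px=cut, body_px=body, flags=flags)


def rolling_median_correct(
    series: SliceSeries,
    window: int = 5,
    mode: str = "repair",
    min_rel_dev: float = 0.2,
) -> SliceSeries:
    """Rolling-median correction of punctual per-slice errors.

    Counts extracted from consecutive slices vary almost linearly, so a
    segmentation failure confined to fewer than ``ceil(window / 2)``
    consecutive slices, flanked by good slices, stands out against the
    local window median and can be repaired without touching good data.

    ``mode="repair"`` (default): Hampel-style correction — a count is an
    outlier when it deviates from its centered-window median by more than
    3 x 1.4826 x the window's median absolute deviation AND by more than
    ``min_rel_dev`` of the local median. Punctual segmentation failures
    gain or lose whole contours, so they deviate at contour scale (tens to
    hundreds of percent); voxelization ripple on small cross-sections can
    reach ~10% of the local count with a near-zero window MAD, so the
    relative floor separates the two regimes. Deviations below the floor
    are treated as legitimate measurement, never repaired. Outlier runs are
    replaced by linear interpolation between the nearest non-outlier
    slices, i.e. adjusted to fit the continuity of the list. Clean series
    pass through unchanged, and isolated spikes narrower than half the
    window are removed exactly wherever the underlying series is locally
    linear.

    ``mode="median"``: the textbook centered rolling median (window
    truncated at the series ends, no padding). Simpler, but it also
    perturbs clean curved series, so it is not the default.

    Both lists are corrected independently; the cuticle <= body invariant
    is re-asserted by clamping. ``window`` must be odd and >= 3.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if mode == "median":
        import pandas as pd

        cut = (
            pd.Series(series.cuticle_px)
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        body = (
            pd.Series(series.body_px)
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    elif mode == "repair":
        cut = _hampel_repair(series.cuticle_px, window, min_rel_dev=min_rel_dev)
        body = _hampel_repair(series.body_px, window, min_rel_dev=min_rel_dev)
    else:
        raise ValueError("mode must be 'repair' or 'median'")
    cut = np.minimum(cut, body)
    return SliceSeries(cuticle_px=cut, body_px=body, flags=list(series.flags))


def _hampel_repair(
    values: np.ndarray,
    window: int,
    n_sigmas: float = 3.0,
    min_rel_dev: float = 0.2,
) -> np.ndarray:
    """Replace Hampel outliers by linear interpolation from clean neighbors."""
    import pandas as pd

    v = np.asarray(values, dtype=float)
    s = pd.Series(v)
    roll = s.rolling(window, center=True, min_periods=1)
    med = roll.median().to_numpy()
    dev = np.abs(v - med)
    # Per-window MAD: median of |window - window median| within each window
    # (a rolling median of the deviation series would itself be contaminated
    # by the spikes it is meant to expose).
    mad = roll.apply(
        lambda w: np.median(np.abs(w - np.median(w))), raw=True
    ).to_numpy()
    outlier = (dev > n_sigmas * 1.4826 * mad + 1e-9) & (
        dev > min_rel_dev * np.maximum(np.abs(med), 1.0)
    )
    if not outlier.any():
        return v.copy()
    idx = np.arange(len(v))
    clean = ~outlier
    if not clean.any():
        return med  # every slice flagged: fall back to the window medians
    out = v.copy()
    out[outlier] = np.interp(idx[outlier], idx[clean], v[clean])
    return out


def integrate_volumes(
    series: SliceSeries,
    meta: ScanMeta,
) -> VolumeSummary:
    """Sum per-slice counts and convert to volumes: V = sum(counts) * p**3."""
    if len(series) == 0:
        raise ValueError("empty series")
    p3 = float(meta.pixel_size_um) ** 3
    return VolumeSummary(
        cuticle_volume_um3=float(series.cuticle_px.sum()) * p3,
        body_volume_um3=float(series.body_px.sum()) * p3,
        n_slices=len(series),
        pixel_size_um=float(meta.pixel_size_um),
        specimen_id=meta.specimen_id,
        caste=meta.caste,
    )
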