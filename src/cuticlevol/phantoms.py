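"""Synthetic tomogram phantoms with voxel-exact ground truth.

Microtomography scans of insects are expensive to acquire and have no
pixel-level ground truth, so every stage of the segmentation pipeline is
validated here against *phantoms*: synthetic slice stacks built from
analytic shapes (hollow spheres/ellipsoids, fused three-lobed "ant-like"
bodies) for which the cuticle and body masks are known exactly.

Voxel membership is decided by a voxel-center-inside test, which keeps the
ground truth integer-exact: a voxel belongs to the shell iff its center
lies between the inner and outer ellipsoid surfaces. Voxels are isotropic
(slice thickness equals pixel size), so a volume is ``count * pixel_size**3``.

The generators cover the imaging situations the pipeline must survive:

* a bright vial rim around the specimen (:func:`embed_in_vial`),
* detector noise and optics blur (:func:`degrade`),
* specimens taller than the field of view, scanned as overlapping height
  steps (:func:`split_height_steps`),
* isolated per-slice segmentation failures (:func:`inject_spikes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "DEFAULT_NOISE_SD",
    "DEFAULT_BLUR_SIGMA",
    "make_hollow_shell_stack",
    "make_ant_like_stack",
    "embed_in_vial",
    "degrade",
    "split_height_steps",
    "inject_spikes",
]

# Documented default degradation level: ~4% of the shell/interior intensity
# gap as Gaussian noise sd, plus a sub-voxel optics blur. The pipeline's
# robustness envelope (volumes within 2% of truth) is stated for this level.
DEFAULT_NOISE_SD = 800.0
DEFAULT_BLUR_SIGMA = 0.8

# Default 16-bit gray levels: ethanol background, soft tissue, cuticle.
BACKGROUND_LEVEL = 5000
INTERIOR_LEVEL = 12000
SHELL_LEVEL = 30000


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic specimen.

    Semi-axes and stack shape are ordered (z, y, x) in voxels; z is the
    stack axis. ``gap_fraction`` removes that angular fraction of the shell
    (in the x-y plane) to emulate unfused, open exoskeleton cross-sections.
    """

    kind: str = "hollow_sphere"  # hollow_sphere | hollow_ellipsoid | ant_like
    semi_axes: tuple[float, float, float] = (20.0, 20.0, 20.0)
    shell_thickness: float = 3.0
    shell_intensity: int = SHELL_LEVEL
    interior_intensity: int = INTERIOR_LEVEL
    background_intensity: int = BACKGROUND_LEVEL
    gap_fraction: float = 0.0
    stack_shape: tuple[int, int, int] = (48, 96, 96)
    pixel_size_um: float = 2.44
    seed: int = 0
    dtype: np.dtype = np.dtype(np.uint16)

    def __post_init__(self) -> None:
        if self.shell_thickness < 1:
            raise ValueError("shell thickness must be >= 1 voxel")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap fraction must be in [0, 1)")
        hi = np.iinfo(self.dtype).max
        for name, v in (
            ("shell", self.shell_intensity),
            ("interior", self.interior_intensity),
            ("background", self.background_intensity),
        ):
            if not (0 <= v <= hi):
                raise ValueError(f"{name} intensity {v} outside bit depth 0..{hi}")
        for ax, a, n in zip("zyx", self.semi_axes, self.stack_shape):
            if 2 * a >= n:
                raise ValueError(
                    f"shape does not fit inside stack along axis {ax}: "
                    f"semi-axis {a} vs extent {n}"
                )


@dataclass
class PhantomTruth:
    """Voxel-exact ground truth for a phantom stack.

    ``body_approximate`` is set when an opened (gap > 0) lobe's body mask is
    defined as the per-slice convex closure of its shell cross-section — the
    intended recovery, not an analytic surface.
    """

    cuticle_mask: np.ndarray  # (nz, ny, nx) bool
    body_mask: np.ndarray  # (nz, ny, nx) bool
    body_approximate: bool = False

    def __post_init__(self) -> None:
        if np.any(self.cuticle_mask & ~self.body_mask):
            raise ValueError("truth invariant violated: cuticle not within body")

    @property
    def cuticle_counts(self) -> np.ndarray:
        return self.cuticle_mask.sum(axis=(1, 2))

    @property
    def body_counts(self) -> np.ndarray:
        return self.body_mask.sum(axis=(1, 2))

    @property
    def total_cuticle(self) -> int:
        return int(self.cuticle_mask.sum())

    @property
    def total_body(self) -> int:
        return int(self.body_mask.sum())


def _voxel_centers(stack_shape: tuple[int, int, int]):
    nz, ny, nx = stack_shape
    return np.meshgrid(
        np.arange(nz, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nx, dtype=float),
        indexing="ij",
        sparse=True,
    )


def _ellipsoid_masks(
    spec_shape: tuple[int, int, int],
    center: Sequence[float],
    semi_axes: Sequence[float],
    thickness: float,
    gap_fraction: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (shell, outer) boolean masks by the voxel-center-inside test."""
    zz, yy, xx = _voxel_centers(spec_shape)
    dz, dy, dx = (zz - center[0], yy - center[1], xx - center[2])
    a, b, c = semi_axes
    outer = (dz / a) ** 2 + (dy / b) ** 2 + (dx / c) ** 2 <= 1.0
    ai, bi, ci = (max(s - thickness, 0.0) for s in semi_axes)
    if min(ai, bi, ci) <= 0:
        inner = np.zeros(spec_shape, dtype=bool)
    else:
        inner = (dz / ai) ** 2 + (dy / bi) ** 2 + (dx / ci) ** 2 < 1.0
    shell = outer & ~inner
    if gap_fraction > 0:
        # Remove an angular wedge in the x-y plane, centered on +x.
        theta = np.arctan2(dy, dx)  # broadcasts to full shape
        half = np.pi * gap_fraction
        wedge = np.abs(theta) <= half
        shell = shell & ~wedge
    return shell, outer


def _render(spec: PhantomSpec, cuticle: np.ndarray, body: np.ndarray) -> np.ndarray:
    img = np.full(spec.stack_shape, spec.background_intensity, dtype=spec.dtype)
    img[body] = spec.interior_intensity
    img[cuticle] = spec.shell_intensity
    return img


def make_hollow_shell_stack(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Noiseless hollow sphere/ellipsoid stack with exact truth.

    The cuticle mask is the closed shell; the body mask is shell plus
    interior. ``spec.gap_fraction`` must be 0 (use the ant-like generator
    for open shells).
    """
    if spec.kind not in ("hollow_sphere", "hollow_ellipsoid"):
        raise ValueError(f"unexpected kind {spec.kind!r} for a hollow shell stack")
    if spec.gap_fraction != 0:
        raise ValueError("hollow shell phantoms are closed; use ant_like for gaps")
    center = [(n - 1) / 2.0 for n in spec.stack_shape]
    axes = spec.semi_axes
    if spec.kind == "hollow_sphere" and len(set(axes)) != 1:
        axes = (axes[0],) * 3
    shell, outer = _ellipsoid_masks(
        spec.stack_shape, center, axes, spec.shell_thickness
    )
    truth = PhantomTruth(cuticle_mask=shell, body_mask=outer)
    return _render(spec, shell, outer), truth


def make_ant_like_stack(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Three fused hollow lobes (head / mesosoma / gaster) along the stack axis.

    A minimal lobed-body geometry: three overlapping hollow ellipsoids whose
    union exercises multi-contour slices and lobe fusion. With
    ``gap_fraction > 0`` the last (gaster) lobe's shell is opened by an
    angular wedge, emulating unfused gaster segments; its ground-truth body
    is then the per-slice convex closure of the remaining shell arc and the
    truth is flagged approximate.
    """
    if spec.kind != "ant_like":
        raise ValueError("spec.kind must be 'ant_like'")
    nz, ny, nx = spec.stack_shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    a, b, c = spec.semi_axes  # per-lobe nominal semi-axes (z, y, x)
    # Lobes are co-axial along z. Consecutive lobes overlap by one shell
    # thickness, so shells fuse while each inner cavity stays tangent to the
    # neighboring lobe's outer surface — no shell wall crosses another
    # lobe's cavity, keeping the per-slice ground truth exact.
    scale = [0.7, 1.0, 1.15]  # head smaller, gaster larger
    z_semi = [a * s for s in scale]
    z0 = z_semi[0] + 1
    centers_z = [z0]
    for i in range(1, 3):
        centers_z.append(
            centers_z[-1] + z_semi[i - 1] + z_semi[i] - spec.shell_thickness
        )
    total = centers_z[-1] + z_semi[-1]
    if total >= nz:
        raise ValueError(
            f"shape does not fit inside stack along axis z: body span {total:.1f} "
            f"vs extent {nz}"
        )
    smax = max(scale)
    if 2 * b * smax >= ny or 2 * c * smax >= nx:
        ax = "y" if 2 * b * smax >= ny else "x"
        raise ValueError(f"shape does not fit inside stack along axis {ax}")
    cuticle = np.zeros(spec.stack_shape, dtype=bool)
    body = np.zeros(spec.stack_shape, dtype=bool)
    gaster_shell = np.zeros(spec.stack_shape, dtype=bool)
    for i, (zc, s) in enumerate(zip(centers_z, scale)):
        gap = spec.gap_fraction if i == 2 else 0.0
        shell, outer = _ellipsoid_masks(
            spec.stack_shape,
            (zc, cy, cx),
            (a * s, b * s, c * s),
            spec.shell_thickness,
            gap_fraction=gap,
        )
        cuticle |= shell
        if i == 2 and gap > 0:
            gaster_shell = shell
        else:
            body |= outer
    approx = False
    if spec.gap_fraction > 0:
        from skimage.morphology import convex_hull_image

        for z in range(nz):
            if gaster_shell[z].any():
                body[z] |= convex_hull_image(gaster_shell[z])
        approx = True
    body |= cuticle
    truth = PhantomTruth(cuticle_mask=cuticle, body_mask=body, body_approximate=approx)
    return _render(spec, cuticle, body & ~cuticle), truth


def embed_in_vial(
    stack: np.ndarray,
    vial_radius: float,
    rim_intensity: int,
    rim_thickness: float = 3.0,
    background_intensity: int | None = None,
) -> np.ndarray:
    """Add a bright vial annulus (centered in frame) to every slice.

    Ground truth is unchanged: the rim is container, not specimen. Raises if
    any non-background voxel lies on or outside the rim's inner edge, i.e.
    the vial is too small to contain the specimen.
    """
    nz, ny, nx = stack.shape
    if vial_radius >= min(ny, nx) / 2.0:
        raise ValueError("vial radius must be smaller than the frame half-width")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(ny) - cy, np.arange(nx) - cx, indexing="ij")
    r = np.hypot(yy, xx)
    rim = (r <= vial_radius) & (r > vial_radius - rim_thickness)
    if background_intensity is None:
        # The most frequent gray level is the background by construction.
        background_intensity = int(np.bincount(stack.ravel()).argmax())
    specimen = stack != background_intensity
    outside = r > vial_radius - rim_thickness
    if np.any(specimen & outside[None, :, :]):
        raise ValueError("vial radius too small to contain the specimen")
    out = stack.copy()
    out[:, rim] = rim_intensity
    return out


def degrade(
    stack: np.ndarray,
    noise_sd: float = DEFAULT_NOISE_SD,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
    seed: int = 0,
) -> np.ndarray:
    """Additive Gaussian noise followed by per-slice Gaussian blur.

    Output is clipped to the input bit depth and rounded back to the input
    dtype; bitwise-reproducible under ``seed``.
    """
    if noise_sd < 0 or blur_sigma < 0:
        raise ValueError("noise_sd and blur_sigma must be >= 0")
    if noise_sd == 0 and blur_sigma == 0:
        return stack.copy()
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    out = stack.astype(np.float64)
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=stack.shape)
    if blur_sigma > 0:
        out = gaussian_filter(out, sigma=(0.0, blur_sigma, blur_sigma))
    info = np.iinfo(stack.dtype)
    return np.clip(np.rint(out), info.min, info.max).astype(stack.dtype)


def split_height_steps(
    stack: np.ndarray, n_steps: int, overlap_slices: int
) -> list[np.ndarray]:
    """Split a stack into ``n_steps`` height-step sub-stacks.

    Consecutive sub-stacks share exactly ``overlap_slices`` slices, as when
    a specimen taller than the field of view is scanned at several vertical
    positions. Concatenating the parts minus the overlaps reproduces the
    original stack.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if overlap_slices < 1:
        raise ValueError("overlap_slices must be >= 1")
    n = stack.shape[0]
    total = n + (n_steps - 1) * overlap_slices
    q, r = divmod(total, n_steps)
    lengths = [q + (1 if i < r else 0) for i in range(n_steps)]
    if overlap_slices >= min(lengths):
        raise ValueError("overlap must be shorter than every sub-stack")
    parts, start = [], 0
    for ln in lengths:
        parts.append(stack[start : start + ln])
        start += ln - overlap_slices
    return parts


def inject_spikes(
    series,
    positions: Sequence[int],
    magnitudes: Sequence[float],
    seed: int = 0,
    width: int = 1,
):
    """Corrupt a slice-count series with isolated multiplicative spikes.

    Emulates segmentation failures confined to a few consecutive slices,
    flanked by good slices. Returns ``(corrupted, clean)`` so the clean
    original can serve as oracle. ``magnitudes`` are multiplicative factors
    applied to both cuticle and body counts starting at each position for
    ``width`` slices.
    """
    from .stack_proc import SliceSeries

    if len(positions) != len(magnitudes):
        raise ValueError("positions and magnitudes must have equal length")
    n = len(series)
    for p in positions:
        if not (0 <= p <= n - width):
            raise ValueError(f"spike position {p} (width {width}) out of range 0..{n-1}")
    cut = series.cuticle_px.astype(float).copy()
    body = series.body_px.astype(float).copy()
    for p, m in zip(positions, magnitudes):
        cut[p : p + width] *= m
        body[p : p + width] *= m
    corrupted = SliceSeries(cuticle_px=cut, body_px=body, flags=list(series.flags))
    return corrupted, series.copy()
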