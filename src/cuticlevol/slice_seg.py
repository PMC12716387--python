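"""Single-slice cuticle/body segmentation by contour-hierarchy filtering.

The cuticle is the outermost, x-ray-dense tissue of an insect, so on any
tomogram slice it appears as the external boundary of the specimen. The
segmentation is a decision tree over the nesting hierarchy of thresholded
contours:

1. enhance the slice (contrast stretch + edge-preserving bilateral filter);
2. detect and crop the bright ethanol-vial rim, if present;
3. apply a band intensity threshold;
4. extract all boundary contours with their parent/child (hole) hierarchy;
5. keep only top-level external contours and their direct holes; drop
   deeper-nested contours and contours with perimeter below a cutoff
   (default 40 px);
6. close "orphan childless" contours — open shell cross-sections of unfused
   segments — by linking nearby arc endpoints or, failing that, by convex
   hull;
7. count cuticle pixels (external regions minus their hole interiors;
   boundary pixels count as cuticle) and body pixels (external regions with
   holes filled).

The hierarchy is represented mask-wise: an external node is a connected
foreground component; its holes are the connected components of its filled
interior minus the component. This makes the pixel counts exact and the
decision rules (depth, perimeter, solidity) unambiguous. Pixel indices are
0-based row-major; areas in px², perimeters in px (diagonal steps √2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import convex_hull_image

__all__ = [
    "SliceImage",
    "SegConfig",
    "ContourNode",
    "ContourTree",
    "SliceResult",
    "enhance_slice",
    "detect_and_crop_vial",
    "threshold_band",
    "extract_contour_tree",
    "filter_hierarchy",
    "close_orphans",
    "link_open_contours",
    "segment_slice",
]


@dataclass
class SliceImage:
    """One 2D grayscale tomogram section with its physical pixel size."""

    data: np.ndarray  # 2D integer grayscale
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("slice must be a non-empty 2D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")

    @property
    def bit_max(self) -> int:
        if np.issubdtype(self.data.dtype, np.integer):
            return int(np.iinfo(self.data.dtype).max)
        return 65535


@dataclass(frozen=True)
class SegConfig:
    """Tunable parameters of the slice decision tree.

    ``t_lo``/``t_hi`` bound the intensity band kept by the threshold; if
    ``t_lo`` is None it is chosen by Otsu's method on the (vial-cropped)
    slice, and ``t_hi`` defaults to the bit-depth maximum — the band is
    broad on purpose and meant to be adjusted per scan. ``min_perimeter``
    removes speckle contours (strict less-than). Orphan open shells are
    detected as external contours with no hole children and solidity below
    ``orphan_solidity_cutoff``.
    """

    t_lo: float | None = None
    t_hi: float | None = None
    min_perimeter: float = 40.0
    enhance: bool = True
    bilateral_sigma_spatial: float = 3.0
    bilateral_sigma_range_frac: float = 0.10
    vial_detect: bool = True
    vial_min_area_frac: float = 0.60
    vial_rim_margin: int = 3
    orphan_solidity_cutoff: float = 0.90
    linking: bool = True
    linking_max_gap: float = 10.0

    def __post_init__(self) -> None:
        if self.t_lo is not None and self.t_hi is not None and not self.t_lo < self.t_hi:
            raise ValueError("threshold band requires t_lo < t_hi")
        if self.min_perimeter < 0:
            raise ValueError("min_perimeter must be >= 0")
        if self.bilateral_sigma_spatial <= 0 or self.bilateral_sigma_range_frac <= 0:
            raise ValueError("bilateral sigmas must be > 0")


@dataclass
class ContourNode:
    """One contour of the hierarchy, carried with its pixel footprint.

    For an external node ``mask`` is the connected foreground component and
    ``filled`` its hole-filled region; for a hole node ``mask`` is the hole
    region itself. ``perimeter`` is the boundary arc length in pixel units,
    ``area`` the enclosed area in px².
    """

    kind: str  # "external" | "hole"
    mask: np.ndarray
    filled: np.ndarray | None = None
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    depth: int = 0
    perimeter: float = 0.0
    area: float = 0.0
    solidity: float = 1.0
    flags: set[str] = field(default_factory=set)

    def polygon(self) -> np.ndarray:
        """Closed boundary polygon (row, col) of this contour."""
        src = self.filled if self.kind == "external" else self.mask
        padded = np.pad(src, 1).astype(float)
        cs = measure.find_contours(padded, 0.5)
        if not cs:
            return np.empty((0, 2))
        return max(cs, key=len) - 1.0


@dataclass
class ContourTree:
    """All contours of a binary slice with parent/child nesting."""

    shape: tuple[int, int]
    nodes: list[ContourNode] = field(default_factory=list)

    def externals(self) -> list[int]:
        return [i for i, n in enumerate(self.nodes) if n.kind == "external"]

    def to_mask(self) -> np.ndarray:
        """Union of external component footprints (the foreground)."""
        out = np.zeros(self.shape, dtype=bool)
        for i in self.externals():
            out |= self.nodes[i].mask
        return out


@dataclass
class SliceResult:
    """Cuticle/body pixel counts and label mask for one slice.

    ``label_mask``: 0 background, 1 cuticle, 2 interior (body minus cuticle).
    """

    cuticle_px: int
    body_px: int
    label_mask: np.ndarray | None = None
    vial_detected: bool = False
    orphans_closed: bool = False
    linking_used: bool = False
    hull_fallback: bool = False

    def __post_init__(self) -> None:
        if self.cuticle_px > self.body_px:
            raise ValueError("invariant violated: cuticle_px > body_px")


# ---------------------------------------------------------------------------
# (1) enhancement


def enhance_slice(
    img: SliceImage,
    cfg: SegConfig = SegConfig(),
    stretch_range: tuple[float, float] | None = None,
) -> SliceImage:
    """Contrast-stretch to the full bit range, then bilateral-smooth.

    The bilateral filter reduces noise while keeping tissue edges in place
    (a step edge's half-max crossing moves by less than a pixel). Constant
    images are returned unchanged. When a stack is processed slice by
    slice, pass the stack-wide intensity range as ``stretch_range`` so all
    slices share one gray mapping.
    """
    from skimage.restoration import denoise_bilateral

    data = img.data
    if stretch_range is not None:
        lo, hi = float(stretch_range[0]), float(stretch_range[1])
    else:
        lo, hi = float(data.min()), float(data.max())
    bit_max = img.bit_max
    if hi == lo:
        return SliceImage(data.copy(), img.pixel_size_um)
    stretched = np.clip((data.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)
    smoothed = denoise_bilateral(
        stretched,
        sigma_color=cfg.bilateral_sigma_range_frac,
        sigma_spatial=cfg.bilateral_sigma_spatial,
    )
    out = np.clip(np.rint(smoothed * bit_max), 0, bit_max).astype(data.dtype)
    return SliceImage(out, img.pixel_size_um)


# ---------------------------------------------------------------------------
# (2) vial detection


def detect_and_crop_vial(
    img: SliceImage, cfg: SegConfig = SegConfig()
) -> tuple[SliceImage, bool]:
    """Mask out the bright vial rim and everything outside it.

    Specimens are scanned inside ethanol-filled vials whose wall shows as a
    large bright ring. The detector looks for a bright closed contour whose
    filled area covers at least ``cfg.vial_min_area_frac`` of the frame,
    whose centroid sits in the central quarter of the frame, and which is
    ring-like (filled area well above its own wall area). Pixels on or
    outside the rim, plus a safety margin of ``cfg.vial_rim_margin`` px
    inside it, are set to the background level. Absence of a vial is not an
    error: the slice is returned unchanged with ``vial_found=False``.
    """
    data = img.data
    ny, nx = data.shape
    try:
        from skimage.filters import threshold_otsu

        t = threshold_otsu(data)
    except ValueError:  # constant image
        return img, False
    bright = data > t
    labels, nlab = ndimage.label(bright, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        return img, False
    frame_area = ny * nx
    background = _background_level(data)
    for lab in range(1, nlab + 1):
        comp = labels == lab
        comp_area = int(comp.sum())
        filled = ndimage.binary_fill_holes(comp)
        filled_area = int(filled.sum())
        if filled_area < cfg.vial_min_area_frac * frame_area:
            continue
        if filled_area < 2 * comp_area:  # solid blob, not a ring
            continue
        cy, cx = ndimage.center_of_mass(filled)
        if abs(cy - (ny - 1) / 2) > ny / 4 or abs(cx - (nx - 1) / 2) > nx / 4:
            continue
        interior = filled & ~comp
        if cfg.vial_rim_margin > 0:
            interior = ndimage.binary_erosion(
                interior, iterations=cfg.vial_rim_margin, border_value=0
            )
        out = np.where(interior, data, background).astype(data.dtype)
        return SliceImage(out, img.pixel_size_um), True
    return img, False


def _background_level(data: np.ndarray) -> int:
    """Most frequent gray level — the background, in any sane tomogram."""
    if np.issubdtype(data.dtype, np.integer):
        return int(np.bincount(data.ravel()).argmax())
    hist, edges = np.histogram(data.ravel(), bins=256)
    return int(edges[int(hist.argmax())])


# ---------------------------------------------------------------------------
# (3) threshold


def threshold_band(img: SliceImage, cfg: SegConfig = SegConfig()) -> np.ndarray:
    """Binary mask of pixels with intensity in [t_lo, t_hi] inclusive."""
    data = img.data
    t_lo, t_hi = resolve_band(img, cfg)
    if t_lo < 0 or t_hi > img.bit_max:
        raise ValueError(f"threshold band [{t_lo}, {t_hi}] outside bit depth")
    return (data >= t_lo) & (data <= t_hi)


def resolve_band(img: SliceImage, cfg: SegConfig) -> tuple[float, float]:
    t_hi = cfg.t_hi if cfg.t_hi is not None else float(img.bit_max)
    if cfg.t_lo is not None:
        t_lo = cfg.t_lo
    else:
        t_lo = band_lower_threshold(img.data, t_hi)
    if not t_lo < t_hi:
        t_lo = min(t_lo, t_hi - 1)
    return float(t_lo), float(t_hi)


def band_lower_threshold(values: np.ndarray, t_hi: float) -> float:
    """Data-adaptive lower band threshold isolating the densest tissue.

    A tomogram has up to three intensity classes: mounting medium, soft
    tissue, dense cuticle. The classes are located by deterministic 1D
    k-means (three means initialized at min / midrange / max), and the
    threshold is the midpoint between the soft-tissue and cuticle class
    means — i.e. the decision boundary that keeps only the densest class.
    If the middle class is essentially empty (< 1% of pixels) the data are
    two-class (medium vs. cuticle) and the midpoint of those two means is
    used. Constant input selects nothing (returns ``t_hi``).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.ptp(values) == 0:
        return float(t_hi)
    means3, masses3 = _kmeans_1d(values, 3)
    if means3 is not None and masses3[1] >= 0.01:
        return float((means3[1] + means3[2]) / 2.0)
    means2, _ = _kmeans_1d(values, 2)
    return float((means2[0] + means2[1]) / 2.0)


def _kmeans_1d(values: np.ndarray, k: int, max_iter: int = 60):
    """Deterministic Lloyd's algorithm on sorted 1D data.

    Means are initialized evenly over [min, max]. Returns (means, masses),
    or (None, None) if a cluster empties (fewer real classes than k).
    """
    vmin, vmax = float(values.min()), float(values.max())
    means = np.linspace(vmin, vmax, k)
    for _ in range(max_iter):
        bounds = (means[:-1] + means[1:]) / 2.0
        labels = np.searchsorted(bounds, values, side="right")
        new_means = np.empty(k)
        masses = np.empty(k)
        for j in range(k):
            sel = labels == j
            masses[j] = sel.mean()
            if masses[j] == 0:
                return None, None
            new_means[j] = values[sel].mean()
        if np.allclose(new_means, means, rtol=0, atol=1e-9 * (vmax - vmin + 1)):
            means = new_means
            break
        means = new_means
    return means, masses


# ---------------------------------------------------------------------------
# (4) contour tree extraction


def _perimeter(mask: np.ndarray) -> float:
    """Boundary arc length in pixel units (4-neighbor steps 1, diagonal √2)."""
    return float(measure.perimeter(mask, neighborhood=4))


def extract_contour_tree(mask: np.ndarray) -> ContourTree:
    """Build the full contour hierarchy of a binary mask.

    External contours are 8-connected foreground components; each one's
    holes are the 4-connected components of its filled interior minus
    itself. An external lying inside another external's hole has depth ≥ 1
    (nested). Empty masks yield an empty tree.
    """
    mask = np.asarray(mask, dtype=bool)
    tree = ContourTree(shape=mask.shape)
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        return tree
    slices = ndimage.find_objects(labels)
    ext_idx: list[int] = []
    filled_masks: list[np.ndarray] = []
    for lab in range(1, nlab + 1):
        comp = labels == lab
        filled = ndimage.binary_fill_holes(comp)
        node = ContourNode(
            kind="external",
            mask=comp,
            filled=filled,
            perimeter=_perimeter(filled),
            area=float(filled.sum()),
        )
        hull_area = float(convex_hull_image(filled).sum()) if filled.any() else 1.0
        node.solidity = node.area / hull_area if hull_area else 1.0
        ext_idx.append(len(tree.nodes))
        filled_masks.append(filled)
        tree.nodes.append(node)
        # hole children: interior components not part of this component
        interior = filled & ~comp
        hlabels, hn = ndimage.label(interior, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int))
        for h in range(1, hn + 1):
            hm = hlabels == h
            hnode = ContourNode(
                kind="hole",
                mask=hm,
                parent=ext_idx[-1],
                perimeter=_perimeter(hm),
                area=float(hm.sum()),
            )
            tree.nodes[ext_idx[-1]].children.append(len(tree.nodes))
            tree.nodes.append(hnode)
    # nesting depth of externals: count of other externals whose filled
    # region strictly contains this component
    for i, lab_i in enumerate(ext_idx):
        comp = tree.nodes[lab_i].mask
        ys, xs = np.nonzero(comp)
        py, px = int(ys[0]), int(xs[0])
        depth = 0
        for j, lab_j in enumerate(ext_idx):
            if i == j:
                continue
            if filled_masks[j][py, px] and not tree.nodes[lab_j].mask[py, px]:
                depth += 1
        tree.nodes[lab_i].depth = depth
    return tree


# ---------------------------------------------------------------------------
# (5) hierarchy + perimeter filtering


def filter_hierarchy(tree: ContourTree, cfg: SegConfig = SegConfig()) -> ContourTree:
    """Keep top-level externals and their direct holes; drop small contours.

    Contours nested inside another contour without being its internal border
    (depth ≥ 1 externals) are removed — their pixels end up inside a kept
    hole and therefore count as body, not cuticle. Contours with perimeter
    strictly below ``cfg.min_perimeter`` are removed: a small external
    disappears entirely; a small hole is absorbed into the cuticle. The
    operation is idempotent.
    """
    out = ContourTree(shape=tree.shape)
    for i in tree.externals():
        node = tree.nodes[i]
        if node.depth != 0:
            continue
        if node.perimeter < cfg.min_perimeter:
            continue
        kept = ContourNode(
            kind="external",
            mask=node.mask,
            filled=node.filled,
            depth=0,
            perimeter=node.perimeter,
            area=node.area,
            solidity=node.solidity,
            flags=set(node.flags),
        )
        idx = len(out.nodes)
        out.nodes.append(kept)
        for c in node.children:
            child = tree.nodes[c]
            if child.perimeter < cfg.min_perimeter:
                continue
            out.nodes.append(
                ContourNode(
                    kind="hole",
                    mask=child.mask,
                    parent=idx,
                    perimeter=child.perimeter,
                    area=child.area,
                    flags=set(child.flags),
                )
            )
            kept.children.append(len(out.nodes) - 1)
    return out


# ---------------------------------------------------------------------------
# (6) orphan closure and contour linking


def _orphan_candidates(tree: ContourTree, cfg: SegConfig) -> list[int]:
    """Externals with no hole children that look like open shells.

    Besides the solidity cutoff, the convex-hull excess must exceed the
    contour perimeter: on small discrete regions the pixel hull always
    overshoots by O(perimeter) even for convex shapes, so solidity alone
    would misclassify compact little disks as open arcs.
    """
    out = []
    for i in tree.externals():
        n = tree.nodes[i]
        if n.children or n.solidity >= cfg.orphan_solidity_cutoff:
            continue
        hull_excess = n.area * (1.0 / max(n.solidity, 1e-12) - 1.0)
        if hull_excess > n.perimeter:
            out.append(i)
    return out


def close_orphans(tree: ContourTree, cfg: SegConfig = SegConfig()) -> ContourTree:
    """Convex-hull closure of orphan childless contours.

    An open exoskeleton cross-section (unfused segment) thresholds to an
    external contour with no hole children and low solidity. Such a contour
    is replaced by its convex hull, flagged ``orphan_closed``; any other
    contour falling inside the new hull is removed (its pixels become part
    of the closed region). Closed annuli and compact blobs are untouched,
    and the operation is idempotent on its own output (a hull has solidity
    ~1).
    """
    orphans = _orphan_candidates(tree, cfg)
    if not orphans:
        return tree
    out = ContourTree(shape=tree.shape)
    hulls: list[np.ndarray] = []
    for i in orphans:
        hulls.append(convex_hull_image(tree.nodes[i].mask))
    hull_union = np.zeros(tree.shape, dtype=bool)
    for h in hulls:
        hull_union |= h
    for i in tree.externals():
        node = tree.nodes[i]
        if i in orphans:
            k = orphans.index(i)
            hull = hulls[k]
            out.nodes.append(
                ContourNode(
                    kind="external",
                    mask=hull,
                    filled=hull,
                    perimeter=_perimeter(hull),
                    area=float(hull.sum()),
                    solidity=1.0,
                    flags=set(node.flags) | {"orphan_closed"},
                )
            )
            continue
        # drop non-orphan contours swallowed by a new hull
        if np.all(~node.mask | hull_union):
            continue
        idx = len(out.nodes)
        clone = ContourNode(
            kind="external",
            mask=node.mask,
            filled=node.filled,
            perimeter=node.perimeter,
            area=node.area,
            solidity=node.solidity,
            flags=set(node.flags),
        )
        out.nodes.append(clone)
        for c in node.children:
            child = tree.nodes[c]
            if np.all(~child.mask | hull_union):
                continue
            out.nodes.append(
                ContourNode(
                    kind="hole",
                    mask=child.mask,
                    parent=idx,
                    perimeter=child.perimeter,
                    area=child.area,
                    flags=set(child.flags),
                )
            )
            clone.children.append(len(out.nodes) - 1)
    return out


def link_open_contours(tree: ContourTree, cfg: SegConfig = SegConfig()) -> ContourTree:
    """Bridge nearby endpoints of open-arc contours into closed shells.

    Where the thresholded cuticle breaks into several arcs separated by
    small gaps (≤ ``cfg.linking_max_gap`` px), the arcs are joined by
    drawing minimal connecting segments at each gap site, the hierarchy is
    re-extracted, and the result is re-filtered. If the linked region is
    still open (no hole child and low solidity), the method falls back to
    convex-hull closure and flags ``hull_fallback``.
    """
    from scipy.spatial import cKDTree
    from skimage.draw import line as draw_line

    orphans = _orphan_candidates(tree, cfg)
    if len(orphans) < 2:
        return tree
    canvas = tree.to_mask().copy()
    coords = [np.argwhere(tree.nodes[i].mask) for i in orphans]
    trees_kd = [cKDTree(c) for c in coords]
    bridges: list[tuple[np.ndarray, np.ndarray]] = []
    for a in range(len(orphans)):
        for b in range(a + 1, len(orphans)):
            pairs = trees_kd[a].query_ball_tree(trees_kd[b], r=cfg.linking_max_gap)
            cand = [
                (float(np.hypot(*(coords[a][ia] - coords[b][ib]))), ia, ib)
                for ia, lst in enumerate(pairs)
                for ib in lst
            ]
            if not cand:
                continue
            cand.sort()
            accepted_mids: list[np.ndarray] = []
            for d, ia, ib in cand:
                mid = (coords[a][ia] + coords[b][ib]) / 2.0
                if any(
                    np.hypot(*(mid - m)) < 2 * cfg.linking_max_gap
                    for m in accepted_mids
                ):
                    continue
                accepted_mids.append(mid)
                bridges.append((coords[a][ia], coords[b][ib]))
    if not bridges:
        fallback = close_orphans(tree, cfg)
        for i in fallback.externals():
            if "orphan_closed" in fallback.nodes[i].flags:
                fallback.nodes[i].flags.add("hull_fallback")
        return fallback
    for p, q in bridges:
        rr, cc = draw_line(int(p[0]), int(p[1]), int(q[0]), int(q[1]))
        canvas[rr, cc] = True
    linked = filter_hierarchy(extract_contour_tree(canvas), cfg)
    for i in linked.externals():
        linked.nodes[i].flags.add("linked")
    if _orphan_candidates(linked, cfg):
        linked = close_orphans(linked, cfg)
        for i in linked.externals():
            if "orphan_closed" in linked.nodes[i].flags:
                linked.nodes[i].flags.add("hull_fallback")
    return linked


# ---------------------------------------------------------------------------
# (7) full slice pipeline


def segment_slice(
    img: SliceImage,
    cfg: SegConfig = SegConfig(),
    keep_mask: bool = True,
    stretch_range: tuple[float, float] | None = None,
) -> SliceResult:
    """Run the whole decision tree on one slice and count pixels.

    Cuticle pixels are those of kept external regions minus kept hole
    interiors (boundary pixels count as cuticle); body pixels are the
    external regions with holes filled. A slice with no surviving contour
    yields (0, 0). For stack processing, ``stretch_range`` (and an explicit
    ``cfg.t_lo``) keep the gray mapping consistent across slices; see
    :func:`cuticlevol.stack_proc.segment_stack`.
    """
    work = enhance_slice(img, cfg, stretch_range=stretch_range) if cfg.enhance else img
    vial_found = False
    if cfg.vial_detect:
        work, vial_found = detect_and_crop_vial(work, cfg)
    mask = threshold_band(work, cfg)
    tree = filter_hierarchy(extract_contour_tree(mask), cfg)
    orphans_before = _orphan_candidates(tree, cfg)
    linking_used = False
    if cfg.linking and len(orphans_before) >= 2:
        tree = link_open_contours(tree, cfg)
        linking_used = True
    tree = close_orphans(tree, cfg)
    body = np.zeros(mask.shape, dtype=bool)
    interior = np.zeros(mask.shape, dtype=bool)
    hull_fallback = False
    orphans_closed = False
    for i in tree.externals():
        node = tree.nodes[i]
        body |= node.filled
        for c in node.children:
            interior |= tree.nodes[c].mask
        if "orphan_closed" in node.flags:
            orphans_closed = True
        if "hull_fallback" in node.flags:
            hull_fallback = True
    interior &= body
    cuticle = body & ~interior
    label = None
    if keep_mask:
        label = np.zeros(mask.shape, dtype=np.uint8)
        label[cuticle] = 1
        label[interior] = 2
    return SliceResult(
        cuticle_px=int(cuticle.sum()),
        body_px=int(body.sum()),
        label_mask=label,
        vial_detected=vial_found,
        orphans_closed=orphans_closed,
        linking_used=linking_used,
        hull_fallback=hull_fallback,
    )
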