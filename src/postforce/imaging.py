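"""Image pipeline: sensor detection, drift registration, post tracking,
aggregate segmentation and calcium quantification.

The structural channel shows rigid blocks (large bright squares, stationary)
and flexible posts (small bright spots that move as aggregates contract).
Blocks double as fiducials: stage drift is estimated from block centroids
only and removed before post displacements are converted to deflections.

Subpixel localization uses an intensity-weighted centroid inside a window of
three post diameters, after subtracting the window median and suppressing
pixels below a robust noise floor; an optional Gaussian fit refines the
estimate.  Deflection is the signed projection of tip displacement onto the
post->block axis (positive = toward the block = contractile) and converts to
force through the cantilever stiffness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage.draw import polygon as _raster_polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects

from .mechanics import DeviceGeneration, bending_stiffness
from .synthetic import FrameStack

__all__ = [
    "SensorSite",
    "PostTrack",
    "AggregateMask",
    "DetectionResult",
    "detect_sensors",
    "register_drift",
    "track_post",
    "segment_aggregate",
    "calcium_series",
    "mask_from_polygon",
]

log = logging.getLogger("postforce.imaging")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class SensorSite:
    """One block-post pair: the block is the fiducial, the post the sensor."""

    site_id: int
    block_centroid: np.ndarray       # (x, y), px
    post_rest_position: np.ndarray   # (x, y), px, subpixel
    axis: np.ndarray                 # unit vector post -> block

    def __post_init__(self) -> None:
        self.block_centroid = np.asarray(self.block_centroid, float)
        self.post_rest_position = np.asarray(self.post_rest_position, float)
        self.axis = np.asarray(self.axis, float)
        n = np.linalg.norm(self.axis)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("axis must be a unit vector")


@dataclass
class DetectionResult:
    sites: list[SensorSite]
    unpaired_blocks: list[np.ndarray] = field(default_factory=list)
    unpaired_posts: list[np.ndarray] = field(default_factory=list)


@dataclass
class PostTrack:
    """Per-frame subpixel tip positions and derived deflections/forces."""

    site_id: int
    times: np.ndarray                # s
    positions: np.ndarray            # (n_frames, 2) px, drift-corrected
    valid: np.ndarray                # (n_frames,) bool
    deflections: np.ndarray          # um, signed; NaN where invalid
    forces: np.ndarray               # nN; NaN where invalid
    usable: bool = True

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class AggregateMask:
    """Per-frame aggregate masks within a site window and projected areas."""

    site_id: int
    window: tuple[slice, slice]
    masks: np.ndarray                # (n_frames, wh, ww) bool
    areas_um2: np.ndarray            # (n_frames,)
    flagged_empty: np.ndarray        # (n_frames,) bool


# ---------------------------------------------------------------------------
# Localization primitives
# ---------------------------------------------------------------------------

def _window(shape, cx, cy, half):
    h, w = shape
    x0, x1 = int(round(cx)) - half, int(round(cx)) + half + 1
    y0, y1 = int(round(cy)) - half, int(round(cy)) + half + 1
    x0, x1 = max(0, x0), min(w, x1)
    y0, y1 = max(0, y0), min(h, y1)
    return (slice(y0, y1), slice(x0, x1))


def weighted_centroid(frame: np.ndarray, window: tuple[slice, slice]):
    """Noise-suppressed intensity-weighted centroid inside ``window``.

    The window median is subtracted as local background; pixels below three
    robust standard deviations (1.4826 x MAD) of the background are zeroed so
    distant noise does not pull the centroid.  Returns ((x, y), total_mass);
    mass 0 signals an empty window.
    """
    patch = frame[window].astype(float)
    med = np.median(patch)
    mad = np.median(np.abs(patch - med))
    floor = 3.0 * 1.4826 * mad
    net = patch - med
    net[net < floor] = 0.0
    mass = net.sum()
    if mass <= 0:
        return np.array([np.nan, np.nan]), 0.0
    ys, xs = np.mgrid[window[0], window[1]]
    cx = float((net * xs).sum() / mass)
    cy = float((net * ys).sum() / mass)
    return np.array([cx, cy]), float(mass)


def localize_spot(frame: np.ndarray, center, half_coarse: int, half_fine: int):
    """Two-pass subpixel spot localization.

    Pass 1: noise-suppressed centroid in the wide search window centred at
    ``center``.  Pass 2: the same estimator in a tight window recentred on
    the first estimate, which removes most of the background-noise
    contribution to the centroid variance.  Returns ((x, y), mass).
    """
    win = _window(frame.shape, center[0], center[1], half_coarse)
    c, mass = weighted_centroid(frame, win)
    if mass <= 0:
        return c, mass
    fwin = _window(frame.shape, c[0], c[1], half_fine)
    c2, mass2 = weighted_centroid(frame, fwin)
    if mass2 <= 0:
        return c, mass
    return c2, mass2


def _gauss2d(coords, a, cx, cy, sigma, off):
    x, y = coords
    return (off + a * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))).ravel()


def gaussian_refine(frame: np.ndarray, window: tuple[slice, slice], start):
    """Least-squares 2-D Gaussian fit; falls back to ``start`` on failure."""
    patch = frame[window].astype(float)
    ys, xs = np.mgrid[window[0], window[1]]
    p0 = (patch.max() - np.median(patch), start[0], start[1], 1.5, np.median(patch))
    try:
        popt, _ = curve_fit(_gauss2d, (xs, ys), patch.ravel(), p0=p0, maxfev=200)
        return np.array([popt[1], popt[2]])
    except Exception:  # pragma: no cover - rare numerical failure
        return np.asarray(start, float)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_sensors(
    first_frame: np.ndarray,
    geom: DeviceGeneration,
    pixel_size: float,
    pairing_radius_um: float | None = None,
) -> DetectionResult:
    """Find block-post pairs in a structural frame.

    Blocks are the large bright components, posts the small compact ones;
    classification is by component area against the expected block footprint.
    Each post pairs with its nearest block within ``pairing_radius_um``
    (default 0.45 x array pitch); unpaired features are reported, never
    silently dropped.  Site ids follow raster order of the block centroids.
    """
    img = np.asarray(first_frame, float)
    if pairing_radius_um is None:
        pairing_radius_um = 0.45 * geom.array_pitch
    if img.max() <= img.min():
        log.warning("detect_sensors: blank frame, no features")
        return DetectionResult(sites=[])
    thr = threshold_otsu(img)
    binary = img > thr
    binary = remove_small_objects(binary, max_size=3)
    if not binary.any():
        log.warning("detect_sensors: nothing above threshold")
        return DetectionResult(sites=[])

    block_area_px = (geom.block_footprint[0] / pixel_size) * (
        geom.block_footprint[1] / pixel_size
    )
    blocks, posts = [], []
    for region in regionprops(_cc_label(binary)):
        c = np.array([region.centroid[1], region.centroid[0]])  # (x, y)
        if region.area >= 0.25 * block_area_px:
            blocks.append(c)
        else:
            posts.append(c)

    if not blocks or not posts:
        log.warning("detect_sensors: %d blocks, %d posts -> no pairs",
                    len(blocks), len(posts))
        return DetectionResult(sites=[], unpaired_blocks=blocks, unpaired_posts=posts)

    blocks_arr = np.asarray(blocks)
    radius_px = pairing_radius_um / pixel_size
    # deterministic ordering: raster order of blocks, then nearest distance
    order = np.lexsort((blocks_arr[:, 0], blocks_arr[:, 1]))
    blocks_arr = blocks_arr[order]

    pairs: dict[int, tuple[int, float]] = {}
    unpaired_posts = []
    for pi, p in enumerate(posts):
        d = np.linalg.norm(blocks_arr - p, axis=1)
        bi = int(np.argmin(d))
        if d[bi] > radius_px:
            unpaired_posts.append(p)
            continue
        if bi in pairs and pairs[bi][1] <= d[bi]:
            unpaired_posts.append(p)      # block already has a closer post
            continue
        pairs[bi] = (pi, float(d[bi]))

    sites = []
    paired_blocks = set()
    half = max(3, int(round(1.5 * geom.post.diameter / pixel_size)))
    for site_id, bi in enumerate(sorted(pairs)):
        pi, _ = pairs[bi]
        paired_blocks.add(bi)
        # refine both centroids to subpixel
        bwin = _window(img.shape, *blocks_arr[bi],
                       int(round(0.75 * max(geom.block_footprint) / pixel_size)))
        bpos, _m = weighted_centroid(img, bwin)
        fine = max(3, int(round(0.5 * geom.post.diameter / pixel_size)))
        ppos, _m = localize_spot(img, posts[pi], half, fine)
        axis = bpos - ppos
        axis = axis / np.linalg.norm(axis)
        sites.append(SensorSite(site_id=site_id, block_centroid=bpos,
                                post_rest_position=ppos, axis=axis))

    unpaired_blocks = [blocks_arr[i] for i in range(len(blocks_arr))
                       if i not in paired_blocks]
    if unpaired_blocks or unpaired_posts:
        log.info("detect_sensors: %d unpaired blocks, %d unpaired posts",
                 len(unpaired_blocks), len(unpaired_posts))
    return DetectionResult(sites=sites, unpaired_blocks=unpaired_blocks,
                           unpaired_posts=unpaired_posts)


# ---------------------------------------------------------------------------
# Drift registration
# ---------------------------------------------------------------------------

def register_drift(
    stack: FrameStack,
    sites: list[SensorSite],
    geom: DeviceGeneration | None = None,
    block_window_half: int | None = None,
    method: str = "phase",
) -> np.ndarray:
    """Per-frame rigid translation offsets estimated from the blocks only.

    Blocks are rigid and stationary, so any apparent motion in a window
    around a block is stage drift; posts never enter the estimate.  The
    default estimator is subpixel phase cross-correlation of each block
    window against frame 0 (``method='phase'``); ``method='centroid'``
    falls back to block intensity centroids.  Returns offsets (n_frames, 2)
    as (dx, dy) relative to frame 0; subtract an offset from a raw position
    to correct it.  Frames where no block yields an estimate get linearly
    interpolated offsets and are logged.
    """
    from skimage.registration import phase_cross_correlation

    if not sites:
        raise ValueError("register_drift needs at least one detected site")
    if block_window_half is None:
        if geom is not None:
            block_window_half = int(round(0.75 * max(geom.block_footprint)
                                          / stack.pixel_size))
        else:
            block_window_half = 20
    n = stack.n_frames
    offsets = np.full((n, 2), np.nan)
    ref = np.array([s.block_centroid for s in sites])
    wins = [_window(stack.shape, r[0], r[1], block_window_half) for r in ref]
    ref_patches = [stack.structural[0][w].astype(float) for w in wins]
    for i in range(n):
        deltas = []
        for s, r, w, rp in zip(sites, ref, wins, ref_patches):
            if method == "phase":
                shift, _err, _ph = phase_cross_correlation(
                    rp, stack.structural[i][w].astype(float),
                    upsample_factor=100, normalization=None)
                # shift maps moving->reference; drift is the negation, (x, y)
                deltas.append(np.array([-shift[1], -shift[0]]))
            else:
                c, mass = weighted_centroid(stack.structural[i], w)
                if mass > 0:
                    deltas.append(c - r)
        if deltas:
            offsets[i] = np.mean(deltas, axis=0)
    bad = np.isnan(offsets[:, 0])
    if bad.all():
        raise ValueError("no frame yielded a block centroid; cannot register")
    if bad.any():
        log.warning("register_drift: interpolating offsets for %d frames", bad.sum())
        idx = np.arange(n)
        for d in range(2):
            offsets[bad, d] = np.interp(idx[bad], idx[~bad], offsets[~bad, d])
    offsets -= offsets[0]
    return offsets


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------

def track_post(
    stack: FrameStack,
    site: SensorSite,
    offsets: np.ndarray | None,
    geom: DeviceGeneration,
    rest_frame: int = 0,
    window_factor: float = 3.0,
    gaussian_fit: bool = False,
    saturation_level: float | None = None,
) -> PostTrack:
    """Track one post tip through the movie and convert to deflection/force.

    The localization window spans ``window_factor`` post diameters (default
    3x).  The rest position is re-measured at ``rest_frame`` (default 0,
    assumed undeflected because fluid drag deflects posts by well under the
    localization noise).  Frames with an empty or saturated window are
    flagged invalid and carry no force; a track with more than half its
    frames invalid is flagged unusable.
    """
    n = stack.n_frames
    if offsets is None:
        offsets = np.zeros((n, 2))
    half = max(3, int(round(window_factor * geom.post.diameter
                            / stack.pixel_size / 2.0)))
    half_fine = max(3, int(round(0.5 * geom.post.diameter / stack.pixel_size)))
    k_nN_per_um = bending_stiffness(geom.post) * 1.0e3

    positions = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    guess = site.post_rest_position.copy()
    for i in range(n):
        center = guess + offsets[i]
        win = _window(stack.shape, center[0], center[1], half)
        frame = stack.structural[i]
        if saturation_level is not None and np.any(frame[win] >= saturation_level):
            continue
        c, mass = localize_spot(frame, center, half, half_fine)
        if mass <= 0:
            continue
        if gaussian_fit:
            c = gaussian_refine(frame, win, c)
        positions[i] = c - offsets[i]          # drift-corrected
        valid[i] = True

    if not valid[rest_frame]:
        usable_rest = site.post_rest_position
    else:
        usable_rest = positions[rest_frame]

    disp = positions - usable_rest             # px
    deflections = (disp @ site.axis) * stack.pixel_size   # um, + toward block
    deflections[~valid] = np.nan
    forces = k_nN_per_um * deflections
    track = PostTrack(
        site_id=site.site_id,
        times=stack.timestamps.copy(),
        positions=positions,
        valid=valid,
        deflections=deflections,
        forces=forces,
        usable=bool(valid.sum() >= 0.5 * n),
    )
    if not track.usable:
        log.warning("track_post: site %d unusable (%d/%d valid frames)",
                    site.site_id, track.n_valid, n)
    return track


# ---------------------------------------------------------------------------
# Aggregate segmentation
# ---------------------------------------------------------------------------

def _site_window(stack: FrameStack, site: SensorSite, geom: DeviceGeneration):
    """Window covering the block's downstream face through the post and beyond."""
    half = int(round(1.4 * np.linalg.norm(site.block_centroid
                                          - site.post_rest_position)))
    half = max(half, int(round(12.0 / stack.pixel_size)))
    cx = (site.block_centroid[0] + site.post_rest_position[0]) / 2.0
    cy = (site.block_centroid[1] + site.post_rest_position[1]) / 2.0
    return _window(stack.shape, cx, cy, half)


def segment_aggregate(
    stack: FrameStack,
    site: SensorSite,
    geom: DeviceGeneration,
    source: str = "calcium",
    reference_frame: int = 0,
    min_contrast: float = 8.0,
    min_object_px: int = 16,
) -> AggregateMask:
    """Threshold-based aggregate segmentation in a window around the site.

    The aggregate-free ``reference_frame`` is subtracted first: the faint
    DiI bleed-through of the structures is constant in every frame, so the
    difference image isolates the growing aggregate.  Per frame the
    difference is Otsu-thresholded within the window; the largest connected
    component survives small-object removal and hole filling.  A frame whose
    foreground stands less than ``min_contrast`` (or four robust noise sds)
    above the residual background is declared aggregate-free (area 0,
    flagged).  Manual polygon tracings can replace this entirely via
    :func:`mask_from_polygon`.
    """
    channel = getattr(stack, source, None)
    if channel is None:
        raise ValueError(f"stack has no '{source}' channel")
    win = _site_window(stack, site, geom)
    n = stack.n_frames
    wh = win[0].stop - win[0].start
    ww = win[1].stop - win[1].start
    masks = np.zeros((n, wh, ww), dtype=bool)
    areas = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    from scipy.ndimage import binary_fill_holes

    ref = channel[reference_frame][win].astype(float)
    for i in range(n):
        diff = channel[i][win].astype(float) - ref
        try:
            thr = threshold_otsu(diff)
        except ValueError:
            flagged[i] = True
            continue
        fg = diff > thr
        bg_med = np.median(diff[~fg]) if (~fg).any() else 0.0
        noise = 1.4826 * np.median(np.abs(diff[~fg] - bg_med)) + 1e-9
        if not fg.any() or (diff[fg].mean() - bg_med) < max(min_contrast, 4.0 * noise):
            flagged[i] = True
            continue
        fg = remove_small_objects(fg, max_size=min_object_px - 1)
        if not fg.any():
            flagged[i] = True
            continue
        lab = _cc_label(fg)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        m = binary_fill_holes(lab == largest)
        masks[i] = m
        areas[i] = m.sum() * stack.pixel_size**2
    return AggregateMask(site_id=site.site_id, window=win, masks=masks,
                         areas_um2=areas, flagged_empty=flagged)


def mask_from_polygon(
    vertices_px: np.ndarray,
    frame_shape: tuple[int, int],
    window: tuple[slice, slice] | None = None,
) -> np.ndarray:
    """Rasterize a manually traced polygon (x, y vertices in px) to a mask."""
    v = np.asarray(vertices_px, float)
    rr, cc = _raster_polygon(v[:, 1], v[:, 0], shape=frame_shape)
    mask = np.zeros(frame_shape, dtype=bool)
    mask[rr, cc] = True
    if window is not None:
        return mask[window]
    return mask


# ---------------------------------------------------------------------------
# Calcium quantification
# ---------------------------------------------------------------------------

def calcium_series(
    stack: FrameStack,
    mask: AggregateMask,
    background_region: tuple[slice, slice] | None = None,
) -> np.ndarray:
    """Mean calcium intensity inside the per-frame aggregate mask, minus a
    constant background.

    The background (camera offset plus the constant DiI bleed-through) is the
    median of a platelet-free region: ``background_region`` if given, else
    the pixels of the full frame outside the site window, evaluated on the
    first frame.  Frames with an empty mask yield NaN, never zero.
    """
    if stack.calcium is None:
        raise ValueError("stack has no calcium channel")
    first = stack.calcium[0].astype(float)
    if background_region is not None:
        background = float(np.median(first[background_region]))
    else:
        outside = np.ones(stack.shape, dtype=bool)
        outside[mask.window] = False
        background = float(np.median(first[outside])) if outside.any() else float(np.median(first))

    n = stack.n_frames
    out = np.full(n, np.nan)
    for i in range(n):
        m = mask.masks[i]
        if not m.any():
            continue
        patch = stack.calcium[i][mask.window].astype(float)
        out[i] = patch[m].mean() - background
    return out
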