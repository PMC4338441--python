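"""Spot detection and linking for TIRF image stacks.

Per-frame processing: divide by an 11x11 median filter (shading
correction), smooth with a 3x3 Gaussian kernel, threshold at background
median + k*1.4826*MAD, keep strict local maxima separated by >= 532 nm, and
measure each spot in a circular ROI of radius 332 nm with an annulus
background.  Frame-to-frame linking is greedy best circle-overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .synthetic_data import Track

__all__ = [
    "Detection",
    "shading_correct",
    "smooth",
    "detect",
    "link",
    "track_movie",
    "kymograph",
]

SEARCH_RADIUS_NM = 532.0
CIRCLE_RADIUS_NM = 332.0


@dataclass
class Detection:
    frame: int
    row: float          # sub-pixel, 0-based pixel index coordinates
    col: float
    radius_px: float
    intensity: float    # background-subtracted sum inside the circle


def shading_correct(frame: np.ndarray, size: int = 11) -> np.ndarray:
    """Divide the frame by its ``size`` x ``size`` median filter.

    Reflection handles the border.  Flattens slowly varying illumination
    while leaving point-like features (which cannot move the median of
    ``size**2`` samples) as local contrast.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < size:
        raise ValueError(f"frame must be 2-D and at least {size}x{size}")
    if not np.any(frame):
        raise ValueError("all-zero frame: shading correction undefined")
    med = ndimage.median_filter(frame, size=size, mode="reflect")
    eps = np.finfo(float).eps
    return frame / np.maximum(med, eps)


def _gaussian_kernel_3x3(sigma: float = 0.8) -> np.ndarray:
    ax = np.arange(-1, 2, dtype=float)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth(frame: np.ndarray, sigma: float = 0.8) -> np.ndarray:
    """Convolve with a unit-sum 3x3 Gaussian kernel (reflect border)."""
    frame = np.asarray(frame, dtype=float)
    return ndimage.convolve(frame, _gaussian_kernel_3x3(sigma), mode="reflect")


def detect(
    frame: np.ndarray,
    frame_index: int = 0,
    pixel_size_nm: float = 133.0,
    threshold_k: float = 3.0,
) -> list[Detection]:
    """Find spots in a shading-corrected, smoothed frame.

    Pixels above ``median + k * 1.4826 * MAD`` are signal.  Signal pixels
    that are strict maxima within the 532 nm search radius seed detections;
    each is measured in a circular ROI of radius 332 nm with local
    background taken as the median of an annulus out to twice that radius.
    A candidate is kept only when its integrated ROI intensity clears
    ``k * sigma * sqrt(n_roi_pixels)`` (isolated noise maxima integrate to
    much less than a PSF); the centroid is the intensity-weighted mean over
    the circle.
    """
    frame = np.asarray(frame, dtype=float)
    search_px = SEARCH_RADIUS_NM / pixel_size_nm
    circle_px = CIRCLE_RADIUS_NM / pixel_size_nm

    med = np.median(frame)
    mad = np.median(np.abs(frame - med))
    thr = med + threshold_k * 1.4826 * mad

    size = 2 * int(np.ceil(search_px)) + 1
    local_max = frame == ndimage.maximum_filter(frame, size=size, mode="reflect")
    # strictness: demote plateaus (ties within the window) except single pixels
    plateau = ndimage.maximum_filter(frame, size=size, mode="reflect") == ndimage.minimum_filter(
        frame, size=size, mode="reflect"
    )
    candidates = np.argwhere(local_max & ~plateau & (frame > thr))

    # ROI geometry on an integer-centred stamp
    r_ceil = int(np.ceil(2 * circle_px))
    dy, dx = np.mgrid[-r_ceil : r_ceil + 1, -r_ceil : r_ceil + 1]
    dist2 = dy**2 + dx**2
    circle_mask = dist2 <= circle_px**2
    annulus_mask = (dist2 > circle_px**2) & (dist2 <= (2 * circle_px) ** 2)
    n_circle = int(circle_mask.sum())

    # integrated ROI statistic for every pixel: circle sum minus local
    # annulus-median background; its frame-wide MAD gives the null scale
    # (smoothing correlates pixels, so a per-pixel MAD would badly
    # underestimate the integral's noise)
    circ_sum = ndimage.convolve(frame, circle_mask.astype(float), mode="reflect")
    ann_med = ndimage.median_filter(frame, footprint=annulus_mask, mode="reflect")
    stat = circ_sum - n_circle * ann_med
    sigma_int = 1.4826 * float(np.median(np.abs(stat - np.median(stat))))
    # hold expected null exceedances under ~0.5/frame; candidate maxima are
    # positively biased, so budget the exceedance over every pixel
    z_frame = float(norm.isf(min(0.5, 0.5 / stat.size)))
    min_intensity = max(threshold_k, z_frame) * sigma_int

    h, w = frame.shape
    out: list[Detection] = []
    for r0, c0 in candidates:
        intensity = float(stat[r0, c0])
        if intensity < min_intensity:
            continue
        # centroid from a local window (reflect-padded at the border)
        rs = np.clip(np.arange(r0 - r_ceil, r0 + r_ceil + 1), 0, h - 1)
        cs = np.clip(np.arange(c0 - r_ceil, c0 + r_ceil + 1), 0, w - 1)
        win = frame[np.ix_(rs, cs)]
        bg = float(ann_med[r0, c0])
        weights = np.clip(np.where(circle_mask, win - bg, 0.0), 0.0, None)
        if weights.sum() > 0:
            rc = float(r0 + (dy * weights).sum() / weights.sum())
            cc = float(c0 + (dx * weights).sum() / weights.sum())
        else:
            rc, cc = float(r0), float(c0)
        out.append(Detection(frame_index, rc, cc, circle_px, intensity))
    return out


def _circle_overlap(d: float, r: float) -> float:
    """Intersection area of two circles of radius ``r`` at centre distance ``d``."""
    if d >= 2 * r:
        return 0.0
    if d <= 0:
        return np.pi * r * r
    return 2 * r * r * np.arccos(d / (2 * r)) - 0.5 * d * np.sqrt(4 * r * r - d * d)


def link(
    detections_per_frame: list[list[Detection]],
    optimal: bool = False,
) -> list[list[Detection]]:
    """Link detections across consecutive frames into tracks.

    Default is greedy one-to-one assignment by decreasing circle-overlap
    area (ties broken by smaller centroid distance, then lower row, then
    lower col); zero-overlap pairs are never linked and there is no gap
    closing.  ``optimal=True`` switches to globally optimal assignment per
    frame pair (scipy Hungarian on overlap), used as a cross-check oracle.
    """
    tracks: list[list[Detection]] = []
    open_tracks: list[list[Detection]] = []
    for frame_dets in detections_per_frame:
        frame_dets = _dedupe(frame_dets)
        if not open_tracks:
            open_tracks = [[d] for d in frame_dets]
            tracks.extend(open_tracks)
            continue
        pairs = []
        for i, tr in enumerate(open_tracks):
            prev = tr[-1]
            for j, det in enumerate(frame_dets):
                dist = float(np.hypot(prev.row - det.row, prev.col - det.col))
                ov = _circle_overlap(dist, det.radius_px)
                if ov > 0:
                    pairs.append((ov, dist, det.row, det.col, i, j))
        used_i: set[int] = set()
        used_j: set[int] = set()
        matches: dict[int, int] = {}
        if optimal and pairs:
            from scipy.optimize import linear_sum_assignment

            cost = np.full((len(open_tracks), len(frame_dets)), 1e12)
            for ov, dist, _, _, i, j in pairs:
                cost[i, j] = -ov
            ri, rj = linear_sum_assignment(cost)
            for i, j in zip(ri, rj):
                if cost[i, j] < 0:
                    matches[i] = j
                    used_i.add(i)
                    used_j.add(j)
        else:
            for ov, dist, row, col, i, j in sorted(
                pairs, key=lambda p: (-p[0], p[1], p[2], p[3])
            ):
                if i in used_i or j in used_j:
                    continue
                matches[i] = j
                used_i.add(i)
                used_j.add(j)
        next_open: list[list[Detection]] = []
        for i, tr in enumerate(open_tracks):
            if i in matches:
                tr.append(frame_dets[matches[i]])
                next_open.append(tr)
        for j, det in enumerate(frame_dets):
            if j not in used_j:
                tr = [det]
                tracks.append(tr)
                next_open.append(tr)
        open_tracks = next_open
    return tracks


def _dedupe(dets: list[Detection]) -> list[Detection]:
    seen: set[tuple[float, float]] = set()
    out = []
    dup = False
    for d in dets:
        key = (round(d.row, 9), round(d.col, 9))
        if key in seen:
            dup = True
            continue
        seen.add(key)
        out.append(d)
    if dup:
        import warnings

        warnings.warn("duplicate detections at identical coordinates dropped",
                      stacklevel=2)
    return out


def track_movie(
    stack: np.ndarray,
    pixel_size_nm: float = 133.0,
    frame_interval_s: float = 3.0,
    threshold_k: float = 3.0,
    axis: tuple[tuple[float, float], tuple[float, float]] | None = None,
    min_length: int = 2,
) -> tuple[list[Track], pd.DataFrame]:
    """Full pipeline: correct, smooth, detect, link; project onto an axis.

    ``axis`` is ((row, col), (row, col)) in pixels defining the microtubule
    segment and its polarity; track positions are nm along it.  Without an
    axis, positions are nm along the column coordinate.  Returns Track
    objects plus a flat detections table.
    """
    det_rows = []
    per_frame: list[list[Detection]] = []
    for f in range(stack.shape[0]):
        frame = smooth(shading_correct(stack[f]))
        dets = detect(frame, f, pixel_size_nm, threshold_k)
        per_frame.append(dets)
        det_rows.extend(
            {"frame": d.frame, "row_px": d.row, "col_px": d.col, "intensity": d.intensity}
            for d in dets
        )
    linked = link(per_frame)

    if axis is not None:
        a0 = np.asarray(axis[0], dtype=float)
        unit = np.asarray(axis[1], dtype=float) - a0
        unit = unit / np.hypot(*unit)
    tracks = []
    tid = 0
    for chain in linked:
        if len(chain) < min_length:
            continue
        times = np.array([d.frame * frame_interval_s for d in chain])
        if axis is not None:
            pos = np.array(
                [np.dot((d.row - a0[0], d.col - a0[1]), unit) for d in chain]
            ) * pixel_size_nm
        else:
            pos = np.array([d.col for d in chain]) * pixel_size_nm
        inten = np.array([max(d.intensity, 0.0) for d in chain])
        tracks.append(Track(tid, times, pos, inten))
        tid += 1
    return tracks, pd.DataFrame(det_rows)


def kymograph(
    stack: np.ndarray,
    axis: tuple[tuple[float, float], tuple[float, float]],
    width_px: int = 1,
) -> np.ndarray:
    """Position-vs-time intensity matrix sampled along an axis segment.

    Returns an array of shape (n_samples_along_axis, n_frames); sampling is
    bilinear at one-pixel spacing, averaged over ``width_px`` perpendicular
    offsets.
    """
    a0 = np.asarray(axis[0], dtype=float)
    a1 = np.asarray(axis[1], dtype=float)
    length = float(np.hypot(*(a1 - a0)))
    unit = (a1 - a0) / length
    perp = np.array([-unit[1], unit[0]])
    n_samples = int(np.floor(length)) + 1
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    s = np.arange(n_samples)
    out = np.zeros((n_samples, stack.shape[0]))
    for f in range(stack.shape[0]):
        acc = np.zeros(n_samples)
        for off in offsets:
            pts = a0[None, :] + s[:, None] * unit[None, :] + off * perp[None, :]
            acc += ndimage.map_coordinates(
                stack[f].astype(float), [pts[:, 0], pts[:, 1]], order=1, mode="nearest"
            )
        out[:, f] = acc / len(offsets)
    return out
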