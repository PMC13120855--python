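"""Odor place-preference quantification for the y-maze assay.

Videos (45 Hz) of flies in a three-armed maze are reduced to per-frame
positions by median background modeling, background subtraction with a
threshold, and connected-component blob detection. Occupancy is scored
per frame against the left/right arm masks (excluding the central bowl)
and summarized as a normalized index (t_left − t_right)/(t_left +
t_right), or optionally as a fraction of all arm frames.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

#: Per-frame lists of (x, y) centroids.
PositionTrace = list[list[tuple[float, float]]]


def estimate_background(frames: np.ndarray, subset_size: int = 25) -> np.ndarray:
    """Per-pixel median over an evenly spaced subset of frames.

    Wherever a moving fly occupies a pixel in fewer than half the subset
    frames, the median recovers the static background there.
    """
    frames = np.asarray(frames)
    if frames.shape[0] < 3:
        raise ValueError("need at least 3 frames to estimate a background")
    k = min(subset_size, frames.shape[0])
    idx = np.linspace(0, frames.shape[0] - 1, k).astype(int)
    return np.median(frames[idx], axis=0)


def _otsu_threshold(values: np.ndarray) -> float:
    hist, edges = np.histogram(values.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    best_t, best_var = centers[0], -1.0
    w0 = np.cumsum(hist)
    w1 = total - w0
    csum = np.cumsum(hist * centers)
    mu_total = csum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (mu_total - csum) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
    var = np.nan_to_num(var, nan=-1.0)
    i = int(np.argmax(var))
    return float(centers[i])


def detect_positions(
    frames: np.ndarray,
    background: np.ndarray,
    threshold: Optional[float] = None,
    min_area: int = 5,
) -> PositionTrace:
    """Blob centroids per frame from thresholded background subtraction.

    ``threshold`` is in absolute intensity units; when omitted, Otsu's
    method on the pooled |frame − background| values is used. Components
    smaller than ``min_area`` pixels are ignored; frames without any blob
    yield an empty centroid list.
    """
    frames = np.asarray(frames)
    background = np.asarray(background)
    if frames.shape[1:] != background.shape:
        raise ValueError("frame and background dimensions do not match")
    diff = np.abs(frames - background[None])
    if threshold is None:
        threshold = _otsu_threshold(diff)
    trace: PositionTrace = []
    for d in diff:
        lab, n = ndimage.label(d > threshold)
        cents: list[tuple[float, float]] = []
        if n:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
            keep = [i + 1 for i, s in enumerate(sizes) if s >= min_area]
            for cy, cx in ndimage.center_of_mass(d > threshold, lab, keep):
                cents.append((float(cx), float(cy)))
        trace.append(cents)
    return trace


def occupancy_index(
    trace: PositionTrace | np.ndarray,
    masks: dict[str, np.ndarray],
    mode: str = "difference",
) -> dict[str, float]:
    """Normalized left-vs-right arm occupancy from a position trace.

    Centroids in the central bowl or outside every mask are excluded.
    ``mode="difference"`` returns (t_left − t_right)/(t_left + t_right);
    ``mode="fraction"`` returns t_left/(t_left + t_right). Multi-fly
    frames contribute one count per detected centroid (cumulative
    positions, no identity tracking). The index is NaN when no centroid
    falls in either arm.
    """
    if isinstance(trace, np.ndarray):
        arr = trace[:, None, :] if trace.ndim == 2 else trace
        trace = [[(float(x), float(y)) for x, y in frame] for frame in arr]
    if not trace:
        raise ValueError("empty trace")
    left_m, right_m = masks["left"], masks["right"]
    H, W = left_m.shape
    t_left = t_right = 0
    for frame in trace:
        for x, y in frame:
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= xi < W and 0 <= yi < H):
                continue
            if left_m[yi, xi]:
                t_left += 1
            elif right_m[yi, xi]:
                t_right += 1
    tot = t_left + t_right
    if tot == 0:
        index = float("nan")
    elif mode == "difference":
        index = (t_left - t_right) / tot
    elif mode == "fraction":
        index = t_left / tot
    else:
        raise ValueError("mode must be 'difference' or 'fraction'")
    return {"t_left": t_left, "t_right": t_right, "index": index}
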