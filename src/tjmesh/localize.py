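"""Single-molecule detection and localization in camera frame stacks.

Signals are found frame by frame by comparing each pixel with a temporal
running-mean background estimate; optically isolated candidates are cut
out in a fixed odd-sized window and localized by background-subtracted
centre of mass.  The per-signal accuracy is the weighted second moment of
the spot divided by sqrt(Q), averaged over the two axes.

Pixel values are assumed photon-calibrated; the background noise width is
Poisson, sqrt(max(B, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FRAME, PHOTONS, SIGMA, X, Y, LocalizationTable


@dataclass
class FrameStack:
    """Ordered grayscale camera frames with a physical pixel size (nm/px)."""

    frames: np.ndarray  # (T, H, W), photon-calibrated counts
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if (self.frames < 0).any():
            raise ValueError("pixel values must be >= 0")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class BackgroundModel:
    """Per-pixel running background B and its Poisson noise width."""

    background: np.ndarray
    smoothing: float

    @property
    def noise_width(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.background, 1.0))

    def update(self, frame: np.ndarray) -> None:
        self.background = (1.0 - self.smoothing) * self.background + self.smoothing * frame


def estimate_background(stack: FrameStack, smoothing: float = 0.1) -> BackgroundModel:
    """Temporal running mean: B_k = (1−s)·B_{k−1} + s·I_k, B_0 = I_0."""
    if not 0 < smoothing <= 1:
        raise ValueError("smoothing must be in (0, 1]")
    if len(stack) == 0:
        raise ValueError("empty frame stack")
    model = BackgroundModel(stack.frames[0].copy(), smoothing)
    for frame in stack.frames[1:]:
        model.update(frame)
    return model


@dataclass
class SignalROI:
    """Background-subtracted pixel window around one candidate signal."""

    frame_index: int
    i0: int  # window origin, row
    j0: int  # window origin, col
    values: np.ndarray  # frame − background, window-sized
    noise: np.ndarray  # background noise width, window-sized

    @property
    def total(self) -> float:
        return float(self.values.sum())


def detect_signals(
    frame: np.ndarray,
    model: BackgroundModel,
    n_sigma: float = 4.0,
    roi_half: int = 3,
    frame_index: int = 0,
) -> list[SignalROI]:
    """Candidate single-molecule signals in one frame.

    Connected pixel groups above B + n_sigma·noise become candidates, each
    represented by a (2·roi_half+1)² window centred on its local intensity
    maximum.  Candidates whose windows overlap are all discarded (the
    centre-of-mass estimator requires optically isolated signals), as are
    windows cut by the frame border.
    """
    if frame.shape != model.background.shape:
        raise ValueError("frame shape does not match the background model")
    above = frame > model.background + n_sigma * model.noise_width
    if not above.any():
        return []
    labels, n = ndimage.label(above)
    centers = []
    for k in range(1, n + 1):
        mask = labels == k
        masked = np.where(mask, frame, -np.inf)
        centers.append(np.unravel_index(int(np.argmax(masked)), frame.shape))
    centers = np.asarray(centers)

    # optical-isolation rule: any two maxima closer than one window kill both
    keep = np.ones(len(centers), dtype=bool)
    win = 2 * roi_half + 1
    for a in range(len(centers)):
        for b in range(a + 1, len(centers)):
            if np.abs(centers[a] - centers[b]).max() < win:
                keep[a] = keep[b] = False

    rois = []
    h, w = frame.shape
    for (ci, cj), ok in zip(centers, keep):
        if not ok:
            continue
        i0, j0 = ci - roi_half, cj - roi_half
        if i0 < 0 or j0 < 0 or i0 + win > h or j0 + win > w:
            continue
        sl = (slice(i0, i0 + win), slice(j0, j0 + win))
        rois.append(
            SignalROI(frame_index, int(i0), int(j0),
                      frame[sl] - model.background[sl], model.noise_width[sl].copy())
        )
    return rois


def localize_center_of_mass(
    roi: SignalROI, pixel_size: float, corner_floor: float = 1.0
) -> dict | None:
    """Centre-of-mass position and accuracy for one signal ROI.

    All pixels are additionally reduced by ``corner_floor`` noise widths
    (then clipped at 0) before the moment sums, which suppresses noisy
    pixels at the window corners.  Returns None (rejected) when no signal
    survives the floors.
    """
    q = np.clip(roi.values - corner_floor * roi.noise, 0.0, None)
    total = q.sum()
    if total <= 0:
        return None
    ii, jj = np.mgrid[0 : q.shape[0], 0 : q.shape[1]]
    xs = (roi.j0 + jj + 0.5) * pixel_size
    ys = (roi.i0 + ii + 0.5) * pixel_size
    xhat = float((q * xs).sum() / total)
    yhat = float((q * ys).sum() / total)
    # the corner floor sharpens the position estimate but biases the spot
    # width low; the accuracy moments use the un-floored signal
    q0 = np.clip(roi.values, 0.0, None)
    total0 = q0.sum()
    var_x = float((q0 * (xs - xhat) ** 2).sum() / total0)
    var_y = float((q0 * (ys - yhat) ** 2).sum() / total0)
    sigma = 0.5 * (np.sqrt(var_x) + np.sqrt(var_y)) / np.sqrt(total0)
    return {X: xhat, Y: yhat, FRAME: roi.frame_index, PHOTONS: float(total), SIGMA: float(sigma)}


def localize_stack(
    stack: FrameStack,
    smoothing: float = 0.1,
    n_sigma: float = 4.0,
    roi_half: int = 3,
    corner_floor: float = 1.0,
) -> tuple[LocalizationTable, int]:
    """Run the full detection/localization pipeline over a frame stack.

    The background for frame k is the running estimate over frames 0..k−1
    (causal, so a molecule does not subtract itself); frame 0 initializes
    the estimate and yields no detections.  Returns the localization table
    and the number of rejected (zero-signal) candidates.  Re-detections of
    one molecule in different frames are emitted as separate records.
    """
    if len(stack) == 0:
        raise ValueError("empty frame stack")
    model = BackgroundModel(stack.frames[0].copy(), smoothing)
    rows: list[dict] = []
    rejected = 0
    for k in range(1, len(stack)):
        frame = stack.frames[k]
        for roi in detect_signals(frame, model, n_sigma=n_sigma, roi_half=roi_half, frame_index=k):
            rec = localize_center_of_mass(roi, stack.pixel_size, corner_floor=corner_floor)
            if rec is None:
                rejected += 1
            else:
                # a point signal has zero second moment; keep sigma positive
                rec[SIGMA] = max(rec[SIGMA], 1e-6)
                rows.append(rec)
        model.update(frame)
    df = pd.DataFrame(rows, columns=[X, Y, FRAME, PHOTONS, SIGMA])
    if len(df):
        df[FRAME] = df[FRAME].astype(int)
    return LocalizationTable(df), rejected
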