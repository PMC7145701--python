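"""Movie-to-trace reduction: drift correction, background correction, spot
detection, sub-pixel Gaussian localization, and aperture photometry.

The pipeline is the standard single-molecule TIRF stack: rigid drift is
estimated by upsampled cross-correlation against frame 0, background by a
wide median filter, candidate spots by thresholded local maxima with
non-maximum suppression, positions by windowed least-squares fits of a
symmetric 2D Gaussian, and traces by fixed-aperture photometry at the mRNA
map positions (so intensity is defined *before* the first antibody binds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .movie import MovieStack
from .simulate import Trace

__all__ = [
    "SpotFit",
    "DriftPath",
    "estimate_drift",
    "correct_drift",
    "subtract_background",
    "detect_spots",
    "localize_spot",
    "extract_traces",
    "robust_noise_sd",
]


@dataclass
class SpotFit:
    """Result of one windowed 2D-Gaussian fit."""

    center_x: float
    center_y: float
    amplitude: float
    sigma: float
    background_local: float
    residual_rms: float
    success: bool


@dataclass
class DriftPath:
    """Per-frame rigid displacements (dx, dy) in pixels relative to frame 0."""

    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 2 or self.displacements.shape[1] != 2:
            raise ValueError("displacements must have shape (T, 2)")
        if not np.allclose(self.displacements[0], 0.0):
            raise ValueError("frame 0 displacement must be (0, 0)")

    def __len__(self) -> int:
        return len(self.displacements)


def robust_noise_sd(frame: np.ndarray) -> float:
    """Noise sd from the median absolute deviation (outlier-immune)."""
    med = np.median(frame)
    return 1.4826 * np.median(np.abs(frame - med))


def estimate_drift(movie: MovieStack, upsample_factor: int = 50) -> DriftPath:
    """Estimate per-frame rigid drift by cross-correlation against frame 0.

    Returns the displacement *of the scene* in each frame relative to frame 0
    (i.e. the applied drift; subtract it to register).  Featureless frames
    yield zero displacement with a warning.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate drift")
    ref = movie.frames[0]
    disp = np.zeros((movie.n_frames, 2))
    if np.ptp(ref) == 0:
        warnings.warn("featureless reference frame; reporting zero drift")
        return DriftPath(disp)
    for k in range(1, movie.n_frames):
        frame = movie.frames[k]
        if np.ptp(frame) == 0:
            warnings.warn(f"featureless frame {k}; zero displacement assumed")
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None)
        # shift registers `frame` onto `ref`: scene displacement is -shift,
        # reported (dx, dy) = (cols, rows)
        disp[k] = (-shift[1], -shift[0])
    return DriftPath(disp)


def correct_drift(movie: MovieStack, drift: DriftPath | None = None) -> MovieStack:
    """Shift every frame back by its estimated displacement (spline interp)."""
    if drift is None:
        drift = estimate_drift(movie)
    out = np.empty_like(movie.frames)
    out[0] = movie.frames[0]
    for k in range(1, movie.n_frames):
        dx, dy = drift.displacements[k]
        out[k] = ndimage.shift(movie.frames[k], (-dy, -dx), order=3, mode="nearest")
    return MovieStack(
        frames=out,
        frame_interval=movie.frame_interval,
        pixel_positions=movie.pixel_positions,
        psf_sigma=movie.psf_sigma,
        truth_traces=movie.truth_traces,
        drift_path=None,
        background=movie.background,
    )


def subtract_background(movie: MovieStack, radius: float | None = None,
                        clip: bool = True) -> MovieStack:
    """Remove slowly varying background with a per-frame median filter.

    ``radius`` defaults to 10 x psf_sigma so spots do not bias the estimate.
    Output pixels are clipped at 0 when ``clip`` (for display/detection);
    photometry should use ``clip=False``.
    """
    if radius is None:
        radius = 10.0 * movie.psf_sigma
    size = 2 * int(np.ceil(radius)) + 1
    out = np.empty_like(movie.frames)
    for k in range(movie.n_frames):
        bg = ndimage.median_filter(movie.frames[k], size=size, mode="nearest")
        out[k] = movie.frames[k] - bg
    if clip:
        out = np.clip(out, 0.0, None)
    return MovieStack(
        frames=out,
        frame_interval=movie.frame_interval,
        pixel_positions=movie.pixel_positions,
        psf_sigma=movie.psf_sigma,
        truth_traces=movie.truth_traces,
        drift_path=movie.drift_path,
        background=0.0,
    )


def detect_spots(frame: np.ndarray, threshold_sigma: float = 5.0,
                 psf_sigma: float = 1.5) -> np.ndarray:
    """Integer-pixel spot candidates: thresholded local maxima with NMS.

    A pixel qualifies if it is the maximum within a (2 x psf_sigma)-radius
    neighbourhood and exceeds ``threshold_sigma`` times the robust noise sd
    of the (background-corrected) frame.
    """
    if threshold_sigma <= 0:
        raise ValueError("threshold_sigma must be positive")
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        return np.empty((0, 2), dtype=int)
    noise = robust_noise_sd(frame)
    if noise == 0:
        noise = frame.std() or 1.0
    nms_size = 2 * int(np.ceil(2 * psf_sigma)) + 1
    local_max = ndimage.maximum_filter(frame, size=nms_size, mode="nearest")
    mask = (frame == local_max) & (frame > threshold_sigma * noise)
    ys, xs = np.nonzero(mask)
    return np.column_stack([xs, ys]).astype(int)


def _gauss2d_model(p, xx, yy):
    amp, x0, y0, sigma, off = p
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)) + off


def localize_spot(frame: np.ndarray, candidate, psf_sigma: float = 1.5,
                  window_half: int | None = None) -> SpotFit:
    """Sub-pixel localization by least-squares 2D Gaussian fit on a window.

    ``success`` is False when the window is clipped by the frame edge, the
    fit diverges, the centre leaves the window, or the fitted width falls
    outside [0.5, 3] x psf_sigma.
    """
    frame = np.asarray(frame, dtype=float)
    cx, cy = int(round(candidate[0])), int(round(candidate[1]))
    if window_half is None:
        window_half = int(np.ceil(3 * psf_sigma))
    h, w = frame.shape

    def fail():
        return SpotFit(float(cx), float(cy), 0.0, psf_sigma, 0.0,
                       float("nan"), False)

    if (cx - window_half < 0 or cx + window_half >= w
            or cy - window_half < 0 or cy + window_half >= h):
        return fail()
    win = frame[cy - window_half:cy + window_half + 1,
                cx - window_half:cx + window_half + 1]
    if np.ptp(win) == 0:
        return fail()

    yy, xx = np.mgrid[cy - window_half:cy + window_half + 1,
                      cx - window_half:cx + window_half + 1]
    off0 = float(win.min())
    amp0 = float(win.max() - off0)
    p0 = [amp0, float(cx), float(cy), psf_sigma, off0]
    try:
        res = optimize.least_squares(
            lambda p: (_gauss2d_model(p, xx, yy) - win).ravel(), p0,
            bounds=([0, cx - window_half, cy - window_half, 1e-3, -np.inf],
                    [np.inf, cx + window_half, cy + window_half, 10 * psf_sigma, np.inf]),
            method="trf", max_nfev=200)
    except Exception:
        return fail()
    amp, x0, y0, sigma, off = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    ok = (res.success and amp > 0
          and 0.5 * psf_sigma <= sigma <= 3.0 * psf_sigma)
    return SpotFit(float(x0), float(y0), float(amp), float(sigma),
                   float(off), rms, bool(ok))


def extract_traces(movie: MovieStack, positions: np.ndarray | None = None,
                   aperture_radius: float | None = None) -> list[Trace]:
    """Fixed-aperture photometry at the mRNA map positions.

    Per frame, the trace value is the background-corrected sum over a
    circular aperture (default radius 2 x psf_sigma), divided by the PSF
    volume ``2*pi*sigma^2`` and by the enclosed-energy fraction of the
    aperture, so trace units equal the rendered PSF *peak* amplitude.
    Molecules within 3 x psf_sigma of the border are skipped with a warning;
    overlapping apertures are flagged with a warning.
    """
    sigma = movie.psf_sigma
    if positions is None:
        positions = movie.pixel_positions
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if aperture_radius is None:
        aperture_radius = 2.0 * sigma
    h, w = movie.shape
    margin = 3.0 * sigma

    if len(positions) > 1:
        from scipy.spatial.distance import pdist
        if len(positions) and pdist(positions).min() < 2 * aperture_radius:
            warnings.warn("overlapping photometry apertures detected")

    # fraction of a 2D Gaussian inside the aperture
    frac = 1.0 - np.exp(-aperture_radius**2 / (2.0 * sigma**2))
    norm = 2.0 * np.pi * sigma**2 * frac

    yy, xx = np.mgrid[0:h, 0:w]
    traces = []
    for i, (x, y) in enumerate(positions):
        if x < margin or x > w - 1 - margin or y < margin or y > h - 1 - margin:
            warnings.warn(f"position {i} within {margin:.1f} px of the border; skipped")
            continue
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= aperture_radius**2
        vals = movie.frames[:, mask].sum(axis=1) / norm
        traces.append(Trace(
            trace_id=i,
            times=movie.times(),
            intensities=vals,
            frame_interval=movie.frame_interval,
            truth=(movie.truth_traces[i].truth
                   if movie.truth_traces is not None and i < len(movie.truth_traces)
                   else None),
        ))
    return traces
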