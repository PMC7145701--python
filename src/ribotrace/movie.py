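"""Synthetic TIRF movie rendering.

Each bound antibody is drawn as a symmetric 2D Gaussian point-spread function
at its molecule's (sub-pixel) position; a constant background, optional rigid
drift, and pixel noise complete the frame.  The ground truth (positions,
event timelines, applied drift) travels with the stack so downstream imaging
code can be validated against it.

Coordinate convention: 0-based pixels, continuous positions, pixel centres at
integer coordinates; the time of frame ``k`` is ``k * frame_interval``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .simulate import SimParams, Trace

__all__ = ["MovieStack", "render_movie", "write_movie", "read_movie"]


@dataclass
class MovieStack:
    """Frame stack (T, H, W) with acquisition metadata and truth registry."""

    frames: np.ndarray
    frame_interval: float
    pixel_positions: np.ndarray          # (n, 2) continuous (x, y)
    psf_sigma: float
    truth_traces: list[Trace] | None = None
    drift_path: np.ndarray | None = None  # (T, 2) applied (dx, dy), px
    background: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        self.pixel_positions = np.atleast_2d(np.asarray(self.pixel_positions, dtype=float))
        if self.drift_path is not None:
            self.drift_path = np.asarray(self.drift_path, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _gaussian_spot(shape: tuple[int, int], x: float, y: float,
                   amplitude: float, sigma: float) -> np.ndarray:
    """Peak-normalised 2D Gaussian times ``amplitude`` on the full frame."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (xx - x) ** 2 + (yy - y) ** 2
    return amplitude * np.exp(-r2 / (2.0 * sigma**2))


def render_movie(
    traces: list[Trace],
    positions: np.ndarray,
    psf_sigma: float,
    background: float,
    params: SimParams,
    shape: tuple[int, int] = (64, 64),
    drift_path: np.ndarray | None = None,
    noise: str = "gaussian",
    noise_sigma: float | None = None,
    rng: np.random.Generator | None = None,
) -> MovieStack:
    """Render intensity traces into a TIRF-like image stack.

    The specific (above-baseline) part of each trace sets the PSF *peak*
    amplitude of its spot, so a spot's integrated intensity is
    ``amplitude * 2 * pi * psf_sigma**2``.  The diffusing-antibody baseline is
    not rendered into the image: under TIRF illumination it raises the
    camera background, which the constant ``background`` term stands for.

    ``noise``: "gaussian" (sd ``noise_sigma``, default ``params.noise_sigma``),
    "poisson" (per-pixel shot noise) or "none".
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(traces) != len(positions):
        raise ValueError("one position per trace required")
    h, w = shape
    if len(positions) and (
        positions[:, 0].min() < 0 or positions[:, 0].max() > w - 1
        or positions[:, 1].min() < 0 or positions[:, 1].max() > h - 1
    ):
        raise ValueError("positions outside frame bounds")

    n_frames = len(traces[0]) if traces else int(round(params.movie_length / params.frame_interval)) + 1
    if drift_path is None:
        drift = np.zeros((n_frames, 2))
    else:
        drift = np.asarray(drift_path, dtype=float)
        if drift.shape != (n_frames, 2):
            raise ValueError("drift_path must have shape (n_frames, 2)")

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(999,)))
    if noise_sigma is None:
        noise_sigma = params.noise_sigma

    # specific signal = trace minus its noiseless baseline ramp
    t0 = params.start_offset + params.dead_time
    frames = np.full((n_frames, h, w), float(background))
    for tr, (x, y) in zip(traces, positions):
        times = tr.times
        if tr.truth is not None:
            amp_t = np.zeros(n_frames)
            for b, u, dyes in zip(tr.truth.binding_times, tr.truth.unbind_times,
                                  tr.truth.dye_counts):
                amp_t += dyes * params.unit_brightness * (
                    (times >= b + t0) & (times < u + t0))
        else:
            baseline = np.clip((times - params.start_offset)
                               / max(params.dead_time, 1e-12), 0, 1) * params.baseline_level
            amp_t = tr.intensities - baseline
        active = np.nonzero(amp_t > 0)[0]
        for k in active:
            dx, dy = drift[k]
            frames[k] += _gaussian_spot((h, w), x + dx, y + dy, amp_t[k], psf_sigma)

    if noise == "gaussian" and noise_sigma > 0:
        frames += rng.normal(0.0, noise_sigma, size=frames.shape)
    elif noise == "poisson":
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    elif noise not in ("none", "gaussian"):
        raise ValueError(f"unknown noise model {noise!r}")

    return MovieStack(
        frames=np.clip(frames, 0.0, None),
        frame_interval=params.frame_interval,
        pixel_positions=positions,
        psf_sigma=psf_sigma,
        truth_traces=traces,
        drift_path=drift,
        background=background,
    )


def write_movie(movie: MovieStack, tiff_path, sidecar_path=None) -> None:
    """Write a 16-bit multi-page TIFF plus a JSON sidecar with the metadata."""
    arr = np.clip(movie.frames, 0, 65535).astype(np.uint16)
    tifffile.imwrite(tiff_path, arr)
    if sidecar_path is not None:
        meta = {
            "frame_interval": movie.frame_interval,
            "psf_sigma": movie.psf_sigma,
            "background": movie.background,
            "pixel_positions": movie.pixel_positions.tolist(),
            "drift_path": None if movie.drift_path is None else movie.drift_path.tolist(),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_movie(tiff_path, sidecar_path=None) -> MovieStack:
    frames = tifffile.imread(tiff_path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    meta = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    return MovieStack(
        frames=frames,
        frame_interval=float(meta.get("frame_interval", 1.0)),
        pixel_positions=np.asarray(meta.get("pixel_positions", np.empty((0, 2)))),
        psf_sigma=float(meta.get("psf_sigma", 1.5)),
        drift_path=None if meta.get("drift_path") is None
        else np.asarray(meta["drift_path"]),
        background=float(meta.get("background", 0.0)),
    )
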