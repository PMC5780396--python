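"""Biospeckle activity maps and transect signal-to-noise.

The central quantity is the generalized-differences (GD) index: for a
time-lapse stack of speckle frames ``I_1 .. I_N`` recorded at one light-sheet
position, the activity at a pixel is

    GD = sum_i sum_j |I_{i+j} - I_i|

i.e. the summed absolute intensity difference over frame pairs.  Static
scatterers (soil particles, dead animals, saturated roots) give a temporally
constant speckle pattern and therefore GD ~ 0 apart from sensor noise, while
moving scatterers (live nematodes) decorrelate the speckle between frames and
light up in the GD map.  By default the double sum runs over *all* unordered
frame pairs; a ``max_lag`` variant restricts the time increment ``j``.

Image quality is quantified by the transect signal-to-noise ratio

    SN = (I_s - <I>) / sigma

where ``I_s`` is the intensity at the detected object on a line profile and
``<I>`` and ``sigma`` are the mean and standard deviation of the profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numba
import numpy as np
from skimage.draw import line as _raster_line

from .errors import ZeroVarianceError

__all__ = [
    "FrameStack",
    "GDImage",
    "Transect",
    "SNResult",
    "generalized_differences",
    "signal_to_noise",
    "extract_transect",
]


@dataclass
class FrameStack:
    """A time series of speckle frames recorded at one light-sheet position.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, ny, nx)`` with non-negative intensities
        (typically uint8 or uint16 digital numbers).
    timestamps
        Optional acquisition times in seconds, one per frame.
    position_index
        Index of the light-sheet position within the volume scan.
    z_position_um
        Physical stage position of this stack in micrometres.
    """

    frames: np.ndarray
    timestamps: Optional[np.ndarray] = None
    position_index: int = 0
    z_position_um: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, ny, nx) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if np.issubdtype(self.frames.dtype, np.floating) and (self.frames < 0).any():
            raise ValueError("frame intensities must be non-negative")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.frames.shape[0],):
                raise ValueError("timestamps must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def image_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class GDImage:
    """A generalized-differences activity map for one stack position."""

    values: np.ndarray
    source_position: int = 0
    lag_policy: str = "all-pairs"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if (self.values < 0).any():
            raise ValueError("GD values are sums of absolute differences and cannot be negative")


@dataclass
class Transect:
    """An ordered line profile of intensities with a marked signal sample."""

    samples: np.ndarray
    signal_index: int
    coords: Optional[np.ndarray] = None  # (n, 2) row/col of each sample

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 3:
            raise ValueError("a transect needs at least 3 samples")
        if not 0 <= self.signal_index < self.samples.size:
            raise ValueError("signal_index must point at one of the samples")


@dataclass
class SNResult:
    """Transect signal-to-noise: ``sn = (i_s - mean) / sd``."""

    sn: float
    i_s: float
    mean: float
    sd: float


@numba.njit(cache=True)
def _gd_allpairs_u8(frames):  # pragma: no cover - exercised via wrapper
    """All-pairs GD for uint8 stacks via per-pixel value counting.

    Uses the identity  sum_{i<j} |x_i - x_j| = sum_t L_t (N - L_t)  where
    ``L_t`` counts samples <= t; for 8-bit data the threshold sweep is cheap
    and avoids the O(N^2) pair loop.
    """
    n, npix = frames.shape
    out = np.empty(npix, dtype=np.int64)
    cnt = np.empty(256, dtype=np.int32)
    for p in range(npix):
        lo = 255
        hi = 0
        for i in range(n):
            v = frames[i, p]
            if v < lo:
                lo = v
            if v > hi:
                hi = v
        for v in range(lo, hi + 1):
            cnt[v] = 0
        for i in range(n):
            cnt[frames[i, p]] += 1
        acc = 0
        ncum = 0
        for v in range(lo, hi):
            ncum += cnt[v]
            acc += ncum * (n - ncum)
        out[p] = acc
    return out


def _gd_allpairs_sorted(frames: np.ndarray) -> np.ndarray:
    """All-pairs GD via the sorted-sample identity (any numeric dtype).

    With ascending order statistics ``x_(0) <= ... <= x_(N-1)`` at a pixel,
    ``sum_{i<j} |x_i - x_j| = sum_k (2k - N + 1) x_(k)``.
    """
    n = frames.shape[0]
    flat = np.ascontiguousarray(frames.reshape(n, -1).T)
    flat = np.sort(flat, axis=1)
    weights = (2.0 * np.arange(n) - n + 1.0)
    return flat.astype(np.float64) @ weights


def generalized_differences(
    stack: FrameStack | np.ndarray,
    max_lag: Optional[int] = None,
    normalized: bool = False,
) -> GDImage:
    """Compute the generalized-differences activity map of a frame stack.

    Parameters
    ----------
    stack
        A :class:`FrameStack` or a raw ``(n_frames, ny, nx)`` array.
    max_lag
        If ``None`` (default) the sum covers every unordered frame pair,
        matching the reading of the double sum as the total variation within
        the stack.  If an integer ``k >= 1``, only time increments
        ``j <= k`` contribute (lag-limited GD).
    normalized
        Divide by the number of contributing pairs, making maps comparable
        across stacks of different length.  Off by default (raw sum).

    Returns
    -------
    GDImage
        Non-negative float32 activity map; zero wherever the pixel series is
        constant.
    """
    if isinstance(stack, FrameStack):
        frames = stack.frames
        position = stack.position_index
    else:
        frames = np.asarray(stack)
        if frames.ndim != 3:
            raise ValueError("expected a (n_frames, ny, nx) array")
        position = 0
    n = frames.shape[0]
    if n < 2:
        raise ValueError("GD needs at least 2 frames")

    if max_lag is not None:
        if max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        max_lag = min(max_lag, n - 1)

    if max_lag is None or max_lag == n - 1:
        policy = "all-pairs"
        if frames.dtype == np.uint8:
            gd = _gd_allpairs_u8(frames.reshape(n, -1)).astype(np.float64)
        else:
            gd = _gd_allpairs_sorted(frames)
        gd = gd.reshape(frames.shape[1:])
        n_pairs = n * (n - 1) // 2
    else:
        policy = f"max-lag-{max_lag}"
        work = frames.astype(np.int64 if frames.dtype.kind in "ui" else np.float64)
        gd = np.zeros(frames.shape[1:], dtype=np.float64)
        for j in range(1, max_lag + 1):
            gd += np.abs(work[j:] - work[:-j]).sum(axis=0)
        n_pairs = sum(n - j for j in range(1, max_lag + 1))

    if normalized:
        gd = gd / n_pairs
        policy += "-normalized"
    return GDImage(values=gd.astype(np.float32), source_position=position, lag_policy=policy)


def signal_to_noise(
    transect: Transect,
    exclude_halfwidth: Optional[int] = None,
) -> SNResult:
    """Transect signal-to-noise ratio ``SN = (I_s - <I>) / sigma``.

    ``<I>`` and ``sigma`` (sample standard deviation, ``n - 1`` denominator)
    are taken over the whole profile by default, signal sample included.
    Passing ``exclude_halfwidth=h`` instead estimates the background mean and
    noise from samples farther than ``h`` positions from the signal, the
    convention used in MRI-style S/N measurements where the object itself
    must not inflate the noise estimate; this is the mode used when comparing
    brightfield and GD contrast, since an included bright object bounds SN by
    ``sqrt(n)`` regardless of the true contrast.

    Raises
    ------
    ZeroVarianceError
        If the reference samples have zero variance.
    """
    samples = transect.samples
    i_s = float(samples[transect.signal_index])
    if exclude_halfwidth is None:
        ref = samples
    else:
        if exclude_halfwidth < 0:
            raise ValueError("exclude_halfwidth must be >= 0")
        idx = np.arange(samples.size)
        ref = samples[np.abs(idx - transect.signal_index) > exclude_halfwidth]
        if ref.size < 2:
            raise ValueError("exclusion window leaves fewer than 2 background samples")
    mean = float(np.mean(ref))
    sd = float(np.std(ref, ddof=1))
    if sd == 0.0:
        raise ZeroVarianceError("transect has zero intensity variance; SN is undefined")
    return SNResult(sn=(i_s - mean) / sd, i_s=i_s, mean=mean, sd=sd)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.hypot(*(p - a)))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return float(np.hypot(*(p - proj)))


def extract_transect(
    image: np.ndarray,
    start: Sequence[int],
    end: Sequence[int],
    signal_point: Sequence[float],
) -> Transect:
    """Read a straight line profile through an image.

    Coordinates are ``(row, col)`` pixel indices.  The segment is rasterized
    with Bresenham's algorithm so every sample is an actual pixel value (no
    interpolation); ``signal_point`` must lie on the segment within half a
    pixel and is snapped to the nearest sample.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    r0, c0 = int(start[0]), int(start[1])
    r1, c1 = int(end[0]), int(end[1])
    for name, (r, c) in (("start", (r0, c0)), ("end", (r1, c1))):
        if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
            raise ValueError(f"{name} point {(r, c)} is outside the image {image.shape}")
    rr, cc = _raster_line(r0, c0, r1, c1)
    if rr.size < 3:
        raise ValueError("transect is shorter than 3 samples")
    sp = np.asarray(signal_point, dtype=float)
    dist = _point_segment_distance(
        sp, np.array([r0, c0], dtype=float), np.array([r1, c1], dtype=float)
    )
    if dist > 0.5 + 1e-9:
        raise ValueError(
            f"signal_point {tuple(sp)} is {dist:.2f} px off the transect (tolerance 0.5 px)"
        )
    coords = np.stack([rr, cc], axis=1)
    signal_index = int(np.argmin(((coords - sp) ** 2).sum(axis=1)))
    return Transect(samples=image[rr, cc].astype(float), signal_index=signal_index, coords=coords)
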