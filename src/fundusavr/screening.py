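"""Frame screening: video splitting, fundus detection, 0-100 quality scoring
and Max(Q) reference selection.

The original pipeline screened frames with a convolutional classifier trained
on tens of thousands of private fundus images.  Here the screen is a small
set of deterministic classical features computed on the frame downscaled to
192 x 192 px (the same working size): the contrast between the bright
circular field of view and its dark surround, a mid-range mean-intensity
term, and dark-ridge (vessel) texture energy.  The decision threshold and
the ridge-energy scale were calibrated once on a seeded set of 100 phantom
fundus and 100 non-fundus fixtures (see ``scripts/calibrate_is_fundus.py``,
which regenerates the set and reports the achieved accuracy).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import sato, sobel
from skimage.transform import resize

from .errors import NoUsableFramesError, VideoReadError

__all__ = [
    "QualityScore", "VideoFrames", "split_video", "is_fundus",
    "fundus_confidence", "score_quality", "select_reference",
    "IS_FUNDUS_THRESHOLD",
]

#: decision threshold on the combined fundus confidence (calibrated once on
#: the shipped 200-fixture set; midway between the score populations)
IS_FUNDUS_THRESHOLD = 0.5

# fixed feature scales (see module docstring / methods note)
_SCREEN_SIZE = 192
_FOV_CONTRAST_SCALE = 0.30     # FOV-vs-corner contrast that saturates the score
_RIDGE_SCALE = 4.0e-3          # sato energy that saturates the ridge score
_BRIGHT_TARGET = 0.45          # quality brightness target mid-level
_BRIGHT_HALFWIDTH = 0.25       # half of the full-width tolerance 0.5
_SHARPNESS_SCALE = 0.05        # p99 sobel soft-normalization constant
_CLARITY_SCALE = 0.05          # p95 sato soft-normalization constant


@dataclass(frozen=True)
class QualityScore:
    """Per-frame 0-100 composite quality with its four sub-scores."""

    frame_index: int
    disc_score: float
    vessel_clarity: float
    sharpness: float
    brightness: float
    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    @property
    def total(self) -> float:
        subs = (self.disc_score, self.vessel_clarity, self.sharpness, self.brightness)
        w = np.asarray(self.weights, dtype=float)
        return float(100.0 * np.dot(w / w.sum(), subs))


@dataclass
class VideoFrames:
    """An ordered frame sequence with timestamps (``index / fps`` seconds)."""

    frames: list[np.ndarray]
    fps: float

    def __len__(self) -> int:
        return len(self.frames)

    def timestamp(self, index: int) -> float:
        return index / self.fps

    def __iter__(self):
        return iter(self.frames)


def _to_float(img: np.ndarray, path=None, index=None) -> np.ndarray:
    if img.ndim == 3:  # collapse an accidental RGB read of a grayscale PNG
        img = img[..., 0]
    img = np.asarray(img)
    if img.dtype == np.uint8:
        img = img / 255.0
    elif img.dtype == np.uint16:
        img = img / 65535.0
    else:
        img = img.astype(float)
    if not np.all(np.isfinite(img)):
        where = f" (frame {index}, {path})" if path is not None else ""
        raise VideoReadError(f"non-finite pixel values{where}")
    return img


_NUM_RE = re.compile(r"(\d+)")


def _natural_key(p: Path):
    return [int(t) if t.isdigit() else t for t in _NUM_RE.split(p.name)]


def split_video(source: str | Path, fps: float = 16.0) -> VideoFrames:
    """Split a video source into an ordered, timestamped frame sequence.

    ``source`` may be a directory of numbered PNG/TIFF frames (the primary
    interchange format) or a media container readable by imageio.  Frames are
    indexed from 0 and timestamped ``index / fps``.
    """
    src = Path(source)
    frames: list[np.ndarray] = []
    if src.is_dir():
        paths = sorted(
            [p for p in src.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")],
            key=_natural_key,
        )
        if not paths:
            raise VideoReadError(f"no frame images found in directory {src}")
        for i, p in enumerate(paths):
            try:
                frames.append(_to_float(iio.imread(p), path=p, index=i))
            except VideoReadError:
                raise
            except Exception as exc:  # noqa: BLE001 - surface decoder failures
                raise VideoReadError(f"failed reading frame {i} ({p}): {exc}") from exc
        return VideoFrames(frames=frames, fps=fps)
    if not src.exists():
        raise VideoReadError(f"video source does not exist: {src}")
    try:
        for i, img in enumerate(iio.imiter(src)):
            frames.append(_to_float(img, path=src, index=i))
    except Exception as exc:  # noqa: BLE001
        raise VideoReadError(
            f"failed reading container {src} at frame {len(frames)}: {exc}"
        ) from exc
    if not frames:
        raise VideoReadError(f"no frames decoded from {src}")
    return VideoFrames(frames=frames, fps=fps)


def _downscale(frame: np.ndarray) -> np.ndarray:
    return resize(frame.astype(float), (_SCREEN_SIZE, _SCREEN_SIZE),
                  anti_aliasing=True, preserve_range=True)


def _fov_masks(shape) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - (w - 1) / 2, yy - (h - 1) / 2)
    inner = r < 0.35 * min(h, w)
    outer = r > 0.62 * min(h, w)  # the corner region beyond any circular FOV
    return inner, outer


def fundus_confidence(frame: np.ndarray) -> float:
    """Confidence in [0, 1] that the frame shows a fundus.

    Computed on the 192 x 192 reduction: (a) bright-FOV-on-dark-surround
    contrast, (b) mid-range mean intensity of the central region, (c)
    dark-ridge texture energy in the centre.  The FOV term gates the other
    two multiplicatively -- texture or mid-range brightness without the
    circular field of view is not evidence of a fundus.
    """
    small = _downscale(np.nan_to_num(frame, nan=0.0))
    inner, outer = _fov_masks(small.shape)
    mu_in = float(small[inner].mean())
    mu_out = float(small[outer].mean())
    fov = float(np.clip((mu_in - mu_out) / _FOV_CONTRAST_SCALE, 0.0, 1.0))
    mid = float(np.clip(1.0 - abs(mu_in - 0.5) / 0.35, 0.0, 1.0))
    ridge = float(sato(small, sigmas=(2.0, 3.0, 4.0), black_ridges=True)[inner].mean())
    ridge = float(np.clip(ridge / _RIDGE_SCALE, 0.0, 1.0))
    return float(np.clip(fov * (0.5 + 0.25 * mid + 0.25 * ridge), 0.0, 1.0))


def is_fundus(frame: np.ndarray, threshold: float = IS_FUNDUS_THRESHOLD
              ) -> tuple[bool, float]:
    """Deterministic fundus/non-fundus screen; flag true iff confidence >= threshold."""
    if frame.size == 0 or not np.any(np.isfinite(frame)):
        return False, 0.0
    conf = fundus_confidence(frame)
    return bool(conf >= threshold), conf


def score_quality(frame: np.ndarray, disc=None,
                  weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
                  frame_index: int = 0) -> QualityScore:
    """0-100 quality score from disc confidence, vessel clarity, sharpness
    and brightness (equal weights by default).

    ``disc`` may be a pre-computed disc location; otherwise disc detection is
    attempted and a miss scores 0.
    """
    from .registration import locate_disc  # local import to avoid a cycle
    from .errors import DiscNotFoundError

    img = np.nan_to_num(frame, nan=0.0)
    if disc is None:
        try:
            disc = locate_disc(img)
        except DiscNotFoundError:
            disc = None
    disc_score = float(disc.confidence) if disc is not None else 0.0

    inner, _ = _fov_masks(img.shape)
    # texture metrics are edge-dominated upper percentiles of a lightly
    # denoised frame: mean energy would reward pixel noise rather than
    # structure, and raw gradients would too
    denoised = gaussian_filter(img, 1.0)
    clarity = float(np.percentile(
        sato(denoised, sigmas=(2.0, 4.0, 6.0), black_ridges=True)[inner], 95))
    vessel_clarity = clarity / (clarity + _CLARITY_SCALE)
    grad = float(np.percentile(sobel(denoised)[inner], 99))
    sharpness = grad / (grad + _SHARPNESS_SCALE)
    mu = float(img[inner].mean())
    brightness = float(np.clip(1.0 - abs(mu - _BRIGHT_TARGET) / _BRIGHT_HALFWIDTH, 0.0, 1.0))
    return QualityScore(frame_index=frame_index, disc_score=disc_score,
                        vessel_clarity=float(vessel_clarity),
                        sharpness=float(sharpness), brightness=brightness,
                        weights=weights)


def select_reference(scores: list[QualityScore]) -> int:
    """Index of the Max(Q) frame; ties broken toward the lowest frame index."""
    if not scores:
        raise NoUsableFramesError("no quality-scored frames to choose a reference from")
    best = max(scores, key=lambda s: (s.total, -s.frame_index))
    return best.frame_index
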