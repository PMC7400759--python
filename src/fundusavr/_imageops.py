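"""Shared low-level raster helpers: rigid warps and masked bilinear sampling.

Conventions used throughout the package:

* images are 2-D float arrays with intensities in [0, 1];
* ``x`` is the column coordinate, ``y`` the row coordinate, both 0-based with
  the origin at the top-left pixel centre;
* rotations are in degrees, counterclockwise positive, about the frame centre
  ``((w-1)/2, (h-1)/2)``;
* invalid pixels (outside the source frame after a warp) carry ``NaN`` and are
  excluded from any later profile fit.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import SimilarityTransform, warp

__all__ = ["frame_center", "rigid_transform", "rigid_warp", "sample_bilinear"]


def frame_center(shape: tuple[int, int]) -> tuple[float, float]:
    """Geometric centre (x, y) of an ``(h, w)`` raster."""
    h, w = shape[:2]
    return (w - 1) / 2.0, (h - 1) / 2.0


def rigid_transform(shape, dx: float, dy: float, alpha_deg: float) -> SimilarityTransform:
    """Forward map: rotate ``alpha_deg`` CCW about the frame centre, then translate."""
    cx, cy = frame_center(shape)
    return (
        SimilarityTransform(translation=(-cx, -cy))
        + SimilarityTransform(rotation=np.deg2rad(alpha_deg))
        + SimilarityTransform(translation=(cx + dx, cy + dy))
    )


def rigid_warp(image: np.ndarray, dx: float, dy: float, alpha_deg: float,
               cval: float = np.nan, order: int = 1) -> np.ndarray:
    """Resample ``image`` under the forward rigid map (bilinear by default).

    Pixels with no source data are filled with ``cval`` (``NaN`` marks them as
    invalid for downstream profile fits).
    """
    if alpha_deg == 0.0 and dx == 0.0 and dy == 0.0:
        return image.astype(float, copy=True)
    tform = rigid_transform(image.shape, dx, dy, alpha_deg)
    return warp(image.astype(float), tform.inverse, order=order, cval=cval,
                mode="constant", preserve_range=True)


def transform_points(points: np.ndarray, shape, dx: float, dy: float,
                     alpha_deg: float) -> np.ndarray:
    """Apply the forward rigid map to an ``(n, 2)`` array of (x, y) points."""
    tform = rigid_transform(shape, dx, dy, alpha_deg)
    return tform(np.atleast_2d(points))


def sample_bilinear(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear samples of ``image`` at (xs, ys); NaN where the sample footprint
    leaves the frame or touches an invalid (NaN) pixel."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    finite = np.isfinite(image)
    filled = np.where(finite, image, 0.0)
    coords = np.vstack([ys.ravel(), xs.ravel()])
    vals = map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
    # validity: the full bilinear footprint must be finite and inside the frame
    weight = map_coordinates(finite.astype(float), coords, order=1,
                             mode="constant", cval=0.0)
    vals = np.where(weight > 0.999, vals, np.nan)
    return vals.reshape(xs.shape)
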