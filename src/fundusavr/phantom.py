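"""Ground-truthed synthetic fundus frames and videos.

The phantom emulates what a handheld monochrome fundus camera sees: a bright
circular field of view (FOV) on a dark surround, a bright quasi-elliptical
optic disc, and dark retinal vessels leaving the disc.  Every vessel is
rendered as an inverted Gaussian ridge: the intensity deficit at distance
``d`` from the centerline is ``contrast * exp(-d^2 / (2 sigma^2))`` with
``sigma = fwhm_px / (2 sqrt(2 ln 2))``, so the true full width at half
maximum of the cross-section is exactly ``fwhm_px``.  This makes the phantom
the definitional oracle for the Gaussian line-profile diameter estimator.

Corruptions are applied in a fixed order -- render, Gaussian blur, additive
noise, rigid transform -- so the recorded truth poses refer to the emitted
image.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from ._imageops import rigid_warp, transform_points
from .errors import PhantomSpecError

__all__ = [
    "OUTSIDE_FOV_LEVEL",
    "VesselPhantom",
    "FramePhantomSpec",
    "FrameTruth",
    "VesselTruth",
    "TruthManifest",
    "JitterSpec",
    "default_phantom_spec",
    "default_seed_positions",
    "generate_fundus_frame",
    "generate_non_fundus_frame",
    "generate_video",
    "write_frame_dir",
]

#: intensity of the region outside the circular field of view (and of pixels
#: that leave the frame under a rigid transform)
OUTSIDE_FOV_LEVEL = 0.02

_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = factor * sigma

NON_FUNDUS_KINDS = ("black", "saturated", "noise", "defocus_scene")


@dataclass(frozen=True)
class VesselPhantom:
    """A single rendered vessel: polyline centerline with a Gaussian cross-section."""

    centerline: tuple[tuple[float, float], ...]
    fwhm_px: float
    contrast: float
    vclass: str  # "arteriole" | "venule"

    def validate(self) -> None:
        if len(self.centerline) < 2:
            raise PhantomSpecError("centerline: needs at least 2 control points")
        if not self.fwhm_px > 0:
            raise PhantomSpecError("fwhm_px: must be > 0")
        if not self.contrast > 0:
            raise PhantomSpecError("contrast: must be > 0")
        if self.vclass not in ("arteriole", "venule"):
            raise PhantomSpecError(f"vclass: unknown class {self.vclass!r}")

    @property
    def sigma_px(self) -> float:
        return self.fwhm_px / _FWHM_FACTOR


@dataclass(frozen=True)
class FramePhantomSpec:
    """Scene description for one synthetic fundus frame.

    The default geometry is half the camera's native 1280x1024 raster; the
    native size is available by passing ``width=1280, height=1024`` and
    scaling the geometry accordingly.
    """

    width: int = 640
    height: int = 512
    fov_center: tuple[float, float] = (320.0, 256.0)
    fov_radius: float = 235.0
    disc_center: tuple[float, float] = (210.0, 190.0)
    disc_radii: tuple[float, float] = (42.0, 38.0)  # (semi-major, semi-minor)
    disc_brightness: float = 0.35
    vessels: tuple[VesselPhantom, ...] = ()
    background_level: float = 0.55
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise PhantomSpecError("width/height: must be positive")
        if not self.fov_radius > max(self.disc_radii):
            raise PhantomSpecError("fov_radius: must exceed the disc semi-major axis")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd: must be >= 0")
        if self.blur_sigma < 0:
            raise PhantomSpecError("blur_sigma: must be >= 0")
        if not (0.0 <= self.disc_brightness <= 1.0):
            raise PhantomSpecError("disc_brightness: must be in [0, 1]")
        for v in self.vessels:
            v.validate()
        arts = [v for v in self.vessels if v.vclass == "arteriole"]
        vens = [v for v in self.vessels if v.vclass == "venule"]
        if len(arts) == 1 and len(vens) == 1:
            a, v = arts[0], vens[0]
            if not (v.fwhm_px > a.fwhm_px and v.contrast > a.contrast):
                raise PhantomSpecError(
                    "vessels: paired venule must be wider and darker than its arteriole"
                )

    @property
    def disc_radius_equiv(self) -> float:
        """Circle-equivalent disc radius: geometric mean of the semi-axes."""
        return math.sqrt(self.disc_radii[0] * self.disc_radii[1])


@dataclass(frozen=True)
class FrameTruth:
    """Ground truth for one emitted frame."""

    index: int
    is_fundus: bool
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    disc_center: tuple[float, float] | None = None  # post-transform position
    disc_radius: float | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["translation"] = list(self.translation)
        if self.disc_center is not None:
            d["disc_center"] = list(self.disc_center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FrameTruth":
        return cls(
            index=int(d["index"]),
            is_fundus=bool(d["is_fundus"]),
            rotation_deg=float(d["rotation_deg"]),
            translation=tuple(float(t) for t in d["translation"]),
            disc_center=None if d.get("disc_center") is None
            else tuple(float(t) for t in d["disc_center"]),
            disc_radius=None if d.get("disc_radius") is None else float(d["disc_radius"]),
        )


@dataclass(frozen=True)
class VesselTruth:
    """Ground truth for one rendered vessel (constant width along the centerline)."""

    vclass: str
    fwhm_px: float
    contrast: float
    centerline: tuple[tuple[float, float], ...]

    def to_dict(self) -> dict:
        return {
            "vclass": self.vclass,
            "fwhm_px": self.fwhm_px,
            "contrast": self.contrast,
            "centerline": [list(p) for p in self.centerline],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselTruth":
        return cls(
            vclass=str(d["vclass"]),
            fwhm_px=float(d["fwhm_px"]),
            contrast=float(d["contrast"]),
            centerline=tuple(tuple(float(c) for c in p) for p in d["centerline"]),
        )


@dataclass
class TruthManifest:
    """Losslessly serializable record of everything the generators decided."""

    seed: int
    fps: float
    frames: list[FrameTruth] = field(default_factory=list)
    vessels: list[VesselTruth] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "fps": self.fps,
            "frames": [f.to_dict() for f in self.frames],
            "vessels": [v.to_dict() for v in self.vessels],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TruthManifest":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = source
            try:
                if "\n" not in source and Path(source).exists():
                    text = Path(source).read_text()
            except OSError:
                pass
        d = json.loads(text)
        return cls(
            seed=int(d["seed"]),
            fps=float(d["fps"]),
            frames=[FrameTruth.from_dict(f) for f in d["frames"]],
            vessels=[VesselTruth.from_dict(v) for v in d["vessels"]],
        )


def _arc_polyline(center, angles_deg, radii) -> tuple[tuple[float, float], ...]:
    """Control points at given polar (angle, radius) offsets from ``center``."""
    cx, cy = center
    pts = []
    for a, r in zip(angles_deg, radii):
        th = math.radians(a)
        pts.append((cx + r * math.cos(th), cy + r * math.sin(th)))
    return tuple(pts)


def default_phantom_spec(*, noise_sd: float = 0.01, blur_sigma: float = 0.6,
                         arteriole_fwhm: float = 7.0, venule_fwhm: float = 10.0,
                         rotation_deg: float = 0.0,
                         translation: tuple[float, float] = (0.0, 0.0)) -> FramePhantomSpec:
    """A paired arteriole/venule scene with both vessels leaving the disc.

    Both vessels are gentle arcs; their control points lie at fixed radii from
    the disc centre so a seed at two disc radii falls exactly on a control
    point (see :func:`default_seed_positions`).
    """
    disc_center = (210.0, 190.0)
    r2 = 2.0 * math.sqrt(42.0 * 38.0)  # two circle-equivalent disc radii
    venule = VesselPhantom(
        centerline=_arc_polyline(disc_center, (22, 26, 30, 33, 35), (45, r2, 130, 185, 245)),
        fwhm_px=venule_fwhm, contrast=0.30, vclass="venule",
    )
    arteriole = VesselPhantom(
        centerline=_arc_polyline(disc_center, (58, 61, 64, 66, 68), (45, r2, 130, 185, 240)),
        fwhm_px=arteriole_fwhm, contrast=0.20, vclass="arteriole",
    )
    return FramePhantomSpec(
        disc_center=disc_center,
        vessels=(arteriole, venule),
        noise_sd=noise_sd,
        blur_sigma=blur_sigma,
        rotation_deg=rotation_deg,
        translation=translation,
    )


def default_seed_positions(spec: FramePhantomSpec) -> dict[str, tuple[float, float]]:
    """Seed positions at two disc radii for the default paired phantom: the
    second control point of each vessel (which is placed at that radius)."""
    out = {}
    for v in spec.vessels:
        out[v.vclass] = v.centerline[1]
    return out


def _polyline_distance(xx: np.ndarray, yy: np.ndarray,
                       pts: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Per-pixel Euclidean distance to a polyline (min over segments)."""
    d = np.full(xx.shape, np.inf)
    for i in range(len(pts) - 1):
        p = np.asarray(pts[i], dtype=float)
        q = np.asarray(pts[i + 1], dtype=float)
        v = q - p
        denom = float(v @ v)
        if denom == 0.0:
            dx, dy = xx - p[0], yy - p[1]
            d = np.minimum(d, np.hypot(dx, dy))
            continue
        t = np.clip(((xx - p[0]) * v[0] + (yy - p[1]) * v[1]) / denom, 0.0, 1.0)
        d = np.minimum(d, np.hypot(xx - (p[0] + t * v[0]), yy - (p[1] + t * v[1])))
    return d


def render_scene(spec: FramePhantomSpec) -> np.ndarray:
    """Noise-free, blur-free, untransformed rendering of the scene."""
    spec.validate()
    yy, xx = np.mgrid[0: spec.height, 0: spec.width].astype(float)
    fx, fy = spec.fov_center
    r_fov = np.hypot(xx - fx, yy - fy)
    # soft FOV edge ~1.5 px wide
    fov_w = expit((spec.fov_radius - r_fov) / 1.5)
    img = OUTSIDE_FOV_LEVEL + (spec.background_level - OUTSIDE_FOV_LEVEL) * fov_w

    # disc: plateau with a sigmoid edge whose half-maximum lies exactly on the
    # ellipse, so a half-contrast threshold recovers the true boundary
    dx, dy = xx - spec.disc_center[0], yy - spec.disc_center[1]
    a, b = spec.disc_radii
    r_ell = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    edge = 1.5 / math.sqrt(a * b)  # ~1.5 px edge softness in normalized units
    img += spec.disc_brightness * expit((1.0 - r_ell) / edge) * fov_w

    for vessel in spec.vessels:
        d = _polyline_distance(xx, yy, vessel.centerline)
        img -= vessel.contrast * np.exp(-d ** 2 / (2.0 * vessel.sigma_px ** 2)) * fov_w
    return np.clip(img, 0.0, 1.0)


def generate_fundus_frame(spec: FramePhantomSpec, seed: int = 0,
                          index: int = 0) -> tuple[np.ndarray, FrameTruth]:
    """Render one frame: scene -> blur -> noise -> rigid transform.

    Returns the image and a :class:`FrameTruth` whose disc position is the
    post-transform (emitted-frame) position.
    """
    img = render_scene(spec)
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    dx, dy = spec.translation
    if spec.rotation_deg != 0.0 or dx != 0.0 or dy != 0.0:
        img = rigid_warp(img, dx, dy, spec.rotation_deg, cval=OUTSIDE_FOV_LEVEL)
    center = transform_points(
        np.array([spec.disc_center]), img.shape, dx, dy, spec.rotation_deg
    )[0]
    truth = FrameTruth(
        index=index, is_fundus=True, rotation_deg=spec.rotation_deg,
        translation=(float(dx), float(dy)),
        disc_center=(float(center[0]), float(center[1])),
        disc_radius=spec.disc_radius_equiv,
    )
    return img, truth


def generate_non_fundus_frame(kind: str, seed: int = 0, width: int = 640,
                              height: int = 512) -> np.ndarray:
    """Frames that must fail the fundus screen: no FOV, disc or vessel structure."""
    rng = np.random.default_rng(seed)
    if kind == "black":
        return np.zeros((height, width))
    if kind == "saturated":
        return np.ones((height, width))
    if kind == "noise":
        return rng.uniform(0.0, 1.0, (height, width))
    if kind == "defocus_scene":
        # heavily smoothed random field rescaled to mid-range: plausible camera
        # pointing at a defocused non-retinal scene
        f = gaussian_filter(rng.normal(size=(height, width)), 25.0)
        lo, hi = f.min(), f.max()
        return 0.25 + 0.5 * (f - lo) / max(hi - lo, 1e-12)
    raise PhantomSpecError(f"kind: unknown non-fundus kind {kind!r}")


@dataclass(frozen=True)
class JitterSpec:
    """Per-frame camera shake: Gaussian rotation (deg) and translation (px)."""

    rotation_sd_deg: float = 1.0
    translation_sd_px: float = 1.0


def generate_video(spec: FramePhantomSpec, n_seconds: float, fps: int = 16,
                   jitter: JitterSpec | None = None,
                   non_fundus_fraction: float = 0.0,
                   seed: int = 0) -> tuple[list[np.ndarray], TruthManifest]:
    """Emit ``n_seconds * fps`` frames with per-frame pose jitter around the
    spec's base pose, interleaving exactly ``round(n * fraction)`` non-fundus
    frames at seeded positions.
    """
    spec.validate()
    if fps < 1:
        raise PhantomSpecError("fps: must be >= 1")
    if not (0.0 <= non_fundus_fraction < 1.0):
        raise PhantomSpecError("non_fundus_fraction: must be in [0, 1)")
    n = int(round(n_seconds * fps))
    jitter = jitter or JitterSpec(0.0, 0.0)
    rng = np.random.default_rng(seed)

    n_bad = int(round(n * non_fundus_fraction))
    bad_idx = set(rng.choice(n, size=n_bad, replace=False).tolist()) if n_bad else set()

    base = render_scene(spec)
    if spec.blur_sigma > 0:
        base = gaussian_filter(base, spec.blur_sigma)

    manifest = TruthManifest(seed=seed, fps=float(fps))
    for v in spec.vessels:
        manifest.vessels.append(VesselTruth(
            vclass=v.vclass, fwhm_px=v.fwhm_px, contrast=v.contrast,
            centerline=v.centerline,
        ))

    frames: list[np.ndarray] = []
    for i in range(n):
        if i in bad_idx:
            kind = NON_FUNDUS_KINDS[int(rng.integers(len(NON_FUNDUS_KINDS)))]
            frames.append(generate_non_fundus_frame(
                kind, seed=int(rng.integers(2 ** 31)),
                width=spec.width, height=spec.height))
            manifest.frames.append(FrameTruth(index=i, is_fundus=False))
            continue
        alpha = spec.rotation_deg + (rng.normal(0.0, jitter.rotation_sd_deg)
                                     if jitter.rotation_sd_deg > 0 else 0.0)
        dx = spec.translation[0] + (rng.normal(0.0, jitter.translation_sd_px)
                                    if jitter.translation_sd_px > 0 else 0.0)
        dy = spec.translation[1] + (rng.normal(0.0, jitter.translation_sd_px)
                                    if jitter.translation_sd_px > 0 else 0.0)
        img = base
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, base.shape)
        img = np.clip(img, 0.0, 1.0)
        if alpha != 0.0 or dx != 0.0 or dy != 0.0:
            img = rigid_warp(img, dx, dy, alpha, cval=OUTSIDE_FOV_LEVEL)
        center = transform_points(np.array([spec.disc_center]), img.shape,
                                  dx, dy, alpha)[0]
        frames.append(img)
        manifest.frames.append(FrameTruth(
            index=i, is_fundus=True, rotation_deg=float(alpha),
            translation=(float(dx), float(dy)),
            disc_center=(float(center[0]), float(center[1])),
            disc_radius=spec.disc_radius_equiv,
        ))
    return frames, manifest


def calibration_fixture_set(seed: int = 0, n_per_class: int = 100,
                            size: tuple[int, int] = (320, 256)
                            ) -> list[tuple[bool, np.ndarray]]:
    """The seeded fundus-screen calibration set: ``n_per_class`` phantom
    fundus frames spanning realistic degradation (noise, blur, pose jitter)
    plus ``n_per_class`` non-fundus frames cycling through all kinds.

    Rendered at 320 x 256 (the screen works on a 192 x 192 reduction, so the
    raster only needs to exceed that); labels are True for fundus.
    """
    rng = np.random.default_rng(seed)
    w, h = size
    scale = w / 640.0
    items: list[tuple[bool, np.ndarray]] = []
    for _ in range(n_per_class):
        spec = default_phantom_spec(
            noise_sd=float(rng.uniform(0.0, 0.05)),
            blur_sigma=float(rng.uniform(0.0, 2.5)),
            rotation_deg=float(rng.uniform(-15, 15)),
            translation=(float(rng.uniform(-10, 10)), float(rng.uniform(-10, 10))),
        )
        spec = dataclasses.replace(
            spec, width=w, height=h,
            fov_center=(spec.fov_center[0] * scale, spec.fov_center[1] * scale),
            fov_radius=spec.fov_radius * scale,
            disc_center=(spec.disc_center[0] * scale, spec.disc_center[1] * scale),
            disc_radii=(spec.disc_radii[0] * scale, spec.disc_radii[1] * scale),
            vessels=tuple(
                dataclasses.replace(
                    v, fwhm_px=v.fwhm_px * scale,
                    centerline=tuple((x * scale, y * scale) for x, y in v.centerline))
                for v in spec.vessels),
        )
        img, _ = generate_fundus_frame(spec, seed=int(rng.integers(2 ** 31)))
        items.append((True, img))
    for i in range(n_per_class):
        kind = NON_FUNDUS_KINDS[i % len(NON_FUNDUS_KINDS)]
        items.append((False, generate_non_fundus_frame(
            kind, seed=int(rng.integers(2 ** 31)), width=w, height=h)))
    return items


def write_frame_dir(frames: list[np.ndarray], out_dir: str | Path,
                    manifest: TruthManifest | None = None) -> Path:
    """Write frames as 16-bit grayscale PNGs ``frame_0000.png ...`` plus the
    truth manifest as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(frames):
        arr = np.clip(f, 0.0, 1.0)
        iio.imwrite(out / f"frame_{i:04d}.png", (arr * 65535.0 + 0.5).astype(np.uint16))
    if manifest is not None:
        manifest.to_json(out / "manifest.json")
    return out
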