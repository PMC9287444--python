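"""Deterministic synthetic test data with recorded ground truth.

Everything the rest of the package needs for end-to-end testing is
generated here, with no downloads: dark-field particle images (bright
disks on a dark background, the look of plankton silhouette imagery),
noisy navigation tracks with injected position spikes, and complete
factory-ready datasets.  Every generator is a pure function of its seed
and parameters — the same call reproduces the same bytes — and records
the ground truth (particle counts, exact mean colours, spike indices,
true trajectory) in a manifest that recovery tests treat as the oracle.

The defaults emulate a deep-sea towed-camera transect: a 600 s track
sampled at 1 Hz drifting at ~0.65 m/s over abyssal depths, half-meter
Gaussian position noise, and five 100 m navigation spikes of the kind
acoustic positioning dropouts produce.  What the generator does *not*
emulate: photorealistic seafloor texture, lighting falloff, or
correlated (random-walk) navigation error.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .factory import CameraGeometry, ProjectConfig
from .model import PersonRef, format_datetime
from .navigation import EARTH_RADIUS_M

__all__ = [
    "ImageTruth",
    "TrackTruth",
    "FixtureManifest",
    "make_image",
    "make_track",
    "make_dataset",
]

_EPOCH_START = _dt.datetime(2022, 7, 15, 10, 0, 0, tzinfo=_dt.timezone.utc)

# A towed-camera transect site on an abyssal nodule field.
_BASE_LAT = 11.85
_BASE_LON = -117.45
_BASE_DEPTH_M = 4150.0

_DISK_RADIUS = 5
_DISK_VALUE = 200
_PLACEMENT_RETRIES = 2000


@dataclass(frozen=True)
class ImageTruth:
    """Ground truth for one generated image."""

    path: Path
    particle_count: int
    mean_colour: tuple[float, float, float]
    entropy_bits: float
    background: int
    datetime: str | None = None


@dataclass(frozen=True)
class TrackTruth:
    """Ground truth for one generated navigation track."""

    path: Path
    timestamps: tuple[str, ...]
    true_latitude: tuple[float, ...]
    true_longitude: tuple[float, ...]
    true_depth: tuple[float, ...]
    outlier_indices: tuple[int, ...]
    spike_magnitude_m: float
    noise_sigma_m: float


@dataclass
class FixtureManifest:
    """Single source of ground truth for a generated dataset."""

    seed: int
    root: Path
    images: list[ImageTruth] = field(default_factory=list)
    track: TrackTruth | None = None
    config: ProjectConfig | None = None
    config_path: Path | None = None
    image_dir: Path | None = None


def _entropy_of(counts: np.ndarray, total: int) -> float:
    # direct histogram entropy; kept independent of ifdo.content
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def make_image(
    seed: int,
    path: str | Path,
    size: tuple[int, int] = (256, 256),
    particles: int = 7,
    background: int = 30,
) -> ImageTruth:
    """Write a synthetic dark-field particle image as PNG.

    ``particles`` bright disks (radius 5 px, gray value 200) are placed
    without overlap by rejection sampling on a uniform background.  The
    recorded ground truth (count, exact mean colour, histogram entropy)
    is computed from the pixel array itself, so the lossless PNG carries
    it exactly.
    """
    if particles < 0:
        raise ValueError("particles must be >= 0")
    rng = np.random.default_rng(seed)
    width, height = size
    arr = np.full((height, width), background, dtype=np.uint8)
    centers: list[tuple[int, int]] = []
    margin = _DISK_RADIUS + 2
    min_sep = 2 * _DISK_RADIUS + 3
    tries = 0
    while len(centers) < particles:
        if tries >= _PLACEMENT_RETRIES:
            raise ValueError(
                f"could not place {particles} non-overlapping disks in {size}"
            )
        tries += 1
        cx = int(rng.integers(margin, width - margin))
        cy = int(rng.integers(margin, height - margin))
        if all(math.hypot(cx - x, cy - y) >= min_sep for x, y in centers):
            centers.append((cx, cy))
    yy, xx = np.mgrid[0:height, 0:width]
    for cx, cy in centers:
        arr[(xx - cx) ** 2 + (yy - cy) ** 2 <= _DISK_RADIUS**2] = _DISK_VALUE

    rgb = np.stack([arr] * 3, axis=-1)
    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    counts = np.bincount(arr.ravel(), minlength=256)
    mean = float(arr.mean())
    return ImageTruth(
        path=path,
        particle_count=particles,
        mean_colour=(round(mean, 2),) * 3,
        entropy_bits=_entropy_of(counts, arr.size),
        background=background,
    )


def _meters_to_latlon(
    east: np.ndarray, north: np.ndarray, lat0: float, lon0: float
) -> tuple[np.ndarray, np.ndarray]:
    lat = lat0 + np.degrees(north / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(east / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    return lat, lon


def make_track(
    seed: int,
    path: str | Path,
    duration_s: float = 600.0,
    rate_hz: float = 1.0,
    noise_sigma_m: float = 0.5,
    outliers: int = 5,
    spike_magnitude_m: float = 100.0,
    start: _dt.datetime = _EPOCH_START,
) -> TrackTruth:
    """Write a synthetic navigation track as CSV with known ground truth.

    The true trajectory is a smooth constant-speed transect with gentle
    sinusoidal cross-track curvature in a local meter frame, mapped to
    latitude/longitude around an abyssal survey site.  Per-sample
    Gaussian noise (``noise_sigma_m``) and ``outliers`` horizontal
    spikes of ``spike_magnitude_m`` at recorded indices are added on
    top.  All timestamps carry the explicit UTC designator.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    # smooth low-order base trajectory in local meters
    east = 0.6 * t
    north = 0.25 * t + 8.0 * np.sin(2 * math.pi * t / max(duration_s, 1.0))
    depth = _BASE_DEPTH_M + 3.0 * np.sin(2 * math.pi * t / (2 * max(duration_s, 1.0)))

    true_lat, true_lon = _meters_to_latlon(east, north, _BASE_LAT, _BASE_LON)

    noisy_east = east + rng.normal(0.0, noise_sigma_m, n)
    noisy_north = north + rng.normal(0.0, noise_sigma_m, n)
    noisy_depth = depth + rng.normal(0.0, 0.2 * noise_sigma_m, n)

    if outliers > len(range(3, n - 3)):
        raise ValueError("more outliers requested than eligible samples")
    idx = np.sort(rng.choice(np.arange(3, n - 3), size=outliers, replace=False))
    angles = rng.uniform(0, 2 * math.pi, size=outliers)
    noisy_east[idx] += spike_magnitude_m * np.cos(angles)
    noisy_north[idx] += spike_magnitude_m * np.sin(angles)

    lat, lon = _meters_to_latlon(noisy_east, noisy_north, _BASE_LAT, _BASE_LON)
    stamps = tuple(
        format_datetime(start + _dt.timedelta(seconds=float(s))) for s in t
    )
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("datetime,latitude,longitude,depth\n")
        for stamp, la, lo, de in zip(stamps, lat, lon, noisy_depth):
            fh.write(f"{stamp},{float(la):.10f},{float(lo):.10f},{float(de):.4f}\n")
    return TrackTruth(
        path=path,
        timestamps=stamps,
        true_latitude=tuple(float(v) for v in true_lat),
        true_longitude=tuple(float(v) for v in true_lon),
        true_depth=tuple(float(v) for v in depth),
        outlier_indices=tuple(int(i) for i in idx),
        spike_magnitude_m=spike_magnitude_m,
        noise_sigma_m=noise_sigma_m,
    )


def _default_config() -> ProjectConfig:
    return ProjectConfig(
        project="SO268",
        event="SO268-1_021",
        platform="OFOS",
        sensor="CAM-1",
        context="Abyssal nodule field monitoring",
        abstract=(
            "Towed-camera seafloor photo transect across a manganese "
            "nodule field for megafauna and particle-flux assessment."
        ),
        pi=PersonRef(name="Josiah Carberry", orcid="0000-0002-1825-0097"),
        creators=[PersonRef(name="Ann Deckhand")],
        license="CC-BY-4.0",
        copyright="(c) 2022 the expedition participants",
        camera=CameraGeometry(
            horizontal_fov_deg=84.0,
            vertical_fov_deg=64.0,
            image_width_px=256,
            image_height_px=256,
        ),
        meters_above_ground=2.5,
        capture_defaults={
            "acquisition": "photo",
            "deployment": "survey",
            "illumination": "artificial light",
            "capture_mode": "timer",
        },
    )


def _write_config(config: ProjectConfig, path: Path) -> None:
    import yaml

    raw: dict = {
        "project": config.project,
        "event": config.event,
        "platform": config.platform,
        "sensor": config.sensor,
        "context": config.context,
        "abstract": config.abstract,
        "license": config.license,
        "copyright": config.copyright,
        "handle_server": config.handle_server,
        "handle_prefix": config.handle_prefix,
        "coordinate_reference_system": config.coordinate_reference_system,
        "meters_above_ground": config.meters_above_ground,
        "capture_defaults": dict(config.capture_defaults),
    }
    if config.pi is not None:
        raw["pi"] = config.pi.to_mapping()
    if config.creators:
        raw["creators"] = [c.to_mapping() for c in config.creators]
    if config.camera is not None:
        raw["camera"] = {
            "horizontal_fov_deg": config.camera.horizontal_fov_deg,
            "vertical_fov_deg": config.camera.vertical_fov_deg,
            "image_width_px": config.camera.image_width_px,
            "image_height_px": config.camera.image_height_px,
        }
    path.write_text(yaml.safe_dump(raw, sort_keys=True))


def make_dataset(
    seed: int,
    out_dir: str | Path,
    n_images: int = 20,
    track_duration_s: float = 600.0,
    outliers: int = 5,
) -> FixtureManifest:
    """Generate a complete factory-ready dataset with known ground truth.

    Layout under ``out_dir``: ``images/`` (timestamp-named PNGs whose
    capture times lie inside the track's span), ``track.csv`` and
    ``config.yaml``.  Per-image particle counts vary deterministically
    with the seed.  ``n_images = 0`` yields a valid empty dataset.
    """
    out_dir = Path(out_dir)
    image_dir = out_dir / "images"
    image_dir.mkdir(parents=True, exist_ok=True)
    manifest = FixtureManifest(seed=seed, root=out_dir, image_dir=image_dir)

    track_path = out_dir / "track.csv"
    manifest.track = make_track(
        seed=seed, path=track_path, duration_s=track_duration_s, outliers=outliers
    )

    if n_images:
        margin = 0.05 * track_duration_s
        offsets = np.linspace(margin, track_duration_s - margin, n_images)
    else:
        offsets = np.array([])
    rng = np.random.default_rng(seed + 1)
    for i, offset in enumerate(offsets):
        stamp = _EPOCH_START + _dt.timedelta(seconds=round(float(offset), 3))
        label = format_datetime(stamp)
        name = (
            "raw_"
            + stamp.strftime("%Y%m%dT%H%M%S")
            + f".{stamp.microsecond // 1000:03d}Z.png"
        )
        particles = int(rng.integers(3, 10))
        truth = make_image(
            seed=seed + 100 + i, path=image_dir / name, particles=particles
        )
        manifest.images.append(
            ImageTruth(
                path=truth.path,
                particle_count=truth.particle_count,
                mean_colour=truth.mean_colour,
                entropy_bits=truth.entropy_bits,
                background=truth.background,
                datetime=label,
            )
        )

    manifest.config = _default_config()
    manifest.config_path = out_dir / "config.yaml"
    _write_config(manifest.config, manifest.config_path)
    return manifest
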