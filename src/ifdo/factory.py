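"""The iFDO factory: from raw images + navigation to one validated file.

The factory pipeline mirrors how marine imaging datasets are curated in
practice: verify that image times are UTC, curate the navigation track
(outlier rejection, smoothing), assign a random UUID to each image and
to the set, mint the item UUIDs into the image files, rename the files
to the ``<project>_<event>_<sensor>_<date>_<time>`` convention, hash the
minted files, geolocate each image on the curated track, derive the
camera footprint where an altitude is known, and assemble everything
into a single iFDO document in which set-wide values live once in the
header and items carry only what deviates.

The emitted document is validated; error-severity findings block the
output unless explicitly forced, because a FAIR publication needs the
complete core section.
"""

from __future__ import annotations

import datetime as _dt
import math
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml
from PIL import Image

from . import identity, navigation
from .model import (
    IfdoDocument,
    ItemMetadata,
    PersonRef,
    SetHeader,
    format_datetime,
    parse_datetime,
)
from .vocabulary import ValidationReport, builtin_vocabulary, validate

__all__ = [
    "ProjectConfig",
    "CameraGeometry",
    "FootprintResult",
    "FootprintRect",
    "FactoryError",
    "rename_file",
    "footprint",
    "overlap_fraction",
    "create_ifdo",
    "image_timestamp",
]

_SAFE_COMPONENT_RE = re.compile(r"^[A-Za-z0-9_-]+$")
_FILENAME_TIME_RE = re.compile(r"(\d{8})[T_](\d{6})(?:\.(\d{1,6}))?Z?")
_EXIF_DT_ORIGINAL = 0x9003


class FactoryError(RuntimeError):
    """Pipeline failure; carries per-file error details where relevant."""

    def __init__(self, message: str, details: Mapping[str, str] | None = None):
        super().__init__(message)
        self.details = dict(details or {})


@dataclass(frozen=True)
class CameraGeometry:
    """Pinhole geometry of a nadir-looking camera."""

    horizontal_fov_deg: float
    vertical_fov_deg: float
    image_width_px: int
    image_height_px: int

    def __post_init__(self) -> None:
        for fov in (self.horizontal_fov_deg, self.vertical_fov_deg):
            if not 0 < fov < 180:
                raise ValueError(f"field of view must be in (0, 180) degrees, got {fov}")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")


@dataclass
class ProjectConfig:
    """Project-level inputs to the factory.

    Everything here becomes a header default in the produced iFDO; the
    camera geometry and navigation parameters steer the derivation
    steps.  ``project``, ``event`` and ``sensor`` appear in canonical
    filenames and must therefore be filename-safe.
    """

    project: str
    event: str
    platform: str
    sensor: str
    context: str = ""
    abstract: str = ""
    pi: PersonRef | None = None
    creators: list[PersonRef] = field(default_factory=list)
    license: str = "CC-BY-4.0"
    copyright: str = ""
    handle_server: str = "https://hdl.handle.net"
    handle_prefix: str = "20.500.12085"
    coordinate_reference_system: str = "EPSG:4326"
    camera: CameraGeometry | None = None
    meters_above_ground: float | None = None
    capture_defaults: dict[str, Any] = field(default_factory=dict)
    nav_window: int = 11
    nav_mad_multiplier: float = 5.0
    nav_sensor_uncertainty_m: float = 0.0
    nav_extrapolation_tolerance_s: float = 5.0

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ProjectConfig":
        raw = yaml.safe_load(Path(source).read_text())
        camera = raw.pop("camera", None)
        pi = raw.pop("pi", None)
        creators = raw.pop("creators", [])
        return cls(
            camera=CameraGeometry(**camera) if camera else None,
            pi=PersonRef.from_mapping(pi) if pi else None,
            creators=[PersonRef.from_mapping(c) for c in creators],
            **raw,
        )


def rename_file(
    config: ProjectConfig,
    datetime_utc: _dt.datetime | str,
    original: str | Path,
    taken: set[str] | None = None,
) -> str:
    """Canonical image filename: project, event, sensor, date, time.

    Form: ``<project>_<event>_<sensor>_<YYYYMMDD>_<HHMMSS.sss><ext>``
    with a lowercased extension.  If ``taken`` already contains the
    name (a distinct file with the same timestamp), an ``_1``, ``_2``
    … suffix is appended before the extension.
    """
    for label, component in (
        ("project", config.project), ("event", config.event), ("sensor", config.sensor)
    ):
        if not _SAFE_COMPONENT_RE.match(component):
            raise ValueError(f"{label} {component!r} is not filename-safe")
    if isinstance(datetime_utc, str):
        datetime_utc = parse_datetime(datetime_utc)
    if datetime_utc.tzinfo is None:
        raise ValueError("timestamp must be UTC-aware")
    stamp = datetime_utc.astimezone(_dt.timezone.utc)
    date_part = stamp.strftime("%Y%m%d")
    time_part = stamp.strftime("%H%M%S") + f".{stamp.microsecond // 1000:03d}"
    ext = Path(original).suffix.lower()
    base = f"{config.project}_{config.event}_{config.sensor}_{date_part}_{time_part}"
    name = base + ext
    if taken is not None:
        counter = 1
        while name in taken:
            name = f"{base}_{counter}{ext}"
            counter += 1
        taken.add(name)
    return name


@dataclass(frozen=True)
class FootprintResult:
    area_square_meter: float
    pixels_per_meter: float
    width_m: float
    height_m: float


def footprint(geometry: CameraGeometry, altitude_m: float) -> FootprintResult:
    """Seafloor footprint of a nadir pinhole camera at a given altitude.

    width = 2 h tan(hfov/2), height = 2 h tan(vfov/2); the image scale
    (pixels per meter) follows from the sensor width.
    """
    if altitude_m <= 0:
        raise ValueError(f"altitude must be positive, got {altitude_m}")
    width_m = 2.0 * altitude_m * math.tan(math.radians(geometry.horizontal_fov_deg) / 2)
    height_m = 2.0 * altitude_m * math.tan(math.radians(geometry.vertical_fov_deg) / 2)
    return FootprintResult(
        area_square_meter=width_m * height_m,
        pixels_per_meter=geometry.image_width_px / width_m,
        width_m=width_m,
        height_m=height_m,
    )


@dataclass(frozen=True)
class FootprintRect:
    """An axis-aligned footprint rectangle in a local meter frame."""

    center_x: float
    center_y: float
    width: float
    height: float

    @property
    def area(self) -> float:
        return self.width * self.height


def overlap_fraction(fp_a: FootprintRect, fp_b: FootprintRect) -> float:
    """Intersection area over the smaller footprint's area, in [0, 1]."""
    dx = min(fp_a.center_x + fp_a.width / 2, fp_b.center_x + fp_b.width / 2) - max(
        fp_a.center_x - fp_a.width / 2, fp_b.center_x - fp_b.width / 2
    )
    dy = min(fp_a.center_y + fp_a.height / 2, fp_b.center_y + fp_b.height / 2) - max(
        fp_a.center_y - fp_a.height / 2, fp_b.center_y - fp_b.height / 2
    )
    if dx <= 0 or dy <= 0:
        return 0.0
    smaller = min(fp_a.area, fp_b.area)
    if smaller <= 0:
        return 0.0
    return min(dx * dy / smaller, 1.0)


# ---------------------------------------------------------------------------
# Timestamps of images


def image_timestamp(path: str | Path) -> _dt.datetime:
    """Capture time of an image, UTC.

    Taken from embedded EXIF ``DateTimeOriginal`` when present, else
    parsed from the filename (``YYYYMMDD[T_]HHMMSS[.sss]``).  If both
    are present they must agree; a conflict is an error, never a silent
    preference.
    """
    path = Path(path)
    from_name: _dt.datetime | None = None
    match = _FILENAME_TIME_RE.search(path.name)
    if match:
        date_s, time_s, frac = match.groups()
        micro = int((frac or "0").ljust(6, "0"))
        from_name = _dt.datetime.strptime(date_s + time_s, "%Y%m%d%H%M%S").replace(
            microsecond=micro, tzinfo=_dt.timezone.utc
        )
    from_exif: _dt.datetime | None = None
    if path.suffix.lower() in (".jpg", ".jpeg"):
        with Image.open(path) as im:
            raw = im.getexif().get_ifd(0x8769).get(_EXIF_DT_ORIGINAL)
        if raw:
            from_exif = _dt.datetime.strptime(str(raw), "%Y:%m:%d %H:%M:%S").replace(
                tzinfo=_dt.timezone.utc
            )
    if from_name and from_exif:
        if abs((from_name - from_exif).total_seconds()) >= 1.0:
            raise FactoryError(
                f"{path.name}: filename time {from_name} conflicts with "
                f"embedded capture time {from_exif}"
            )
        return from_name  # sub-second precision only exists in the filename
    stamp = from_name or from_exif
    if stamp is None:
        raise FactoryError(f"{path.name}: no parseable capture timestamp")
    return stamp


# ---------------------------------------------------------------------------
# The factory process


_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def create_ifdo(
    image_dir: str | Path,
    nav: navigation.NavigationTrack,
    config: ProjectConfig,
    set_name: str | None = None,
    rng: random.Random | int | None = None,
    curate_nav: bool = True,
    force: bool = False,
) -> tuple[IfdoDocument, ValidationReport]:
    """Run the full factory pipeline over a directory of images.

    Images are minted and renamed **in place**.  UUID assignment is
    reproducible when ``rng`` is a seed or seeded generator, and the
    output is independent of file-discovery order (files are processed
    sorted by capture time, then name).  With error-severity validation
    findings the document is refused unless ``force`` is set.

    Returns the document together with its validation report.
    """
    image_dir = Path(image_dir)
    if isinstance(rng, int):
        rng = random.Random(rng)
    files = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )

    # 1. capture times, verified UTC
    errors: dict[str, str] = {}
    stamped: list[tuple[_dt.datetime, Path]] = []
    for path in files:
        try:
            stamped.append((image_timestamp(path), path))
        except FactoryError as exc:
            errors[path.name] = str(exc)
    if errors:
        raise FactoryError("capture timestamps could not be established", errors)
    stamped.sort(key=lambda pair: (pair[0], pair[1].name))
    utc_report = navigation.verify_utc([ts for ts, _ in stamped])
    if utc_report.non_monotone:
        # same capture second across cameras is fine; regressions are not
        pass

    # 2. curate navigation
    if curate_nav and len(nav):
        nav = navigation.remove_outliers(
            nav, window=config.nav_window, k=config.nav_mad_multiplier
        )
        nav = navigation.smooth(nav, window=config.nav_window)

    # 3. identities: one set UUID, then per-image UUIDs in canonical order
    set_uuid = identity.generate_uuid(rng)
    item_uuids = [identity.generate_uuid(rng) for _ in stamped]

    # 4-6. mint, rename, hash
    taken: set[str] = set()
    items: dict[str, ItemMetadata] = {}
    item_fields: dict[str, dict[str, Any]] = {}
    renamed_paths: dict[str, Path] = {}
    for (stamp, path), item_uuid in zip(stamped, item_uuids):
        try:
            identity.mint_uuid(path, item_uuid)
            new_name = rename_file(config, stamp, path, taken)
            target = path.with_name(new_name)
            if target != path:
                if target.exists():
                    raise FactoryError(f"rename target {new_name} already exists")
                path = path.rename(target)
            digest = identity.compute_hash(path)
        except (identity.MintError, FactoryError, OSError) as exc:
            errors[path.name] = str(exc)
            continue
        item_fields[new_name] = {
            "datetime": format_datetime(stamp),
            "uuid": item_uuid,
            "hash_sha256": digest.hex,
        }
        renamed_paths[new_name] = path
    if errors:
        raise FactoryError("image curation failed", errors)

    # 7. geolocate image times on the curated track
    if len(nav) and item_fields:
        order = sorted(item_fields)
        fixes = navigation.interpolate_to(
            nav,
            [item_fields[name]["datetime"] for name in order],
            sensor_uncertainty_m=config.nav_sensor_uncertainty_m,
            extrapolation_tolerance_s=config.nav_extrapolation_tolerance_s,
        )
        for name, fix in zip(order, fixes):
            if fix.error:
                errors[name] = fix.error
                continue
            item_fields[name].update(
                latitude=fix.latitude,
                longitude=fix.longitude,
                depth=fix.depth,
                coordinate_uncertainty_meters=round(fix.uncertainty_meters, 3),
            )
    if errors:
        raise FactoryError("geolocation failed", errors)

    # 8. footprint-derived fields when geometry + altitude are known
    defaults: dict[str, Any] = {}
    if config.camera is not None and config.meters_above_ground is not None:
        fp = footprint(config.camera, config.meters_above_ground)
        defaults["meters_above_ground"] = config.meters_above_ground
        defaults["area_square_meter"] = round(fp.area_square_meter, 3)

    # 9. header assembly: config defaults + factored common item fields
    defaults.update(
        context=config.context,
        project=config.project,
        event=config.event,
        platform=config.platform,
        sensor=config.sensor,
        abstract=config.abstract,
        license=config.license,
        copyright=config.copyright,
        coordinate_reference_system=config.coordinate_reference_system,
    )
    if config.pi is not None:
        defaults["pi"] = config.pi.to_mapping()
    if config.creators:
        defaults["creators"] = [c.to_mapping() for c in config.creators]
    defaults.update(config.capture_defaults)

    if item_fields:
        shared = set.intersection(*(set(f) for f in item_fields.values()))
        names = list(item_fields)
        for fname in sorted(shared):
            first = item_fields[names[0]][fname]
            if all(item_fields[n][fname] == first for n in names[1:]):
                defaults[fname] = first
                for n in names:
                    del item_fields[n][fname]
    for name in sorted(item_fields):
        items[name] = ItemMetadata(item_fields[name])

    handle = identity.build_handle_url(
        config.handle_server, config.handle_prefix, set_uuid, view="ifdo"
    )
    header = SetHeader(
        name=set_name or f"{config.project} {config.event} {config.sensor}",
        uuid=set_uuid,
        handle=handle.render(),
        defaults=ItemMetadata(defaults),
    )
    doc = IfdoDocument(header=header, items=items)

    # 10. validate; refuse on errors unless forced
    report = validate(doc, builtin_vocabulary(doc.header.ifdo_version))
    if report.errors and not force:
        raise FactoryError(
            "document has error-severity validation findings; "
            "pass force=True to emit anyway",
            {f"{f.location}/{f.field}": f.message for f in report.errors},
        )
    return doc, report
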