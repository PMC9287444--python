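"""Domain model for iFDO documents.

An iFDO (image FAIR Digital Object) file is a YAML document with two
top-level parts: ``image-set-header`` holds set-wide metadata and default
values, ``image-set-items`` holds one record per image.  Item values
supersede header defaults field by field.  A photo item is a single
mapping of fields; a video item is a list of mappings whose first entry
gives video-wide defaults and whose subsequent entries describe single
timepoints.

In-file field names use the standard's hyphenated spelling
(``image-datetime``); in memory the ``image-`` prefix is stripped and
hyphens become underscores (``datetime``).  Fields outside the controlled
vocabulary are preserved verbatim under their file spelling so that
arbitrary extension metadata survives a parse/write round trip.
"""

from __future__ import annotations

import datetime as _dt
import re
import uuid as _uuid
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping, Union

import yaml

__all__ = [
    "IfdoDocument",
    "ItemMetadata",
    "SetHeader",
    "PersonRef",
    "LabelDef",
    "CreatorDef",
    "IfdoParseError",
    "IfdoStructureError",
    "IfdoSerializationError",
    "parse_ifdo",
    "write_ifdo",
    "resolve_item",
    "resolve_timepoint",
    "format_datetime",
    "parse_datetime",
]

HEADER_KEY = "image-set-header"
ITEMS_KEY = "image-set-items"

#: Header-only fields; must never appear (or be overridden) at item level.
SET_LEVEL_KEYS = ("image-set-name", "image-set-uuid", "image-set-handle")
VERSION_KEY = "image-set-ifdo-version"
DEFAULT_FORMAT_VERSION = "1.0.0"

#: Controlled item-level fields, by in-memory (underscored) name.
CORE_FIELDS = (
    "datetime",
    "latitude",
    "longitude",
    "depth",
    "coordinate_reference_system",
    "coordinate_uncertainty_meters",
    "uuid",
    "hash_sha256",
    "context",
    "project",
    "event",
    "platform",
    "sensor",
    "abstract",
    "pi",
    "creators",
    "license",
    "copyright",
)
CAPTURE_FIELDS = (
    "acquisition",
    "deployment",
    "illumination",
    "capture_mode",
    "area_square_meter",
    "meters_above_ground",
    "overlap_fraction",
    "camera_housing_viewport",
    "camera_calibration_model",
    "objective",
    "target_environment",
    "fauna_attraction",
    "temporal_constraints",
)
CONTENT_FIELDS = (
    "entropy",
    "particle_count",
    "average_colour",
    "mpeg7_colorstructure",
    "annotation_labels",
    "annotation_creators",
    "annotations",
)
KNOWN_FIELDS: tuple[str, ...] = CORE_FIELDS + CAPTURE_FIELDS + CONTENT_FIELDS


def file_key(name: str) -> str:
    """In-memory field name -> hyphenated in-file key (``image-…``)."""
    return "image-" + name.replace("_", "-")


def memory_name(key: str) -> str:
    """In-file key -> in-memory name, if the field is known; else the key."""
    if key.startswith("image-"):
        candidate = key[len("image-"):].replace("-", "_")
        if candidate in _KNOWN_SET:
            return candidate
    return key


_KNOWN_SET = frozenset(KNOWN_FIELDS)
_FILE_KEYS = {name: file_key(name) for name in KNOWN_FIELDS}

# Canonical datetime lexical form: ISO 8601 with an explicit UTC 'Z'.
DATETIME_RE = re.compile(r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}(\.\d+)?Z$")


def format_datetime(dt: _dt.datetime) -> str:
    """Render an aware UTC datetime in the canonical millisecond form."""
    if dt.tzinfo is None:
        raise ValueError("naive datetime: iFDO timestamps must be UTC-aware")
    dt = dt.astimezone(_dt.timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%S.") + f"{dt.microsecond // 1000:03d}Z"


def parse_datetime(text: str) -> _dt.datetime:
    """Parse a canonical ``…Z`` timestamp into an aware UTC datetime."""
    if not DATETIME_RE.match(text):
        raise ValueError(f"not a canonical UTC timestamp: {text!r}")
    return _dt.datetime.fromisoformat(text.replace("Z", "+00:00"))


class IfdoParseError(ValueError):
    """Malformed YAML input; carries the reported line where available."""


class IfdoStructureError(ValueError):
    """Well-formed YAML that is not an iFDO document."""


class IfdoSerializationError(ValueError):
    """A document invariant is violated; serialization is refused."""


class _StringTimestampLoader(yaml.SafeLoader):
    """SafeLoader that leaves timestamps as strings.

    The default loader would convert ``2022-07-15T10:00:00Z`` into a
    datetime object, destroying the lexical form (and the explicit UTC
    designator) that validation must inspect and round-trip.
    """


_StringTimestampLoader.add_constructor(
    "tag:yaml.org,2002:timestamp", _StringTimestampLoader.construct_yaml_str
)
# Drop the implicit resolver so scalars never match the timestamp tag.
_StringTimestampLoader.yaml_implicit_resolvers = {
    ch: [(tag, regexp) for tag, regexp in resolvers if tag != "tag:yaml.org,2002:timestamp"]
    for ch, resolvers in _StringTimestampLoader.yaml_implicit_resolvers.items()
}


@dataclass(frozen=True)
class PersonRef:
    """A person (PI or creator), optionally with an ORCID identifier."""

    name: str
    orcid: str | None = None

    def to_mapping(self) -> dict[str, str]:
        out = {"name": self.name}
        if self.orcid is not None:
            out["orcid"] = self.orcid
        return out

    @classmethod
    def from_mapping(cls, m: Mapping[str, Any]) -> "PersonRef":
        return cls(name=m["name"], orcid=m.get("orcid"))


@dataclass(frozen=True)
class LabelDef:
    """A semantic label usable by annotations; ``id`` is document-unique."""

    id: str
    name: str

    def to_mapping(self) -> dict[str, str]:
        return {"id": self.id, "name": self.name}


@dataclass(frozen=True)
class CreatorDef:
    """An annotator (human or machine); ``id`` is document-unique."""

    id: str
    name: str
    kind: str = "human"  # "human" | "machine"

    def to_mapping(self) -> dict[str, str]:
        return {"id": self.id, "name": self.name, "kind": self.kind}


class ItemMetadata:
    """An ordered bag of item-level metadata fields.

    Known fields are stored under their in-memory names, unknown fields
    verbatim under their in-file key.  All values are YAML-native
    (strings, numbers, lists, mappings); timestamps are canonical
    strings, not datetime objects.
    """

    __slots__ = ("_fields",)

    def __init__(self, fields: Mapping[str, Any] | None = None, **kw: Any):
        merged: dict[str, Any] = {}
        for k, v in {**(dict(fields) if fields else {}), **kw}.items():
            merged[memory_name(k)] = v
        self._fields = merged

    # -- mapping-ish protocol -------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return memory_name(name) in self._fields

    def __getitem__(self, name: str) -> Any:
        return self._fields[memory_name(name)]

    def get(self, name: str, default: Any = None) -> Any:
        return self._fields.get(memory_name(name), default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._fields)

    def __len__(self) -> int:
        return len(self._fields)

    def __getattr__(self, name: str) -> Any:
        if name in _KNOWN_SET:
            return self._fields.get(name)
        raise AttributeError(name)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ItemMetadata) and self._fields == other._fields

    def __repr__(self) -> str:
        return f"ItemMetadata({self._fields!r})"

    def keys(self) -> Iterator[str]:
        return iter(self._fields)

    def items(self) -> Iterator[tuple[str, Any]]:
        return iter(self._fields.items())

    # -- construction / conversion --------------------------------------------
    @classmethod
    def from_mapping(cls, m: Mapping[str, Any]) -> "ItemMetadata":
        return cls(m)

    def to_mapping(self) -> dict[str, Any]:
        """File representation: hyphenated keys, alphabetical order."""
        out = {}
        for name, value in self._fields.items():
            out[_FILE_KEYS.get(name, name)] = value
        return {k: out[k] for k in sorted(out)}

    def overlay(self, other: "ItemMetadata | None") -> "ItemMetadata":
        """Field-by-field merge; ``other``'s values win.

        Header-only set-level keys never propagate through an overlay.
        """
        merged = {k: v for k, v in self._fields.items() if k not in SET_LEVEL_KEYS}
        if other is not None:
            for k, v in other._fields.items():
                if k not in SET_LEVEL_KEYS:
                    merged[k] = v
        return ItemMetadata(merged)

    def without(self, *names: str) -> "ItemMetadata":
        drop = {memory_name(n) for n in names}
        return ItemMetadata({k: v for k, v in self._fields.items() if k not in drop})


#: A photo is a single field mapping; a video is a list whose entry 0 is
#: the video-wide defaults and entries 1..n are per-timepoint overrides.
ItemRecord = Union[ItemMetadata, list]


def is_video(record: ItemRecord) -> bool:
    return isinstance(record, list)


@dataclass
class SetHeader:
    """The image-set header: identity triple, format version, defaults."""

    name: str
    uuid: str
    handle: str
    ifdo_version: str = DEFAULT_FORMAT_VERSION
    defaults: ItemMetadata = field(default_factory=ItemMetadata)


@dataclass
class IfdoDocument:
    """One iFDO file: a header plus an ordered map of item records."""

    header: SetHeader
    items: dict[str, ItemRecord] = field(default_factory=dict)

    @property
    def format_version(self) -> str:
        return self.header.ifdo_version


def _require_uuid4(value: Any, what: str) -> None:
    try:
        parsed = _uuid.UUID(str(value))
    except (ValueError, AttributeError, TypeError):
        raise IfdoSerializationError(f"{what} is not a valid UUID: {value!r}") from None
    if parsed.version != 4:
        raise IfdoSerializationError(f"{what} is not a version-4 UUID: {value!r}")


_URL_RE = re.compile(r"^[a-z][a-z0-9+.-]*://\S+$", re.IGNORECASE)


def parse_ifdo(text: str) -> IfdoDocument:
    """Parse iFDO YAML text into a document.

    Unknown fields are preserved verbatim.  Photo items given as a
    one-element list are normalized to the single-object form.
    """
    try:
        raw = yaml.load(text, Loader=_StringTimestampLoader)
    except yaml.MarkedYAMLError as exc:
        mark = exc.problem_mark
        line = mark.line + 1 if mark is not None else "?"
        raise IfdoParseError(f"malformed YAML at line {line}: {exc.problem}") from exc
    except yaml.YAMLError as exc:  # pragma: no cover - unmarked errors are rare
        raise IfdoParseError(f"malformed YAML: {exc}") from exc

    if not isinstance(raw, Mapping):
        raise IfdoStructureError("top level of an iFDO file must be a mapping")
    for key in (HEADER_KEY, ITEMS_KEY):
        if key not in raw:
            raise IfdoStructureError(f"missing required top-level key {key!r}")

    raw_header = raw[HEADER_KEY]
    if not isinstance(raw_header, Mapping):
        raise IfdoStructureError(f"{HEADER_KEY!r} must be a mapping")
    header_fields = dict(raw_header)
    name = header_fields.pop("image-set-name", None)
    set_uuid = header_fields.pop("image-set-uuid", None)
    handle = header_fields.pop("image-set-handle", None)
    version = header_fields.pop(VERSION_KEY, DEFAULT_FORMAT_VERSION)
    missing = [k for k, v in zip(SET_LEVEL_KEYS, (name, set_uuid, handle)) if v is None]
    if missing:
        raise IfdoStructureError(f"header lacks required set-level fields: {missing}")
    header = SetHeader(
        name=str(name),
        uuid=str(set_uuid),
        handle=str(handle),
        ifdo_version=str(version),
        defaults=ItemMetadata(header_fields),
    )

    raw_items = raw[ITEMS_KEY]
    if raw_items is None:
        raw_items = {}
    if not isinstance(raw_items, Mapping):
        raise IfdoStructureError(f"{ITEMS_KEY!r} must be a mapping")
    items: dict[str, ItemRecord] = {}
    for item_name, value in raw_items.items():
        if isinstance(value, Mapping):
            items[str(item_name)] = ItemMetadata(value)
        elif isinstance(value, list):
            entries = []
            for i, entry in enumerate(value):
                if not isinstance(entry, Mapping):
                    raise IfdoStructureError(
                        f"item {item_name!r} entry {i} is not a mapping"
                    )
                entries.append(ItemMetadata(entry))
            if len(entries) == 1:
                # photo written in list form: normalize to single object
                items[str(item_name)] = entries[0]
            else:
                items[str(item_name)] = entries
        else:
            raise IfdoStructureError(
                f"item {item_name!r} must be a mapping or a list of mappings"
            )
    doc = IfdoDocument(header=header, items=items)
    return doc


def _check_invariants(doc: IfdoDocument) -> None:
    header = doc.header
    for what, value in (("image-set-name", header.name), ("image-set-handle", header.handle)):
        if not value:
            raise IfdoSerializationError(f"{what} must be present and non-empty")
    _require_uuid4(header.uuid, "image-set-uuid")
    if not _URL_RE.match(header.handle):
        raise IfdoSerializationError(
            f"image-set-handle must be an absolute URL: {header.handle!r}"
        )
    for item_name, record in doc.items.items():
        if is_video(record):
            if not record:
                raise IfdoSerializationError(f"video item {item_name!r} has no entries")
            previous = None
            for i, entry in enumerate(record[1:], start=1):
                ts = entry.get("datetime")
                if ts is None:
                    raise IfdoSerializationError(
                        f"video item {item_name!r} entry {i} lacks a datetime"
                    )
                if previous is not None and str(ts) < previous:
                    raise IfdoSerializationError(
                        f"video item {item_name!r} timepoints are not non-decreasing"
                    )
                previous = str(ts)


def write_ifdo(doc: IfdoDocument) -> str:
    """Serialize a document to canonical iFDO YAML.

    Canonical order is: the three set-level fields, the format version,
    header defaults alphabetically, then items alphabetically with each
    item's fields alphabetical.  The same document always yields
    byte-identical text.
    """
    _check_invariants(doc)
    header_map: dict[str, Any] = {
        "image-set-name": doc.header.name,
        "image-set-uuid": doc.header.uuid,
        "image-set-handle": doc.header.handle,
        VERSION_KEY: doc.header.ifdo_version,
    }
    header_map.update(doc.header.defaults.to_mapping())
    items_map: dict[str, Any] = {}
    for item_name in sorted(doc.items):
        record = doc.items[item_name]
        if is_video(record):
            items_map[item_name] = [entry.to_mapping() for entry in record]
        else:
            items_map[item_name] = record.to_mapping()
    payload = {HEADER_KEY: header_map, ITEMS_KEY: items_map}
    return yaml.safe_dump(
        payload,
        sort_keys=False,
        indent=2,
        default_flow_style=False,
        allow_unicode=True,
        width=100000,
    )


def resolve_item(doc: IfdoDocument, item_name: str) -> ItemMetadata:
    """Header defaults overlaid by the item's own values (item wins).

    For a video item only entry 0 (the video-wide defaults) is applied.
    The three set-level fields are never copied into the result.
    """
    if item_name not in doc.items:
        raise KeyError(f"no such item: {item_name!r}")
    record = doc.items[item_name]
    own = record[0] if is_video(record) else record
    return doc.header.defaults.overlay(own)


def resolve_timepoint(doc: IfdoDocument, item_name: str, index: int) -> ItemMetadata:
    """Resolved metadata for one video timepoint.

    Layering is header defaults, then the video-wide entry 0, then entry
    ``index``; later layers win field by field.  ``index`` counts the
    timepoint entries, so it must be >= 1 (entry 0 is the defaults layer).
    """
    if item_name not in doc.items:
        raise KeyError(f"no such item: {item_name!r}")
    record = doc.items[item_name]
    if not is_video(record):
        raise ValueError(f"item {item_name!r} is a photo, not a video")
    if index == 0:
        raise ValueError("index 0 is the video defaults layer, not a timepoint")
    if not 1 <= index < len(record):
        raise KeyError(
            f"timepoint {index} out of range for item {item_name!r} "
            f"(valid: 1..{len(record) - 1})"
        )
    return doc.header.defaults.overlay(record[0]).overlay(record[index])
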