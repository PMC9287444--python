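"""Persistent identification and integrity for image files.

Every image item (and the image set itself) is identified by a random
version-4 UUID.  The item UUID is written ("minted") into the metadata
header of the image file itself — the EXIF ``ImageUniqueID`` tag for
JPEG, a ``tEXt`` chunk for PNG — and only *then* is the SHA-256 file
hash computed, so the hash covers the identifier.  Minting never touches
pixel data: JPEG minting splices an APP1 segment into the byte stream
and PNG minting inserts a chunk, with no re-encode in either case.

Identity is immutable: re-minting the same UUID is a byte-level no-op,
minting a different UUID into an already-identified file is refused.
"""

from __future__ import annotations

import hashlib
import io
import random
import re
import struct
import uuid as _uuid
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

from PIL import Image

__all__ = [
    "HandleUrl",
    "HashDigest",
    "VerificationResult",
    "MintError",
    "generate_uuid",
    "build_handle_url",
    "parse_handle_url",
    "mint_uuid",
    "read_minted_uuid",
    "compute_hash",
    "verify_item",
]

_EXIF_IFD_POINTER = 0x8769
_TAG_IMAGE_UNIQUE_ID = 0xA420
_PNG_SIGNATURE = b"\x89PNG\r\n\x1a\n"
_PNG_UUID_KEYWORD = b"image-uuid"
_HASH_CHUNK = 1 << 20  # 1 MiB streaming window; bounded memory on any file size
_HEX_RE = re.compile(r"^[0-9a-f]{64}$")


class MintError(RuntimeError):
    """Minting refused: immutable identity or unsupported format."""


def generate_uuid(rng: random.Random | None = None) -> str:
    """Draw a random version-4 UUID, canonical hyphenated lowercase form.

    With an explicit ``rng`` the draw is reproducible; otherwise the
    system entropy source is used.  The version nibble is 4 and the
    variant bits are ``10``, leaving 122 random bits (about 5.3e36
    possible values).
    """
    if rng is None:
        return str(_uuid.uuid4())
    return str(_uuid.UUID(int=rng.getrandbits(128), version=4))


def uuid4_population() -> float:
    """Number of distinct version-4 UUIDs (122 free bits)."""
    return float(2**122)


@dataclass(frozen=True)
class HandleUrl:
    """A handle-system URL identifying an image set or item.

    The metadata view renders with an ``@ifdo`` suffix and resolves to
    the iFDO file; the data view renders as the bare handle and resolves
    to the image bytes.
    """

    server: str
    prefix: str
    uuid: str
    view: str = "ifdo"  # "ifdo" | "data"

    def render(self) -> str:
        suffix = "@ifdo" if self.view == "ifdo" else ""
        return f"{self.server}/{self.prefix}/{self.uuid}{suffix}"


def build_handle_url(server: str, prefix: str, uuid: str, view: str = "ifdo") -> HandleUrl:
    if not prefix:
        raise ValueError("handle prefix must be non-empty")
    if view not in ("ifdo", "data"):
        raise ValueError(f"view must be 'ifdo' or 'data', got {view!r}")
    parsed = _uuid.UUID(uuid)  # raises ValueError on malformed input
    if parsed.version != 4:
        raise ValueError(f"not a version-4 UUID: {uuid!r}")
    return HandleUrl(server=server.rstrip("/"), prefix=prefix, uuid=str(parsed), view=view)


def parse_handle_url(url: str) -> HandleUrl:
    """Inverse of :meth:`HandleUrl.render`."""
    view = "data"
    body = url
    if body.endswith("@ifdo"):
        view = "ifdo"
        body = body[: -len("@ifdo")]
    server, _, rest = body.rpartition("/")
    prefix_server, _, prefix = server.rpartition("/")
    if not prefix_server or not prefix or not rest:
        raise ValueError(f"not a handle URL: {url!r}")
    return build_handle_url(prefix_server, prefix, rest, view)


# ---------------------------------------------------------------------------
# Minting


def mint_uuid(image_file: str | Path, uuid: str, sidecar: bool = False) -> None:
    """Write ``uuid`` into the metadata header of ``image_file``.

    JPEG files receive the EXIF ``ImageUniqueID`` tag (hyphen-stripped
    32-hex per EXIF ASCII convention); PNG files a ``tEXt`` chunk keyed
    ``image-uuid``.  Other formats are only supported through a
    ``<file>.uuid`` sidecar, which must be enabled explicitly and emits
    a warning.  Re-minting the same UUID is a no-op; a different UUID is
    refused because identity is immutable.
    """
    path = Path(image_file)
    canonical = str(_uuid.UUID(uuid))
    existing = read_minted_uuid(path)
    if existing is not None:
        if existing == canonical:
            return
        raise MintError(
            f"{path.name} already carries UUID {existing}; identity is immutable"
        )
    suffix = path.suffix.lower()
    if suffix in (".jpg", ".jpeg"):
        _mint_jpeg(path, canonical)
    elif suffix == ".png":
        _mint_png(path, canonical)
    elif sidecar:
        warnings.warn(
            f"{path.name}: format {suffix!r} has no in-file minting target; "
            "writing sidecar file",
            stacklevel=2,
        )
        path.with_name(path.name + ".uuid").write_text(canonical + "\n")
    else:
        raise MintError(
            f"cannot mint into {suffix!r} files; pass sidecar=True to allow "
            "a <file>.uuid sidecar"
        )


def read_minted_uuid(image_file: str | Path) -> str | None:
    """Read the embedded UUID back, canonical hyphenated form, or None."""
    path = Path(image_file)
    suffix = path.suffix.lower()
    if suffix in (".jpg", ".jpeg"):
        with Image.open(path) as im:
            raw = im.getexif().get_ifd(_EXIF_IFD_POINTER).get(_TAG_IMAGE_UNIQUE_ID)
        if raw is None:
            return None
        return str(_uuid.UUID(str(raw).strip()))
    if suffix == ".png":
        raw = _png_find_uuid(path.read_bytes())
        return str(_uuid.UUID(raw)) if raw is not None else None
    sidecar = path.with_name(path.name + ".uuid")
    if sidecar.exists():
        return str(_uuid.UUID(sidecar.read_text().strip()))
    return None


def _exif_payload_with_uuid(existing_payload: bytes | None, canonical: str) -> bytes:
    exif = Image.Exif()
    if existing_payload is not None:
        exif.load(existing_payload)
    exif.get_ifd(_EXIF_IFD_POINTER)[_TAG_IMAGE_UNIQUE_ID] = canonical.replace("-", "")
    return exif.tobytes()


def _mint_jpeg(path: Path, canonical: str) -> None:
    data = path.read_bytes()
    if data[:2] != b"\xff\xd8":
        raise MintError(f"{path.name}: not a JPEG stream")
    # Locate an existing EXIF APP1 segment, walking segment headers only.
    offset = 2
    insert_at = 2
    exif_span: tuple[int, int] | None = None
    existing_payload: bytes | None = None
    while offset + 4 <= len(data):
        if data[offset] != 0xFF:
            break
        marker = data[offset + 1]
        if marker in (0xD8, 0xD9) or 0xD0 <= marker <= 0xD7 or marker == 0x01:
            offset += 2
            continue
        seg_len = struct.unpack(">H", data[offset + 2 : offset + 4])[0]
        seg_end = offset + 2 + seg_len
        if marker == 0xE0:  # JFIF APP0: EXIF convention puts APP1 after it
            insert_at = seg_end
        if marker == 0xE1 and data[offset + 4 : offset + 10] == b"Exif\x00\x00":
            exif_span = (offset, seg_end)
            existing_payload = data[offset + 4 : seg_end]
            break
        if marker == 0xDA:  # start of scan: no metadata beyond this point
            break
        offset = seg_end
    payload = _exif_payload_with_uuid(existing_payload, canonical)
    segment = b"\xff\xe1" + struct.pack(">H", len(payload) + 2) + payload
    if exif_span is None:
        minted = data[:insert_at] + segment + data[insert_at:]
    else:
        start, end = exif_span
        minted = data[:start] + segment + data[end:]
    path.write_bytes(minted)


def _iter_png_chunks(data: bytes):
    offset = len(_PNG_SIGNATURE)
    while offset + 8 <= len(data):
        length, ctype = struct.unpack(">I4s", data[offset : offset + 8])
        yield ctype, offset, offset + 12 + length
        if ctype == b"IEND":
            break
        offset += 12 + length


def _png_find_uuid(data: bytes) -> str | None:
    if not data.startswith(_PNG_SIGNATURE):
        return None
    for ctype, start, end in _iter_png_chunks(data):
        if ctype == b"tEXt":
            body = data[start + 8 : end - 4]
            keyword, _, text = body.partition(b"\x00")
            if keyword == _PNG_UUID_KEYWORD:
                return text.decode("latin-1")
    return None


def _mint_png(path: Path, canonical: str) -> None:
    data = path.read_bytes()
    if not data.startswith(_PNG_SIGNATURE):
        raise MintError(f"{path.name}: not a PNG stream")
    body = _PNG_UUID_KEYWORD + b"\x00" + canonical.encode("latin-1")
    chunk = (
        struct.pack(">I", len(body))
        + b"tEXt"
        + body
        + struct.pack(">I", zlib.crc32(b"tEXt" + body) & 0xFFFFFFFF)
    )
    for ctype, _start, end in _iter_png_chunks(data):
        if ctype == b"IHDR":
            minted = data[:end] + chunk + data[end:]
            path.write_bytes(minted)
            return
    raise MintError(f"{path.name}: PNG stream lacks an IHDR chunk")


# ---------------------------------------------------------------------------
# Hashing and verification


@dataclass(frozen=True)
class HashDigest:
    """A SHA-256 file fingerprint."""

    hex: str
    algorithm: str = "SHA-256"

    def __post_init__(self) -> None:
        if not _HEX_RE.match(self.hex):
            raise ValueError(f"not a 64-char lowercase hex digest: {self.hex!r}")


def compute_hash(image_file: str | Path | io.BufferedIOBase) -> HashDigest:
    """SHA-256 over the exact byte content, streamed in 1 MiB chunks."""
    sha = hashlib.sha256()
    if isinstance(image_file, (str, Path)):
        with open(image_file, "rb") as fh:
            while block := fh.read(_HASH_CHUNK):
                sha.update(block)
    else:
        while block := image_file.read(_HASH_CHUNK):
            sha.update(block)
    return HashDigest(hex=sha.hexdigest())


@dataclass(frozen=True)
class VerificationResult:
    """Outcome of checking a file against its recorded identity."""

    uuid_ok: bool
    hash_ok: bool
    messages: tuple[str, ...] = ()

    @property
    def verified(self) -> bool:
        return self.uuid_ok and self.hash_ok


def verify_item(image_file: str | Path, meta) -> VerificationResult:
    """Check that a file still matches its recorded UUID and SHA-256.

    ``meta`` is any object with ``uuid`` and ``hash_sha256`` fields (an
    :class:`~ifdo.model.ItemMetadata` works).  Mismatches are reported,
    not raised: a broken file is a result, not a programming error.
    """
    expected_uuid = meta.get("uuid") if hasattr(meta, "get") else meta.uuid
    expected_hash = (
        meta.get("hash_sha256") if hasattr(meta, "get") else meta.hash_sha256
    )
    messages: list[str] = []
    embedded = read_minted_uuid(image_file)
    uuid_ok = embedded is not None and expected_uuid is not None and str(
        _uuid.UUID(str(expected_uuid))
    ) == embedded
    if not uuid_ok:
        messages.append(
            f"uuid mismatch: embedded={embedded!r} recorded={expected_uuid!r}"
        )
    actual = compute_hash(image_file).hex
    hash_ok = expected_hash is not None and actual == str(expected_hash).lower()
    if not hash_ok:
        messages.append(
            f"hash mismatch: computed={actual} recorded={expected_hash!r}"
        )
    return VerificationResult(uuid_ok=uuid_ok, hash_ok=hash_ok, messages=tuple(messages))
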