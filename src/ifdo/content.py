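"""Image-content descriptors and annotation interchange.

The content section of an iFDO carries semantic information extracted
from the pixels: scalar descriptors (Shannon entropy of the grayscale
histogram, mean colour, particle count) and annotations — pixel regions
labelled by humans or machines.  An annotation's geometry class follows
from its coordinate list: no coordinates means the whole image, one
point is a point annotation, two points with a declared bounding-box
kind span an axis-aligned box, and three or more points with the first
repeated last form a closed polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from PIL import Image
from skimage import measure
from skimage.filters import threshold_otsu

from .model import CreatorDef, LabelDef

__all__ = [
    "Annotation",
    "image_entropy",
    "average_colour",
    "particle_count",
    "to_grayscale",
    "encode_annotations",
    "decode_annotations",
]


def _as_array(image: np.ndarray | Image.Image | str | Path) -> np.ndarray:
    if isinstance(image, (str, Path)):
        with Image.open(image) as im:
            return np.asarray(im.convert("RGB"))
    if isinstance(image, Image.Image):
        return np.asarray(image.convert("RGB"))
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("zero-pixel image")
    return arr


def to_grayscale(image: np.ndarray | Image.Image | str | Path) -> np.ndarray:
    """8-bit grayscale by BT.601 luma, rounded half-up."""
    arr = _as_array(image)
    if arr.size == 0:
        raise ValueError("zero-pixel image")
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    luma = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return np.floor(luma + 0.5).astype(np.uint8)


def image_entropy(image: np.ndarray | Image.Image | str | Path) -> float:
    """Shannon entropy of the 256-bin grayscale histogram, in bits.

    Bounded by [0, 8]: a constant image scores 0, a uniform histogram 8.
    Invariant under any permutation of pixel positions.
    """
    gray = to_grayscale(image)
    counts = np.bincount(gray.ravel(), minlength=256)
    p = counts[counts > 0] / gray.size
    return float(-(p * np.log2(p)).sum())


def average_colour(image: np.ndarray | Image.Image | str | Path) -> tuple[float, float, float]:
    """Per-channel arithmetic mean RGB, reported to 2 decimals."""
    arr = _as_array(image)
    if arr.size == 0:
        raise ValueError("zero-pixel image")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    means = arr.reshape(-1, arr.shape[-1])[:, :3].mean(axis=0)
    return tuple(round(float(m), 2) for m in means)


def particle_count(
    image: np.ndarray | Image.Image | str | Path,
    min_area: int = 10,
    threshold: float | str = "otsu",
    invert: bool = False,
) -> int:
    """Count bright connected components ("particles") in an image.

    The grayscale image is binarized (Otsu's threshold by default, or a
    fixed level), 8-connected foreground components are labelled, and
    components smaller than ``min_area`` pixels are discarded.
    Foreground means brighter than the threshold — the dark-field
    convention of plankton imaging — unless ``invert`` is set.
    """
    gray = to_grayscale(image)
    if threshold == "otsu":
        if int(gray.min()) == int(gray.max()):
            return 0  # constant image: no separable foreground
        level = float(threshold_otsu(gray))
    else:
        level = float(threshold)
    mask = gray < level if invert else gray > level
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int((areas >= min_area).sum())


# ---------------------------------------------------------------------------
# Annotations


@dataclass(frozen=True)
class Annotation:
    """A labelled pixel region.

    ``coordinates`` are ``[x, y]`` pixel points, origin top-left,
    x right, y down, 0-based.  ``kind`` is derived from the coordinate
    count except for the two-point bounding-box form, which must be
    declared (two points could otherwise be an open polyline).
    """

    coordinates: tuple[tuple[float, float], ...] = ()
    labels: tuple[str, ...] = ()
    annotators: tuple[str, ...] = ()
    confidence: float | None = None
    frames: str | None = None  # timepoint datetime, for video annotations
    declared_kind: str | None = None

    @property
    def kind(self) -> str:
        if self.declared_kind == "bounding-box":
            return "bounding-box"
        if len(self.coordinates) == 0:
            return "whole-image"
        if len(self.coordinates) == 1:
            return "point"
        if (
            len(self.coordinates) >= 3
            and self.coordinates[0] == self.coordinates[-1]
        ):
            return "polygon"
        return "polyline"

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("annotation needs at least one label id")
        if not self.annotators:
            raise ValueError("annotation needs at least one annotator id")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.declared_kind == "bounding-box":
            if len(self.coordinates) != 2:
                raise ValueError("bounding box needs exactly 2 corner points")
            (x0, y0), (x1, y1) = self.coordinates
            if not (x0 <= x1 and y0 <= y1):
                raise ValueError("bounding box corners must be [xmin,ymin],[xmax,ymax]")

    def to_mapping(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "coordinates": [[x, y] for x, y in self.coordinates],
            "labels": list(self.labels),
            "annotators": list(self.annotators),
        }
        if self.declared_kind == "bounding-box":
            out["shape"] = "bounding-box"
        if self.confidence is not None:
            out["confidence"] = self.confidence
        if self.frames is not None:
            out["frames"] = self.frames
        return out

    @classmethod
    def from_mapping(cls, m: Mapping[str, Any]) -> "Annotation":
        return cls(
            coordinates=tuple((float(x), float(y)) for x, y in m.get("coordinates", [])),
            labels=tuple(m.get("labels", [])),
            annotators=tuple(m.get("annotators", [])),
            confidence=m.get("confidence"),
            frames=m.get("frames"),
            declared_kind="bounding-box" if m.get("shape") == "bounding-box" else None,
        )


def encode_annotations(
    labels: Sequence[LabelDef],
    creators: Sequence[CreatorDef],
    annotations: Sequence[Annotation],
) -> dict[str, Any]:
    """Encode labels, annotators and annotations as content-section fields.

    Referential integrity is enforced: every label and annotator id used
    by an annotation must be defined.  Returns a mapping with the
    ``image-annotation-labels`` / ``-creators`` / ``image-annotations``
    keys, ready to merge into item metadata.
    """
    label_ids = {l.id for l in labels}
    creator_ids = {c.id for c in creators}
    for ann in annotations:
        for lid in ann.labels:
            if lid not in label_ids:
                raise ValueError(f"annotation references undefined label id {lid!r}")
        for cid in ann.annotators:
            if cid not in creator_ids:
                raise ValueError(f"annotation references undefined annotator id {cid!r}")
    return {
        "image-annotation-labels": [l.to_mapping() for l in labels],
        "image-annotation-creators": [c.to_mapping() for c in creators],
        "image-annotations": [a.to_mapping() for a in annotations],
    }


def decode_annotations(
    fields: Mapping[str, Any],
) -> tuple[list[LabelDef], list[CreatorDef], list[Annotation]]:
    """Inverse of :func:`encode_annotations`."""
    labels = [
        LabelDef(id=m["id"], name=m.get("name", ""))
        for m in fields.get("image-annotation-labels", [])
    ]
    creators = [
        CreatorDef(id=m["id"], name=m.get("name", ""), kind=m.get("kind", "human"))
        for m in fields.get("image-annotation-creators", [])
    ]
    annotations = [
        Annotation.from_mapping(m) for m in fields.get("image-annotations", [])
    ]
    label_ids = {l.id for l in labels}
    creator_ids = {c.id for c in creators}
    for ann in annotations:
        for lid in ann.labels:
            if lid not in label_ids:
                raise ValueError(f"annotation references undefined label id {lid!r}")
        for cid in ann.annotators:
            if cid not in creator_ids:
                raise ValueError(f"annotation references undefined annotator id {cid!r}")
    return labels, creators, annotations
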