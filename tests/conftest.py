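"""Shared fixtures: programmatic documents and a generated dataset."""

from __future__ import annotations

import random

import pytest

from ifdo.model import IfdoDocument, ItemMetadata, SetHeader
from ifdo import fixtures as fx
from ifdo import factory, navigation

VALID_ORCID = "0000-0002-1825-0097"
SET_UUID = "9a1f8a29-2552-4c11-895b-051f7424d2d2"
ITEM_UUID = "b48e2a01-6c12-4b7a-9f2e-3d8a1c5e7f90"
SHA = "e3b0c44298fc1c149afbf4c8996fb92427ae41e4649b934ca495991b7852b855"


def core_fields(**overrides) -> dict:
    """A complete, valid set of required core fields for one item."""
    fields = {
        "datetime": "2022-07-15T10:00:00.000Z",
        "latitude": 11.85,
        "longitude": -117.45,
        "depth": 4150.0,
        "coordinate_reference_system": "EPSG:4326",
        "coordinate_uncertainty_meters": 2.0,
        "uuid": ITEM_UUID,
        "hash_sha256": SHA,
        "context": "monitoring",
        "project": "SO268",
        "event": "SO268-1_021",
        "platform": "OFOS",
        "sensor": "CAM-1",
        "abstract": "nodule field transect",
        "pi": {"name": "Josiah Carberry", "orcid": VALID_ORCID},
        "creators": [{"name": "Ann Deckhand"}],
        "license": "CC-BY-4.0",
        "copyright": "(c) 2022",
    }
    fields.update(overrides)
    return fields


def minimal_document(**item_overrides) -> IfdoDocument:
    """One photo item carrying every required core field."""
    header = SetHeader(
        name="SO268 test set",
        uuid=SET_UUID,
        handle=f"https://hdl.handle.net/20.500.12085/{SET_UUID}",
    )
    item = ItemMetadata(core_fields(**item_overrides))
    return IfdoDocument(header=header, items={"img_0001.png": item})


_WORDS = ["pelagic", "benthic", "transect", "mooring", "nodule", "fauna", "survey"]


def random_document(rng: random.Random) -> IfdoDocument:
    """A structurally valid document with randomized fields and items.

    Exercises photos, videos, unknown extension fields, and header
    defaults; values are YAML-native scalars and containers.
    """
    set_uuid = str(
        __import__("uuid").UUID(int=rng.getrandbits(128), version=4)
    )
    defaults = {}
    if rng.random() < 0.7:
        defaults["sensor"] = rng.choice(["CAM-1", "CAM-2"])
    if rng.random() < 0.5:
        defaults["license"] = "CC-BY-4.0"
    if rng.random() < 0.4:
        defaults["x-" + rng.choice(_WORDS)] = rng.choice(_WORDS)
    header = SetHeader(
        name=" ".join(rng.sample(_WORDS, 2)),
        uuid=set_uuid,
        handle=f"https://hdl.handle.net/20.500.12085/{set_uuid}",
        defaults=ItemMetadata(defaults),
    )
    items: dict = {}
    for i in range(rng.randint(0, 5)):
        fields = {
            "datetime": f"2022-07-15T10:00:{i:02d}.000Z",
            "latitude": round(rng.uniform(-80, 80), 6),
            "longitude": round(rng.uniform(-179, 179), 6),
        }
        if rng.random() < 0.5:
            fields["depth"] = round(rng.uniform(0, 6000), 2)
        if rng.random() < 0.3:
            fields["custom-vehicle-heading"] = round(rng.uniform(0, 360), 1)
        name = f"img_{i:04d}.png"
        if rng.random() < 0.25:  # video record with two timepoints
            tp = [
                ItemMetadata({"acquisition": "video"}),
                ItemMetadata({"datetime": f"2022-07-15T10:01:{i:02d}.000Z", "depth": 10.0 + i}),
                ItemMetadata({"datetime": f"2022-07-15T10:02:{i:02d}.000Z", "depth": 20.0 + i}),
            ]
            items[f"vid_{i:04d}.mov"] = tp
        else:
            items[name] = ItemMetadata(fields)
    return IfdoDocument(header=header, items=items)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory) -> fx.FixtureManifest:
    """The reference synthetic dataset: 20 images, curated track, config."""
    root = tmp_path_factory.mktemp("dataset")
    return fx.make_dataset(seed=7, out_dir=root, n_images=20)


@pytest.fixture(scope="session")
def built(dataset):
    """The dataset run through the full factory pipeline once."""
    track = navigation.load_track(dataset.track.path)
    doc, report = factory.create_ifdo(
        dataset.image_dir, track, dataset.config, rng=7
    )
    return dataset, doc, report
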