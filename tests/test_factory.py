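"""Factory pipeline: renaming, footprints, overlap, end-to-end assembly."""

import datetime as dt
import shutil

import pytest

from ifdo import factory, fixtures as fx, navigation
from ifdo.factory import (
    CameraGeometry,
    FootprintRect,
    ProjectConfig,
    footprint,
    overlap_fraction,
    rename_file,
)
from ifdo.identity import verify_item
from ifdo.model import parse_ifdo, resolve_item, write_ifdo

UTC = dt.timezone.utc


def _config(**kw):
    defaults = dict(project="SO268", event="SO268-1_021", platform="OFOS", sensor="OFOS")
    defaults.update(kw)
    return ProjectConfig(**defaults)


class TestRename:
    def test_canonical_name_from_components_and_timestamp(self):
        name = rename_file(
            _config(),
            dt.datetime(2019, 3, 15, 12, 0, 1, 500_000, tzinfo=UTC),
            "img.JPG",
        )
        assert name == "SO268_SO268-1_021_OFOS_20190315_120001.500.jpg"

    def test_same_inputs_same_name(self):
        stamp = dt.datetime(2019, 3, 15, 12, 0, 1, 500_000, tzinfo=UTC)
        assert rename_file(_config(), stamp, "a.png") == rename_file(
            _config(), stamp, "a.png"
        )

    def test_timestamp_collision_appends_counter(self):
        stamp = dt.datetime(2019, 3, 15, 12, 0, 1, tzinfo=UTC)
        taken: set = set()
        first = rename_file(_config(), stamp, "a.png", taken)
        second = rename_file(_config(), stamp, "b.png", taken)
        third = rename_file(_config(), stamp, "c.png", taken)
        assert first.endswith("_120001.000.png")
        assert second.endswith("_120001.000_1.png")
        assert third.endswith("_120001.000_2.png")

    def test_unsafe_component_is_rejected(self):
        with pytest.raises(ValueError, match="filename-safe"):
            rename_file(
                _config(event="dive 21/3"),
                dt.datetime(2019, 3, 15, tzinfo=UTC),
                "a.png",
            )


class TestFootprint:
    GEOM = CameraGeometry(
        horizontal_fov_deg=90.0, vertical_fov_deg=90.0,
        image_width_px=4000, image_height_px=3000,
    )

    def test_closed_form_pinhole_at_45_degree_half_angle(self):
        result = footprint(self.GEOM, altitude_m=2.0)
        assert result.area_square_meter == pytest.approx(16.0)
        assert result.pixels_per_meter == pytest.approx(1000.0)

    def test_area_shrinks_monotonically_toward_zero_altitude(self):
        areas = [footprint(self.GEOM, h).area_square_meter for h in (2.0, 1.0, 0.5, 0.1)]
        assert areas == sorted(areas, reverse=True)

    def test_scaling_law_doubling_altitude(self):
        one = footprint(self.GEOM, 1.5)
        two = footprint(self.GEOM, 3.0)
        assert two.area_square_meter == pytest.approx(4 * one.area_square_meter)
        assert two.pixels_per_meter == pytest.approx(one.pixels_per_meter / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            footprint(self.GEOM, 0.0)
        with pytest.raises(ValueError):
            CameraGeometry(180.0, 60.0, 100, 100)


class TestOverlap:
    def test_identical_footprints_fully_overlap(self):
        a = FootprintRect(0, 0, 4, 4)
        assert overlap_fraction(a, a) == 1.0

    def test_disjoint_footprints_do_not_overlap(self):
        assert overlap_fraction(
            FootprintRect(0, 0, 4, 4), FootprintRect(100, 0, 4, 4)
        ) == 0.0

    def test_half_offset_squares_overlap_half(self):
        assert overlap_fraction(
            FootprintRect(0, 0, 4, 4), FootprintRect(2, 0, 4, 4)
        ) == pytest.approx(0.5)


class TestCreateIfdo:
    def test_twenty_items_no_validation_errors(self, built):
        _dataset, doc, report = built
        assert len(doc.items) == 20
        assert report.errors == []
        assert report.is_fair

    def test_shared_sensor_lives_in_header_not_items(self, built):
        _dataset, doc, _report = built
        assert doc.header.defaults.get("sensor") == "CAM-1"
        for record in doc.items.values():
            assert "sensor" not in record

    def test_no_field_constant_across_all_items_stays_in_items(self, built):
        _dataset, doc, _report = built
        records = list(doc.items.values())
        common = set(records[0])
        for record in records[1:]:
            common &= set(record)
        for name in common:
            values = {repr(record.get(name)) for record in records}
            assert len(values) > 1, f"{name} is constant across items yet not factored"

    def test_every_item_verifies_against_its_file(self, built):
        dataset, doc, _report = built
        for name in doc.items:
            result = verify_item(dataset.image_dir / name, resolve_item(doc, name))
            assert result.verified, result.messages

    def test_corrupted_file_fails_verification_for_exactly_that_item(self, built, tmp_path):
        dataset, doc, _report = built
        copy_dir = tmp_path / "copy"
        shutil.copytree(dataset.image_dir, copy_dir)
        victim = sorted(doc.items)[3]
        data = bytearray((copy_dir / victim).read_bytes())
        data[-15] ^= 0x55
        (copy_dir / victim).write_bytes(bytes(data))
        outcomes = {
            name: verify_item(copy_dir / name, resolve_item(doc, name)).verified
            for name in doc.items
        }
        assert outcomes[victim] is False
        assert all(ok for name, ok in outcomes.items() if name != victim)

    def test_output_is_deterministic_given_seed(self, tmp_path):
        texts = []
        for run in ("a", "b"):
            root = tmp_path / run
            manifest = fx.make_dataset(seed=13, out_dir=root, n_images=6)
            track = navigation.load_track(manifest.track.path)
            doc, _ = factory.create_ifdo(
                manifest.image_dir, track, manifest.config, rng=13
            )
            text = write_ifdo(doc)
            # the set handle embeds a fresh UUID per run; fix it for comparison
            texts.append(text.replace(doc.header.uuid, "UUID"))
        assert texts[0] == texts[1]

    def test_empty_dataset_yields_header_only_document(self, tmp_path):
        manifest = fx.make_dataset(seed=5, out_dir=tmp_path / "empty", n_images=0)
        track = navigation.load_track(manifest.track.path)
        doc, report = factory.create_ifdo(
            manifest.image_dir, track, manifest.config, rng=5
        )
        assert len(doc.items) == 0
        assert report.is_fair
        assert parse_ifdo(write_ifdo(doc)).header.name == doc.header.name

    def test_missing_core_input_refuses_to_emit(self, tmp_path):
        manifest = fx.make_dataset(seed=6, out_dir=tmp_path / "nolicense", n_images=3)
        manifest.config.license = ""
        manifest.config.pi = None
        track = navigation.load_track(manifest.track.path)
        with pytest.raises(factory.FactoryError, match="force"):
            factory.create_ifdo(manifest.image_dir, track, manifest.config, rng=6)

    def test_force_emits_despite_errors(self, tmp_path):
        manifest = fx.make_dataset(seed=8, out_dir=tmp_path / "forced", n_images=3)
        manifest.config.pi = None
        track = navigation.load_track(manifest.track.path)
        doc, report = factory.create_ifdo(
            manifest.image_dir, track, manifest.config, rng=8, force=True
        )
        assert len(doc.items) == 3
        assert not report.is_fair


class TestImageTimestamp:
    def test_filename_pattern_parses_with_milliseconds(self, tmp_path):
        from ifdo.factory import image_timestamp

        path = tmp_path / "raw_20220715T100003.500Z.png"
        path.write_bytes(b"")
        assert image_timestamp(path) == dt.datetime(
            2022, 7, 15, 10, 0, 3, 500_000, tzinfo=UTC
        )

    def test_missing_timestamp_is_factory_error(self, tmp_path):
        from ifdo.factory import image_timestamp

        path = tmp_path / "holiday-photo.png"
        path.write_bytes(b"")
        with pytest.raises(factory.FactoryError, match="timestamp"):
            image_timestamp(path)

    def test_conflicting_exif_and_filename_time_is_error(self, tmp_path):
        from PIL import Image

        from ifdo.factory import image_timestamp

        path = tmp_path / "raw_20220715T100003.000Z.jpg"
        exif = Image.Exif()
        exif.get_ifd(0x8769)[0x9003] = "2022:07:15 11:00:03"
        Image.new("RGB", (8, 8)).save(path, format="JPEG", exif=exif.tobytes())
        with pytest.raises(factory.FactoryError, match="conflict"):
            image_timestamp(path)
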