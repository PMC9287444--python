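"""Navigation curation: loading, UTC checks, outliers, smoothing, interpolation."""

import datetime as dt

import numpy as np
import pytest

from ifdo import fixtures as fx
from ifdo.model import format_datetime
from ifdo.navigation import (
    EARTH_RADIUS_M,
    NavigationTrack,
    interpolate_to,
    load_track,
    remove_outliers,
    smooth,
    verify_utc,
)

UTC = dt.timezone.utc


def _write_csv(path, rows):
    path.write_text("datetime,latitude,longitude,depth\n" + "".join(rows))


def _linear_track(n=61, lat0=10.0, dlat=0.001):
    import pandas as pd

    times = [dt.datetime(2022, 7, 15, 10, 0, 0, tzinfo=UTC) + dt.timedelta(seconds=i) for i in range(n)]
    frame = pd.DataFrame(
        {
            "datetime": pd.to_datetime(times, utc=True),
            "latitude": [lat0 + i * dlat for i in range(n)],
            "longitude": [-117.0 + i * dlat for i in range(n)],
            "depth": [100.0 + i * 0.1 for i in range(n)],
            "flags": [() for _ in range(n)],
        }
    )
    return NavigationTrack(samples=frame)


class TestLoadTrack:
    def test_well_formed_csv_loads_all_rows(self, tmp_path):
        path = tmp_path / "t.csv"
        _write_csv(path, [
            "2022-07-15T10:00:00Z,10.0,-117.0,100.0\n",
            "2022-07-15T10:00:01Z,10.1,-117.0,100.5\n",
            "2022-07-15T10:00:02Z,10.2,-117.0,101.0\n",
        ])
        assert len(load_track(path)) == 3

    def test_out_of_order_rows_are_sorted_and_flagged(self, tmp_path):
        path = tmp_path / "t.csv"
        _write_csv(path, [
            "2022-07-15T10:00:02Z,10.2,-117.0,101.0\n",
            "2022-07-15T10:00:00Z,10.0,-117.0,100.0\n",
        ])
        track = load_track(path)
        assert track.samples["latitude"].tolist() == [10.0, 10.2]
        assert any("sorted" in w for w in track.warnings)
        assert all("reordered" in flags for flags in track.samples["flags"])

    def test_non_utc_offset_is_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        _write_csv(path, ["2022-07-15T10:00:00+02:00,10.0,-117.0,100.0\n"])
        with pytest.raises(ValueError, match="non-UTC"):
            load_track(path)

    def test_unparseable_datetime_reports_row_number(self, tmp_path):
        path = tmp_path / "t.csv"
        _write_csv(path, [
            "2022-07-15T10:00:00Z,10.0,-117.0,100.0\n",
            "yesterday,10.0,-117.0,100.0\n",
        ])
        with pytest.raises(ValueError, match="row 3"):
            load_track(path)

    def test_duplicate_timestamps_collapse_to_mean(self, tmp_path):
        path = tmp_path / "t.csv"
        _write_csv(path, [
            "2022-07-15T10:00:00Z,10.0,-117.0,100.0\n",
            "2022-07-15T10:00:00Z,10.2,-117.0,102.0\n",
            "2022-07-15T10:00:01Z,10.4,-117.0,104.0\n",
        ])
        track = load_track(path)
        assert len(track) == 2
        assert track.samples["latitude"].iloc[0] == pytest.approx(10.1)
        assert "duplicate-mean" in track.samples["flags"].iloc[0]


class TestVerifyUtc:
    def test_monotone_designated_timestamps_are_clean(self):
        stamps = [f"2022-07-15T10:00:{i:02d}Z" for i in range(10)]
        assert verify_utc(stamps).clean

    def test_naive_timestamp_is_flagged(self):
        report = verify_utc(["2022-07-15T10:00:00Z", "2022-07-15T10:00:01"])
        assert report.naive == [1]

    def test_gap_beyond_threshold_is_flagged(self):
        base = dt.datetime(2022, 7, 15, 10, 0, 0, tzinfo=UTC)
        stamps = [base + dt.timedelta(seconds=s) for s in [0, 1, 2, 62, 63]]
        report = verify_utc(stamps, gap_threshold_s=10.0)
        assert report.gaps == [(3, 60.0)]


class TestRemoveOutliers:
    def test_constant_position_track_is_unchanged(self):
        import pandas as pd

        n = 30
        times = pd.date_range("2022-07-15T10:00:00Z", periods=n, freq="s")
        frame = pd.DataFrame({
            "datetime": times, "latitude": [10.0] * n,
            "longitude": [-117.0] * n, "depth": [100.0] * n,
            "flags": [()] * n,
        })
        track = NavigationTrack(samples=frame)
        assert len(remove_outliers(track, window=11, k=5)) == n

    def test_exactly_the_injected_spikes_are_removed(self, tmp_path):
        truth = fx.make_track(
            seed=3, path=tmp_path / "t.csv", noise_sigma_m=0.0, outliers=5
        )
        track = load_track(truth.path)
        cleaned = remove_outliers(track, window=11, k=5)
        kept = {format_datetime(ts) for ts in cleaned.timestamps}
        removed = [i for i, s in enumerate(truth.timestamps) if s not in kept]
        assert removed == sorted(truth.outlier_indices)

    def test_pathological_track_is_not_silently_gutted(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 40
        times = pd.date_range("2022-07-15T10:00:00Z", periods=n, freq="s")
        frame = pd.DataFrame({
            "datetime": times,
            "latitude": 10.0 + rng.uniform(-0.5, 0.5, n),
            "longitude": -117.0 + rng.uniform(-0.5, 0.5, n),
            "depth": rng.uniform(0, 4000, n),
            "flags": [()] * n,
        })
        track = NavigationTrack(samples=frame)
        cleaned = remove_outliers(track, window=5, k=0.05)
        assert len(cleaned) == n
        assert any("refusing" in w for w in cleaned.warnings)

    def test_short_track_returned_unchanged_with_warning(self):
        track = _linear_track(n=5)
        cleaned = remove_outliers(track, window=11, k=5)
        assert len(cleaned) == 5
        assert any("shorter than window" in w for w in cleaned.warnings)

    @pytest.mark.parametrize("window,k", [(4, 5.0), (1, 5.0), (11, 0.0)])
    def test_invalid_parameters_are_rejected(self, window, k):
        with pytest.raises(ValueError):
            remove_outliers(_linear_track(), window=window, k=k)


class TestSmooth:
    def test_linear_track_is_fixed_point(self):
        track = _linear_track()
        out = smooth(track, window=11)
        for col in ("latitude", "longitude", "depth"):
            np.testing.assert_allclose(
                out.samples[col], track.samples[col], atol=1e-9
            )

    def test_endpoints_pass_through_unchanged(self):
        truth = None
        track = _linear_track(n=31)
        noisy = track.samples.copy()
        rng = np.random.default_rng(1)
        noisy["latitude"] += rng.normal(0, 1e-4, len(noisy))
        noisy_track = NavigationTrack(samples=noisy)
        out = smooth(noisy_track, window=7)
        assert out.samples["latitude"].iloc[0] == noisy["latitude"].iloc[0]
        assert out.samples["latitude"].iloc[-1] == noisy["latitude"].iloc[-1]

    def test_white_noise_std_shrinks_about_sqrt_window(self):
        rng = np.random.default_rng(42)
        window = 11
        n = 4001
        import pandas as pd

        times = pd.date_range("2022-07-15T10:00:00Z", periods=n, freq="s")
        sigma = 1e-4
        noise = rng.normal(0, sigma, n)
        frame = pd.DataFrame({
            "datetime": times,
            "latitude": 10.0 + noise,
            "longitude": [-117.0] * n,
            "depth": [100.0] * n,
            "flags": [()] * n,
        })
        out = smooth(NavigationTrack(samples=frame), window=window)
        interior = out.samples["latitude"].to_numpy()[window:-window] - 10.0
        ratio = noise[window:-window].std() / interior.std()
        assert ratio == pytest.approx(np.sqrt(window), rel=0.15)


class TestInterpolate:
    def test_query_at_sample_time_is_exact(self):
        track = _linear_track()
        stamp = track.timestamps[7]
        fix = interpolate_to(track, [stamp])[0]
        assert fix.latitude == pytest.approx(track.samples["latitude"].iloc[7], abs=1e-12)

    def test_midpoint_query_is_linear_midpoint(self):
        import pandas as pd

        times = pd.to_datetime(
            ["2022-07-15T10:00:00Z", "2022-07-15T10:00:10Z"], utc=True
        )
        frame = pd.DataFrame({
            "datetime": times, "latitude": [10.0, 10.2],
            "longitude": [-117.0, -117.0], "depth": [100.0, 110.0],
            "flags": [(), ()],
        })
        track = NavigationTrack(samples=frame)
        fix = interpolate_to(track, ["2022-07-15T10:00:05Z"])[0]
        assert fix.latitude == pytest.approx(10.1)
        assert fix.depth == pytest.approx(105.0)

    def test_matches_brute_force_linear_interpolator(self):
        track = _linear_track(n=101)
        t0 = track.timestamps[0]
        rng = np.random.default_rng(5)
        queries = [t0 + dt.timedelta(seconds=float(s)) for s in rng.uniform(0, 100, 100)]
        fixes = interpolate_to(track, queries)
        times = np.array([ts.timestamp() for ts in track.timestamps])
        lats = track.samples["latitude"].to_numpy()
        for query, fix in zip(queries, fixes):
            q = query.timestamp()
            j = int(np.searchsorted(times, q, side="right")) - 1
            j = min(max(j, 0), len(times) - 2)
            frac = (q - times[j]) / (times[j + 1] - times[j])
            expected = lats[j] + frac * (lats[j + 1] - lats[j])
            assert abs(fix.latitude - expected) < 1e-12

    def test_uncertainty_is_sensor_plus_half_bracketing_displacement(self):
        import pandas as pd

        times = pd.to_datetime(
            ["2022-07-15T10:00:00Z", "2022-07-15T10:00:10Z"], utc=True
        )
        dlat = 0.001  # ~111.2 m of northing
        frame = pd.DataFrame({
            "datetime": times, "latitude": [10.0, 10.0 + dlat],
            "longitude": [-117.0, -117.0], "depth": [100.0, 100.0],
            "flags": [(), ()],
        })
        track = NavigationTrack(samples=frame)
        fix = interpolate_to(track, ["2022-07-15T10:00:05Z"], sensor_uncertainty_m=2.0)[0]
        displacement = np.radians(dlat) * EARTH_RADIUS_M
        assert fix.uncertainty_meters == pytest.approx(2.0 + displacement / 2, rel=1e-6)

    def test_out_of_span_query_is_per_timestamp_error(self):
        track = _linear_track(n=10)
        late = track.timestamps[-1] + dt.timedelta(seconds=30)
        inside = track.timestamps[3]
        fixes = interpolate_to(track, [inside, late], extrapolation_tolerance_s=5.0)
        assert fixes[0].error is None
        assert fixes[1].error is not None and fixes[1].latitude is None


class TestEndToEndRecovery:
    def test_curation_beats_raw_and_spike_floor(self, tmp_path):
        truth = fx.make_track(seed=11, path=tmp_path / "t.csv")
        track = load_track(truth.path)
        curated = smooth(remove_outliers(track, window=11, k=5), window=11)
        lookup = {
            s: (la, lo)
            for s, la, lo in zip(truth.timestamps, truth.true_latitude, truth.true_longitude)
        }

        def rms(trk):
            errs = []
            for ts, la, lo in zip(
                trk.timestamps, trk.samples["latitude"], trk.samples["longitude"]
            ):
                tla, tlo = lookup[format_datetime(ts)]
                dn = np.radians(la - tla) * EARTH_RADIUS_M
                de = np.radians(lo - tlo) * EARTH_RADIUS_M * np.cos(np.radians(tla))
                errs.append(dn * dn + de * de)
            return float(np.sqrt(np.mean(errs)))

        raw_rms = rms(track)
        curated_rms = rms(curated)
        assert curated_rms < raw_rms
        assert curated_rms < truth.spike_magnitude_m / 3
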