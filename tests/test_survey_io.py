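"""Survey ingest, projection, segmentation, and covariate annotation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsmtools import survey_io as sio
from dsmtools.projection import Projection, ProjectionError
from dsmtools.rasters import CovariateRaster, RasterStack, read_ascii_grid, write_ascii_grid


# ---------------------------------------------------------------------------
# perpendicular distance


@pytest.mark.parametrize(
    "r, theta, expected",
    [(1000.0, 30.0, 500.0), (750.0, 0.0, 0.0), (500.0, 90.0, 500.0), (500.0, 180.0, 0.0)],
)
def test_perpendicular_distance_geometry(r, theta, expected):
    assert sio.perpendicular_distance(r, theta) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("r, theta", [(-1.0, 30.0), (100.0, -5.0), (100.0, 181.0)])
def test_perpendicular_distance_rejects_bad_input(r, theta):
    with pytest.raises(sio.ValidationError):
        sio.perpendicular_distance(r, theta)


@given(r=st.floats(0, 1e5), theta=st.floats(0, 180))
@settings(max_examples=200, deadline=None)
def test_perpendicular_never_exceeds_radial(r, theta):
    assert sio.perpendicular_distance(r, theta) <= r + 1e-9


# ---------------------------------------------------------------------------
# projection


def test_projection_round_trip(proj):
    lon = np.array([10.2, 12.5, 14.9])
    lat = np.array([35.1, 37.0, 38.9])
    x, y = proj.forward(lon, lat)
    lon2, lat2 = proj.inverse(x, y)
    np.testing.assert_allclose(lon2, lon, atol=1e-6)
    np.testing.assert_allclose(lat2, lat, atol=1e-6)


def test_projection_degree_of_latitude(proj):
    """One degree of latitude spans ~111.2 km at mid-latitudes."""
    x1, y1 = proj.forward(12.0, 36.5)
    x2, y2 = proj.forward(12.0, 37.5)
    d = np.hypot(x2 - x1, y2 - y1)
    assert d == pytest.approx(111.2e3, rel=0.005)


def test_projection_malformed_spec():
    with pytest.raises(ProjectionError):
        Projection.from_spec({"kind": "mercator"})
    with pytest.raises(ProjectionError):
        Projection.from_spec({"kind": "lcc", "lat1": 36.0})  # missing keys
    with pytest.raises(ProjectionError):
        Projection.from_spec("EPSG:3035")


def test_projection_out_of_domain(proj):
    with pytest.raises(ProjectionError):
        proj.forward(10.0, 95.0)


# ---------------------------------------------------------------------------
# transects and segmentation


def _straight_effort(length_km: float, n_fix: int = 21, tid: str = "T1", status=None, proj=None):
    """North-going fixes with exactly ``length_km`` of projected trackline
    (planar points inverse-projected to lat/lon)."""
    proj = proj or Projection.for_bounds(35.0, 39.0, 10.0, 15.0)
    x0, y0 = proj.forward(12.0, 36.0)
    ys = y0 + np.linspace(0, length_km * 1000.0, n_fix)
    lon, lat = proj.inverse(np.full(n_fix, x0), ys)
    t0 = dt.datetime(2019, 6, 1, 8, 0)
    return pd.DataFrame(
        {
            "transect_id": tid,
            "timestamp": [(t0 + dt.timedelta(seconds=10 * i)).isoformat() for i in range(n_fix)],
            "lat": lat,
            "lon": lon,
            "effort_status": status if status is not None else "on",
            "sea_state": 2,
        }
    )


@pytest.mark.parametrize(
    "length_km, n_expected, seg_len",
    [(10.0, 10, 1.0), (10.4, 10, 1.04), (0.3, 1, 0.3)],
)
def test_segment_counts_and_lengths(proj, length_km, n_expected, seg_len):
    tr = sio.build_transects(_straight_effort(length_km), proj)
    segs = sio.segment_transects(tr, 1.0)
    assert len(segs) == n_expected
    np.testing.assert_allclose(segs["length_km"], seg_len, rtol=1e-3)


def test_segment_length_conservation(proj, small_survey):
    segs = sio.segment_transects(small_survey.transects, 1.0)
    total_seg = segs["length_km"].sum()
    total_tr = sum(t.length_km for t in small_survey.transects)
    assert total_seg == pytest.approx(total_tr, rel=1e-6)
    # per-transect conservation too
    per = segs.groupby("transect_id")["length_km"].sum()
    for t in small_survey.transects:
        assert per[t.transect_id] == pytest.approx(t.length_km, rel=1e-6)


def test_segment_midpoints_on_polyline(proj):
    tr = sio.build_transects(_straight_effort(10.0), proj)[0]
    segs = sio.segment_transects([tr], 1.0)
    for _, s in segs.iterrows():
        _, off = tr.station_of(s["x"], s["y"])
        assert off < 1.0  # metres


def test_off_effort_fixes_split_transects(proj):
    status = ["on"] * 8 + ["off"] * 4 + ["on"] * 9
    eff = _straight_effort(10.0, n_fix=21, status=status)
    trs = sio.build_transects(eff, proj)
    assert len(trs) == 2
    assert {t.transect_id for t in trs} == {"T1/0", "T1/1"}
    assert all(t.parent_id == "T1" for t in trs)
    total = sum(t.length_km for t in trs)
    assert total < 10.0  # the off-effort gap is excluded


# ---------------------------------------------------------------------------
# truncation


def test_truncation_closed_interval():
    s = pd.DataFrame({"perp_distance_m": [100.0, 499.0, 500.0, 501.0]})
    out = sio.truncate_sightings(s, 500.0)
    assert out["perp_distance_m"].tolist() == [100.0, 499.0, 500.0]
    # identity when all within
    out2 = sio.truncate_sightings(out, 500.0)
    assert len(out2) == len(out)
    with pytest.raises(ValueError):
        sio.truncate_sightings(s, 0.0)


# ---------------------------------------------------------------------------
# rasters and annotation


def _const_raster(c=7.5, name="depth", cell=1000.0, n=10):
    return CovariateRaster(name=name, x0=0.0, y0=0.0, cell=cell,
                           values=np.full((n, n), c))


def test_ascii_grid_round_trip(tmp_path):
    r = CovariateRaster(
        name="sst", x0=-5000.0, y0=2000.0, cell=500.0,
        values=np.array([[1.5, np.nan], [3.25, 4.0]]),
        window=(dt.date(2019, 6, 1), dt.date(2019, 6, 8)),
    )
    path = write_ascii_grid(r, tmp_path / "sst.asc")
    r2 = read_ascii_grid(path)
    assert r2.name == "sst"
    assert r2.window == r.window
    np.testing.assert_allclose(r2.values, r.values, equal_nan=True)
    assert (r2.x0, r2.y0, r2.cell) == (r.x0, r.y0, r.cell)


def test_annotate_constant_raster():
    stack = RasterStack()
    stack.add(_const_raster(7.5))
    pts = pd.DataFrame({"x": [500.0, 9500.0], "y": [500.0, 9500.0]})
    out = sio.annotate(pts, stack)
    assert (out["depth"] == 7.5).all()
    assert not out["covariate_missing"].any()
    # determinism: identical call, identical table
    out2 = sio.annotate(pts, stack)
    pd.testing.assert_frame_equal(out, out2)


def test_annotate_half_open_cell_convention():
    vals = np.arange(4.0).reshape(2, 2)  # row 0 = north
    r = CovariateRaster(name="v", x0=0.0, y0=0.0, cell=10.0, values=vals)
    # (10, 10) sits on the shared corner: belongs to the east/north cell
    assert r.value_at(10.0, 10.0) == vals[0, 1]
    assert r.value_at(0.0, 0.0) == vals[1, 0]
    assert np.isnan(r.value_at(20.0, 5.0))  # right edge is exclusive


def test_annotate_dynamic_window_matching():
    stack = RasterStack()
    w1 = (dt.date(2019, 6, 1), dt.date(2019, 6, 8))
    w2 = (dt.date(2019, 6, 9), dt.date(2019, 6, 16))
    stack.add(CovariateRaster("sst", 0.0, 0.0, 10.0, np.full((2, 2), 20.0), window=w1))
    stack.add(CovariateRaster("sst", 0.0, 0.0, 10.0, np.full((2, 2), 22.0), window=w2))
    pts = pd.DataFrame(
        {"x": [5.0, 5.0, 5.0], "y": [5.0, 5.0, 5.0],
         "date": [dt.date(2019, 6, 2), dt.date(2019, 6, 10), dt.date(2019, 7, 1)]}
    )
    out = sio.annotate(pts, stack)
    assert out["sst"].tolist()[:2] == [20.0, 22.0]
    assert np.isnan(out["sst"].iloc[2]) and out["covariate_missing"].iloc[2]


def test_annotate_outside_extent_flagged():
    stack = RasterStack()
    stack.add(_const_raster())
    out = sio.annotate(pd.DataFrame({"x": [-50.0], "y": [5.0]}), stack)
    assert out["covariate_missing"].iloc[0]


# ---------------------------------------------------------------------------
# sighting -> segment assignment


def _sighting_at(tr, s_km, proj, tid="T1", sid="S1"):
    x, y = tr.point_at(s_km)
    lon, lat = proj.inverse(x, y)
    return pd.DataFrame(
        {
            "sighting_id": [sid], "transect_id": [tid], "species": ["striped"],
            "cluster_size": [3], "perp_distance_m": [100.0], "sea_state": [2],
            "lat": [lat], "lon": [lon], "date": [dt.date(2019, 6, 1)],
        }
    )


def test_assignment_by_chainage(proj):
    trs = sio.build_transects(_straight_effort(10.0), proj)
    segs = sio.segment_transects(trs, 1.0)
    s = _sighting_at(trs[0], 2.5, proj)
    out = sio.assign_sightings_to_segments(sio.project_sightings(s, proj), trs, segs)
    assert out["segment_id"].iloc[0] == "T1-2"  # third segment


def test_assignment_boundary_goes_to_earlier_segment(proj):
    trs = sio.build_transects(_straight_effort(10.0), proj)
    segs = sio.segment_transects(trs, 1.0)
    s = _sighting_at(trs[0], 2.0, proj)
    out = sio.assign_sightings_to_segments(sio.project_sightings(s, proj), trs, segs)
    assert out["segment_id"].iloc[0] == "T1-1"


def test_assignment_unknown_transect_errors(proj):
    trs = sio.build_transects(_straight_effort(10.0), proj)
    segs = sio.segment_transects(trs, 1.0)
    s = _sighting_at(trs[0], 2.0, proj, tid="NOPE")
    with pytest.raises(sio.ValidationError):
        sio.assign_sightings_to_segments(sio.project_sightings(s, proj), trs, segs)


def test_assignment_partition_property(proj, small_survey):
    """Every retained sighting maps to exactly one existing segment."""
    segs = sio.segment_transects(small_survey.transects, 1.0)
    s = sio.project_sightings(small_survey.sightings, small_survey.config.projection)
    out = sio.assign_sightings_to_segments(s, small_survey.transects, segs)
    assert len(out) == len(s)  # none off-effort in a synthetic survey
    assert out["segment_id"].isin(segs["segment_id"]).all()
    assert out["segment_id"].notna().all()


# ---------------------------------------------------------------------------
# readers and validation


def test_effort_reader_reports_line_numbers(tmp_path):
    p = tmp_path / "effort.csv"
    p.write_text(
        "transect_id,timestamp,lat,lon,effort_status\n"
        "T1,2019-06-01T08:00:00,36.0,12.0,on\n"
        "T1,2019-06-01T08:00:10,95.0,12.0,on\n"     # bad lat (line 3)
        "T1,2019-06-01T08:00:20,36.0,12.0,maybe\n"  # bad status (line 4)
    )
    with pytest.raises(sio.ValidationError) as err:
        sio.read_effort(p)
    msg = str(err.value)
    assert "line 3" in msg and "line 4" in msg


def test_sightings_reader_checks_polar_consistency(tmp_path):
    p = tmp_path / "s.csv"
    hdr = ("sighting_id,transect_id,date,species,cluster_size,radial_distance_m,"
           "angle_deg,perp_distance_m,sea_state,lat,lon\n")
    p.write_text(
        hdr
        + "S1,T1,2019-06-01,striped,3,1000,30,500.0000001,2,36,12\n"  # consistent
        + "S2,T1,2019-06-01,striped,3,1000,30,400,2,36,12\n"          # inconsistent
    )
    with pytest.raises(sio.ValidationError) as err:
        sio.read_sightings(p)
    assert "line 3" in str(err.value)


def test_sightings_reader_fills_perp_from_polar(tmp_path):
    p = tmp_path / "s.csv"
    hdr = ("sighting_id,transect_id,date,species,cluster_size,radial_distance_m,"
           "angle_deg,perp_distance_m,sea_state,lat,lon\n")
    p.write_text(hdr + "S1,T1,2019-06-01,common,2,1000,30,,1,36,12\n")
    df = sio.read_sightings(p)
    assert df["perp_distance_m"].iloc[0] == pytest.approx(500.0)


def test_sightings_reader_rejects_bad_rows(tmp_path):
    p = tmp_path / "s.csv"
    hdr = ("sighting_id,transect_id,date,species,cluster_size,radial_distance_m,"
           "angle_deg,perp_distance_m,sea_state,lat,lon\n")
    p.write_text(
        hdr
        + "S1,T1,2019-06-01,orca,3,,,100,2,36,12\n"      # unknown species
        + "S2,T1,2019-06-01,striped,0,,,100,2,36,12\n"   # cluster size 0
        + "S3,T1,2019-06-01,striped,3,,,100,7,36,12\n"   # sea state 7
    )
    with pytest.raises(sio.ValidationError) as err:
        sio.read_sightings(p)
    assert len(err.value.errors) == 3
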