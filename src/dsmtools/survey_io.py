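"""Survey data ingest and geometry.

Reads effort (GPS fixes) and sighting records from delimited text, validates
them row by row, projects WGS84 coordinates to planar metres, cuts on-effort
tracklines into ~1 km analysis segments, and attaches environmental
covariates from gridded rasters.

Conventions fixed here and used throughout the package:

* coordinates in files are WGS84 decimal degrees; internal geometry is
  projected metres (see :mod:`dsmtools.projection`); dates are ISO-8601;
* off-effort fixes break a transect into separate on-effort polylines;
* a transect of length L is split into ``max(1, round(L / target))``
  equal-length segments, so effort length is conserved exactly and no sliver
  segments are produced;
* distance truncation retains the closed interval ``x <= w``;
* along-track segment intervals are half-open ``(start, end]`` so a sighting
  exactly on a boundary belongs to the earlier segment.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import Projection
from .rasters import RasterStack

__all__ = [
    "ValidationError",
    "Transect",
    "perpendicular_distance",
    "read_effort",
    "read_sightings",
    "build_transects",
    "segment_transects",
    "annotate",
    "truncate_sightings",
    "assign_sightings_to_segments",
    "project_sightings",
]

log = logging.getLogger(__name__)

SPECIES = ("striped", "bottlenose", "common", "unidentified")
MAX_SEA_STATE = 4  # surveys run up to Beaufort 4


class ValidationError(ValueError):
    """Input file failed validation; carries per-row messages."""

    def __init__(self, path, errors: list[str]):
        self.errors = errors
        shown = "\n  ".join(errors[:20])
        more = f"\n  ... and {len(errors) - 20} more" if len(errors) > 20 else ""
        super().__init__(f"{path}: {len(errors)} invalid rows:\n  {shown}{more}")


def perpendicular_distance(r: float, theta_deg: float) -> float:
    """Perpendicular distance x = r * sin(theta) from radial distance and
    sighting angle (degrees off the trackline, in [0, 180])."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(r < 0):
        raise ValidationError("perpendicular_distance", ["radial distance < 0"])
    if np.any((theta < 0) | (theta > 180)):
        raise ValidationError("perpendicular_distance", ["angle outside [0, 180]"])
    return r * np.sin(np.radians(theta))


# ---------------------------------------------------------------------------
# readers

_EFFORT_COLS = ["transect_id", "timestamp", "lat", "lon", "effort_status"]
_SIGHT_COLS = [
    "sighting_id", "transect_id", "date", "species", "cluster_size",
    "radial_distance_m", "angle_deg", "perp_distance_m", "sea_state", "lat", "lon",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(path, [f"missing columns: {missing}"])


def read_effort(path) -> pd.DataFrame:
    """Read GPS fixes.  Columns: transect_id, timestamp, lat, lon,
    effort_status ('on'/'off'); optional sea_state.  Fixes must be
    time-ordered within a transect."""
    df = pd.read_csv(path, dtype={"transect_id": str})
    _require_columns(df, _EFFORT_COLS, path)
    errors: list[str] = []
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    for i in np.flatnonzero(ts.isna()):
        errors.append(f"line {i + 2}: unparseable timestamp {df['timestamp'].iloc[i]!r}")
    df["timestamp"] = ts
    bad_lat = ~df["lat"].between(-90, 90)
    bad_lon = ~df["lon"].between(-180, 180)
    for i in np.flatnonzero(bad_lat | bad_lon):
        errors.append(f"line {i + 2}: lat/lon out of range ({df['lat'].iloc[i]}, {df['lon'].iloc[i]})")
    bad_status = ~df["effort_status"].isin(["on", "off"])
    for i in np.flatnonzero(bad_status):
        errors.append(f"line {i + 2}: effort_status {df['effort_status'].iloc[i]!r} not 'on'/'off'")
    if not errors:
        for tid, grp in df.groupby("transect_id", sort=False):
            if not grp["timestamp"].is_monotonic_increasing:
                errors.append(f"transect {tid}: fixes not time-ordered")
    if errors:
        raise ValidationError(path, errors)
    if "sea_state" not in df.columns:
        df["sea_state"] = np.nan
    return df


def read_sightings(path) -> pd.DataFrame:
    """Read sighting records.  Either perp_distance_m or both
    radial_distance_m and angle_deg must be present per row; when all three
    are given they must be mutually consistent (x = r sin θ, 1e-6 relative)."""
    df = pd.read_csv(path, dtype={"sighting_id": str, "transect_id": str})
    _require_columns(df, _SIGHT_COLS, path)
    errors: list[str] = []
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    for i in np.flatnonzero(dates.isna()):
        errors.append(f"line {i + 2}: unparseable date {df['date'].iloc[i]!r}")
    df["date"] = dates.dt.date

    for i, row in df.iterrows():
        line = i + 2
        if row["species"] not in SPECIES:
            errors.append(f"line {line}: species {row['species']!r} not in {SPECIES}")
        if not (float(row["cluster_size"]) >= 1 and float(row["cluster_size"]).is_integer()):
            errors.append(f"line {line}: cluster_size {row['cluster_size']!r} not a positive integer")
        ss = row["sea_state"]
        if not (0 <= ss <= MAX_SEA_STATE and float(ss).is_integer()):
            errors.append(f"line {line}: sea_state {ss!r} not an integer in 0..{MAX_SEA_STATE}")
        if not (-90 <= row["lat"] <= 90 and -180 <= row["lon"] <= 180):
            errors.append(f"line {line}: lat/lon out of range")
        r, th, x = row["radial_distance_m"], row["angle_deg"], row["perp_distance_m"]
        have_polar = pd.notna(r) and pd.notna(th)
        if have_polar:
            if r < 0 or not (0 <= th <= 180):
                errors.append(f"line {line}: invalid radial distance/angle ({r}, {th})")
                continue
            x_calc = float(r) * np.sin(np.radians(float(th)))
            if pd.notna(x):
                tol = 1e-6 * max(1.0, abs(x_calc))
                if abs(x - x_calc) > tol:
                    errors.append(
                        f"line {line}: perp_distance_m {x} inconsistent with r*sin(theta)={x_calc:.6f}"
                    )
            else:
                df.loc[i, "perp_distance_m"] = x_calc
        elif pd.isna(x):
            errors.append(f"line {line}: need perp_distance_m or radial_distance_m+angle_deg")
        elif x < 0:
            errors.append(f"line {line}: perp_distance_m {x} < 0")
    if errors:
        raise ValidationError(path, errors)
    df["cluster_size"] = df["cluster_size"].astype(int)
    df["sea_state"] = df["sea_state"].astype(int)
    return df


# ---------------------------------------------------------------------------
# transects and segments


@dataclass
class Transect:
    """One contiguous on-effort polyline in projected metres.

    ``transect_id`` is the on-effort piece id (``<parent>/<k>`` when
    off-effort gaps split a field transect); ``chainage_km`` holds the
    cumulative along-track distance at each vertex.
    """

    transect_id: str
    parent_id: str
    xy: np.ndarray               # (n, 2) metres
    times: np.ndarray            # (n,) datetime64
    sea_state: float = np.nan

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        d = np.hypot(*np.diff(self.xy, axis=0).T) / 1000.0
        self.chainage_km = np.concatenate([[0.0], np.cumsum(d)])

    @property
    def length_km(self) -> float:
        return float(self.chainage_km[-1])

    def point_at(self, s_km: float) -> tuple[float, float]:
        """Interpolated point at along-track distance ``s_km``."""
        x = np.interp(s_km, self.chainage_km, self.xy[:, 0])
        y = np.interp(s_km, self.chainage_km, self.xy[:, 1])
        return float(x), float(y)

    def date_at(self, s_km: float) -> dt.date:
        """Date of the vertex nearest to chainage ``s_km``."""
        i = int(np.argmin(np.abs(self.chainage_km - s_km)))
        return pd.Timestamp(self.times[i]).date()

    def station_of(self, x: float, y: float) -> tuple[float, float]:
        """(chainage_km, offline_distance_m) of the polyline point nearest to
        (x, y) — the orthogonal projection onto the nearest leg."""
        p = np.array([x, y])
        a = self.xy[:-1]
        b = self.xy[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        dist = np.hypot(*(p - proj).T)
        k = int(np.argmin(dist))
        leg_len = self.chainage_km[k + 1] - self.chainage_km[k]
        return float(self.chainage_km[k] + t[k] * leg_len), float(dist[k])


def build_transects(effort: pd.DataFrame, projection: Projection) -> list[Transect]:
    """Project fixes and split each transect at off-effort gaps."""
    transects: list[Transect] = []
    for tid, grp in effort.groupby("transect_id", sort=False):
        on = (grp["effort_status"] == "on").to_numpy()
        # contiguous runs of on-effort fixes
        runs = np.flatnonzero(np.diff(np.concatenate([[0], on.view(np.int8), [0]])))
        pieces = list(zip(runs[::2], runs[1::2]))
        multi = len(pieces) > 1
        for k, (i0, i1) in enumerate(pieces):
            piece = grp.iloc[i0:i1]
            if len(piece) < 2:
                log.warning("transect %s piece %d has < 2 on-effort fixes; skipped", tid, k)
                continue
            x, y = projection.forward(piece["lon"].to_numpy(), piece["lat"].to_numpy())
            tr = Transect(
                transect_id=f"{tid}/{k}" if multi else str(tid),
                parent_id=str(tid),
                xy=np.column_stack([x, y]),
                times=piece["timestamp"].to_numpy(),
                sea_state=float(piece["sea_state"].iloc[0]) if "sea_state" in piece else np.nan,
            )
            if tr.length_km <= 0:
                log.warning("transect %s has zero length; skipped", tr.transect_id)
                continue
            transects.append(tr)
    return transects


def segment_transects(transects: list[Transect], target_length_km: float = 1.0) -> pd.DataFrame:
    """Cut each transect into ``max(1, round(L/target))`` equal segments.

    Returns one row per segment: segment_id, transect_id, length_km,
    midpoint x/y (on the polyline), date (nearest fix), sea_state.
    """
    if target_length_km <= 0:
        raise ValueError("target_length_km must be positive")
    rows = []
    for tr in transects:
        L = tr.length_km
        if L <= 0:
            log.warning("zero-length transect %s skipped", tr.transect_id)
            continue
        n_seg = max(1, round(L / target_length_km))
        seg_len = L / n_seg
        for j in range(n_seg):
            mid = (j + 0.5) * seg_len
            x, y = tr.point_at(mid)
            rows.append(
                {
                    "segment_id": f"{tr.transect_id}-{j}",
                    "transect_id": tr.transect_id,
                    "segment_index": j,
                    "length_km": seg_len,
                    "x": x,
                    "y": y,
                    "date": tr.date_at(mid),
                    "sea_state": tr.sea_state,
                }
            )
    return pd.DataFrame(rows)


def annotate(
    table: pd.DataFrame,
    stack: RasterStack,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Attach raster covariate values at each record's (x, y) midpoint.

    Dynamic rasters are matched to the composite window containing the
    record's ``date``.  Records on missing cells, outside every raster
    extent, or dated outside every composite window get NaN and
    ``covariate_missing=True``; downstream stages drop and count them.
    """
    out = table.copy()
    names = covariates or stack.names
    dates = out["date"] if "date" in out.columns else pd.Series([None] * len(out))
    xs = out["x"].to_numpy(dtype=float)
    ys = out["y"].to_numpy(dtype=float)
    for name in names:
        vals = np.full(len(out), np.nan)
        if all(r.window is None for r in stack.rasters[name]):
            vals = stack.select(name, None).value_at(xs, ys)
        else:
            # vectorize by composite: all records sharing a date window at once
            for d in pd.unique(dates):
                r = stack.select(name, d)
                idx = np.flatnonzero((dates == d).to_numpy())
                if r is not None and len(idx):
                    vals[idx] = r.value_at(xs[idx], ys[idx])
        out[name] = vals
    out["covariate_missing"] = out[names].isna().any(axis=1)
    n_miss = int(out["covariate_missing"].sum())
    if n_miss:
        log.info("annotate: %d/%d records have missing covariates", n_miss, len(out))
    return out


def truncate_sightings(sightings: pd.DataFrame, w: float) -> pd.DataFrame:
    """Drop sightings beyond the truncation distance w (closed: x <= w kept)."""
    if w <= 0:
        raise ValueError("truncation distance must be positive")
    keep = sightings["perp_distance_m"] <= w
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("truncation at %g m removed %d of %d sightings", w, n_removed, len(sightings))
    return sightings.loc[keep].reset_index(drop=True)


def assign_sightings_to_segments(
    sightings: pd.DataFrame,
    transects: list[Transect],
    segments: pd.DataFrame,
    max_offline_m: float = 5000.0,
) -> pd.DataFrame:
    """Map each sighting to the segment whose along-track interval contains
    its nearest-trackline-point chainage.

    Expects projected columns ``_x``/``_y`` (see :func:`project_sightings`).
    Intervals are half-open ``(start, end]``: a sighting exactly on a segment
    boundary goes to the earlier segment.  Sightings farther than
    ``max_offline_m`` from every on-effort polyline of their transect are
    treated as off-effort and excluded (logged).  Unknown transect -> error.
    """
    by_parent: dict[str, list[Transect]] = {}
    for tr in transects:
        by_parent.setdefault(tr.parent_id, []).append(tr)
    seg_info = {
        tid: (grp["length_km"].iloc[0], len(grp), grp["segment_id"].to_list())
        for tid, grp in segments.groupby("transect_id")
    }
    out = sightings.copy()
    seg_ids: list[str | None] = []
    n_off = 0
    for _, row in out.iterrows():
        parent = str(row["transect_id"])
        if parent not in by_parent:
            raise ValidationError("sightings", [f"sighting {row['sighting_id']}: unknown transect {parent!r}"])
        best = None  # (offline_m, transect, chainage_km)
        for tr in by_parent[parent]:
            s_km, off_m = tr.station_of(row["_x"], row["_y"])
            if best is None or off_m < best[0]:
                best = (off_m, tr, s_km)
        off_m, tr, s_km = best
        if off_m > max_offline_m:
            n_off += 1
            seg_ids.append(None)
            continue
        seg_len, n_seg, ids = seg_info[tr.transect_id]
        # (start, end] intervals with a 1e-6 slack so projection round-trip
        # noise cannot push an exact-boundary sighting into the next segment
        idx = min(max(int(np.ceil(s_km / seg_len - 1e-6)) - 1, 0), n_seg - 1)
        seg_ids.append(ids[idx])
    out["segment_id"] = seg_ids
    if n_off:
        log.info("assign: %d sightings off-effort (> %g m from trackline); excluded", n_off, max_offline_m)
    return out.loc[out["segment_id"].notna()].reset_index(drop=True)


def project_sightings(sightings: pd.DataFrame, projection: Projection) -> pd.DataFrame:
    """Add projected planar coordinates (columns ``_x``, ``_y``)."""
    out = sightings.copy()
    x, y = projection.forward(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["_x"] = x
    out["_y"] = y
    return out
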