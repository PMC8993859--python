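"""Reading, filtering, and summarizing check-in and call-record datasets.

Two on-disk dialects are supported out of the box:

* check-in TSV in the layout of the archived location-based social-network
  snapshots: ``user <TAB> ISO-8601 time <TAB> latitude <TAB> longitude
  <TAB> location id``, no header;
* call-record CSV: ``caller, callee, epoch timestamp, antenna_id`` — each
  call becomes one check-in for the caller at the antenna, and the full
  call log is retained for social-tie inference.

All timestamps are normalized to UTC seconds on ingestion so colocation
windows and the time-constrained parsers share one time axis. Rows missing
a mandatory attribute (user, time, location) are dropped and counted; the
count is reported, never silently discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import CheckinDataset, IngestionReport, MobilitySummary, Trajectory

__all__ = [
    "Dialect",
    "LBSN_DIALECT",
    "read_checkins",
    "read_social_edges",
    "read_cdr",
    "filter_dataset",
    "summarize_mobility",
    "haversine_km",
    "EARTH_RADIUS_KM",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Dialect:
    """Column order, separator, and timestamp convention of a check-in file."""

    columns: Tuple[str, ...] = ("user", "time", "lat", "lon", "location")
    sep: str = "\t"
    timestamp: str = "iso8601"  # "iso8601" | "epoch"


LBSN_DIALECT = Dialect()


def _parse_times(raw: pd.Series, convention: str) -> pd.Series:
    if convention == "iso8601":
        parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="mixed")
        return parsed.map(lambda x: x.timestamp() if pd.notna(x) else np.nan)
    if convention == "epoch":
        return pd.to_numeric(raw, errors="coerce")
    raise ValueError(f"unknown timestamp convention {convention!r}")


def _build_trajectories(frame: pd.DataFrame, with_coords: bool) -> dict:
    trajectories = {}
    # stable sort: equal timestamps keep file order, so ingestion never
    # reorders a user's events beyond the time ordering itself
    frame = frame.sort_values(["user", "t"], kind="stable")
    for uid, grp in frame.groupby("user", sort=True):
        trajectories[str(uid)] = Trajectory(
            user_id=str(uid),
            locations=[str(x) for x in grp["location"]],
            timestamps=grp["t"].to_numpy(dtype=float),
            latitude=grp["lat"].to_numpy(dtype=float) if with_coords else None,
            longitude=grp["lon"].to_numpy(dtype=float) if with_coords else None,
        )
    return trajectories


def read_checkins(
    path, dialect: Dialect = LBSN_DIALECT
) -> Tuple[CheckinDataset, IngestionReport]:
    """Read a check-in file into a dataset plus an ingestion report.

    Rows with a missing or unparseable user, timestamp, or location id are
    dropped and counted. Out-of-range coordinates are nulled (coordinates
    are optional on an event) and counted separately. Raises if the file
    is missing or no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"check-in file not found: {path}")
    frame = pd.read_csv(
        path, sep=dialect.sep, header=None, names=list(dialect.columns), dtype=str
    )
    report = IngestionReport(rows_read=len(frame))

    frame["t"] = _parse_times(frame["time"], dialect.timestamp)
    mandatory_ok = (
        frame["user"].notna()
        & (frame["user"].astype(str).str.len() > 0)
        & frame["t"].notna()
        & np.isfinite(frame["t"].fillna(np.nan))
        & frame["location"].notna()
        & (frame["location"].astype(str).str.len() > 0)
    )
    n_bad = int((~mandatory_ok).sum())
    if n_bad:
        report.drop_reasons["missing_mandatory"] = n_bad
    frame = frame[mandatory_ok].copy()
    report.rows_dropped = n_bad

    has_coords = "lat" in frame.columns and "lon" in frame.columns
    if has_coords:
        frame["lat"] = pd.to_numeric(frame["lat"], errors="coerce")
        frame["lon"] = pd.to_numeric(frame["lon"], errors="coerce")
        bad_coord = (
            (frame["lat"].abs() > 90) | (frame["lon"].abs() > 180)
        ).fillna(False)
        if bad_coord.any():
            report.drop_reasons["coordinates_nulled"] = int(bad_coord.sum())
            frame.loc[bad_coord, ["lat", "lon"]] = np.nan
    else:
        frame["lat"] = np.nan
        frame["lon"] = np.nan

    if frame.empty:
        raise ValueError(f"no valid rows in {path}")

    trajectories = _build_trajectories(frame, with_coords=True)
    report.users_found = len(trajectories)
    logger.info(
        "read %s: %d rows, %d dropped, %d users",
        path,
        report.rows_read,
        report.rows_dropped,
        report.users_found,
    )
    ds = CheckinDataset(
        trajectories=trajectories,
        provenance={"source": str(path), "filters": []},
    )
    return ds, report


def read_social_edges(path) -> set:
    """Read a two-column edge list into an undirected, deduplicated edge set.

    Self-loops are removed; malformed rows are skipped with a logged count.
    Edges are stored as sorted ``(u, v)`` tuples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge file not found: {path}")
    edges: set = set()
    skipped = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 2:
                if line.strip():
                    skipped += 1
                continue
            a, b = parts
            if a == b:
                continue
            edges.add((a, b) if a < b else (b, a))
    if skipped:
        logger.warning("skipped %d malformed edge rows in %s", skipped, path)
    return edges


def read_cdr(path) -> Tuple[CheckinDataset, IngestionReport]:
    """Read a call-record CSV: ``caller, callee, epoch timestamp, antenna``.

    Each call yields one check-in for the caller at the antenna; the full
    directed call log is kept on the dataset for social-tie inference.
    Calls missing any field are dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"call-record file not found: {path}")
    frame = pd.read_csv(
        path, header=None, names=["caller", "callee", "time", "antenna"], dtype=str
    )
    report = IngestionReport(rows_read=len(frame))
    frame["t"] = pd.to_numeric(frame["time"], errors="coerce")
    ok = (
        frame["caller"].notna()
        & frame["callee"].notna()
        & frame["t"].notna()
        & frame["antenna"].notna()
        & (frame["antenna"].astype(str).str.len() > 0)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        report.drop_reasons["missing_mandatory"] = n_bad
    report.rows_dropped = n_bad
    frame = frame[ok].copy()
    if frame.empty:
        raise ValueError(f"no valid rows in {path}")

    events = frame.rename(columns={"caller": "user", "antenna": "location"})[
        ["user", "location", "t"]
    ].copy()
    events["lat"] = np.nan
    events["lon"] = np.nan
    trajectories = _build_trajectories(events, with_coords=False)
    report.users_found = len(trajectories)
    call_log = frame[["caller", "callee", "t"]].rename(columns={"t": "timestamp"})
    call_log = call_log.reset_index(drop=True)
    ds = CheckinDataset(
        trajectories=trajectories,
        call_log=call_log,
        provenance={"source": str(path), "filters": []},
    )
    return ds, report


def filter_dataset(
    ds: CheckinDataset,
    min_checkins: int = 150,
    min_active_days: Optional[int] = None,
) -> CheckinDataset:
    """Retain users with at least ``min_checkins`` logged events (inclusive).

    ``min_active_days`` optionally also requires a minimum number of
    distinct UTC days with activity (off by default). Social edges are
    restricted to retained users; the filter settings are appended to the
    dataset provenance. Raises if no user survives. Idempotent.
    """
    kept = {}
    for uid, traj in ds.trajectories.items():
        if traj.N < min_checkins:
            continue
        if min_active_days is not None:
            days = np.unique(np.floor(traj.timestamps / 86400.0))
            if len(days) < min_active_days:
                continue
        kept[uid] = traj
    if not kept:
        raise ValueError(
            f"no users with >= {min_checkins} check-ins; lower the threshold"
        )
    edges = None
    if ds.social_edges is not None:
        edges = {e for e in ds.social_edges if e[0] in kept and e[1] in kept}
    provenance = {
        "source": ds.provenance.get("source", "unknown"),
        "filters": list(ds.provenance.get("filters", []))
        + [{"min_checkins": min_checkins, "min_active_days": min_active_days}],
    }
    return CheckinDataset(
        trajectories=kept,
        social_edges=edges,
        call_log=ds.call_log,
        provenance=provenance,
    )


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (haversine, Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def summarize_mobility(ds: CheckinDataset) -> MobilitySummary:
    """Distinct-location counts, jump lengths, and radii of gyration.

    Jump length: great-circle distance between consecutive events of one
    user. Radius of gyration: root-mean-square great-circle distance of a
    user's events from the user's coordinate centroid. Users without
    complete coordinates are excluded from the distance statistics and
    listed in ``excluded_users``.
    """
    distinct = {uid: traj.n for uid, traj in ds.trajectories.items()}
    jumps = {}
    rgs = {}
    excluded = []
    for uid in ds.users:
        traj = ds.trajectories[uid]
        if not traj.has_coordinates:
            excluded.append(uid)
            continue
        lat, lon = traj.latitude, traj.longitude
        jumps[uid] = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) if traj.N > 1 else np.array([])
        d = haversine_km(lat, lon, lat.mean(), lon.mean())
        rgs[uid] = float(np.sqrt(np.mean(d**2)))
    if excluded:
        logger.warning("%d users lack coordinates; excluded from distances", len(excluded))
    return MobilitySummary(
        distinct_locations=distinct,
        jump_lengths_km=jumps,
        radius_of_gyration_km=rgs,
        excluded_users=excluded,
    )
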