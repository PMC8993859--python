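"""Canonical event / trajectory containers shared by every analysis stage.

A check-in is a tuple (user, location, time): a user visited an opaque
location id at an instant. A trajectory is one user's time-ordered sequence
of such visits; its length ``N`` counts visits, ``n`` counts distinct
locations, and ``distinct`` is the set of distinct location ids. All
timestamps are kept on a single internal axis: UTC seconds since the epoch,
as floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CheckinEvent",
    "Trajectory",
    "CheckinDataset",
    "IngestionReport",
    "MobilitySummary",
]


@dataclass(frozen=True)
class CheckinEvent:
    """A single located, timestamped visit by one user.

    ``timestamp`` is UTC seconds. Coordinates are optional decimal degrees;
    when present they must lie in [-90, 90] x [-180, 180].
    """

    user_id: str
    timestamp: float
    location_id: str
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.timestamp):
            raise ValueError("timestamp must be finite")
        if self.location_id is None or str(self.location_id) == "":
            raise ValueError("location_id must be non-empty")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


class Trajectory:
    """One user's time-ordered location sequence.

    Parameters
    ----------
    user_id:
        Opaque user identifier.
    locations:
        Visit sequence of hashable location ids, in time order.
    timestamps:
        UTC seconds per visit; must be nondecreasing and finite.
    latitude, longitude:
        Optional per-visit coordinates (NaN marks a missing coordinate).
    """

    __slots__ = ("user_id", "locations", "timestamps", "latitude", "longitude", "_distinct")

    def __init__(
        self,
        user_id: str,
        locations: Iterable[Hashable],
        timestamps: Iterable[float],
        latitude: Optional[Iterable[float]] = None,
        longitude: Optional[Iterable[float]] = None,
    ) -> None:
        self.user_id = user_id
        self.locations = tuple(locations)
        self.timestamps = np.asarray(timestamps, dtype=float)
        if len(self.locations) == 0:
            raise ValueError(f"trajectory for {user_id!r} is empty")
        if self.timestamps.shape != (len(self.locations),):
            raise ValueError("locations and timestamps must have equal length")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValueError("timestamps must be finite")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError(f"timestamps for {user_id!r} are not nondecreasing")
        self.latitude = None if latitude is None else np.asarray(latitude, dtype=float)
        self.longitude = None if longitude is None else np.asarray(longitude, dtype=float)
        for coord in (self.latitude, self.longitude):
            if coord is not None and coord.shape != (len(self.locations),):
                raise ValueError("coordinate arrays must match the visit count")
        self._distinct: Optional[frozenset] = None

    @property
    def N(self) -> int:
        """Total number of visits."""
        return len(self.locations)

    @property
    def distinct(self) -> frozenset:
        """Set of distinct location ids (``Y`` in the overlap statistics)."""
        if self._distinct is None:
            self._distinct = frozenset(self.locations)
        return self._distinct

    @property
    def n(self) -> int:
        """Number of distinct locations visited."""
        return len(self.distinct)

    @property
    def has_coordinates(self) -> bool:
        return (
            self.latitude is not None
            and self.longitude is not None
            and bool(np.all(np.isfinite(self.latitude)))
            and bool(np.all(np.isfinite(self.longitude)))
        )

    def __len__(self) -> int:
        return self.N

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Trajectory({self.user_id!r}, N={self.N}, n={self.n})"


@dataclass
class IngestionReport:
    """Per-file accounting of what was read and what was discarded."""

    rows_read: int = 0
    rows_dropped: int = 0
    users_found: int = 0
    drop_reasons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_dropped": self.rows_dropped,
            "users_found": self.users_found,
            "drop_reasons": dict(self.drop_reasons),
        }


@dataclass
class CheckinDataset:
    """Trajectories plus optional social-edge and call-log side information.

    ``social_edges`` holds unordered, deduplicated user-id pairs (stored as
    sorted tuples). ``call_log`` is a DataFrame with columns
    ``caller, callee, timestamp`` retained in full for social-tie inference
    on call-record data. ``provenance`` records the source and every filter
    applied, in order.
    """

    trajectories: dict
    social_edges: Optional[set] = None
    call_log: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=lambda: {"source": "unknown", "filters": []})

    @property
    def users(self) -> list:
        return sorted(self.trajectories)

    @property
    def n_users(self) -> int:
        return len(self.trajectories)

    @property
    def n_events(self) -> int:
        return sum(t.N for t in self.trajectories.values())

    def events_frame(self) -> pd.DataFrame:
        """All events as a flat DataFrame (user, location, t), time-sorted per user."""
        users, locs, ts = [], [], []
        for uid in self.users:
            traj = self.trajectories[uid]
            users.extend([uid] * traj.N)
            locs.extend(traj.locations)
            ts.append(traj.timestamps)
        return pd.DataFrame(
            {"user": users, "location": locs, "t": np.concatenate(ts) if ts else np.array([])}
        )


@dataclass
class MobilitySummary:
    """Descriptive mobility statistics for a dataset.

    Distinct-location counts cover every user; jump lengths (great-circle km
    between consecutive visits) and radius of gyration (root-mean-square
    great-circle distance from the visit centroid, km) cover users with
    complete coordinates. Users lacking coordinates are listed in
    ``excluded_users``.
    """

    distinct_locations: dict
    jump_lengths_km: dict
    radius_of_gyration_km: dict
    excluded_users: list
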