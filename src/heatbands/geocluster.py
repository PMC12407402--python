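"""Geographic clustering of birth locations with bounded spatial extent.

Cluster-robust standard errors are taken at the level of location groups
whose maximum pairwise great-circle distance (diameter) is bounded, by
default at 50 miles.  Complete-linkage agglomerative clustering is used
because its merge height equals the merged cluster's diameter, so cutting
the dendrogram at the bound directly enforces it.  Distances are computed
on the sphere (haversine), not a planar projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["GeoPoint", "ClusterAssignment", "haversine_miles", "cluster_max_diameter"]

EARTH_RADIUS_MILES = 3958.8


@dataclass(frozen=True)
class GeoPoint:
    location_id: str
    lat: float
    lon: float

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ValueError(
                f"invalid coordinates for {self.location_id!r}: "
                f"({self.lat}, {self.lon})"
            )


def haversine_miles(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in miles between two points."""
    la1, lo1, la2, lo2 = map(np.radians, (a.lat, a.lon, b.lat, b.lon))
    h = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(h)))


def _pairwise_miles(points: list[GeoPoint]) -> np.ndarray:
    lat = np.radians([p.lat for p in points])
    lon = np.radians([p.lon for p in points])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    h = np.clip(h, 0.0, 1.0)
    return 2 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(h))


@dataclass(frozen=True)
class ClusterAssignment:
    """location_id -> cluster_id, with audited per-cluster diameters."""

    assignment: dict[str, int]
    diameters: dict[int, float]

    @property
    def n_clusters(self) -> int:
        return len(self.diameters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["location_id", "cluster_id"]
        )


def cluster_max_diameter(
    points: list[GeoPoint], max_diameter: float = 50.0
) -> ClusterAssignment:
    """Group locations so every cluster's diameter is <= ``max_diameter``.

    Complete-linkage agglomeration on pairwise haversine distances, cut at
    the diameter bound.  Points are processed in location_id order so the
    partition is invariant to input order; cluster ids are renumbered from
    0 in order of each cluster's smallest location_id.
    """
    if not points:
        raise ValueError("cluster_max_diameter requires at least one point")
    pts = sorted(points, key=lambda p: str(p.location_id))
    if len(pts) == 1:
        return ClusterAssignment({pts[0].location_id: 0}, {0: 0.0})
    dmat = _pairwise_miles(pts)
    z = linkage(squareform(dmat, checks=False), method="complete")
    raw = fcluster(z, t=max_diameter, criterion="distance")
    # renumber deterministically by first (smallest) member location_id
    order: dict[int, int] = {}
    for lbl in raw:
        if lbl not in order:
            order[lbl] = len(order)
    assignment = {p.location_id: order[lbl] for p, lbl in zip(pts, raw)}
    diameters: dict[int, float] = {}
    for cid in set(assignment.values()):
        idx = [i for i, p in enumerate(pts) if assignment[p.location_id] == cid]
        diameters[cid] = float(dmat[np.ix_(idx, idx)].max()) if len(idx) > 1 else 0.0
    bad = {c: d for c, d in diameters.items() if d > max_diameter + 1e-9}
    if bad:
        raise AssertionError(f"cluster diameter bound violated: {bad}")
    return ClusterAssignment(assignment, diameters)
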