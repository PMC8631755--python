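"""Great-circle geometry helpers and the occurrence-point container."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "pairwise_distance_km",
    "spherical_midpoint",
    "OccurrenceSet",
]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between (lon, lat) pairs in degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def pairwise_distance_km(lons, lats) -> np.ndarray:
    """Symmetric great-circle distance matrix in km."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def spherical_midpoint(lon1: float, lat1: float, lon2: float, lat2: float
                       ) -> tuple[float, float]:
    """Midpoint of the great-circle segment between two points (degrees).

    Antipodal pairs have no unique midpoint and raise ``ValueError``.
    """
    v1 = _unit(lon1, lat1)
    v2 = _unit(lon2, lat2)
    m = v1 + v2
    norm = np.linalg.norm(m)
    if norm < 1e-9:
        raise ValueError(f"antipodal pair ({lon1},{lat1})-({lon2},{lat2})")
    m /= norm
    lat = np.degrees(np.arcsin(np.clip(m[2], -1, 1)))
    lon = np.degrees(np.arctan2(m[1], m[0]))
    return float(lon), float(lat)


def _unit(lon: float, lat: float) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])


@dataclass
class OccurrenceSet:
    """Species occurrence points (lon/lat degrees) with a provenance tag."""

    lons: np.ndarray
    lats: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.lons = np.atleast_1d(np.asarray(self.lons, dtype=float))
        self.lats = np.atleast_1d(np.asarray(self.lats, dtype=float))
        if self.lons.shape != self.lats.shape:
            raise ValueError("lon/lat length mismatch")

    def __len__(self) -> int:
        return len(self.lons)

    def points(self) -> np.ndarray:
        return np.column_stack([self.lons, self.lats])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"lon": self.lons, "lat": self.lats}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "OccurrenceSet":
        df = pd.read_csv(path)
        return cls(df["lon"].to_numpy(), df["lat"].to_numpy(), provenance or str(path))
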