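"""Track reading/writing, distance and grade computation, synthetic routes.

Routes are ordered sequences of GPS points with elevation.  Distances are
great-circle (haversine) on a spherical Earth, which is accurate to well
under a metre over the few-hundred-metre steps that matter here.  Grades
are rise over run, dimensionless, one value per inter-point step.
"""

from __future__ import annotations

import csv
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

EARTH_RADIUS_M = 6371008.8
#: consecutive points closer than this are treated as duplicates
DEDUP_DISTANCE_M = 0.1
#: grades are clipped to this magnitude; steeper values are GPS artefacts
MAX_GRADE = 0.35

GPX_NS = "http://www.topografix.com/GPX/1/1"


class TrackError(ValueError):
    """Raised for unusable input tracks (missing elevation, too few points)."""


@dataclass(frozen=True)
class TrackPoint:
    """A single GPS fix with elevation.

    latitude/longitude are WGS84 degrees, elevation is metres above sea
    level, timestamp (optional) is seconds since the epoch.
    """

    latitude: float
    longitude: float
    elevation: float
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise TrackError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise TrackError(f"longitude {self.longitude} outside [-180, 180]")
        if not math.isfinite(self.elevation):
            raise TrackError("elevation must be finite")


@dataclass
class Route:
    """An ordered track with per-point cumulative distance and step grades.

    ``cumulative_distance[k]`` is the along-track distance of point k from
    the start (``[0] == 0``); ``grade[k]`` is the rise-over-run slope of the
    step from point k to k+1, so ``len(grade) == len(points) - 1``.
    """

    points: list[TrackPoint]
    cumulative_distance: np.ndarray = field(default=None)  # type: ignore[assignment]
    grade: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise TrackError("degenerate track: fewer than 2 usable points")
        if self.cumulative_distance is None:
            self.cumulative_distance = _cumulative_distances(self.points)
        self.cumulative_distance = np.asarray(self.cumulative_distance, dtype=float)
        if self.grade is None:
            self.grade = _raw_grades(self.points, self.cumulative_distance)
        self.grade = np.asarray(self.grade, dtype=float)
        if len(self.grade) != len(self.points) - 1:
            raise TrackError("grade array must have one entry per step")

    @property
    def length_m(self) -> float:
        return float(self.cumulative_distance[-1])

    @property
    def elevations(self) -> np.ndarray:
        return np.array([p.elevation for p in self.points])


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres between two WGS84 points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def _cumulative_distances(points: Sequence[TrackPoint]) -> np.ndarray:
    dist = np.zeros(len(points))
    for k in range(1, len(points)):
        p, q = points[k - 1], points[k]
        dist[k] = dist[k - 1] + haversine_m(p.latitude, p.longitude, q.latitude, q.longitude)
    return dist


def _raw_grades(points: Sequence[TrackPoint], dist: np.ndarray) -> np.ndarray:
    ele = np.array([p.elevation for p in points])
    run = np.diff(dist)
    if np.any(run <= 0):
        raise TrackError("zero-length step after deduplication (internal error)")
    return np.clip(np.diff(ele) / run, -MAX_GRADE, MAX_GRADE)


def _dedupe(points: list[TrackPoint]) -> list[TrackPoint]:
    out = [points[0]]
    for p in points[1:]:
        q = out[-1]
        if haversine_m(q.latitude, q.longitude, p.latitude, p.longitude) >= DEDUP_DISTANCE_M:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# reading and writing

def _parse_time(text: str) -> float:
    text = text.strip()
    try:
        return float(text)  # epoch seconds
    except ValueError:
        pass
    dt = datetime.fromisoformat(text.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def read_track(path: str | Path, format: Optional[str] = None) -> Route:
    """Read a GPX 1.1 or CSV (``lat,lon,ele[,time]``) track into a Route.

    Duplicate consecutive points (< 0.1 m apart) are collapsed; timestamps
    are preserved when present.  Missing elevation on any point is a hard
    error naming the point index; fewer than 2 usable points is a hard
    error ("degenerate track").
    """
    path = Path(path)
    fmt = format or ("gpx" if path.suffix.lower() == ".gpx" else "csv")
    if fmt == "gpx":
        raw = _read_gpx(path)
    elif fmt == "csv":
        raw = _read_csv(path)
    else:
        raise TrackError(f"unknown track format {fmt!r}")
    if len(raw) < 2:
        raise TrackError("degenerate track: fewer than 2 usable points")
    pts = _dedupe(raw)
    if len(pts) < 2:
        raise TrackError("degenerate track: fewer than 2 usable points")
    return Route(points=pts)


def _read_gpx(path: Path) -> list[TrackPoint]:
    root = ET.parse(path).getroot()
    # accept namespaced and bare GPX alike, track points or route points
    trkpts: list[ET.Element] = []
    for tag in ("trkpt", "rtept"):
        trkpts = root.findall(f".//{{{GPX_NS}}}{tag}") or root.findall(f".//{tag}")
        if trkpts:
            break
    points = []
    for idx, el in enumerate(trkpts):
        ele_el = el.find(f"{{{GPX_NS}}}ele")
        if ele_el is None:
            ele_el = el.find("ele")
        if ele_el is None or ele_el.text is None:
            raise TrackError(f"missing elevation at point index {idx}")
        time_el = el.find(f"{{{GPX_NS}}}time")
        if time_el is None:
            time_el = el.find("time")
        ts = _parse_time(time_el.text) if time_el is not None and time_el.text else None
        points.append(
            TrackPoint(
                latitude=float(el.get("lat")),
                longitude=float(el.get("lon")),
                elevation=float(ele_el.text),
                timestamp=ts,
            )
        )
    return points


def _read_csv(path: Path) -> list[TrackPoint]:
    points = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"lat", "lon", "ele"} <= set(reader.fieldnames):
            raise TrackError("CSV track must have header lat,lon,ele[,time]")
        for idx, row in enumerate(reader):
            if row.get("ele") in (None, ""):
                raise TrackError(f"missing elevation at point index {idx}")
            ts = _parse_time(row["time"]) if row.get("time") else None
            points.append(
                TrackPoint(
                    latitude=float(row["lat"]),
                    longitude=float(row["lon"]),
                    elevation=float(row["ele"]),
                    timestamp=ts,
                )
            )
    return points


def write_track(route: Route, path: str | Path, format: Optional[str] = None) -> None:
    """Write a Route as GPX 1.1 (``<trkpt>``) or the CSV dialect."""
    path = Path(path)
    fmt = format or ("gpx" if path.suffix.lower() == ".gpx" else "csv")
    if fmt == "gpx":
        _write_gpx(route, path)
    elif fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["lat", "lon", "ele", "time"])
            for p in route.points:
                writer.writerow(
                    [f"{p.latitude:.7f}", f"{p.longitude:.7f}", f"{p.elevation:.3f}",
                     "" if p.timestamp is None else f"{p.timestamp:.1f}"]
                )
    else:
        raise TrackError(f"unknown track format {fmt!r}")


def _write_gpx(route: Route, path: Path) -> None:
    ET.register_namespace("", GPX_NS)
    gpx = ET.Element(f"{{{GPX_NS}}}gpx", version="1.1", creator="ebiketrainer")
    trk = ET.SubElement(gpx, f"{{{GPX_NS}}}trk")
    seg = ET.SubElement(trk, f"{{{GPX_NS}}}trkseg")
    for p in route.points:
        el = ET.SubElement(seg, f"{{{GPX_NS}}}trkpt",
                           lat=f"{p.latitude:.7f}", lon=f"{p.longitude:.7f}")
        ET.SubElement(el, f"{{{GPX_NS}}}ele").text = f"{p.elevation:.3f}"
        if p.timestamp is not None:
            iso = datetime.fromtimestamp(p.timestamp, tz=timezone.utc)
            ET.SubElement(el, f"{{{GPX_NS}}}time").text = iso.strftime("%Y-%m-%dT%H:%M:%SZ")
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# grades

def compute_grades(route: Route, smoothing_window: float = 30.0) -> Route:
    """Recompute step grades after moving-average elevation smoothing.

    The elevation of each point is replaced by the mean elevation of all
    points within ``smoothing_window / 2`` metres along-track (a centred
    window); grades are then the smoothed rise over run per step, clipped
    to +/-0.35.  ``smoothing_window == 0`` leaves elevations untouched.
    """
    if smoothing_window < 0:
        raise ValueError("smoothing_window must be >= 0")
    dist = route.cumulative_distance
    ele = route.elevations
    if smoothing_window > 0:
        half = smoothing_window / 2.0
        smooth = np.empty_like(ele)
        for k in range(len(ele)):
            lo = np.searchsorted(dist, dist[k] - half, side="left")
            hi = np.searchsorted(dist, dist[k] + half, side="right")
            smooth[k] = ele[lo:hi].mean()
        ele = smooth
    run = np.diff(dist)
    grade = np.clip(np.diff(ele) / run, -MAX_GRADE, MAX_GRADE)
    return replace(route, grade=grade)


# ---------------------------------------------------------------------------
# synthetic routes

def synthesize_route(
    spec: Sequence[tuple[float, float]],
    step: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    start_lat: float = 46.0,
    start_lon: float = 6.8,
    start_elevation: float = 400.0,
) -> Route:
    """Generate a piecewise-constant-grade route heading due north.

    ``spec`` is a list of (length_m, grade) legs; points are laid every
    ``step`` metres along a great circle, elevations follow the exact leg
    grades plus optional iid Gaussian noise of standard deviation
    ``noise_sd`` metres.  Deterministic for a fixed seed.
    """
    if not spec:
        raise ValueError("spec must contain at least one (length, grade) leg")
    for length, grade in spec:
        if length <= 0:
            raise ValueError("leg lengths must be > 0")
        if abs(grade) > MAX_GRADE:
            raise ValueError(f"|grade| {abs(grade)} exceeds {MAX_GRADE}")
    if step <= 0:
        raise ValueError("step must be > 0")
    rng = np.random.default_rng(seed)

    total = sum(length for length, _ in spec)
    n_steps = int(round(total / step))
    dists = np.arange(n_steps + 1) * step
    # true elevation profile from the leg spec
    edges = np.cumsum([0.0] + [length for length, _ in spec])
    grades = np.array([g for _, g in spec])
    elev = np.empty(n_steps + 1)
    elev[0] = start_elevation
    for k in range(1, n_steps + 1):
        d0, d1 = dists[k - 1], dists[k]
        leg = min(np.searchsorted(edges, d0, side="right") - 1, len(grades) - 1)
        elev[k] = elev[k - 1] + grades[leg] * (d1 - d0)
    if noise_sd > 0:
        elev = elev + rng.normal(0.0, noise_sd, size=elev.shape)

    dlat = np.degrees(dists / EARTH_RADIUS_M)
    points = [
        TrackPoint(latitude=start_lat + dlat[k], longitude=start_lon, elevation=float(elev[k]))
        for k in range(n_steps + 1)
    ]
    return Route(points=points)
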