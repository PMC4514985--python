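"""T-LoCoH utilization distributions for a single animal track.

The time-scaled local convex hull (T-LoCoH) method builds a small convex
polygon ("hull") around every GPS fix and its *k* nearest neighbours,
where nearness is measured with the time-scaled distance (TSD)

    TSD(a, b) = sqrt(dx^2 + dy^2 + (s * v_max * dt)^2)

so that fixes close in space but far apart in time are pushed apart.
``v_max`` is the maximum speed observed along the track, and ``s`` (the
time-scaling factor, dimensionless) controls how strongly time separates
points; ``s = 0`` recovers the purely spatial LoCoH method.

Hulls are sorted by ascending area — smallest hulls sit in the most
densely used places — and cumulatively unioned.  The isopleth (density
quantile) at level *q* is the smallest cumulative union enclosing at
least a fraction *q* of the fixes: the 25 % isopleth outlines the most
intensely used area, the 95 % isopleth the overall range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Fix",
    "Track",
    "LocohParams",
    "Hull",
    "Isopleth",
    "tsd_distance",
    "max_observed_speed",
    "knn_tsd",
    "build_hull",
    "occupancy_time",
    "build_isopleths",
    "fraction_time_selected",
    "edge_area_diagnostic",
    "utilization_distribution",
]

DEFAULT_QUANTILES = (0.25, 0.50, 0.75, 0.95)
#: Nominal surfacing interval between GPS fixes (seconds); the tags are
#: programmed for 15-min attempts but realized intervals average ~18 min.
NOMINAL_FIX_INTERVAL_S = 18 * 60.0


@dataclass(frozen=True)
class Fix:
    """A single timestamped, projected GPS location of one animal."""

    animal_id: str
    t: pd.Timestamp
    x: float
    y: float
    at_sea: bool = True

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")
        if pd.isna(self.t):
            raise ValueError("Fix timestamp is undefined")


def _as_utc(t) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(t))
    if idx.tz is None:
        return idx.tz_localize("UTC")
    return idx.tz_convert("UTC")


class Track:
    """An ordered sequence of fixes, stored column-wise.

    A track normally belongs to one animal; pooled multi-animal fix sets
    (used for collective coverage) are represented as a Track whose
    per-fix ``animal_ids`` differ.  Timestamps must be non-decreasing.
    """

    def __init__(self, animal_ids, t, x, y, at_sea=None):
        self.t = _as_utc(t)
        n = len(self.t)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if np.isscalar(animal_ids) or isinstance(animal_ids, str):
            animal_ids = [animal_ids] * n
        self.animal_ids = np.asarray(animal_ids, dtype=object)
        if at_sea is None:
            at_sea = np.ones(n, dtype=bool)
        self.at_sea = np.asarray(at_sea, dtype=bool)
        if not (len(self.x) == len(self.y) == len(self.animal_ids)
                == len(self.at_sea) == n):
            raise ValueError("Track columns have unequal lengths")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("Track contains non-finite coordinates")
        if n > 1 and (np.diff(self.t.asi8) < 0).any():
            raise ValueError("Track timestamps must be non-decreasing")
        # seconds since the unix epoch, as float (sub-ms precision is
        # preserved over any realistic deployment length)
        self.t_seconds = self.t.asi8 / 1e9
        # rank of each fix within its own animal's subsequence; used to
        # define per-animal visit runs on pooled tracks
        self._pos_in_animal = self._rank_within_animal()

    def _rank_within_animal(self) -> np.ndarray:
        pos = np.empty(len(self), dtype=np.int64)
        counters: dict = {}
        for i, a in enumerate(self.animal_ids):
            c = counters.get(a, 0)
            pos[i] = c
            counters[a] = c + 1
        return pos

    @classmethod
    def from_fixes(cls, fixes: Sequence[Fix]) -> "Track":
        fixes = list(fixes)
        return cls(
            [f.animal_id for f in fixes],
            [f.t for f in fixes],
            [f.x for f in fixes],
            [f.y for f in fixes],
            [f.at_sea for f in fixes],
        )

    @property
    def animal_id(self) -> str:
        ids = set(self.animal_ids)
        return self.animal_ids[0] if len(ids) == 1 else "pooled"

    def __len__(self) -> int:
        return len(self.x)

    def __getitem__(self, i: int) -> Fix:
        return Fix(
            animal_id=self.animal_ids[i],
            t=self.t[i],
            x=float(self.x[i]),
            y=float(self.y[i]),
            at_sea=bool(self.at_sea[i]),
        )

    def fixes(self) -> list[Fix]:
        return [self[i] for i in range(len(self))]

    def subset(self, idx) -> "Track":
        idx = np.asarray(idx)
        return Track(
            self.animal_ids[idx], self.t[idx], self.x[idx], self.y[idx],
            self.at_sea[idx],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Track {self.animal_id}: {len(self)} fixes>"


@dataclass(frozen=True)
class LocohParams:
    """Parameters of the T-LoCoH pipeline.

    k : number of nearest neighbours per hull (k-method).
    s : TSD time-scaling factor; 0 disables time (pure LoCoH).
    v_max : maximum observed speed (m/s); derived from the track when None.
    quantiles : density-quantile levels, strictly increasing, in (0, 1].
    nominal_fix_interval_s : surfacing interval used for single-fix
        occupancy runs (default 18 min).
    """

    k: int = 10
    s: float = 0.03
    v_max: float | None = None
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    nominal_fix_interval_s: float = NOMINAL_FIX_INTERVAL_S

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.s < 0:
            raise ValueError("s must be non-negative")
        q = np.asarray(self.quantiles, dtype=float)
        if len(q) == 0 or (np.diff(q) <= 0).any() or q[0] <= 0 or q[-1] > 1:
            raise ValueError("quantiles must be strictly increasing in (0, 1]")


@dataclass
class Hull:
    """A local convex hull around one parent fix and its k neighbours."""

    parent_idx: int
    member_idx: np.ndarray          # parent + neighbours, track indices
    geom: BaseGeometry              # convex polygon (degenerate: line/point)
    area_km2: float
    perimeter_km: float
    enclosed_idx: np.ndarray        # all track fixes inside or on boundary
    occupancy_h: float
    time_selected: bool
    track: Track = field(repr=False, default=None)

    @property
    def parent(self) -> Fix:
        return self.track[self.parent_idx]

    @property
    def members(self) -> list[Fix]:
        return [self.track[i] for i in self.member_idx]

    @property
    def n_enclosed(self) -> int:
        return int(len(self.enclosed_idx))

    @property
    def polygon(self) -> list[tuple[float, float]]:
        """Vertex list of the hull boundary (projected metres)."""
        g = self.geom
        if g.geom_type == "Polygon":
            return list(g.exterior.coords)
        return list(g.coords)


@dataclass(frozen=True)
class Isopleth:
    """Merged polygon for one density-quantile level."""

    level: float
    geom: BaseGeometry
    area_km2: float
    n_fixes: int


# ---------------------------------------------------------------------------
# distance and neighbour selection


def tsd_distance(a: Fix, b: Fix, s: float, v_max: float | None = None) -> float:
    """Time-scaled distance between two fixes, in metres.

    With ``s = 0`` (or equal timestamps) this is the planar Euclidean
    distance; otherwise the time separation contributes a third axis
    scaled by ``s * v_max``, the fraction of the maximum distance the
    animal could have covered in that interval.
    """
    for f in (a, b):
        if not (math.isfinite(f.x) and math.isfinite(f.y)):
            raise ValueError("non-finite coordinates")
    dx = a.x - b.x
    dy = a.y - b.y
    if s == 0:
        return math.hypot(dx, dy)
    if v_max is None or v_max <= 0:
        raise ValueError("v_max must be positive when s > 0")
    # nanosecond integers: exact and symmetric (Timedelta.total_seconds
    # floors at microsecond precision)
    dt = abs(pd.Timestamp(a.t).value - pd.Timestamp(b.t).value) / 1e9
    return math.sqrt(dx * dx + dy * dy + (s * v_max * dt) ** 2)


def max_observed_speed(track: Track) -> float:
    """Maximum speed over consecutive fix pairs (m/s).

    Pairs with zero time separation are skipped.  A track whose fixes all
    coincide returns 0.0 (degenerate but valid).
    """
    if len(track) < 2:
        raise ValueError("max_observed_speed needs at least 2 fixes")
    dt = np.diff(track.t_seconds)
    if (dt <= 0).all():
        raise ValueError("track has no pairs with distinct timestamps")
    d = np.hypot(np.diff(track.x), np.diff(track.y))
    ok = dt > 0
    return float(np.max(d[ok] / dt[ok]))


def _knn_indices(track: Track, k: int, s: float, v_max: float,
                 chunk: int = 256) -> np.ndarray:
    """(n, k) neighbour indices under TSD, spec tie-break, self excluded.

    Exact: full distance sort per focal with ties broken by (distance,
    timestamp, input order), so results are deterministic and match a
    brute-force oracle bit-for-bit.
    """
    n = len(track)
    if k >= n:
        raise ValueError(f"k={k} requires a track longer than {k} fixes")
    x, y, ts = track.x, track.y, track.t_seconds
    zt = (s * v_max) * ts if s > 0 else None
    idx_arr = np.arange(n)
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = (x[start:stop, None] - x[None, :]) ** 2 \
            + (y[start:stop, None] - y[None, :]) ** 2
        if zt is not None:
            d2 += (zt[start:stop, None] - zt[None, :]) ** 2
        for row, i in enumerate(range(start, stop)):
            d = d2[row]
            d[i] = np.inf  # exclude focal
            order = np.lexsort((idx_arr, ts, d))
            out[i] = order[:k]
    return out


def knn_tsd(track: Track, focal: Fix | int, params: LocohParams) -> list[Fix]:
    """The k fixes nearest to ``focal`` under the time-scaled distance.

    The focal fix itself is excluded.  Ties are broken by earlier
    timestamp, then input order, for determinism.
    """
    if isinstance(focal, Fix):
        matches = np.flatnonzero(
            (track.x == focal.x) & (track.y == focal.y)
            & (track.t == focal.t)
        )
        if len(matches) == 0:
            raise ValueError("focal fix is not part of the track")
        focal_i = int(matches[0])
    else:
        focal_i = int(focal)
    v_max = params.v_max
    if params.s > 0 and v_max is None:
        v_max = max_observed_speed(track)
    nn = _knn_indices(track, params.k, params.s, v_max or 0.0)
    return [track[j] for j in nn[focal_i]]


# ---------------------------------------------------------------------------
# hull construction


def _hull_geometry(xs: np.ndarray, ys: np.ndarray) -> BaseGeometry:
    """Minimum convex polygon of the points (may degenerate to a
    segment or point for collinear/duplicate inputs, e.g. haul-outs)."""
    return MultiPoint(np.column_stack([xs, ys])).convex_hull


def _enclosed(geom: BaseGeometry, points: np.ndarray) -> np.ndarray:
    """Indices of track points inside or on the boundary of ``geom``."""
    shapely.prepare(geom)
    return np.flatnonzero(shapely.covers(geom, points))


def _run_partition(enclosed_idx: np.ndarray, track: Track) -> list[np.ndarray]:
    """Split enclosed fixes into maximal per-animal visit runs.

    A run is a maximal set of enclosed fixes consecutive in the owning
    animal's own subsequence; on a single-animal track this is simply
    consecutiveness in track order.
    """
    runs: list[np.ndarray] = []
    for a in pd.unique(track.animal_ids[enclosed_idx]):
        sub = enclosed_idx[track.animal_ids[enclosed_idx] == a]
        pos = track._pos_in_animal[sub]
        breaks = np.flatnonzero(np.diff(pos) != 1) + 1
        runs.extend(np.split(sub, breaks))
    return runs


def occupancy_time(hull: Hull, track: Track,
                   nominal_fix_interval_s: float = NOMINAL_FIX_INTERVAL_S,
                   ) -> float:
    """Total time (hours) the hull polygon was occupied by the track.

    Enclosed fixes are partitioned into maximal visit runs; each run
    contributes its elapsed time (last minus first fix), and single-fix
    runs contribute one nominal surfacing interval so that a brief visit
    never counts as zero.
    """
    idx = np.asarray(hull.enclosed_idx if isinstance(hull, Hull) else hull)
    return occupancy_time_idx(idx, track, nominal_fix_interval_s)


def build_hull(focal: Fix | int, neighbours: Iterable[Fix | int],
               track: Track, params: LocohParams,
               time_selected: bool = False) -> Hull:
    """Construct the local hull of ``focal`` and its neighbours.

    Degenerate member sets (collinear or duplicated points, common while
    hauled out) yield zero-area hulls that are retained: they mark
    maximal point density.
    """
    def _to_index(f) -> int:
        if isinstance(f, Fix):
            m = np.flatnonzero((track.x == f.x) & (track.y == f.y)
                               & (track.t == f.t))
            if len(m) == 0:
                raise ValueError("fix is not part of the track")
            return int(m[0])
        return int(f)

    focal_i = _to_index(focal)
    nb = [_to_index(f) for f in neighbours]
    if not nb:
        raise ValueError("neighbour set must be non-empty")
    members = np.unique(np.r_[focal_i, nb])
    geom = _hull_geometry(track.x[members], track.y[members])
    pts = shapely.points(track.x, track.y)
    enclosed = _enclosed(geom, pts)
    occ = occupancy_time_idx(enclosed, track, params.nominal_fix_interval_s)
    return Hull(
        parent_idx=focal_i,
        member_idx=members,
        geom=geom,
        area_km2=geom.area / 1e6,
        perimeter_km=geom.length / 1e3,
        enclosed_idx=enclosed,
        occupancy_h=occ,
        time_selected=time_selected,
        track=track,
    )


def occupancy_time_idx(enclosed_idx: np.ndarray, track: Track,
                       nominal_fix_interval_s: float = NOMINAL_FIX_INTERVAL_S,
                       ) -> float:
    """``occupancy_time`` on a raw index array instead of a Hull."""
    enclosed_idx = np.asarray(enclosed_idx)
    if len(enclosed_idx) == 0:
        raise ValueError("occupancy requires at least one enclosed fix")
    total_s = 0.0
    for run in _run_partition(enclosed_idx, track):
        if len(run) == 1:
            total_s += nominal_fix_interval_s
        else:
            total_s += track.t_seconds[run[-1]] - track.t_seconds[run[0]]
    return total_s / 3600.0


def _build_all_hulls(track: Track, params: LocohParams) -> list[Hull]:
    """One hull per fix, with time-selection flags resolved against the
    purely spatial (s=0) neighbour sets."""
    n = len(track)
    v_max = params.v_max
    if params.s > 0 and v_max is None:
        v_max = max_observed_speed(track)
    nn = _knn_indices(track, params.k, params.s, v_max or 0.0)
    if params.s > 0:
        nn0 = _knn_indices(track, params.k, 0.0, 0.0)
    else:
        nn0 = nn
    pts = shapely.points(track.x, track.y)
    hulls = []
    for i in range(n):
        members = np.unique(np.r_[i, nn[i]])
        geom = _hull_geometry(track.x[members], track.y[members])
        enclosed = _enclosed(geom, pts)
        occ = occupancy_time_idx(enclosed, track,
                                 params.nominal_fix_interval_s)
        tsel = set(nn[i]) != set(nn0[i])
        hulls.append(Hull(
            parent_idx=i, member_idx=members, geom=geom,
            area_km2=geom.area / 1e6, perimeter_km=geom.length / 1e3,
            enclosed_idx=enclosed, occupancy_h=occ,
            time_selected=bool(tsel), track=track,
        ))
    return hulls


def fraction_time_selected(track: Track, params: LocohParams) -> float:
    """Fraction of hulls whose TSD neighbour set differs from the s=0 set.

    Used to pick ``s``: the study design targets ~60 % of hulls being
    time-selected.  Identically 0 when ``s = 0``.
    """
    if params.s == 0:
        return 0.0
    v_max = params.v_max if params.v_max is not None \
        else max_observed_speed(track)
    nn = _knn_indices(track, params.k, params.s, v_max)
    nn0 = _knn_indices(track, params.k, 0.0, 0.0)
    diff = [set(nn[i]) != set(nn0[i]) for i in range(len(track))]
    return float(np.mean(diff))


# ---------------------------------------------------------------------------
# isopleths


def _sorted_hulls(hulls: Sequence[Hull]) -> list[Hull]:
    # ascending area; ties (typically degenerate zero-area duplicates)
    # broken by parent timestamp for determinism
    return sorted(hulls,
                  key=lambda h: (h.area_km2,
                                 h.track.t_seconds[h.parent_idx]
                                 if h.track is not None else h.parent_idx))


def build_isopleths(hulls: Sequence[Hull], n_total: int,
                    quantiles: Sequence[float] = DEFAULT_QUANTILES,
                    ) -> list[Isopleth]:
    """Merge sorted hulls into density-quantile isopleths.

    Hulls are sorted by ascending area and cumulatively unioned; the
    isopleth at level *q* is the smallest prefix union enclosing at least
    ``ceil(q * n_total)`` distinct fixes.  Isopleths are nested and their
    areas non-decreasing in *q* by construction.
    """
    hulls = list(hulls)
    if not hulls:
        raise ValueError("build_isopleths requires at least one hull")
    q = np.asarray(quantiles, dtype=float)
    if (np.diff(q) <= 0).any():
        raise ValueError("quantiles must be strictly increasing")
    ordered = _sorted_hulls(hulls)
    covered = np.zeros(n_total, dtype=bool)
    cum_counts = np.empty(len(ordered), dtype=np.int64)
    for j, h in enumerate(ordered):
        covered[h.enclosed_idx] = True
        cum_counts[j] = covered.sum()
    out = []
    for level in q:
        need = int(math.ceil(level * n_total - 1e-9))
        j = int(np.searchsorted(cum_counts, need, side="left"))
        if j >= len(ordered):  # unreachable: every fix is in its own hull
            j = len(ordered) - 1
        geom = shapely.union_all([h.geom for h in ordered[: j + 1]])
        out.append(Isopleth(
            level=float(level), geom=geom, area_km2=geom.area / 1e6,
            n_fixes=int(cum_counts[j]),
        ))
    return out


def utilization_distribution(track: Track, params: LocohParams,
                             ) -> tuple[list[Hull], list[Isopleth]]:
    """Full T-LoCoH pipeline: hulls plus density-quantile isopleths."""
    if len(track) <= params.k:
        raise ValueError(
            f"track has {len(track)} fixes; needs more than k={params.k}")
    hulls = _build_all_hulls(track, params)
    isopleths = build_isopleths(hulls, len(track), params.quantiles)
    return hulls, isopleths


def edge_area_diagnostic(track: Track, k_values: Sequence[int],
                         s: float = 0.0,
                         quantiles: Sequence[float] = DEFAULT_QUANTILES,
                         ) -> pd.DataFrame:
    """Area-by-quantile and perimeter:area (edge:area) across a k grid.

    Used to check that the chosen k does not produce a sudden jump in
    area.  Returns one row per (k, level) with the isopleth area (km²),
    perimeter (km) and their edge:area ratio (1/km).
    """
    rows = []
    for k in k_values:
        params = LocohParams(k=int(k), s=s, quantiles=tuple(quantiles))
        _, isos = utilization_distribution(track, params)
        for iso in isos:
            per_km = iso.geom.length / 1e3
            rows.append({
                "k": int(k),
                "level": iso.level,
                "area_km2": iso.area_km2,
                "perimeter_km": per_km,
                "edge_area_ratio": per_km / iso.area_km2
                if iso.area_km2 > 0 else np.inf,
            })
    return pd.DataFrame(rows)
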