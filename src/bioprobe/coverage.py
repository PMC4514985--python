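"""Collective multi-animal sampling coverage, stratified by month.

Fixes from all instrumented animals are pooled and grouped by UTC
calendar month.  Collective isopleths use a conservative, purely spatial
neighbour rule (k = 5, no time scaling): nearby fixes from different
animals may legitimately share a hull, but without time in the metric a
small k keeps the hulls tight to the observed locations.  Per month the
module reports area by density quantile, time-at-sea (the number of
at-sea GPS fixes inside each quantile), and the expected area under an
equal-use null.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import shapely

from .locoh import (
    DEFAULT_QUANTILES,
    Hull,
    Isopleth,
    LocohParams,
    Track,
    utilization_distribution,
)

__all__ = [
    "PooledFixSet",
    "MonthlySummary",
    "pool_and_stratify",
    "collective_isopleths",
    "time_at_sea",
    "equal_use_expectation",
    "monthly_summaries",
]

COLLECTIVE_K = 5


@dataclass
class PooledFixSet:
    """All animals' fixes falling in one UTC calendar month."""

    month: pd.Period
    track: Track  # pooled multi-animal track, time-sorted

    def __len__(self) -> int:
        return len(self.track)


@dataclass
class MonthlySummary:
    """Per-month coverage metrics, one value per quantile level."""

    month: pd.Period
    area_km2: dict[float, float]
    n_fixes: dict[float, int]            # time-at-sea proxy
    expected_area_km2: dict[float, float]

    def to_frame(self) -> pd.DataFrame:
        levels = sorted(self.area_km2)
        return pd.DataFrame({
            "month": str(self.month),
            "level": levels,
            "area_km2": [self.area_km2[q] for q in levels],
            "n_fixes": [self.n_fixes[q] for q in levels],
            "expected_area_km2": [self.expected_area_km2[q] for q in levels],
        })


def pool_and_stratify(tracks: list[Track]) -> list[PooledFixSet]:
    """Pool fixes from all tracks and group them by UTC calendar month.

    Animal identity is retained on every fix.  Within a month, fixes are
    sorted by time (ties by animal id) so the pooled set is itself a
    valid Track.  A fix at 23:59 on the last day of a month belongs to
    that month.
    """
    if not tracks:
        raise ValueError("pool_and_stratify requires at least one track")
    frames = [
        pd.DataFrame({
            "animal_id": tr.animal_ids, "t": tr.t, "x": tr.x, "y": tr.y,
            "at_sea": tr.at_sea,
        })
        for tr in tracks
    ]
    df = pd.concat(frames, ignore_index=True)
    # months are assigned in UTC; drop the tz before Period conversion
    df["month"] = df["t"].dt.tz_convert("UTC").dt.tz_localize(None) \
        .dt.to_period("M")
    out = []
    for month, grp in df.groupby("month", sort=True):
        grp = grp.sort_values(["t", "animal_id"], kind="stable")
        out.append(PooledFixSet(
            month=month,
            track=Track(grp["animal_id"].to_numpy(), grp["t"],
                        grp["x"].to_numpy(), grp["y"].to_numpy(),
                        grp["at_sea"].to_numpy()),
        ))
    return out


def collective_isopleths(pool: PooledFixSet | Track,
                         k: int = COLLECTIVE_K,
                         quantiles=DEFAULT_QUANTILES,
                         ) -> tuple[list[Hull], list[Isopleth]]:
    """Collective utilization distribution of a pooled fix set.

    Runs the standard hull pipeline on the pooled fixes with ``s = 0``
    (no time scaling): hulls may mix fixes from different animals, and
    each hull's occupancy time sums the visit runs of every contributing
    animal.  For a pool drawn from a single animal this reduces exactly
    to the individual pipeline at the same parameters.
    """
    track = pool.track if isinstance(pool, PooledFixSet) else pool
    if len(track) <= k:
        raise ValueError(
            f"pooled set has {len(track)} fixes; needs more than k={k}")
    params = LocohParams(k=k, s=0.0, quantiles=tuple(quantiles))
    return utilization_distribution(track, params)


def time_at_sea(pool: PooledFixSet | Track,
                isopleths: list[Isopleth]) -> dict[float, int]:
    """Number of at-sea fixes inside each isopleth (boundary inclusive).

    The fix count is the study's time-at-sea proxy: fixes arrive roughly
    every 18 min while the animal is in the water.
    """
    track = pool.track if isinstance(pool, PooledFixSet) else pool
    pts = shapely.points(track.x[track.at_sea], track.y[track.at_sea])
    out = {}
    for iso in isopleths:
        shapely.prepare(iso.geom)
        out[iso.level] = int(shapely.covers(iso.geom, pts).sum())
    return out


def equal_use_expectation(isopleths: list[Isopleth]) -> dict[float, float]:
    """Expected area per level if all areas were used equally.

    Normalized to the 95 % level (the overall-range reference):
    ``expected(q) = (q / 0.95) * area(0.95)``.
    """
    ref = next((iso for iso in isopleths if abs(iso.level - 0.95) < 1e-9),
               None)
    if ref is None:
        raise ValueError("equal-use expectation requires the 0.95 level")
    return {iso.level: (iso.level / 0.95) * ref.area_km2
            for iso in isopleths}


def monthly_summaries(tracks: list[Track], k: int = COLLECTIVE_K,
                      quantiles=DEFAULT_QUANTILES,
                      min_fixes: int | None = None,
                      ) -> tuple[list[MonthlySummary], dict]:
    """Pool, stratify and summarize collective coverage per month.

    Months with too few fixes to build hulls (fewer than ``k + 1``, or
    ``min_fixes`` if given) are skipped.  Returns the summaries plus a
    dict of each month's (hulls, isopleths) for export.
    """
    floor = max(k + 1, min_fixes or 0)
    summaries, detail = [], {}
    for pool in pool_and_stratify(tracks):
        if len(pool) < floor:
            continue
        hulls, isos = collective_isopleths(pool, k=k, quantiles=quantiles)
        tas = time_at_sea(pool, isos)
        summaries.append(MonthlySummary(
            month=pool.month,
            area_km2={iso.level: iso.area_km2 for iso in isos},
            n_fixes=tas,
            expected_area_km2=equal_use_expectation(isos),
        ))
        detail[pool.month] = (hulls, isos)
    return summaries, detail
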