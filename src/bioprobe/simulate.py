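"""Synthetic seal tracks and acoustic ping logs.

The generator emulates the statistical structure of the study system so
every pipeline stage can be exercised without field data:

* **Movement** — a central-place forager alternating haul-outs on an
  island colony with offshore foraging trips.  Each trip transits to a
  weighted hotspot, dwells there (a correlated wander inside the hotspot
  radius), and returns.  Dwell durations are chosen so that each
  hotspot's share of at-sea time matches its configured weight.
* **GPS sampling** — surfacing-driven fixes whose inter-fix intervals
  follow a gamma distribution matched to the observed mean 17.92 min and
  sd 3.92 min; during haul-outs longer than 12 h the tag dries out and
  emits roughly one fix per 8 days.
* **Acoustics** — moored 69 kHz transmitters emit 8-ping coded
  transmissions every 40–60 s with inter-ping intervals of 0.30–0.70 s.
  A ping is received iff the seal (linearly interpolated between fixes)
  is within the detection range drawn for that transmission (482.4 m in
  the roughest to 750.4 m in the calmest conditions) and survives an
  independent per-ping loss draw.  Background noise pings arrive as a
  Poisson stream, and the receiver clock drifts linearly.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locoh import Track

__all__ = [
    "Hotspot",
    "Transmitter",
    "SimConfig",
    "sample_surfacing_intervals",
    "simulate_track",
    "simulate_ping_log",
    "ground_truth",
    "simulate_acoustics",
]

_EPOCH = pd.Timestamp("1970-01-01", tz="UTC")


@dataclass(frozen=True)
class Hotspot:
    """An offshore foraging patch: centre (m), radius (m) and the target
    fraction of at-sea time spent inside it."""

    x: float
    y: float
    radius_m: float
    weight: float


@dataclass(frozen=True)
class Transmitter:
    """A moored acoustic transmitter at a fixed projected position."""

    tx_id: str
    x: float
    y: float


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults encode the instrumented-grey-seal system: surfacing-driven
    GPS fixes (gamma intervals, mean 17.92 / sd 3.92 min), haul-out
    fixes every 8 days when hauled out > 12 h, 8-ping transmissions
    every 40–60 s, detection range 482.4–750.4 m.  Coordinates are
    projected metres (UTM zone 20N plane by default).
    """

    seed: int = 0
    n_animals: int = 3
    duration_days: float = 14.0
    start: str = "2011-06-15T00:00:00Z"
    colony_xy: tuple[float, float] = (400_000.0, 4_830_000.0)
    colony_scatter_m: float = 400.0
    surfacing_interval_mean_min: float = 17.92
    surfacing_interval_sd_min: float = 3.92
    haulout_fix_period_days: float = 8.0
    haulout_min_duration_h: float = 12.0
    haulout_duration_range_h: tuple[float, float] = (14.0, 40.0)
    hotspots: tuple[Hotspot, ...] = (
        Hotspot(430_000.0, 4_858_000.0, 3_000.0, 0.35),
        Hotspot(378_000.0, 4_864_000.0, 4_000.0, 0.25),
    )
    travel_speed_mps: float = 1.4
    heading_sd_rad: float = 0.25
    gps_noise_m: float = 15.0
    transmitters: tuple[Transmitter, ...] = ()
    transmission_period_s: tuple[float, float] = (40.0, 60.0)
    ping_count_per_transmission: int = 8
    inter_ping_interval_s: tuple[float, float] = (0.30, 0.70)
    detection_range_m: tuple[float, float] = (482.4, 750.4)
    per_ping_loss: float = 0.1
    noise_ping_rate_hz: float = 0.0
    clock_drift_s_per_day: float = 0.2

    def __post_init__(self):
        if self.surfacing_interval_mean_min <= 0 \
                or self.surfacing_interval_sd_min <= 0:
            raise ValueError("surfacing interval moments must be positive")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        w = sum(h.weight for h in self.hotspots)
        if self.hotspots and not 0 < w < 1:
            raise ValueError("hotspot weights must sum into (0, 1)")

    @property
    def start_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.start).tz_convert("UTC") \
            if pd.Timestamp(self.start).tzinfo \
            else pd.Timestamp(self.start, tz="UTC")


def _rng(cfg: SimConfig, *scope) -> np.random.Generator:
    """Independent, reproducible stream per (seed, scope) pair."""
    tags = [zlib.crc32(str(s).encode()) for s in scope]
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, *tags])


def sample_surfacing_intervals(cfg: SimConfig, n: int,
                               rng: np.random.Generator | None = None,
                               ) -> np.ndarray:
    """Draw n inter-fix surfacing intervals (minutes).

    Gamma-distributed with shape/scale matched to the configured mean
    and sd; the gamma keeps support positive while matching both
    moments.
    """
    if rng is None:
        rng = _rng(cfg, "surfacing")
    m = cfg.surfacing_interval_mean_min
    sd = cfg.surfacing_interval_sd_min
    shape = (m / sd) ** 2
    scale = sd * sd / m
    return rng.gamma(shape, scale, size=n)


# ---------------------------------------------------------------------------
# movement


def _build_schedule(cfg: SimConfig, rng: np.random.Generator):
    """Piecewise-linear waypoint schedule (t_s, x, y, at_sea) covering the
    deployment.  Haul-outs sit at the colony; trips transit to a hotspot
    with heading noise, wander inside it, and return."""
    total_s = cfg.duration_days * 86400.0
    cx, cy = cfg.colony_xy
    W = sum(h.weight for h in cfg.hotspots)
    weights = np.array([h.weight for h in cfg.hotspots], dtype=float)
    probs = weights / weights.sum() if len(weights) else None

    t = 0.0
    wps = [(0.0, cx, cy, False)]
    hauled = [True]

    def _haulout():
        nonlocal t
        lo, hi = cfg.haulout_duration_range_h
        dur = rng.uniform(lo, hi) * 3600.0
        t += dur
        wps.append((t, cx, cy, False))
        hauled.append(True)

    def _transit(x0, y0, x1, y1):
        """Correlated walk toward the target; returns realized duration."""
        nonlocal t
        start_t = t
        x, y = x0, y0
        step_s = 1200.0
        while np.hypot(x1 - x, y1 - y) > cfg.travel_speed_mps * step_s:
            bearing = np.arctan2(y1 - y, x1 - x) \
                + rng.normal(0.0, cfg.heading_sd_rad)
            x += cfg.travel_speed_mps * step_s * np.cos(bearing)
            y += cfg.travel_speed_mps * step_s * np.sin(bearing)
            t += step_s
            wps.append((t, x, y, True))
            hauled.append(False)
        d = np.hypot(x1 - x, y1 - y)
        t += d / cfg.travel_speed_mps
        wps.append((t, x1, y1, True))
        hauled.append(False)
        return t - start_t

    def _dwell(h: Hotspot, dur_s: float):
        nonlocal t
        end = t + dur_s
        x, y = wps[-1][1], wps[-1][2]
        while t < end:
            # next wander waypoint inside the patch (uniform over disc)
            r = h.radius_m * 0.9 * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            nx, ny = h.x + r * np.cos(th), h.y + r * np.sin(th)
            seg = min(1800.0, end - t)
            t += seg
            wps.append((t, nx, ny, True))
            hauled.append(False)
            x, y = nx, ny

    while t < total_s:
        _haulout()
        if t >= total_s or not cfg.hotspots:
            continue
        h = cfg.hotspots[int(rng.choice(len(cfg.hotspots), p=probs))]
        out_s = _transit(cx, cy, h.x, h.y)
        # dwell so that hotspot time / at-sea time matches the summed
        # weight W (transit shares the remaining 1 - W); the tail of the
        # transit already inside the patch radius counts toward the
        # inside share, so it is deducted from the dwell budget
        edge_s = 2.0 * h.radius_m / cfg.travel_speed_mps
        transit_s = 2.0 * out_s
        dwell_s = max(
            W / (1.0 - W) * (transit_s - edge_s) - edge_s, 600.0)
        _dwell(h, dwell_s)
        _transit(wps[-1][1], wps[-1][2], cx, cy)

    arr = np.array([(w[0], w[1], w[2]) for w in wps])
    return arr[:, 0], arr[:, 1], arr[:, 2], np.array(hauled, dtype=bool)


def _position_at(ts, xs, ys, query_s):
    return np.interp(query_s, ts, xs), np.interp(query_s, ts, ys)


def simulate_track(cfg: SimConfig, animal_id: str) -> Track:
    """Simulate one animal's GPS track.

    At sea, fix times follow the configured gamma surfacing intervals;
    during haul-outs longer than the 12-h threshold the tag emits one
    fix per 8 days (short haul-outs emit a single fix at entry).  Fix
    positions are the schedule position plus isotropic GPS noise.
    """
    rng = _rng(cfg, "track", animal_id)
    wt, wx, wy, hauled = _build_schedule(cfg, rng)
    total_s = cfg.duration_days * 86400.0

    # haul-out episodes: consecutive waypoints flagged hauled at colony
    episodes = []  # (t_start, t_end)
    i = 0
    while i < len(wt):
        if hauled[i]:
            j = i
            while j + 1 < len(wt) and hauled[j + 1]:
                j += 1
            episodes.append((wt[i - 1] if i > 0 else 0.0, wt[j]))
            i = j + 1
        else:
            i += 1

    fix_times: list[float] = []
    at_sea_flags: list[bool] = []
    cursor = 0.0
    ep_idx = 0
    eps = [(s, e) for s, e in episodes if e > s]
    while cursor < total_s:
        inside = next(((s, e) for s, e in eps if s <= cursor < e), None)
        if inside is not None:
            s, e = inside
            dur_h = (e - s) / 3600.0
            fix_times.append(cursor)
            at_sea_flags.append(False)
            if dur_h > cfg.haulout_min_duration_h:
                period = cfg.haulout_fix_period_days * 86400.0
                nxt = cursor + period
                while nxt < e:
                    fix_times.append(nxt)
                    at_sea_flags.append(False)
                    nxt += period
            cursor = e + 1.0
        else:
            fix_times.append(cursor)
            at_sea_flags.append(True)
            cursor += sample_surfacing_intervals(cfg, 1, rng)[0] * 60.0

    ft = np.array(fix_times)
    keep = ft <= total_s
    ft = ft[keep]
    flags = np.array(at_sea_flags, dtype=bool)[keep]
    fx, fy = _position_at(wt, wx, wy, ft)
    fx = fx + rng.normal(0, cfg.gps_noise_m, len(ft))
    fy = fy + rng.normal(0, cfg.gps_noise_m, len(ft))
    # hauled-out fixes scatter on the island, not at one exact point
    n_h = int((~flags).sum())
    fx[~flags] += rng.normal(0, cfg.colony_scatter_m, n_h)
    fy[~flags] += rng.normal(0, cfg.colony_scatter_m, n_h)

    t_abs = cfg.start_ts + pd.to_timedelta(ft, unit="s")
    return Track(animal_id, t_abs, fx, fy, flags)


# ---------------------------------------------------------------------------
# acoustics


@dataclass
class AcousticSim:
    """Received ping log plus emission-level ground truth."""

    pings: pd.DataFrame   # receiver_id, t (drifted clock), source, tx_id
    truth: pd.DataFrame   # one row per emitted transmission
    drift_rate: float


def simulate_acoustics(cfg: SimConfig, track: Track) -> AcousticSim:
    """Simulate reception of transmitter pings (plus noise) by a seal.

    Reception: hard range cutoff (range drawn per transmission between
    the configured rough/calm bounds) with independent per-ping loss.
    Receiver timestamps include the configured linear clock drift.
    """
    rng = _rng(cfg, "acoustics", track.animal_id)
    t0_s = track.t_seconds[0]
    t1_s = track.t_seconds[-1]
    rate = cfg.clock_drift_s_per_day / 86400.0

    truth_rows = []
    recv_times: list[float] = []
    recv_src: list[str] = []
    recv_tx: list[str] = []
    lo_p, hi_p = cfg.transmission_period_s
    lo_i, hi_i = cfg.inter_ping_interval_s
    lo_r, hi_r = cfg.detection_range_m
    n_ping = cfg.ping_count_per_transmission

    for tx in cfg.transmitters:
        t = t0_s + rng.uniform(lo_p, hi_p)
        while t < t1_s:
            sx, sy = _position_at(track.t_seconds, track.x, track.y, t)
            dist = float(np.hypot(tx.x - sx, tx.y - sy))
            rng_m = rng.uniform(lo_r, hi_r)
            offsets = np.concatenate(
                [[0.0], np.cumsum(rng.uniform(lo_i, hi_i, n_ping - 1))])
            n_recv = 0
            if dist <= rng_m:
                kept = rng.uniform(size=n_ping) >= cfg.per_ping_loss
                n_recv = int(kept.sum())
                for off in offsets[kept]:
                    recv_times.append(t + off)
                    recv_src.append("transmitter")
                    recv_tx.append(tx.tx_id)
            truth_rows.append({
                "tx_id": tx.tx_id, "t_emit_s": t, "in_range": dist <= rng_m,
                "dist_m": dist, "n_pings_received": n_recv,
                "complete": n_recv == n_ping,
                "seal_x": sx, "seal_y": sy,
            })
            t += rng.uniform(lo_p, hi_p)

    if cfg.noise_ping_rate_hz > 0:
        n_noise = rng.poisson(cfg.noise_ping_rate_hz * (t1_s - t0_s))
        for tn in np.sort(rng.uniform(t0_s, t1_s, n_noise)):
            recv_times.append(float(tn))
            recv_src.append("noise")
            recv_tx.append("")

    order = np.argsort(recv_times, kind="stable")
    times = np.array(recv_times)[order] if recv_times else np.array([])
    # receiver clock runs fast/slow: raw = true + rate * elapsed
    raw = times + rate * (times - t0_s)
    pings = pd.DataFrame({
        "receiver_id": track.animal_id,
        "t": pd.to_datetime(raw, unit="s", utc=True) if len(raw) else
        pd.DatetimeIndex([], tz="UTC"),
        "t_true_s": times,
        "source": np.array(recv_src, dtype=object)[order] if recv_times
        else np.array([], dtype=object),
        "tx_id": np.array(recv_tx, dtype=object)[order] if recv_times
        else np.array([], dtype=object),
    })
    truth = pd.DataFrame(truth_rows)
    if len(truth):
        truth["t_emit"] = pd.to_datetime(truth.pop("t_emit_s"), unit="s",
                                         utc=True)
    return AcousticSim(pings=pings, truth=truth, drift_rate=rate)


def simulate_ping_log(cfg: SimConfig, track: Track) -> pd.DataFrame:
    """Received ping log (drift-affected receiver timestamps)."""
    return simulate_acoustics(cfg, track).pings


def ground_truth(cfg: SimConfig, track: Track) -> pd.DataFrame:
    """Emission-level truth table for end-to-end scoring.

    Re-runs the deterministic reception simulation for the same config
    and track, so truth rows correspond exactly to the ping log."""
    return simulate_acoustics(cfg, track).truth
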