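"""Threshold-based dive and take-off detection from tri-axial accelerometry.

A plunge into water shows up on the surge (X) axis as a negative running
mean (the bird pitches head-down) combined with a burst of variance from
impact and submerged motion; the subsequent take-off from the surface is a
burst of heave (Z) variance from heavy flapping.  Detection therefore runs
on per-sample running means and SDs over short windows:

* dive start: running mean X < 0 g and running SD X > 1.4 g;
* dive end: the 1-s-lagged extremum of pitch change within 60 s of the
  start (surfacing flips body pitch sharply);
* take-off: begins after the dive where running SD Z > 1.8 g and SD X >
  1.0 g, and has ended once SD Z < 1.4 g and SD X < 1.4 g.

Dives shorter than 5 s are plunge dives (immediate surfacing); longer ones
are pursuit dives (underwater chase).  Detected dives can be validated
against trigger-gated depth-recorder traces by one-to-one start matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from morus.config import ClassifierParams
from morus.io import AccelTrace, DepthTrace


# ---------------------------------------------------------------------------
# running statistics and pitch
# ---------------------------------------------------------------------------

@dataclass
class RunningStats:
    """Centred running mean/SD per axis, computed within segments only.

    At segment edges the largest available symmetric window is used, so
    windows never span logger dropouts.  ``usable`` marks samples from
    segments long enough to carry at least a 2-sample window.
    """

    mean_x: np.ndarray
    mean_y: np.ndarray
    mean_z: np.ndarray
    sd_x: np.ndarray
    sd_y: np.ndarray
    sd_z: np.ndarray
    usable: np.ndarray


def _running_mean_sd(x: np.ndarray, half: int,
                     bounds: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    mean = np.empty_like(x)
    sd = np.empty_like(x)
    for s, e in bounds:
        xs = x[s:e]
        m = len(xs)
        idx = np.arange(m)
        h = np.minimum(half, np.minimum(idx, m - 1 - idx))
        lo, hi = idx - h, idx + h + 1
        c1 = np.concatenate([[0.0], np.cumsum(xs)])
        c2 = np.concatenate([[0.0], np.cumsum(xs * xs)])
        cnt = hi - lo
        mu = (c1[hi] - c1[lo]) / cnt
        var = np.maximum((c2[hi] - c2[lo]) / cnt - mu * mu, 0.0)
        mean[s:e] = mu
        sd[s:e] = np.sqrt(var)
    return mean, sd


def running_stats(trace: AccelTrace, window_s: float | None = None,
                  params: ClassifierParams | None = None) -> RunningStats:
    """Per-sample centred running mean and SD of each axis.

    SDs are population SDs over the window.  Segments shorter than the
    window are flagged unusable rather than silently smoothed.
    """
    params = params or ClassifierParams()
    window_s = window_s if window_s is not None else params.mean_window_s
    half = max(1, int(round(window_s * trace.rate_hz / 2)))
    win_samples = 2 * half + 1
    bounds = trace.segment_bounds()
    out = {}
    for axis in ("x", "y", "z"):
        arr = getattr(trace, f"a{axis}")
        out[f"mean_{axis}"], out[f"sd_{axis}"] = _running_mean_sd(arr, half, bounds)
    usable = np.ones(len(trace), dtype=bool)
    for s, e in bounds:
        usable[s:e] = (e - s) >= win_samples
    return RunningStats(usable=usable, **out)


def compute_pitch(trace: AccelTrace, params: ClassifierParams | None = None,
                  stats: RunningStats | None = None) -> np.ndarray:
    """Per-sample body pitch (degrees) from the static acceleration vector.

    Pitch is the surge-axis inclination, arcsin of the normalised static X
    component: 0 deg when level (static = (0,0,1)), +90 deg head-up.  A
    zero-magnitude static vector leaves pitch undefined at that sample; the
    previous value is carried forward.
    """
    params = params or ClassifierParams()
    if stats is None:
        stats = running_stats(trace, params.mean_window_s, params)
    norm = np.sqrt(stats.mean_x ** 2 + stats.mean_y ** 2 + stats.mean_z ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(norm > 0, stats.mean_x / np.where(norm > 0, norm, 1.0),
                         np.nan)
    pitch = np.degrees(np.arcsin(np.clip(ratio, -1.0, 1.0)))
    # carry forward over undefined samples; leading undefined -> 0
    if np.isnan(pitch).any():
        idx = np.arange(len(pitch))
        good = ~np.isnan(pitch)
        if not good.any():
            return np.zeros_like(pitch)
        fill = np.maximum.accumulate(np.where(good, idx, -1))
        pitch = np.where(fill >= 0, pitch[np.maximum(fill, 0)], 0.0)
    return pitch


def _pitch_change(pitch: np.ndarray, trace: AccelTrace,
                  spacing_s: float) -> np.ndarray:
    """|pitch(t) - pitch(t - spacing)|, zero within the leading margin and
    across segment boundaries."""
    lag = max(1, int(round(spacing_s * trace.rate_hz)))
    dp = np.zeros_like(pitch)
    for s, e in trace.segment_bounds():
        if e - s > lag:
            dp[s + lag:e] = pitch[s + lag:e] - pitch[s:e - lag]
    return np.abs(dp)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass
class BehaviourEvent:
    """A labelled interval: a dive or the take-off linked to it."""

    bird_id: str
    kind: str  # "dive" | "takeoff"
    start_s: float
    end_s: float
    dive_type: str = "n/a"  # "plunge" | "pursuit" | "n/a"
    event_id: int = -1
    linked_id: int = -1
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.kind == "takeoff" and self.dive_type != "n/a":
            raise ValueError("take-offs carry no dive type")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def classify_dive_type(duration_s: float,
                       params: ClassifierParams | None = None) -> str:
    """Plunge if shorter than the 5 s split, else pursuit (boundary ->
    pursuit by convention)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    split = (params or ClassifierParams()).dive_type_split_s
    return "plunge" if duration_s < split else "pursuit"


def _dive_end_index(dp: np.ndarray, start: int, seg_end: int,
                    trace: AccelTrace, params: ClassifierParams) -> tuple[int, bool]:
    """End index for a dive opened at ``start``; True flag if no extremum."""
    rate = trace.rate_hz
    lag = max(1, int(round(params.dive_end_lag_s * rate)))
    horizon = min(seg_end, start + 1 + int(round(params.dive_end_search_s * rate)))
    window = dp[start + 1:horizon]
    if len(window) == 0 or not np.any(window > 0):
        return min(horizon, seg_end) - 1, True
    if params.dive_end_mode == "series":
        # max of the lag-shifted series: arg over j of dp[j - lag]
        shifted_lo = max(start + 1 - lag, 0)
        window = dp[shifted_lo:horizon - lag]
        if len(window) == 0:
            return min(horizon, seg_end) - 1, True
        j = shifted_lo + int(np.argmax(window)) + lag
        return min(j, seg_end - 1), False
    j = start + 1 + int(np.argmax(window))
    return min(j + lag, seg_end - 1), False


def detect_dives(trace: AccelTrace, params: ClassifierParams | None = None,
                 stats: RunningStats | None = None) -> list[BehaviourEvent]:
    """Detect dives; see module docstring for the threshold logic.

    A refractory rule suppresses new dive starts until the previous dive's
    take-off has ended (or its search horizon lapsed), so one plunge is
    never double-counted.
    """
    params = params or ClassifierParams()
    if stats is None:
        stats = running_stats(trace, params.mean_window_s, params)
    pitch = compute_pitch(trace, params, stats)
    dp = _pitch_change(pitch, trace, params.pitch_delta_spacing_s)
    dive_cand = (stats.usable & (stats.mean_x < params.dive_mean_x_max)
                 & (stats.sd_x > params.dive_sd_x_min))
    dives: list[BehaviourEvent] = []
    bounds = trace.segment_bounds()
    for s, e in bounds:
        cursor = s
        while True:
            rel = np.flatnonzero(dive_cand[cursor:e])
            if len(rel) == 0:
                break
            start = cursor + int(rel[0])
            end, no_ext = _dive_end_index(dp, start, e, trace, params)
            if end <= start:
                cursor = start + 1
                continue
            flags = ("no_pitch_extremum",) if no_ext else ()
            ev = BehaviourEvent(trace.bird_id, "dive", trace.t[start],
                                trace.t[end], flags=flags,
                                event_id=len(dives) * 2)
            ev.dive_type = classify_dive_type(ev.duration_s, params)
            dives.append(ev)
            # refractory: skip past the linked take-off (or its horizon)
            to = _find_takeoff(trace, stats, end, e, params)
            cursor = to[1] + 1 if to else min(
                e, end + int(round(params.takeoff_horizon_s * trace.rate_hz)))
    return dives


def _find_takeoff(trace: AccelTrace, stats: RunningStats, dive_end: int,
                  seg_end: int, params: ClassifierParams) -> tuple[int, int] | None:
    """(start, end) sample indices of the take-off after a dive, or None."""
    rate = trace.rate_hz
    horizon = min(seg_end, dive_end + 1 + int(round(params.takeoff_horizon_s * rate)))
    active = (stats.sd_z[dive_end:horizon] > params.takeoff_sd_z_min) & \
             (stats.sd_x[dive_end:horizon] > params.takeoff_sd_x_min)
    rel = np.flatnonzero(active)
    if len(rel) == 0:
        return None
    start = dive_end + int(rel[0])
    ended = (stats.sd_z[start + 1:seg_end] < params.takeoff_end_sd_z_max) & \
            (stats.sd_x[start + 1:seg_end] < params.takeoff_end_sd_x_max)
    rel_end = np.flatnonzero(ended)
    end = start + 1 + int(rel_end[0]) if len(rel_end) else seg_end - 1
    return start, end


def detect_takeoffs(trace: AccelTrace, dives: list[BehaviourEvent],
                    params: ClassifierParams | None = None,
                    stats: RunningStats | None = None) -> list[BehaviourEvent]:
    """Find the take-off linked to each dive.

    The search begins at the dive end; a dive with no take-off within the
    horizon is flagged ``no_takeoff`` (its cost is later computed over the
    dive alone).
    """
    params = params or ClassifierParams()
    if stats is None:
        stats = running_stats(trace, params.sd_window_s, params)
    takeoffs: list[BehaviourEvent] = []
    seg_for_index = trace.segment
    bounds = trace.segment_bounds()
    for dive in dives:
        end_idx = int(np.searchsorted(trace.t, dive.end_s))
        end_idx = min(end_idx, len(trace) - 1)
        s, e = bounds[seg_for_index[end_idx]]
        found = _find_takeoff(trace, stats, end_idx, e, params)
        if found is None:
            dive.flags = tuple(set(dive.flags) | {"no_takeoff"})
            continue
        to = BehaviourEvent(trace.bird_id, "takeoff", trace.t[found[0]],
                            trace.t[found[1]], event_id=dive.event_id + 1,
                            linked_id=dive.event_id)
        dive.linked_id = to.event_id
        takeoffs.append(to)
    return takeoffs


def classify_events(trace: AccelTrace,
                    params: ClassifierParams | None = None
                    ) -> tuple[list[BehaviourEvent], list[BehaviourEvent]]:
    """Full pass: dives plus linked take-offs."""
    params = params or ClassifierParams()
    stats = running_stats(trace, params.mean_window_s, params)
    dives = detect_dives(trace, params, stats)
    takeoffs = detect_takeoffs(trace, dives, params, stats)
    return dives, takeoffs


# ---------------------------------------------------------------------------
# TDR validation
# ---------------------------------------------------------------------------

@dataclass
class TdrMatchReport:
    """Result of matching accelerometer dive starts to TDR dive starts."""

    n_accel: int
    n_tdr: int
    n_matched: int
    offsets_s: np.ndarray
    unmatched_accel: list[int]
    unmatched_tdr: list[int]
    warning: str | None = None

    @property
    def match_rate(self) -> float:
        """Fraction of accelerometer dives with a TDR partner."""
        return self.n_matched / self.n_accel if self.n_accel else float("nan")


def tdr_dive_starts(depth: DepthTrace) -> np.ndarray:
    """Times at which depth first exceeds the trigger threshold per dive.

    An upward crossing of the trigger threshold opens a TDR dive; the first
    sample of a recording segment already above threshold also counts,
    since segments begin on trigger.
    """
    starts = []
    thr = depth.trigger_threshold_m
    edges = np.flatnonzero(np.diff(depth.segment)) + 1
    seg_starts = set(np.concatenate([[0], edges]).tolist()) if len(depth) else set()
    above = depth.depth_m > thr
    for i in range(len(depth)):
        if above[i] and (i in seg_starts or not above[i - 1]):
            starts.append(depth.t[i])
    return np.asarray(starts)


def validate_against_tdr(dives: list[BehaviourEvent], depth: DepthTrace,
                         params: ClassifierParams | None = None,
                         time_offset_s: float = 0.0) -> TdrMatchReport:
    """Greedy one-to-one nearest matching of dive starts within tolerance.

    ``time_offset_s`` is added to accelerometer times before matching (per
    bird clock offset between loggers).  Candidate pairs are accepted in
    order of increasing |offset|.
    """
    params = params or ClassifierParams()
    tol = params.tdr_match_tol_s
    accel_starts = np.asarray([d.start_s + time_offset_s for d in dives])
    tdr_starts = tdr_dive_starts(depth)
    if len(tdr_starts) == 0:
        return TdrMatchReport(len(accel_starts), 0, 0, np.zeros(0),
                              list(range(len(accel_starts))), [],
                              warning="empty TDR trace: no dives recorded")
    pairs = []
    for i, a in enumerate(accel_starts):
        for j, b in enumerate(tdr_starts):
            off = b - a
            if abs(off) <= tol:
                pairs.append((abs(off), i, j, off))
    pairs.sort()
    used_a: set[int] = set()
    used_t: set[int] = set()
    offsets = []
    for _, i, j, off in pairs:
        if i in used_a or j in used_t:
            continue
        used_a.add(i)
        used_t.add(j)
        offsets.append(off)
    return TdrMatchReport(
        n_accel=len(accel_starts), n_tdr=len(tdr_starts),
        n_matched=len(offsets), offsets_s=np.asarray(offsets),
        unmatched_accel=[i for i in range(len(accel_starts)) if i not in used_a],
        unmatched_tdr=[j for j in range(len(tdr_starts)) if j not in used_t])


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def events_to_frame(events: list[BehaviourEvent]):
    import pandas as pd

    return pd.DataFrame([{
        "bird_id": ev.bird_id, "kind": ev.kind, "start_s": ev.start_s,
        "end_s": ev.end_s, "duration_s": ev.duration_s,
        "dive_type": ev.dive_type, "linked_id": ev.linked_id,
        "flags": ";".join(ev.flags),
    } for ev in events])
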