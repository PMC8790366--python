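"""From acceleration to kilojoules.

The movement-energy proxy is vectorial dynamic body acceleration (VeDBA):
the Euclidean norm of the gravity-removed acceleration vector, accumulated
per second (units g-seconds).  It is converted to kilojoules through a
per-individual gradient *k* anchored by two allometric quantities:

* basal metabolic rate, BMR = a * mass_kg ** b (kJ/day);
* field metabolic rate, log10 FMR = b0 + b1*log10(mass_g) + b2*|latitude|.

Activity energy expenditure AEE = FMR - BMR is the energy a typical bird
spends on movement in 24 h.  Assuming zero VeDBA means zero locomotion
energy, the line through the origin and (mean VeDBA24, AEE) has slope
k = AEE / mean(VeDBA24) in kJ per g-second, where VeDBA24 is the VeDBA
accumulated over one complete 24-h period.  Dive costs, trip expenditure
and total energetic demand (TED, adding the bird's sex-specific share of
chick provisioning) all follow from k.

Any uniform rescaling of the per-second VeDBA accumulation convention
cancels through k, so kilojoule outputs are invariant to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from morus.classify import BehaviourEvent, running_stats
from morus.config import AllometricParams, DemandParams
from morus.io import AccelTrace

SECONDS_PER_DAY = 86400.0


# ---------------------------------------------------------------------------
# VeDBA
# ---------------------------------------------------------------------------

@dataclass
class VeDBASeries:
    """Per-second VeDBA in g-seconds; ``t0_s`` anchors second 0.

    ``vedba[i]`` covers the second [t0 + i, t0 + i + 1); seconds with less
    than half their samples present are NaN and excluded from daily sums.
    """

    bird_id: str
    t0_s: float
    vedba: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.vedba = np.asarray(self.vedba, dtype=float)
        if np.nanmin(self.vedba, initial=0.0) < 0:
            raise ValueError("VeDBA must be non-negative")

    def __len__(self) -> int:
        return len(self.vedba)

    def rescaled(self, factor: float) -> "VeDBASeries":
        """Same series under a rescaled accumulation convention."""
        return VeDBASeries(self.bird_id, self.t0_s, self.vedba * factor,
                           self.rate_hz)


def compute_vedba(trace: AccelTrace, static_window_s: float = 2.0) -> VeDBASeries:
    """Per-second VeDBA from a segmented trace.

    The static (gravity) component is the centred running mean per axis
    within segments; the dynamic component is raw minus static; per-sample
    VeDBA is the norm of the dynamic vector, and the per-second value is
    the sum of per-sample VeDBA divided by the sampling rate.
    """
    stats = running_stats(trace, static_window_s)
    dx = trace.ax - stats.mean_x
    dy = trace.ay - stats.mean_y
    dz = trace.az - stats.mean_z
    v = np.sqrt(dx * dx + dy * dy + dz * dz)
    t0 = float(trace.t[0])
    sec = np.floor(trace.t - t0).astype(np.int64)
    n_sec = int(sec[-1]) + 1
    sums = np.bincount(sec, weights=v, minlength=n_sec)
    counts = np.bincount(sec, minlength=n_sec)
    out = sums / trace.rate_hz
    out[counts < 0.5 * trace.rate_hz] = np.nan
    return VeDBASeries(trace.bird_id, t0, out, trace.rate_hz)


def vedba24_sums(series: VeDBASeries,
                 min_coverage: float = 0.95) -> np.ndarray:
    """Summed VeDBA per complete 24-h period, aligned to deployment start.

    A period is complete when it lies fully within the series span and at
    least ``min_coverage`` of its seconds carry a value.
    """
    n = len(series)
    day = int(SECONDS_PER_DAY)
    out = []
    for start in range(0, n - day + 1, day):
        chunk = series.vedba[start:start + day]
        present = np.isfinite(chunk)
        if present.mean() >= min_coverage:
            out.append(np.nansum(chunk))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# allometry and calibration
# ---------------------------------------------------------------------------

def bmr_allometric(mass_kg: float, params: AllometricParams | None = None) -> float:
    """Basal metabolic rate in kJ/day from body mass."""
    if mass_kg <= 0:
        raise ValueError("mass_kg must be > 0")
    p = params or AllometricParams()
    return p.bmr_a * mass_kg ** p.bmr_b


def fmr_allometric(mass_kg: float, latitude_deg: float = 52.0,
                   params: AllometricParams | None = None) -> float:
    """Field metabolic rate in kJ/day from body mass and colony latitude."""
    if mass_kg <= 0:
        raise ValueError("mass_kg must be > 0")
    p = params or AllometricParams()
    return 10.0 ** (p.fmr_b0 + p.fmr_b1 * math.log10(1000.0 * mass_kg)
                    + p.fmr_b2 * abs(latitude_deg))


@dataclass
class BirdEnergyProfile:
    """Per-bird calibration: BMR, FMR, mean VeDBA24 and gradient k."""

    bird_id: str
    bmr_kj_day: float
    fmr_kj_day: float
    vedba24_mean: float
    n_complete_days: int

    def __post_init__(self) -> None:
        if self.vedba24_mean <= 0:
            raise ValueError("vedba24_mean must be > 0")
        if self.fmr_kj_day <= self.bmr_kj_day:
            raise ValueError("FMR must exceed BMR")

    @property
    def aee_kj_day(self) -> float:
        return self.fmr_kj_day - self.bmr_kj_day

    @property
    def k(self) -> float:
        """kJ per g-second of VeDBA (line through the origin)."""
        return self.aee_kj_day / self.vedba24_mean

    def predict_aee(self, vedba24: float) -> float:
        return self.k * vedba24


class NoCompleteDaysError(ValueError):
    """Raised when a bird has no complete 24-h period to calibrate on."""


def calibrate_k(bird_id: str, bmr_kj_day: float, fmr_kj_day: float,
                daily_vedba_sums: np.ndarray) -> BirdEnergyProfile:
    """Fit the per-bird VeDBA-to-kJ gradient from daily VeDBA totals."""
    daily = np.asarray(daily_vedba_sums, dtype=float)
    if len(daily) == 0:
        raise NoCompleteDaysError(
            f"{bird_id}: no complete 24-h period; excluded from energy "
            "analyses")
    return BirdEnergyProfile(bird_id, bmr_kj_day, fmr_kj_day,
                             float(daily.mean()), len(daily))


# ---------------------------------------------------------------------------
# costs and demand
# ---------------------------------------------------------------------------

@dataclass
class DiveCost:
    """Energetic cost of one prey-capture attempt (dive + take-off)."""

    event_id: int
    summed_vedba: float
    cost_kj: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def _sum_vedba_interval(series: VeDBASeries, start_s: float,
                        end_s: float) -> tuple[float, bool]:
    """Pro-rated VeDBA sum over [start_s, end_s]; True if coverage gap."""
    if end_s < start_s:
        raise ValueError("end before start")
    lo = start_s - series.t0_s
    hi = end_s - series.t0_s
    i0 = max(int(np.floor(lo)), 0)
    i1 = min(int(np.ceil(hi)), len(series))
    total = 0.0
    gap = False
    for i in range(i0, i1):
        frac = min(hi, i + 1) - max(lo, i)
        if frac <= 0:
            continue
        v = series.vedba[i]
        if np.isnan(v):
            gap = True
            continue
        total += v * frac
    return total, gap


def event_cost(dive: BehaviourEvent, series: VeDBASeries,
               profile: BirdEnergyProfile,
               takeoff: BehaviourEvent | None = None) -> DiveCost:
    """k times the VeDBA summed from dive start to take-off completion.

    With no linked take-off the sum covers the dive alone and the cost is
    flagged; a coverage gap inside the span flags the cost partial.
    """
    end_s = takeoff.end_s if takeoff is not None else dive.end_s
    flags = [] if takeoff is not None else ["no_takeoff"]
    total, gap = _sum_vedba_interval(series, dive.start_s, end_s)
    if gap:
        flags.append("partial_coverage")
    if end_s == dive.start_s:
        flags.append("zero_length")
    return DiveCost(dive.event_id, total, profile.k * total, tuple(flags))


def trip_expenditure(series: VeDBASeries, profile: BirdEnergyProfile,
                     interval: tuple[float, float]) -> float:
    """Total expenditure over an interval: movement energy plus BMR.

    movement = k * sum(VeDBA) over the interval; basal metabolism is added
    at ``bmr_kj_day`` prorated for fractional days.
    """
    start_s, end_s = interval
    if start_s < series.t0_s or end_s > series.t0_s + len(series):
        raise ValueError("interval outside VeDBA coverage")
    total, _ = _sum_vedba_interval(series, start_s, end_s)
    days = (end_s - start_s) / SECONDS_PER_DAY
    return profile.k * total + profile.bmr_kj_day * days


def total_energetic_demand(expenditure_kj: float, sex: str, days: float,
                           demand: DemandParams | None = None) -> float:
    """TED: expenditure plus the sex-specific share of chick provisioning.

    TED = expenditure + share(sex) * chick_demand_kj_day * days; the female
    share is 60% and the male share 40% by default (unequal parenting
    roles).  Unknown sex is rejected — those birds are excluded upstream.
    """
    if days <= 0:
        raise ValueError("days must be > 0")
    demand = demand or DemandParams()
    return expenditure_kj + demand.share(sex) * demand.chick_demand_kj_day * days
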