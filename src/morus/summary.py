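"""Per-bird trip summaries and sex-level headline statistics.

A trip summary assembles, for one tracked bird, the counts and energy
quantities of its deployment — dives, dive rate, tracking expenditure,
total energetic demand (TED), the kilojoule intake value (KIV) of one
successful dive — and from them the minimum dive-success statistics:

    successful dives needed = TED / KIV           (fractional, not rounded)
    minimum success percent = 100 * needed / number of dives

Sex summaries are unweighted per-bird means (+/- SD); birds of unknown
sex are excluded from sex contrasts.  A packaged fixture with the printed
columns of the study's per-bird results table ships with the module for
end-to-end reconstruction checks (:func:`load_reference_trips`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from morus.io import read_table


@dataclass
class TripSummary:
    """One bird's trip-level results row."""

    bird_id: str
    sex: str
    year: int
    tracking_days: float
    n_dives: int
    dives_per_day: float
    expenditure_kj: float
    ted_kj: float
    ted_per_day_kj: float
    kiv_kj: float
    successful_dives_needed: float
    pct_dives_successful_min: float


def successful_dives_needed(ted_kj: float, kiv_kj: float) -> float:
    """How many successful dives cover the total energetic demand."""
    if not kiv_kj > 0:
        raise ValueError("kiv_kj must be > 0")
    return ted_kj / kiv_kj


def min_success_rate(needed: float, n_dives: int) -> float:
    """Needed successes as a percent of dives performed — a minimum
    success rate, since needed is itself a lower bound."""
    if n_dives <= 0:
        raise ValueError("n_dives must be > 0")
    return 100.0 * needed / n_dives


def build_trip_summary(bird_id: str, sex: str, year: int,
                       tracking_days: float, n_dives: int,
                       expenditure_kj: float, ted_kj: float,
                       kiv_kj: float,
                       dives_per_day: float | None = None,
                       ted_per_day_kj: float | None = None) -> TripSummary:
    """Assemble one summary row, recomputing the derived success columns.

    ``dives_per_day`` and ``ted_per_day_kj`` may be supplied directly when
    they come from a source with more precise durations than
    ``tracking_days`` (e.g. a published table with rounded days);
    otherwise they are recomputed.
    """
    needed = successful_dives_needed(ted_kj, kiv_kj)
    return TripSummary(
        bird_id=bird_id, sex=sex, year=year, tracking_days=tracking_days,
        n_dives=n_dives,
        dives_per_day=(dives_per_day if dives_per_day is not None
                       else n_dives / tracking_days),
        expenditure_kj=expenditure_kj, ted_kj=ted_kj,
        ted_per_day_kj=(ted_per_day_kj if ted_per_day_kj is not None
                        else ted_kj / tracking_days),
        kiv_kj=kiv_kj, successful_dives_needed=needed,
        pct_dives_successful_min=min_success_rate(needed, n_dives))


def load_reference_trips(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged per-bird reference table (printed input columns)."""
    if path is None:
        ref = resources.files("morus").joinpath("data/trip_table.csv")
        with resources.as_file(ref) as p:
            return read_table(p, "trip_table")
    return read_table(path, "trip_table")


def trips_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute the derived success columns from a trip-format table.

    Rows without TED or KIV (e.g. a bird excluded from sex analyses) keep
    NaN in the derived columns.  Printed per-day columns are taken as
    given when present.
    """
    rows = []
    for _, r in table.iterrows():
        if pd.isna(r.get("ted_kj")) or pd.isna(r.get("kiv_kj")):
            rows.append({
                "bird_id": r["bird_id"], "sex": r["sex"], "year": int(r["year"]),
                "tracking_days": r["tracking_days"], "n_dives": int(r["n_dives"]),
                "dives_per_day": r.get("dives_per_day",
                                       r["n_dives"] / r["tracking_days"]),
                "expenditure_kj": r["expenditure_kj"], "ted_kj": np.nan,
                "ted_per_day_kj": np.nan, "kiv_kj": np.nan,
                "successful_dives_needed": np.nan,
                "pct_dives_successful_min": np.nan,
            })
            continue
        ts = build_trip_summary(
            str(r["bird_id"]), str(r["sex"]), int(r["year"]),
            float(r["tracking_days"]), int(r["n_dives"]),
            float(r["expenditure_kj"]), float(r["ted_kj"]), float(r["kiv_kj"]),
            dives_per_day=(float(r["dives_per_day"])
                           if pd.notna(r.get("dives_per_day")) else None),
            ted_per_day_kj=(float(r["ted_per_day_kj"])
                            if pd.notna(r.get("ted_per_day_kj")) else None))
        rows.append(vars(ts))
    return pd.DataFrame(rows)


@dataclass
class SexSummary:
    """Headline statistics for one sex (unweighted per-bird means)."""

    sex: str
    n_birds: int
    dives_per_day_mean: float
    dives_per_day_sd: float
    ted_per_day_mean: float
    ted_per_day_sd: float
    pct_success_mean: float
    pct_success_sd: float


def summarize_by_sex(trips: pd.DataFrame
                     ) -> tuple[dict[str, SexSummary], float]:
    """Per-sex summaries and the female TED percent excess.

    Returns ``(summaries, ted_excess_pct)`` where ``ted_excess_pct`` is
    ``100 * (female mean - male mean) / male mean`` of per-day TED.  Birds
    of unknown sex are excluded; a single bird in a sex yields NaN SDs.
    """
    known = trips[trips["sex"].isin(["female", "male"])]
    out: dict[str, SexSummary] = {}
    for sex, g in known.groupby("sex"):
        def _mean_sd(col):
            vals = g[col].dropna().to_numpy(float)
            mean = float(vals.mean()) if len(vals) else math.nan
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
            return mean, sd

        dm, ds = _mean_sd("dives_per_day")
        tm, tsd = _mean_sd("ted_per_day_kj")
        pm, ps = _mean_sd("pct_dives_successful_min")
        out[sex] = SexSummary(sex, len(g), dm, ds, tm, tsd, pm, ps)
    if "female" in out and "male" in out and out["male"].ted_per_day_mean:
        excess = 100.0 * (out["female"].ted_per_day_mean
                          - out["male"].ted_per_day_mean) \
            / out["male"].ted_per_day_mean
    else:
        excess = math.nan
    return out, excess


def dive_cost_share(trips: pd.DataFrame,
                    mean_attempt_cost_kj: dict[str, float]) -> pd.Series:
    """Fraction (%) of tracking expenditure spent on prey-capture attempts.

    Per bird: ``100 * n_dives * sex-mean attempt cost / expenditure``.
    Birds of unknown sex are skipped (no sex-mean cost applies).
    """
    known = trips[trips["sex"].isin(mean_attempt_cost_kj)]
    cost = known["sex"].map(mean_attempt_cost_kj)
    share = 100.0 * known["n_dives"] * cost / known["expenditure_kj"]
    share.index = known["bird_id"]
    return share
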