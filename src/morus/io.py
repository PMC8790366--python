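"""Readers and writers for the plain delimited formats the pipeline touches.

Accelerometer and depth traces are CSV with a header row; all tabular
inputs (bird metadata, consumer isotopes, prey sources, prey energies,
behaviour events, trip-summary tables) go through :func:`read_table` with a
named schema.  Logger dropouts are handled at read time: a time step larger
than twice the nominal sampling interval starts a new segment, and running
statistics downstream never span segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEXES = ("female", "male", "unknown")

#: gap rule — a step exceeding this many sampling intervals opens a segment
GAP_FACTOR = 2.0


# ---------------------------------------------------------------------------
# trace containers
# ---------------------------------------------------------------------------

def _segment_ids(t: np.ndarray, rate_hz: float) -> np.ndarray:
    """Segment index per sample; a new segment starts after a gap."""
    if len(t) == 0:
        return np.zeros(0, dtype=np.int64)
    dt = np.diff(t)
    breaks = dt > GAP_FACTOR / rate_hz
    return np.concatenate([[0], np.cumsum(breaks)]).astype(np.int64)


@dataclass
class AccelTrace:
    """Timestamped tri-axial acceleration in units of g.

    Axes follow the tag convention X = surge, Y = sway, Z = heave; at rest
    with the tag level, Z is close to +1 g and X, Y close to 0 g.  ``t`` is
    seconds since deployment start and must be strictly increasing.
    ``time_offset_s`` holds any per-bird clock offset relative to the depth
    recorder (applied by the TDR validation, never silently).
    """

    bird_id: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    rate_hz: float = 50.0
    time_offset_s: float = 0.0
    segment: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("ax", "ay", "az"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} length does not match time axis")
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name}")
            setattr(self, name, arr)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")
        if len(self.t) > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError("time axis must be strictly increasing")
        self.segment = _segment_ids(self.t, self.rate_hz)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_segments(self) -> int:
        return int(self.segment[-1]) + 1 if len(self.t) else 0

    def segment_bounds(self) -> list[tuple[int, int]]:
        """(start, stop) index pairs, stop exclusive, one per segment."""
        if len(self.t) == 0:
            return []
        edges = np.flatnonzero(np.diff(self.segment)) + 1
        starts = np.concatenate([[0], edges])
        stops = np.concatenate([edges, [len(self.t)]])
        return list(zip(starts.tolist(), stops.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, "ax": self.ax, "ay": self.ay,
                             "az": self.az})


@dataclass
class DepthTrace:
    """Depth in metres at a fixed rate; recording is trigger-gated.

    The depth recorder only logs once depth exceeds ``trigger_threshold_m``,
    so the trace is naturally segmented into dive excursions.
    """

    bird_id: str
    t: np.ndarray
    depth_m: np.ndarray
    rate_hz: float = 4.0
    trigger_threshold_m: float = 0.5
    segment: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if self.depth_m.shape != self.t.shape:
            raise ValueError("depth length does not match time axis")
        if (self.depth_m < 0).any():
            raise ValueError("depth_m must be >= 0")
        if self.trigger_threshold_m not in (0.5, 1.0):
            # both tag set-ups used in the field; anything else is a typo
            raise ValueError("trigger_threshold_m must be 0.5 or 1.0")
        if len(self.t) > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError("time axis must be strictly increasing")
        self.segment = _segment_ids(self.t, self.rate_hz)

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, "depth_m": self.depth_m})


def read_accel(path: str | Path, rate_hz: float = 50.0,
               bird_id: str | None = None) -> AccelTrace:
    """Read an accelerometer CSV (columns time, ax, ay, az; units g)."""
    df = _read_nonempty(path)
    _require_columns(df, ("time", "ax", "ay", "az"), path)
    t = df["time"].to_numpy(dtype=float)
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise ValueError(f"{path}: time column is not strictly increasing")
    return AccelTrace(bird_id or Path(path).stem, t,
                      df["ax"].to_numpy(float), df["ay"].to_numpy(float),
                      df["az"].to_numpy(float), rate_hz=rate_hz)


def read_depth(path: str | Path, rate_hz: float = 4.0,
               trigger_threshold_m: float = 0.5,
               bird_id: str | None = None) -> DepthTrace:
    """Read a time-depth-recorder CSV (columns time, depth_m)."""
    df = _read_nonempty(path)
    _require_columns(df, ("time", "depth_m"), path)
    return DepthTrace(bird_id or Path(path).stem,
                      df["time"].to_numpy(float),
                      df["depth_m"].to_numpy(float),
                      rate_hz=rate_hz, trigger_threshold_m=trigger_threshold_m)


def write_accel(trace: AccelTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_depth(trace: DepthTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tabular schemas
# ---------------------------------------------------------------------------

@dataclass
class BirdMetadata:
    """One tracked bird: identity, sex, mass and deployment bookkeeping."""

    bird_id: str
    sex: str
    mass_kg: float
    year: int
    deployment_days: float
    n_complete_days: int = 0
    colony_latitude_deg: float = 52.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be > 0")
        if self.deployment_days <= 0:
            raise ValueError("deployment_days must be > 0")
        if not 0 <= self.n_complete_days <= int(self.deployment_days) + 1:
            raise ValueError("n_complete_days inconsistent with deployment")

    @property
    def in_sex_contrasts(self) -> bool:
        """Birds of unknown sex are kept but excluded from sex contrasts."""
        return self.sex in ("female", "male")


_SCHEMAS: dict[str, dict] = {
    "metadata": {
        "required": ["bird_id", "sex", "mass_kg", "year", "deployment_days"],
        "optional": ["n_complete_days", "colony_latitude_deg"],
        "numeric": ["mass_kg", "year", "deployment_days", "n_complete_days",
                    "colony_latitude_deg"],
    },
    "isotopes": {
        "required": ["bird_id", "sex", "year", "d13C", "d15N", "pctC", "pctN"],
        "optional": [],
        "numeric": ["year", "d13C", "d15N", "pctC", "pctN"],
    },
    "sources": {
        "required": ["species", "d13C_mean", "d13C_sd", "d15N_mean",
                     "d15N_sd", "historical_diet_pct"],
        "optional": ["pctC", "pctN"],
        "numeric": ["d13C_mean", "d13C_sd", "d15N_mean", "d15N_sd",
                    "historical_diet_pct", "pctC", "pctN"],
    },
    "prey_energy": {
        "required": ["species", "gross_kj"],
        "optional": [],
        "numeric": ["gross_kj"],
    },
    "events": {
        "required": ["bird_id", "kind", "start_s", "end_s", "duration_s",
                     "dive_type"],
        "optional": ["linked_id", "flags"],
        "numeric": ["start_s", "end_s", "duration_s"],
    },
    "trip_table": {
        "required": ["bird_id", "sex", "year", "tracking_days", "n_dives",
                     "expenditure_kj", "ted_kj", "kiv_kj"],
        "optional": ["dives_per_day", "ted_per_day_kj", "needed_printed",
                     "pct_printed"],
        "numeric": ["year", "tracking_days", "n_dives", "dives_per_day",
                    "expenditure_kj", "ted_kj", "ted_per_day_kj", "kiv_kj",
                    "needed_printed", "pct_printed"],
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a delimited table against a named schema.

    Returns typed rows; for schemas with a ``sex`` column an
    ``in_sex_contrasts`` flag column is added (False for unknown sex).
    Schema violations are rejected with the offending row number.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; "
                         f"expected one of {sorted(_SCHEMAS)}")
    spec = _SCHEMAS[schema]
    df = _read_nonempty(path)
    _require_columns(df, spec["required"], path)
    for col in spec["numeric"]:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        fresh_na = coerced.isna() & df[col].notna()
        if fresh_na.any():
            row = int(np.flatnonzero(fresh_na.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric value in column {col!r} "
                             f"at line {row}")
        df[col] = coerced
    if "sex" in df.columns:
        bad = ~df["sex"].isin(SEXES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: invalid sex value at line {row}")
        df["in_sex_contrasts"] = df["sex"].isin(["female", "male"])
    return df


def metadata_records(df: pd.DataFrame) -> list[BirdMetadata]:
    """Convert a metadata table to validated :class:`BirdMetadata` rows."""
    records = []
    for _, row in df.iterrows():
        kwargs = dict(bird_id=str(row["bird_id"]), sex=str(row["sex"]),
                      mass_kg=float(row["mass_kg"]), year=int(row["year"]),
                      deployment_days=float(row["deployment_days"]))
        if "n_complete_days" in df.columns and pd.notna(row.get("n_complete_days")):
            kwargs["n_complete_days"] = int(row["n_complete_days"])
        if "colony_latitude_deg" in df.columns and pd.notna(row.get("colony_latitude_deg")):
            kwargs["colony_latitude_deg"] = float(row["colony_latitude_deg"])
        records.append(BirdMetadata(**kwargs))
    return records


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_nonempty(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
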