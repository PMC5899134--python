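"""Plate-reader kinetics to capacity statistics.

Reduces raw GFP/RFP/OD time series to the summary numbers the assays are
built on: windowed growth rate, per-OD (in vivo) and absolute (lysate) GFP
production rates, the maximal production rate ("capacity"), and capacities
normalized to a monitor-alone reference.

All windowed statistics share one convention: a rate at time ``t2`` is the
finite difference between the samples nearest ``t2 - 0.5 h`` and
``t2 + 0.5 h``, divided by the actual time spanned. No smoothing is applied
to the traces before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlateTimeSeries",
    "CapacityMeasurement",
    "NoGrowthError",
    "growth_rate",
    "find_mid_exponential",
    "production_rate_in_vivo",
    "production_rate_in_vitro",
    "capacity",
    "normalize",
    "subtract_blank",
    "read_plate_csv",
    "write_plate_csv",
    "write_statistics_csv",
]

HALF_WINDOW_H = 0.5  # printed for growth rate; adopted for production rates
#: growth below this (doubling time ~3 days) is treated as no growth
MIN_GROWTH_RATE = 0.01

_CHANNELS = ("gfp", "rfp", "od600", "od700")


class NoGrowthError(ValueError):
    """The OD trace shows no usable exponential phase."""


@dataclass
class PlateTimeSeries:
    """One well's kinetic trace. ``time`` in hours, strictly increasing."""

    time: np.ndarray
    gfp: np.ndarray
    rfp: np.ndarray | None = None
    od600: np.ndarray | None = None
    od700: np.ndarray | None = None
    well_id: str = ""
    sample: str = ""
    condition: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("time must be a 1-d array with >= 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for ch in ("gfp", "rfp", "od600", "od700"):
            v = getattr(self, ch)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            setattr(self, ch, v)
            if v.shape != self.time.shape:
                raise ValueError(f"{ch} length does not match time")

    @property
    def od(self) -> np.ndarray:
        """Growth OD channel; OD700 preferred when both are present."""
        if self.od700 is not None:
            return self.od700
        if self.od600 is not None:
            return self.od600
        raise ValueError(f"well {self.well_id!r} has no OD channel")

    @property
    def has_od(self) -> bool:
        return self.od600 is not None or self.od700 is not None

    def channel(self, name: str) -> np.ndarray:
        v = getattr(self, name, None)
        if v is None:
            raise ValueError(f"well {self.well_id!r} has no {name} channel")
        return v


@dataclass(frozen=True)
class CapacityMeasurement:
    """A normalized capacity with its provenance."""

    value: float
    raw_max_rate: float
    mode: str  # "lysate" or "in_vivo"
    reference_rate: float
    condition: str = ""
    sample: str = ""


def _nearest(time: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(time - t)))


def _window_indices(ts: PlateTimeSeries, t2: float) -> tuple[int, int]:
    t1, t3 = t2 - HALF_WINDOW_H, t2 + HALF_WINDOW_H
    eps = 1e-9
    if t1 < ts.time[0] - eps or t3 > ts.time[-1] + eps:
        raise ValueError(
            f"window {t1:.3g}-{t3:.3g} h outside series "
            f"[{ts.time[0]:.3g}, {ts.time[-1]:.3g}] h"
        )
    i1, i3 = _nearest(ts.time, t1), _nearest(ts.time, t3)
    if i1 == i3:
        raise ValueError("sampling too sparse for the +/-0.5 h window")
    return i1, i3


def growth_rate(ts: PlateTimeSeries, t2: float) -> float:
    """Specific growth rate (h^-1) at ``t2``: d(ln OD)/dt over +/-0.5 h."""
    od = ts.od
    i1, i3 = _window_indices(ts, t2)
    if od[i1] <= 0 or od[i3] <= 0:
        raise ValueError("OD must be positive inside the growth window")
    return float((np.log(od[i3]) - np.log(od[i1])) / (ts.time[i3] - ts.time[i1]))


def _admissible_t2(ts: PlateTimeSeries, exclude_edges: bool = True) -> np.ndarray:
    mask = (ts.time >= ts.time[0] + HALF_WINDOW_H - 1e-9) & (
        ts.time <= ts.time[-1] - HALF_WINDOW_H + 1e-9
    )
    t2s = ts.time[mask]
    if exclude_edges and len(t2s) > 2:
        t2s = t2s[1:-1]
    return t2s


def find_mid_exponential(ts: PlateTimeSeries) -> float:
    """Time of mid-exponential phase: the sample maximizing the centered
    log-OD slope over +/-0.5 h windows (edge windows excluded)."""
    if ts.time[-1] - ts.time[0] < 2 * HALF_WINDOW_H:
        raise ValueError("series must span at least 1 h")
    od = ts.od
    if np.any(od <= 0):
        raise NoGrowthError("OD must be positive throughout")
    t2s = _admissible_t2(ts)
    if len(t2s) == 0:
        raise ValueError("no admissible window centres")
    rates = np.array([growth_rate(ts, t2) for t2 in t2s])
    best = int(np.argmax(rates))
    if rates[best] < MIN_GROWTH_RATE:
        raise NoGrowthError(
            f"maximal windowed growth rate {rates[best]:.3g} h^-1 is below "
            f"{MIN_GROWTH_RATE} h^-1"
        )
    return float(t2s[best])


def production_rate_in_vivo(ts: PlateTimeSeries, t2: float, channel: str = "gfp") -> float:
    """Per-OD production rate at ``t2`` (fluorescence h^-1 OD^-1)."""
    f = ts.channel(channel)
    i1, i3 = _window_indices(ts, t2)
    od2 = ts.od[_nearest(ts.time, t2)]
    if od2 <= 0:
        raise ValueError("OD at t2 must be positive")
    return float((f[i3] - f[i1]) / (ts.time[i3] - ts.time[i1]) / od2)


def production_rate_in_vitro(ts: PlateTimeSeries, t2: float, channel: str = "gfp") -> float:
    """Absolute production rate at ``t2`` (fluorescence h^-1)."""
    f = ts.channel(channel)
    i1, i3 = _window_indices(ts, t2)
    return float((f[i3] - f[i1]) / (ts.time[i3] - ts.time[i1]))


def capacity(ts: PlateTimeSeries, mode: str, channel: str = "gfp") -> float:
    """Raw capacity of a well.

    ``mode="lysate"``: the maximum windowed production rate over the trace
    (max dGFP/dt), first and last admissible windows excluded.
    ``mode="in_vivo"``: the per-OD production rate at the mid-exponential
    time point.
    """
    if mode == "lysate":
        t2s = _admissible_t2(ts)
        if len(t2s) < 3:
            raise ValueError("series too short: need at least 3 windows")
        return float(max(production_rate_in_vitro(ts, t2, channel) for t2 in t2s))
    if mode == "in_vivo":
        t2 = find_mid_exponential(ts)
        return production_rate_in_vivo(ts, t2, channel)
    raise ValueError(f"unknown mode {mode!r}; expected 'lysate' or 'in_vivo'")


def normalize(
    raw_max_rate: float,
    reference_rate: float,
    mode: str = "lysate",
    condition: str = "",
    sample: str = "",
) -> CapacityMeasurement:
    """Normalize a raw rate against the monitor-alone reference rate."""
    if reference_rate <= 0:
        raise ValueError(f"reference_rate must be > 0, got {reference_rate}")
    return CapacityMeasurement(
        value=raw_max_rate / reference_rate,
        raw_max_rate=raw_max_rate,
        mode=mode,
        reference_rate=reference_rate,
        condition=condition,
        sample=sample,
    )


def subtract_blank(
    wells: list[PlateTimeSeries], blank_sample: str = "blank"
) -> list[PlateTimeSeries]:
    """Subtract the mean blank-well trace, channel by channel.

    Optional: no background correction is applied anywhere by default.
    Wells labelled ``blank_sample`` define the background; they are removed
    from the returned list. Raises if no blank wells are present.
    """
    blanks = [w for w in wells if w.sample == blank_sample]
    if not blanks:
        raise ValueError(f"no wells with sample {blank_sample!r} to use as blanks")
    rest = [w for w in wells if w.sample != blank_sample]
    out = []
    for w in rest:
        corrected = {}
        for ch in _CHANNELS:
            v = getattr(w, ch)
            if v is None:
                continue
            traces = [getattr(b, ch) for b in blanks if getattr(b, ch) is not None]
            corrected[ch] = v - np.mean(traces, axis=0) if traces else v
        out.append(
            PlateTimeSeries(
                time=w.time, gfp=corrected["gfp"], rfp=corrected.get("rfp"),
                od600=corrected.get("od600"), od700=corrected.get("od700"),
                well_id=w.well_id, sample=w.sample, condition=w.condition,
            )
        )
    return out


# --- CSV I/O -------------------------------------------------------------
#
# Long format (canonical): columns time, well, channel, value and optional
# sample, condition; channel one of gfp, rfp, od600, od700.
# Wide format: a time column plus one column per "<well>:<channel>" pair
# (well metadata is not representable in wide form).


def read_plate_csv(path: str | Path, format: str = "long") -> list[PlateTimeSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    if format == "long":
        return _from_long(df)
    if format == "wide":
        return _from_wide(df)
    raise ValueError(f"unknown format {format!r}")


def _from_long(df: pd.DataFrame) -> list[PlateTimeSeries]:
    required = {"time", "well", "channel", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format plate CSV missing columns: {sorted(missing)}")
    bad = set(df["channel"].unique()) - set(_CHANNELS)
    if bad:
        raise ValueError(f"unknown channels {sorted(bad)}; expected {_CHANNELS}")
    wells = []
    for well, g in df.groupby("well", sort=True):
        channels = {}
        time = None
        for ch, gc in g.groupby("channel"):
            gc = gc.sort_values("time")
            if time is None:
                time = gc["time"].to_numpy()
            elif not np.array_equal(time, gc["time"].to_numpy()):
                raise ValueError(f"well {well}: channels sampled on different grids")
            channels[ch] = gc["value"].to_numpy()
        if "gfp" not in channels:
            raise ValueError(f"well {well} has no gfp channel")
        meta = g.iloc[0]
        wells.append(
            PlateTimeSeries(
                time=time,
                gfp=channels["gfp"],
                rfp=channels.get("rfp"),
                od600=channels.get("od600"),
                od700=channels.get("od700"),
                well_id=str(well),
                sample=str(meta["sample"]) if "sample" in g.columns else "",
                condition=str(meta["condition"]) if "condition" in g.columns else "",
            )
        )
    return wells


def _from_wide(df: pd.DataFrame) -> list[PlateTimeSeries]:
    if "time" not in df.columns:
        raise ValueError("wide-format plate CSV needs a 'time' column")
    by_well: dict[str, dict[str, np.ndarray]] = {}
    for col in df.columns:
        if col == "time":
            continue
        if ":" not in col:
            raise ValueError(f"wide column {col!r} is not '<well>:<channel>'")
        well, ch = col.rsplit(":", 1)
        if ch not in _CHANNELS:
            raise ValueError(f"unknown channel {ch!r} in column {col!r}")
        by_well.setdefault(well, {})[ch] = df[col].to_numpy()
    time = df["time"].to_numpy()
    out = []
    for well in sorted(by_well):
        channels = by_well[well]
        if "gfp" not in channels:
            raise ValueError(f"well {well} has no gfp channel")
        out.append(
            PlateTimeSeries(
                time=time,
                gfp=channels["gfp"],
                rfp=channels.get("rfp"),
                od600=channels.get("od600"),
                od700=channels.get("od700"),
                well_id=well,
            )
        )
    return out


def write_plate_csv(wells: list[PlateTimeSeries], path: str | Path) -> None:
    """Write wells in the canonical long format."""
    rows = []
    for w in wells:
        for ch in _CHANNELS:
            v = getattr(w, ch)
            if v is None:
                continue
            for t, val in zip(w.time, v):
                rows.append(
                    {
                        "time": t,
                        "well": w.well_id,
                        "channel": ch,
                        "value": val,
                        "sample": w.sample,
                        "condition": w.condition,
                    }
                )
    # %.17g round-trips float64 exactly through the reader
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_statistics_csv(measurements: list[CapacityMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": m.sample,
                "condition": m.condition,
                "mode": m.mode,
                "raw_max_rate": m.raw_max_rate,
                "reference_rate": m.reference_rate,
                "normalized_capacity": m.value,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)
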