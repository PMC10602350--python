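"""Cardiac-cycle segmentation and per-cycle hemodynamics from PV recordings.

A pressure-volume (PV) recording is a uniformly sampled left-ventricular
pressure (mmHg) and volume (μl) trace.  Cycles are delimited at end diastole:
the local volume maximum immediately preceding each pressure upstroke, the
upstroke being detected where dP/dt rises through 10% of its record-wide
maximum.  Within each cycle fourteen standard parameters are extracted:

HR, ESP, EDP, Pmax, Pmin, [dP/dt]max, [dP/dt]min, Vmax, Vmin, ESV, EDV, SV,
CO and EF.  Landmark conventions (the acquisition literature leaves them to
the implementer): end diastole is the segmentation boundary itself (EDV, EDP
read there); end systole is the instant of minimum dP/dt (ESV, ESP read
there); SV = EDV - ESV by construction, so the identity also holds for means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UnsegmentableRecordError

__all__ = [
    "PVRecord",
    "BEAT_COLUMNS",
    "read_pv_csv",
    "write_pv_csv",
    "segment_cycles",
    "extract_cycle_params",
    "summarize_record",
    "analyze_record",
]

logger = logging.getLogger(__name__)

BEAT_COLUMNS = [
    "duration_ms", "HR_bpm", "ESP_mmHg", "EDP_mmHg", "Pmax_mmHg", "Pmin_mmHg",
    "dPdt_max_mmHg_per_s", "dPdt_min_mmHg_per_s", "Vmax_ul", "Vmin_ul",
    "ESV_ul", "EDV_ul", "SV_ul", "EF_pct",
]


@dataclass
class PVRecord:
    """Uniformly sampled pressure-volume time series for one animal."""

    time: np.ndarray          # s
    pressure: np.ndarray      # mmHg
    volume: np.ndarray        # μl
    sampling_rate: float      # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.time.size
        if n < 2 or self.pressure.size != n or self.volume.size != n:
            raise ValueError("time, pressure and volume must share length >= 2")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
            raise ValueError("time grid inconsistent with sampling_rate")

    def __len__(self) -> int:
        return self.time.size


def read_pv_csv(path: str | Path, sampling_rate: float | None = None) -> PVRecord:
    """Read a `time_s, pressure_mmHg, volume_ul` CSV into a :class:`PVRecord`.

    When ``sampling_rate`` is omitted it is inferred from the median time step.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "pressure_mmHg", "volume_ul"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    fs = sampling_rate if sampling_rate is not None else 1.0 / float(np.median(np.diff(t)))
    return PVRecord(
        time=t,
        pressure=df["pressure_mmHg"].to_numpy(dtype=float),
        volume=df["volume_ul"].to_numpy(dtype=float),
        sampling_rate=fs,
    )


def write_pv_csv(record: PVRecord, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": record.time, "pressure_mmHg": record.pressure, "volume_ul": record.volume}
    ).to_csv(path, index=False)


def _dpdt(record: PVRecord) -> np.ndarray:
    # central differences in the interior, one-sided at the edges
    return np.gradient(record.pressure, 1.0 / record.sampling_rate)


def segment_cycles(record: PVRecord) -> np.ndarray:
    """Indices of end-diastolic cycle boundaries, strictly increasing.

    Boundaries are local volume maxima preceding each pressure upstroke
    (dP/dt rising through 10% of its maximum).  Partial cycles before the
    first and after the last boundary are implicitly discarded by consumers.

    Raises :class:`UnsegmentableRecordError` when no periodic pressure
    activity is detectable.
    """
    p = record.pressure
    if np.ptp(p) < 1e-9 or np.ptp(record.volume) < 1e-9:
        raise UnsegmentableRecordError("flat pressure/volume trace: no cycles present")
    dpdt = _dpdt(record)
    peak = dpdt.max()
    if peak <= 0:
        raise UnsegmentableRecordError("pressure never rises: no upstrokes detectable")
    thr = 0.1 * peak

    above = dpdt >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if crossings.size < 2:
        raise UnsegmentableRecordError("fewer than two pressure upstrokes detected")

    # debounce: secondary within-cycle crossings (e.g. a late-systolic pressure
    # rise) produce short gaps; the upper-quartile gap tracks the true period
    period = float(np.percentile(np.diff(crossings), 75))
    kept = [int(crossings[0])]
    for c in crossings[1:]:
        if c - kept[-1] >= 0.5 * period:
            kept.append(int(c))
    if len(kept) < 2:
        raise UnsegmentableRecordError("upstroke debouncing left fewer than two cycles")

    back = max(1, int(round(0.75 * float(np.median(np.diff(kept))))))
    boundaries = []
    for c in kept:
        w0 = max(0, c - back)
        boundaries.append(w0 + int(np.argmax(record.volume[w0:c + 1])))
    boundaries = np.unique(np.asarray(boundaries, dtype=int))
    if boundaries.size < 2:
        raise UnsegmentableRecordError("could not locate two distinct end-diastolic points")
    return boundaries


def extract_cycle_params(record: PVRecord, boundaries: np.ndarray) -> pd.DataFrame:
    """Per-cycle hemodynamic parameters (one row per complete cycle).

    Cycles with non-positive EDV or negative SV are dropped and counted in
    ``df.attrs['n_rejected']``.
    """
    boundaries = np.asarray(boundaries, dtype=int)
    if boundaries.size < 2 or np.any(np.diff(boundaries) <= 0):
        raise ValueError("need >= 2 strictly increasing boundaries")
    dpdt = _dpdt(record)
    fs = record.sampling_rate

    rows, n_rejected = [], 0
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        p = record.pressure[s:e]
        v = record.volume[s:e]
        d = dpdt[s:e]
        edv = float(record.volume[s])
        edp = float(record.pressure[s])
        ies = int(np.argmin(d))
        esv = float(v[ies])
        esp = float(p[ies])
        sv = edv - esv
        if edv <= 0 or sv < 0:
            n_rejected += 1
            continue
        duration_ms = (e - s) / fs * 1000.0
        rows.append({
            "duration_ms": duration_ms,
            "HR_bpm": 60000.0 / duration_ms,
            "ESP_mmHg": esp,
            "EDP_mmHg": edp,
            "Pmax_mmHg": float(p.max()),
            "Pmin_mmHg": float(p.min()),
            "dPdt_max_mmHg_per_s": float(d.max()),
            "dPdt_min_mmHg_per_s": float(d.min()),
            "Vmax_ul": float(v.max()),
            "Vmin_ul": float(v.min()),
            "ESV_ul": esv,
            "EDV_ul": edv,
            "SV_ul": sv,
            "EF_pct": 100.0 * sv / edv,
        })
    if n_rejected:
        logger.warning("extract_cycle_params: rejected %d invalid cycle(s)", n_rejected)
    beats = pd.DataFrame(rows, columns=BEAT_COLUMNS)
    beats.attrs["n_rejected"] = n_rejected
    return beats


def summarize_record(beats: pd.DataFrame) -> pd.DataFrame:
    """Per-animal mean and SD of every beat-table column, plus cardiac output.

    CO (μl/min) is defined as mean SV x mean HR; its tabulated SD is the SD of
    the per-cycle products SV_i x HR_i.
    """
    if len(beats) < 2:
        raise ValueError("need at least 2 valid cycles to summarize")
    summary = pd.DataFrame({"mean": beats.mean(), "sd": beats.std(ddof=1)})
    co_per_cycle = beats["SV_ul"] * beats["HR_bpm"]
    summary.loc["CO_ul_per_min"] = [
        float(beats["SV_ul"].mean() * beats["HR_bpm"].mean()),
        float(co_per_cycle.std(ddof=1)),
    ]
    summary.index.name = "parameter"
    return summary


def analyze_record(record: PVRecord) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: segment, extract and summarize one record."""
    beats = extract_cycle_params(record, segment_cycles(record))
    return beats, summarize_record(beats)
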