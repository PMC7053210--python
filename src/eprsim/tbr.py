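"""Tumor-to-background ratio (TBR) arithmetic for longitudinal imaging.

Works on already-summarized total radiant efficiency (TRE) values, units
(p/sec)/(uW/cm2): per acquisition time, one tumor ROI value and three
equal-area background ROI values.  The TBR at a time point is the tumor
TRE divided by the mean of the three backgrounds; a TBR of 2 is the
conventional threshold for clinically useful contrast.  All analyses stay
at the acquired time points — no interpolation between acquisitions.

A closed-form synthetic time-course generator is included so the
arithmetic can be exercised and tested without animal data: signal is zero
until an onset delay (an off-to-on probe is dark in circulation), rises
with a saturating uptake, and decays exponentially, with the background
clearing faster than the tumor so the TBR keeps growing late in the
series.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "IntensityRecord",
    "TBRSeries",
    "tbr",
    "tbr_series",
    "threshold_crossings",
    "fold_change",
    "synth_timecourse",
    "read_records_csv",
    "write_records_csv",
    "write_tbr_csv",
    "TBRError",
]

#: Default acquisition schedule (hours): frequent early imaging, then daily.
DEFAULT_TIMES = (0.17, 0.5, 1.0, 3.0, 6.0, 9.0, 24.0, 48.0, 72.0, 96.0, 168.0)

RECORD_CSV_HEADER = ["time_h", "tumor_tre", "bg1_tre", "bg2_tre", "bg3_tre"]


class TBRError(ValueError):
    """Undefined ratio or malformed longitudinal series."""


@dataclass(frozen=True)
class IntensityRecord:
    """One acquisition: tumor TRE and exactly three background TREs."""

    time: float
    tumor_tre: float
    bg_tre: tuple[float, float, float]

    def __post_init__(self):
        if len(self.bg_tre) != 3:
            raise TBRError("IntensityRecord: exactly three background values required")
        if self.tumor_tre < 0 or any(b < 0 for b in self.bg_tre):
            raise TBRError("IntensityRecord: intensities must be non-negative")


@dataclass
class TBRSeries:
    """(time, tbr) pairs with the comparison threshold (default 2)."""

    times: np.ndarray
    tbr: np.ndarray
    threshold: float = 2.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.tbr = np.asarray(self.tbr, dtype=float)
        if self.times.shape != self.tbr.shape:
            raise TBRError("TBRSeries: times and tbr must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise TBRError("TBRSeries: times must be strictly increasing")
        if np.any(self.tbr < 0):
            raise TBRError("TBRSeries: tbr values must be non-negative")


def tbr(record: IntensityRecord) -> float:
    """Tumor TRE over the mean of the three background TREs."""
    mean_bg = float(np.mean(record.bg_tre))
    if mean_bg <= 0.0:
        raise TBRError(f"tbr: zero mean background at t={record.time} h; ratio undefined")
    return record.tumor_tre / mean_bg


def tbr_series(records: Sequence[IntensityRecord], threshold: float = 2.0) -> TBRSeries:
    """Per-time TBR for a longitudinal record set.

    Acquisitions where tumor and all backgrounds are exactly zero (probe
    still dark, e.g. during the onset delay) are assigned a TBR of 0 — no
    signal anywhere means no contrast.  Zero background with nonzero tumor
    is an undefined ratio and raises.
    """
    recs = sorted(records, key=lambda r: r.time)
    values = []
    for r in recs:
        if float(np.mean(r.bg_tre)) == 0.0 and r.tumor_tre == 0.0:
            values.append(0.0)
        else:
            values.append(tbr(r))
    return TBRSeries(times=np.array([r.time for r in recs]), tbr=np.array(values),
                     threshold=threshold)


def threshold_crossings(series: TBRSeries) -> tuple[float | None, list[tuple[float, float]]]:
    """First time at/above threshold, and all maximal at/above intervals.

    Intervals are maximal runs of consecutive samples with
    ``tbr >= threshold``, reported as (start_time, end_time) at sample
    resolution; a single qualifying sample yields a zero-length interval.
    """
    if series.times.size == 0:
        raise TBRError("threshold_crossings: empty series")
    above = series.tbr >= series.threshold
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(series.times[start]), float(series.times[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(series.times[start]), float(series.times[-1])))
    first = intervals[0][0] if intervals else None
    return first, intervals


def fold_change(series: Sequence[tuple[float, float]], t_ref: float, t_end: float) -> float:
    """Intensity at ``t_ref`` divided by intensity at ``t_end``.

    Used as a retention indicator, e.g. peak-emission time vs the final
    acquisition.  Both times must be present in the series exactly — there
    is no interpolation — and the end intensity must be positive.
    """
    lookup = {float(t): float(v) for t, v in series}

    def _get(t: float) -> float:
        if float(t) not in lookup:
            raise TBRError(f"fold_change: time {t} h not present in series (no interpolation)")
        return lookup[float(t)]

    ref = _get(t_ref)
    end = _get(t_end)
    if end <= 0.0:
        raise TBRError(f"fold_change: non-positive intensity at t_end={t_end} h")
    return ref / end


def timecourse_closed_form(
    times: np.ndarray,
    uptake_rate: float,
    clearance_rate: float,
    amplitude: float,
    onset_delay: float,
) -> np.ndarray:
    """Noise-free intensity curve A*(1 - exp(-k_up*tau)) * exp(-k_cl*tau).

    ``tau = max(t - onset_delay, 0)``; the curve is exactly zero at and
    before the onset delay.
    """
    t = np.asarray(times, dtype=float)
    tau = np.clip(t - onset_delay, 0.0, None)
    return amplitude * (1.0 - np.exp(-uptake_rate * tau)) * np.exp(-clearance_rate * tau)


def synth_timecourse(
    uptake_rate: float = 0.3,
    clearance_rate_tumor: float = 0.012,
    clearance_rate_bg: float = 0.04,
    amplitude: float = 5e9,
    onset_delay: float = 1.0,
    noise_cv: float = 0.1,
    times: Sequence[float] = DEFAULT_TIMES,
    seed: int = 0,
    bg_amplitude_fraction: float = 0.95,
) -> list[IntensityRecord]:
    """Seed-deterministic synthetic tumor + 3-background TRE time course.

    Tumor and background share the uptake rate and onset delay; the
    background clears faster (``clearance_rate_bg > clearance_rate_tumor``
    by default) and has a slightly smaller amplitude, so the noise-free TBR
    grows monotonically once signal appears.  Each intensity is multiplied
    by independent lognormal noise with coefficient of variation
    ``noise_cv`` (mean 1); ``noise_cv=0`` returns the closed form exactly.
    """
    if uptake_rate <= 0 or clearance_rate_tumor <= 0 or clearance_rate_bg <= 0:
        raise TBRError("synth_timecourse: rates must be positive")
    if noise_cv < 0:
        raise TBRError("synth_timecourse: noise_cv must be >= 0")
    t = np.asarray(times, dtype=float)
    tumor = timecourse_closed_form(t, uptake_rate, clearance_rate_tumor, amplitude, onset_delay)
    bg = timecourse_closed_form(
        t, uptake_rate, clearance_rate_bg, amplitude * bg_amplitude_fraction, onset_delay
    )
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mu = -0.5 * sigma**2
        noise = rng.lognormal(mean=mu, sigma=sigma, size=(t.size, 4))
    else:
        noise = np.ones((t.size, 4))
    records = []
    for i, ti in enumerate(t):
        records.append(IntensityRecord(
            time=float(ti),
            tumor_tre=float(tumor[i] * noise[i, 0]),
            bg_tre=tuple(float(bg[i] * noise[i, j]) for j in (1, 2, 3)),
        ))
    return records


# ---------------------------------------------------------------------------
# CSV plumbing


def read_records_csv(path) -> list[IntensityRecord]:
    """Read ``time_h,tumor_tre,bg1_tre,bg2_tre,bg3_tre`` rows."""
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != RECORD_CSV_HEADER:
            raise TBRError(f"read_records_csv: unexpected header {header} in {path}")
        for row in reader:
            records.append(IntensityRecord(
                time=float(row[0]),
                tumor_tre=float(row[1]),
                bg_tre=(float(row[2]), float(row[3]), float(row[4])),
            ))
    return records


def write_records_csv(records: Sequence[IntensityRecord], path) -> None:
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_CSV_HEADER)
        for r in records:
            writer.writerow([repr(float(r.time)), repr(float(r.tumor_tre)),
                             *(repr(float(b)) for b in r.bg_tre)])


def write_tbr_csv(series: TBRSeries, path) -> None:
    """Write ``time_h,tbr`` rows."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_h", "tbr"])
        for t, v in zip(series.times, series.tbr):
            writer.writerow([repr(float(t)), repr(float(v))])
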