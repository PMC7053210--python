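"""Distribution sampling, contrast summary metrics, and CSV export.

The chart the engine feeds records, every ``sample_cadence`` frames, the
percentage of all administered particles currently in the background FOV,
in the tumor ROI, and already cleared (percentages are of the administered
total, so both curves can decay to zero as clearance completes).  The
summary extracts the contrast phenomenology a surgeon would care about:
when tumor uptake peaks, when the ROI first holds at least as much
fluorophore as the background, and the contrast window during which the
background is fully clear while fluorophore remains in the tumor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import REGION_ROI
from .engine import STATUS_ACTIVE, STATUS_CLEARED, SimulationConfig, SimulationState

__all__ = [
    "DistributionSample",
    "DistributionSeries",
    "SummaryMetrics",
    "make_sample",
    "sample_distribution",
    "summarize",
    "export_csv",
    "read_csv",
    "plot_series",
]

CSV_HEADER = ["frame", "pct_fov", "pct_roi", "pct_cleared", "n_emitting_roi", "n_emitting_fov"]


@dataclass(frozen=True)
class DistributionSample:
    """One chart point: compartment percentages and emitting counts."""

    frame: int
    pct_fov: float
    pct_roi: float
    pct_cleared: float
    n_emitting_roi: int
    n_emitting_fov: int


@dataclass
class DistributionSeries:
    """Ordered chart samples from one run."""

    samples: list[DistributionSample] = field(default_factory=list)
    mode: str | None = None
    n_particles: int | None = None

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.samples], columns=CSV_HEADER)


@dataclass(frozen=True)
class SummaryMetrics:
    """Contrast phenomenology of one distribution series.

    ``crossover_frame`` is the first sample at which the ROI percentage is
    at least the FOV percentage; samples where both are zero (before any
    release, or after everything cleared) never count as a crossover.
    ``contrast_window`` is the first maximal run of samples with the FOV
    fully cleared while fluorophore remains in the ROI.
    ``detect_onset_frame`` is only reported for responsive-mode runs: the
    first sample with at least one switched-on particle in the ROI.
    """

    peak_roi_pct: float
    peak_roi_frame: int
    crossover_frame: int | None
    contrast_window: tuple[int, int] | None
    detect_onset_frame: int | None


def make_sample(state: SimulationState, config: SimulationConfig) -> DistributionSample:
    """Measure the current distribution (no cadence gate)."""
    n = config.n_particles
    active = state.status == STATUS_ACTIVE
    if config.count_epr_as_fov_in_series:
        in_roi = active & (state.region == REGION_ROI)
    else:
        # chart the tumor periphery with the tumor signal instead
        in_roi = active & (state.region >= 1)
    in_fov = active & ~in_roi
    n_cleared = int(np.sum(state.status == STATUS_CLEARED))
    emitting = state.emitting_mask(config.mode)
    scale = 100.0 / n if n > 0 else 0.0
    return DistributionSample(
        frame=state.frame,
        pct_fov=float(np.sum(in_fov)) * scale,
        pct_roi=float(np.sum(in_roi)) * scale,
        pct_cleared=n_cleared * scale,
        n_emitting_roi=int(np.sum(emitting & (state.region == REGION_ROI))),
        n_emitting_fov=int(np.sum(emitting & (state.region != REGION_ROI))),
    )


def sample_distribution(state: SimulationState, config: SimulationConfig) -> DistributionSample | None:
    """A chart sample when the frame is on the sampling cadence, else None."""
    if state.frame % config.sample_cadence != 0:
        return None
    return make_sample(state, config)


def summarize(series: DistributionSeries) -> SummaryMetrics:
    """Single-pass contrast summary; peak ties break to the earliest frame."""
    if len(series) == 0:
        raise ValueError("summarize: empty distribution series")
    peak_pct = -1.0
    peak_frame = series.samples[0].frame
    crossover = None
    detect_onset = None
    window_start = None
    window: tuple[int, int] | None = None
    prev_in_window_frame = None
    for s in series.samples:
        if s.pct_roi > peak_pct:
            peak_pct = s.pct_roi
            peak_frame = s.frame
        nonzero = (s.pct_roi > 0.0) or (s.pct_fov > 0.0)
        if crossover is None and nonzero and s.pct_roi >= s.pct_fov:
            crossover = s.frame
        if detect_onset is None and series.mode == "responsive" and s.n_emitting_roi > 0:
            detect_onset = s.frame
        in_window = s.pct_fov == 0.0 and s.pct_roi > 0.0
        if in_window:
            if window_start is None:
                window_start = s.frame
            prev_in_window_frame = s.frame
        elif window_start is not None and window is None:
            window = (window_start, prev_in_window_frame)
            window_start = None
    if window is None and window_start is not None:
        window = (window_start, prev_in_window_frame)
    return SummaryMetrics(
        peak_roi_pct=peak_pct,
        peak_roi_frame=peak_frame,
        crossover_frame=crossover,
        contrast_window=window,
        detect_onset_frame=detect_onset,
    )


def _fmt(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def export_csv(series: DistributionSeries, path) -> None:
    """Write the series as RFC 4180 CSV (CRLF line endings, header row).

    Floats are written with ``repr`` so a write -> read -> write cycle is
    byte-identical.
    """
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for s in series.samples:
                writer.writerow([
                    s.frame,
                    _fmt(s.pct_fov),
                    _fmt(s.pct_roi),
                    _fmt(s.pct_cleared),
                    s.n_emitting_roi,
                    s.n_emitting_fov,
                ])
    except OSError as exc:
        raise OSError(f"export_csv: cannot write {path}: {exc}") from exc


def read_csv(path) -> DistributionSeries:
    """Read a series previously written by :func:`export_csv`."""
    path = Path(path)
    samples = []
    try:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header != CSV_HEADER:
                raise ValueError(f"read_csv: unexpected header {header} in {path}")
            for row in reader:
                samples.append(DistributionSample(
                    frame=int(row[0]),
                    pct_fov=float(row[1]),
                    pct_roi=float(row[2]),
                    pct_cleared=float(row[3]),
                    n_emitting_roi=int(row[4]),
                    n_emitting_fov=int(row[5]),
                ))
    except OSError as exc:
        raise OSError(f"read_csv: cannot read {path}: {exc}") from exc
    return DistributionSeries(samples=samples)


def plot_series(series: DistributionSeries, path, title: str | None = None) -> None:
    """Line plot of %FOV and %ROI against frame, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = series.to_dataframe()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(df["frame"], df["pct_fov"], label="% FOV", color="tab:blue")
    ax.plot(df["frame"], df["pct_roi"], label="% ROI", color="tab:red")
    ax.set_xlabel("frame")
    ax.set_ylabel("% of administered fluorophore")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
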