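"""Live-cell biosensor time-course processing.

Ingests plate-reader style exports of a ratiometric aspartate biosensor
(green fluorescence of the sensor over a co-expressed nuclear RFP) together
with per-well nuclei counts, and computes normalized ratio traces,
proliferation rates in doublings per day, and descriptors of the
non-monotonic "rebound" shape seen in aspartate traces under SDH inhibition.

Times are in hours throughout; rates are reported in doublings per day
(24 h conversion applied explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HOURS_PER_DAY = 24.0

__all__ = [
    "BiosensorTrace",
    "RateSeries",
    "ReboundDescriptor",
    "normalize_trace",
    "proliferation_rate",
    "windowed_rates",
    "characterize_rebound",
    "read_biosensor_csv",
    "traces_to_frame",
]


@dataclass(frozen=True)
class BiosensorTrace:
    """Per-well biosensor time series.

    ``pretreatment_index`` marks the scan taken immediately before
    treatment; count normalization is anchored there.
    """

    well_id: str
    condition: str
    times: np.ndarray  # hours, strictly increasing
    gfp: np.ndarray  # a.u., >= 0
    rfp: np.ndarray  # a.u., > 0 where a ratio is requested
    nuclei: np.ndarray  # counts >= 0
    pretreatment_index: int = 0
    # populated by normalize_trace
    ratio: np.ndarray | None = field(default=None, compare=False)
    ratio_norm: np.ndarray | None = field(default=None, compare=False)
    nuclei_norm: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("times", "gfp", "rfp", "nuclei"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        if any(len(getattr(self, name)) != n for name in ("gfp", "rfp", "nuclei")):
            raise ValueError(f"well {self.well_id!r}: gfp/rfp/nuclei must match times in length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"well {self.well_id!r}: times must be strictly increasing")
        if np.any(self.gfp < 0) or np.any(self.nuclei < 0):
            raise ValueError(f"well {self.well_id!r}: gfp and nuclei must be non-negative")
        if not (0 <= self.pretreatment_index < n):
            raise ValueError(
                f"well {self.well_id!r}: pretreatment_index {self.pretreatment_index} "
                f"out of range for {n} samples"
            )


@dataclass(frozen=True)
class RateSeries:
    """Per-window proliferation rates (doublings per day, may be negative)."""

    window_starts: np.ndarray  # hours
    rates: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "window_starts", np.asarray(self.window_starts, dtype=float))
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if len(self.window_starts) != len(self.rates):
            raise ValueError("one rate per window required")
        if len(self.window_starts) >= 2 and not np.all(np.diff(self.window_starts) > 0):
            raise ValueError("windows must be ordered and non-overlapping")


@dataclass(frozen=True)
class ReboundDescriptor:
    """Summary of a decline-then-recover trace shape.

    ``rebound_fraction`` is (final - nadir) / (initial - nadir) clipped to
    [0, 1]; ``monotonic`` is True when the fraction falls below the
    classification threshold, in which case the fraction is reported as 0.
    """

    t_nadir: float  # hours
    nadir_value: float
    rebound_fraction: float
    monotonic: bool


def normalize_trace(trace: BiosensorTrace, pretreat_norm: bool = True) -> BiosensorTrace:
    """Compute GFP/RFP ratio and pre-treatment-anchored normalizations.

    The sensor ratio is gfp/rfp per scan.  Nuclei counts are divided by the
    count at the pre-treatment scan.  With ``pretreat_norm`` (default), the
    ratio series is additionally divided by its value at the pre-treatment
    scan so wells with different sensor expression are comparable; the
    operation is invertible and idempotent on already-normalized counts.
    """
    if np.any(trace.rfp <= 0):
        raise ValueError(f"well {trace.well_id!r}: RFP signal must be positive to form a ratio")
    pre = trace.pretreatment_index
    if trace.nuclei[pre] <= 0:
        raise ValueError(f"well {trace.well_id!r}: zero nuclei count at the pre-treatment scan")
    ratio = trace.gfp / trace.rfp
    nuclei_norm = trace.nuclei / trace.nuclei[pre]
    if pretreat_norm:
        if ratio[pre] == 0:
            raise ValueError(f"well {trace.well_id!r}: zero ratio at the pre-treatment scan")
        ratio_norm = ratio / ratio[pre]
    else:
        ratio_norm = ratio.copy()
    return replace(trace, ratio=ratio, ratio_norm=ratio_norm, nuclei_norm=nuclei_norm)


def proliferation_rate(initial_count: float, final_count: float, elapsed_days: float) -> float:
    """Doublings per day: log2(final / initial) / days."""
    if initial_count <= 0 or final_count <= 0:
        raise ValueError("cell counts must be positive")
    if elapsed_days <= 0:
        raise ValueError("elapsed time must be positive")
    return float(np.log2(final_count / initial_count) / elapsed_days)


def windowed_rates(
    trace: BiosensorTrace,
    window_h: float = 6.0,
    regression: bool = False,
) -> RateSeries:
    """Proliferation rate per fixed time window (doublings/day).

    Windows tile the trace starting at the pre-treatment scan.  By default
    each window's rate uses only its first and last sample (the two-point
    doubling formula); ``regression=True`` instead fits log2(counts) against
    time by least squares within the window, which is more robust to count
    noise.
    """
    if window_h <= 0:
        raise ValueError("window must be positive")
    times = trace.times
    counts = trace.nuclei
    t0 = times[trace.pretreatment_index]
    sel = times >= t0
    times, counts = times[sel], counts[sel]
    if len(times) >= 2 and window_h < np.min(np.diff(times)):
        raise ValueError("window shorter than the sampling interval")
    starts, rates = [], []
    n_windows = int(np.ceil((times[-1] - t0) / window_h))
    for k in range(n_windows):
        lo, hi = t0 + k * window_h, t0 + (k + 1) * window_h
        in_win = (times >= lo) & (times <= hi)
        tw, cw = times[in_win], counts[in_win]
        if len(tw) < 2:
            continue
        if np.any(cw <= 0):
            raise ValueError(f"well {trace.well_id!r}: non-positive counts in window at {lo} h")
        if regression:
            days = (tw - tw[0]) / HOURS_PER_DAY
            slope = np.polyfit(days, np.log2(cw), 1)[0]
            rates.append(float(slope))
        else:
            rates.append(proliferation_rate(cw[0], cw[-1], (tw[-1] - tw[0]) / HOURS_PER_DAY))
        starts.append(lo)
    return RateSeries(np.array(starts), np.array(rates))


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge replication."""
    if width <= 1:
        return values.astype(float)
    half = width // 2
    padded = np.pad(values.astype(float), half, mode="edge")
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


def characterize_rebound(
    times: np.ndarray,
    values: np.ndarray,
    smooth_width: int = 3,
    monotonic_threshold: float = 0.05,
) -> ReboundDescriptor:
    """Locate the nadir of a trace and quantify its recovery.

    The series is lightly smoothed (centered moving average, default width
    3 samples) before the global minimum after the first sample is taken as
    the nadir.  The rebound fraction (final - nadir)/(initial - nadir),
    clipped to [0, 1], is 1 for a full return to the starting value and 0
    for a monotonic decline; degenerate flat traces count as monotonic.
    The result is invariant to positive rescaling of the values.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 5:
        raise ValueError("at least 5 samples are required to characterize a rebound")
    if len(times) != len(values):
        raise ValueError("times and values must have equal length")
    smoothed = _moving_average(values, smooth_width)
    idx = 1 + int(np.argmin(smoothed[1:]))
    nadir = float(smoothed[idx])
    initial, final = float(smoothed[0]), float(smoothed[-1])
    depth = initial - nadir
    # a dip below ~1e-9 of the trace scale is indistinguishable from a flat
    # series (degenerate case: initial == nadir reads as no rebound)
    if depth <= 1e-9 * np.max(np.abs(smoothed)):
        fraction = 0.0
    else:
        fraction = float(np.clip((final - nadir) / depth, 0.0, 1.0))
    monotonic = fraction < monotonic_threshold
    return ReboundDescriptor(
        t_nadir=float(times[idx]),
        nadir_value=nadir,
        rebound_fraction=0.0 if monotonic else fraction,
        monotonic=monotonic,
    )


# ---------------------------------------------------------------------------
# CSV interchange

REQUIRED_COLUMNS = ["well_id", "condition", "time_h", "gfp", "rfp", "nuclei"]


def read_biosensor_csv(path) -> list[BiosensorTrace]:
    """Read one trace per well from a long-format CSV export."""
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"biosensor CSV missing columns: {missing}")
    traces = []
    for well, grp in frame.groupby("well_id", sort=False):
        grp = grp.sort_values("time_h")
        traces.append(
            BiosensorTrace(
                well_id=str(well),
                condition=str(grp["condition"].iloc[0]),
                times=grp["time_h"].to_numpy(),
                gfp=grp["gfp"].to_numpy(),
                rfp=grp["rfp"].to_numpy(),
                nuclei=grp["nuclei"].to_numpy(),
                pretreatment_index=int(grp["pretreatment_index"].iloc[0])
                if "pretreatment_index" in grp.columns
                else 0,
            )
        )
    return traces


def traces_to_frame(traces: list[BiosensorTrace]) -> pd.DataFrame:
    """Long-format frame mirroring the input schema plus derived columns."""
    rows = []
    for tr in traces:
        for i in range(len(tr.times)):
            rows.append(
                {
                    "well_id": tr.well_id,
                    "condition": tr.condition,
                    "time_h": tr.times[i],
                    "gfp": tr.gfp[i],
                    "rfp": tr.rfp[i],
                    "nuclei": tr.nuclei[i],
                    "pretreatment_index": tr.pretreatment_index,
                    "ratio": None if tr.ratio is None else tr.ratio[i],
                    "ratio_norm": None if tr.ratio_norm is None else tr.ratio_norm[i],
                    "nuclei_norm": None if tr.nuclei_norm is None else tr.nuclei_norm[i],
                }
            )
    return pd.DataFrame(rows)
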