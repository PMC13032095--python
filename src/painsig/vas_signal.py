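"""Continuous VAS trace handling: validation, I/O, denoising, epoching.

A trace is the continuous 0-100 pain rating recorded while one 30-s tonic
heat stimulus is delivered.  Time is expressed in seconds relative to the
onset of the analysis window (plateau onset); the window is split into three
10-s epochs A [0, 10), B [10, 20) and C [20, 30] whose arithmetic means feed
every downstream index.  Epoch boundaries are half-open on the left two
epochs and closed at 30 s, so a sample at exactly t = 10 belongs to epoch B
and a sample at exactly t = 30 belongs to epoch C.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateWindowError,
    RejectedTraceError,
    SequenceMismatchError,
    TraceParseError,
)
from .protocol import StimulusProtocol

EPOCHS = ("A", "B", "C")
#: (closed left, open/closed right) bounds of the three epochs in seconds.
EPOCH_BOUNDS = {"A": (0.0, 10.0), "B": (10.0, 20.0), "C": (20.0, 30.0)}

TRACE_COLUMNS = ["participant_id", "stimulus_index", "target_temp_c", "time_s", "vas"]


@dataclass
class VASTrace:
    """One stimulus presentation's continuous rating signal."""

    participant_id: str
    stimulus_index: int
    target_temp_c: float
    sample_times_s: np.ndarray
    vas_values: np.ndarray
    window_onset_s: float = 0.0  # ramp duration preceding the analysis window

    def __post_init__(self):
        self.sample_times_s = np.asarray(self.sample_times_s, dtype=float)
        self.vas_values = np.asarray(self.vas_values, dtype=float)
        self.validate()

    def validate(self) -> None:
        t, v = self.sample_times_s, self.vas_values
        if t.size == 0:
            raise TraceParseError(
                f"{self._tag()}: empty trace"
            )
        if t.size != v.size:
            raise TraceParseError(f"{self._tag()}: time/value length mismatch")
        if np.any(np.diff(t) < 0):
            raise TraceParseError(f"{self._tag()}: non-monotone sample times")
        if t[0] < 0 or t[-1] > 30.0 + 1e-9:
            raise TraceParseError(f"{self._tag()}: sample times outside [0, 30] s")
        if np.any(v < 0) or np.any(v > 100):
            raise TraceParseError(f"{self._tag()}: VAS values outside [0, 100]")

    def _tag(self) -> str:
        return f"participant {self.participant_id}, stimulus {self.stimulus_index}"

    @property
    def duration_s(self) -> float:
        return float(self.sample_times_s[-1] - self.sample_times_s[0])


@dataclass(frozen=True)
class EpochMeans:
    """Per-stimulus epoch summary consumed by the modulation indexes."""

    participant_id: str
    stimulus_index: int
    target_temp_c: float
    mean_a: float
    mean_b: float
    mean_c: float
    preceding_temp_c: float | None


def in_epoch(times: np.ndarray, epoch: str) -> np.ndarray:
    """Boolean mask of samples belonging to an epoch (A/B half-open, C closed)."""
    lo, hi = EPOCH_BOUNDS[epoch]
    if epoch == "C":
        return (times >= lo) & (times <= hi + 1e-9)
    return (times >= lo) & (times < hi)


def epoch_means(trace: VASTrace, protocol: StimulusProtocol) -> EpochMeans:
    """Arithmetic mean of the samples in each 10-s epoch.

    Raises
    ------
    RejectedTraceError
        If any epoch contains no samples; the stimulus is meant to be dropped
        and reported by the caller, not interpolated.
    """
    t, v = trace.sample_times_s, trace.vas_values
    means = {}
    for epoch in EPOCHS:
        mask = in_epoch(t, epoch)
        if not mask.any():
            raise RejectedTraceError(trace.participant_id, trace.stimulus_index, epoch)
        means[epoch] = float(v[mask].mean())
    return EpochMeans(
        participant_id=trace.participant_id,
        stimulus_index=trace.stimulus_index,
        target_temp_c=trace.target_temp_c,
        mean_a=means["A"],
        mean_b=means["B"],
        mean_c=means["C"],
        preceding_temp_c=protocol.preceding_temp(trace.stimulus_index),
    )


def epoch_means_table(
    traces: list[VASTrace], protocol: StimulusProtocol
) -> tuple[pd.DataFrame, list[dict]]:
    """Epoch all traces; rejected stimuli are reported, not fatal.

    Returns the long epoch-means table and a list of rejection records
    (participant_id, stimulus_index, epoch).
    """
    rows, rejected = [], []
    for trace in traces:
        try:
            em = epoch_means(trace, protocol)
        except RejectedTraceError as err:
            rejected.append(
                {
                    "participant_id": err.participant_id,
                    "stimulus_index": err.stimulus_index,
                    "empty_epoch": err.epoch,
                }
            )
            continue
        rows.append(
            {
                "participant_id": em.participant_id,
                "stimulus_index": em.stimulus_index,
                "target_temp_c": em.target_temp_c,
                "preceding_temp_c": em.preceding_temp_c,
                "mean_A": em.mean_a,
                "mean_B": em.mean_b,
                "mean_C": em.mean_c,
            }
        )
    cols = [
        "participant_id", "stimulus_index", "target_temp_c",
        "preceding_temp_c", "mean_A", "mean_B", "mean_C",
    ]
    return pd.DataFrame(rows, columns=cols), rejected


def preprocess(trace: VASTrace, window_s: float = 1.0, target_rate_hz: float = 10.0) -> VASTrace:
    """Denoise a trace: centered moving average, then decimation.

    The moving average uses a window of ``window_s`` seconds (shrunk
    symmetrically at the edges, so a constant trace is a fixed point and the
    output never leaves the data's min/max envelope), after which the trace is
    decimated to ``target_rate_hz`` by subsampling.  Because epoch statistics
    are 10-s means, this preserves them up to edge effects smaller than one
    window at each boundary.
    """
    if window_s <= 0:
        raise DegenerateWindowError("window_s must be positive")
    t, v = trace.sample_times_s, trace.vas_values
    span = t[-1] - t[0]
    if t.size > 1 and window_s > span:
        raise DegenerateWindowError(
            f"window ({window_s} s) longer than trace span ({span:.3f} s)"
        )
    if t.size > 1:
        dt = float(np.median(np.diff(t)))
    else:
        dt = window_s
    w = max(1, int(round(window_s / dt)) | 1) if dt > 0 else 1  # odd window
    smoothed = (
        pd.Series(v).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )
    step = max(1, int(round((1.0 / target_rate_hz) / dt))) if dt > 0 else 1
    return VASTrace(
        participant_id=trace.participant_id,
        stimulus_index=trace.stimulus_index,
        target_temp_c=trace.target_temp_c,
        sample_times_s=t[::step].copy(),
        vas_values=smoothed[::step],
        window_onset_s=trace.window_onset_s,
    )


def write_traces(traces: list[VASTrace], path) -> None:
    """Serialize traces as a long CSV (participant, stimulus, temp, time, vas)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "stimulus_index": tr.stimulus_index,
                    "target_temp_c": tr.target_temp_c,
                    "time_s": tr.sample_times_s,
                    "vas": tr.vas_values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_traces(path, protocol: StimulusProtocol) -> list[VASTrace]:
    """Read and validate a long-format trace CSV.

    Every (participant, stimulus) group becomes one :class:`VASTrace`.  The
    group's temperature must match the protocol sequence at its stimulus
    index; rows with out-of-range VAS or non-monotone time raise a parse
    error naming the offending group.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise TraceParseError(f"{path}: empty trace file")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns {missing}")
    traces = []
    for (pid, sidx), grp in df.groupby(["participant_id", "stimulus_index"], sort=True):
        sidx = int(sidx)
        temps = grp["target_temp_c"].unique()
        if len(temps) != 1:
            raise TraceParseError(
                f"participant {pid}, stimulus {sidx}: inconsistent temperatures {temps}"
            )
        temp = float(temps[0])
        expected = protocol.temperature_at(sidx)
        if temp != expected:
            raise SequenceMismatchError(
                f"participant {pid}, stimulus {sidx}: temperature {temp} degC "
                f"does not match protocol sequence ({expected} degC expected)"
            )
        traces.append(
            VASTrace(
                participant_id=str(pid),
                stimulus_index=sidx,
                target_temp_c=temp,
                sample_times_s=grp["time_s"].to_numpy(dtype=float),
                vas_values=grp["vas"].to_numpy(dtype=float),
            )
        )
    return traces
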