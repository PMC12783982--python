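"""Preprocessing from raw extracellular traces to putative spike event times.

Chain: common average referencing → zero-phase band-pass (300–5000 Hz,
4th-order Butterworth) → amplitude-threshold event detection at
``threshold_factor ×`` a median-based noise estimate of the preprocessed
signal.  Spike sorting into single-units is out of scope; synthetic sessions
are born sorted, and this module exists to validate the preprocessing chain.

The noise estimator "median deviation of the absolute values" is read
literally as ``median(|x|)`` (``median_abs``); the conventional MAD-derived
estimate of a Gaussian SD, ``median(|x|)/0.6745``, is available as
``scaled_median_abs``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass
class FilterSpec:
    low_hz: float = 300.0
    high_hz: float = 5000.0
    order: int = 4

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ValueError("high_hz must be below the Nyquist frequency fs/2")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class DetectionSpec:
    threshold_factor: float = 7.5
    noise_estimator: str = "median_abs"  # or scaled_median_abs
    refractory_window: float = 0.001
    polarity: str = "negative"  # negative | positive | both

    def validate(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be > 0")
        if self.refractory_window < 0:
            raise ValueError("refractory_window must be >= 0")
        if self.noise_estimator not in ("median_abs", "scaled_median_abs"):
            raise ValueError(f"unknown noise estimator {self.noise_estimator!r}")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def common_average_reference(traces: np.ndarray) -> np.ndarray:
    """Subtract the per-sample mean across channels from every channel."""
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("common average referencing needs >= 2 channels")
    return traces - traces.mean(axis=0, keepdims=True)


def bandpass_filter(trace: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass of one trace."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    sos = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def noise_estimate(trace: np.ndarray, estimator: str = "median_abs") -> float:
    m = float(np.median(np.abs(trace)))
    if estimator == "scaled_median_abs":
        m /= 0.6745
    return m


def detect_spikes(trace: np.ndarray, fs: float, spec: DetectionSpec | None = None) -> np.ndarray:
    """Threshold-crossing event times (s) on a preprocessed single trace.

    Threshold θ = threshold_factor × noise_estimate(|trace|).  Crossings of
    the same polarity closer than the refractory window collapse to the
    sample of extreme amplitude.  An all-zero trace yields no events (the
    noise estimate is 0), by design rather than as an error.
    """
    spec = spec or DetectionSpec()
    spec.validate()
    trace = np.asarray(trace, dtype=float)
    theta = spec.threshold_factor * noise_estimate(trace, spec.noise_estimator)
    if theta == 0:
        return np.empty(0)
    if spec.polarity == "negative":
        score = -trace
    elif spec.polarity == "positive":
        score = trace
    else:
        score = np.abs(trace)
    above = score > theta
    if not above.any():
        return np.empty(0)
    # contiguous supra-threshold segments -> extremum sample per segment
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    segments = np.split(idx, breaks + 1)
    peaks = np.array([seg[np.argmax(score[seg])] for seg in segments])
    # collapse events closer than the refractory window to the larger one
    min_gap = int(round(spec.refractory_window * fs))
    if min_gap > 0 and peaks.size > 1:
        kept = [peaks[0]]
        for p in peaks[1:]:
            if p - kept[-1] < min_gap:
                if score[p] > score[kept[-1]]:
                    kept[-1] = p
            else:
                kept.append(p)
        peaks = np.array(kept)
    return peaks / fs


def filter_units_by_rate(units, duration: float, min_rate: float = 0.5):
    """Retain units whose mean firing rate over the session exceeds min_rate."""
    if duration <= 0:
        raise ValueError("session duration must be > 0")
    return [u for u in units if u.spike_times.size / duration > min_rate]


def dedup_units(sessions):
    """Drop re-sampled units across temporally ordered sessions.

    For each tetrode, only units from the first session in which that
    tetrode appears are retained (later sessions likely resample the same
    cells).  Sessions must be given in recording order.
    """
    seen_tetrodes: set[tuple[str, int]] = set()
    out = []
    for s in sessions:
        kept = []
        session_tets = set()
        for u in s.units:
            if u.tetrode_id is None:
                raise ValueError(f"unit {u.unit_id} lacks a tetrode_id")
            key = (s.meta.get("mouse_id", s.session_id.split("-seed")[0]), u.tetrode_id)
            session_tets.add(key)
            if key not in seen_tetrodes:
                kept.append(u)
        seen_tetrodes |= session_tets
        out.append(
            type(s)(
                session_id=s.session_id,
                genotype=s.genotype,
                region=s.region,
                units=kept,
                trials=s.trials,
                duration=s.duration,
                meta=s.meta,
            )
        )
    return out
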