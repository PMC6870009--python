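"""Paired-click ERP preprocessing and P50 sensory-gating measures.

The paired-click paradigm presents two identical clicks (S1 at t=0, S2 at
+500 ms).  The P50 is scored as the maximum positive deflection 30-90 ms
after each click on a small vertex-channel average; gating is summarised by
the S1-S2 amplitude difference and the S2/S1 ratio.  Three condition
segments (S1, S2, and the pointwise S1-S2 gating response) feed the
source-reconstruction and connectivity stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "EpochSet",
    "P50Measures",
    "ConditionSegments",
    "preprocess",
    "average_erp",
    "detect_p50",
    "gating_measures",
    "extract_segments",
    "average_reference",
]

#: scoring window relative to each click onset, ms (endpoints inclusive)
P50_WINDOW_MS = (30.0, 90.0)


@dataclass
class EpochSet:
    """Per-subject epoched multichannel ERP data.

    Parameters
    ----------
    data
        ``trials x channels x samples`` array in microvolts.
    fs
        Sampling rate in Hz.
    t0_idx
        Sample index of the S1 click onset within each epoch.
    s2_offset_ms
        Latency of the S2 click relative to S1, in ms (paradigm constant,
        500 ms).
    ch_names
        Channel labels, one per channel.
    subject
        Subject identifier used in error messages and exports.
    """

    data: np.ndarray
    fs: float
    t0_idx: int
    s2_offset_ms: float = 500.0
    ch_names: list[str] = field(default_factory=list)
    subject: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n_samples = self.data.shape[2]
        if not 0 <= self.t0_idx < n_samples:
            raise ValueError("t0_idx outside the epoch")
        if not self.ch_names:
            self.ch_names = [f"EEG{i:03d}" for i in range(self.data.shape[1])]
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length does not match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to the S1 onset."""
        return (np.arange(self.n_samples) - self.t0_idx) * 1000.0 / self.fs


@dataclass
class P50Measures:
    """P50 amplitudes, latencies and gating summary for one subject."""

    s1_amp: float
    s1_latency: float
    s2_amp: float
    s2_latency: float
    diff: float
    ratio: float | None
    valid: bool


@dataclass
class ConditionSegments:
    """30-90 ms analysis segments for the S1, S2 and gating conditions."""

    s1_seg: np.ndarray
    s2_seg: np.ndarray
    gating_seg: np.ndarray
    fs: float
    conditions: tuple[str, str, str] = ("S1", "S2", "S1-S2")

    def __post_init__(self) -> None:
        if not (self.s1_seg.shape == self.s2_seg.shape == self.gating_seg.shape):
            raise ValueError("condition segments must share one shape")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"S1": self.s1_seg, "S2": self.s2_seg, "S1-S2": self.gating_seg}


def average_reference(data: np.ndarray) -> np.ndarray:
    """Re-reference to the channel average (channel axis is the penultimate)."""
    return data - data.mean(axis=-2, keepdims=True)


def _bandpass_sos(band: tuple[float, float], fs: float) -> np.ndarray:
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, fs/2)")
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def preprocess(
    raw_epochs: EpochSet,
    band: tuple[float, float] = (1.0, 40.0),
    reject_threshold_uv: float = 100.0,
) -> EpochSet:
    """Average-reference, band-pass filter, baseline-correct and reject trials.

    Filtering is zero-phase (forward-backward second-order sections, order-4
    equivalent).  The baseline is the mean of the pre-stimulus window
    (-200...0 ms before S1).  Trials whose peak absolute amplitude exceeds
    ``reject_threshold_uv`` after filtering are dropped.

    Raises
    ------
    ValueError
        If every trial is rejected (names the subject) or the band is
        invalid.
    """
    sos = _bandpass_sos(band, raw_epochs.fs)
    data = average_reference(np.asarray(raw_epochs.data, dtype=np.float64))

    # reject on the unfiltered data: brief large artifacts would otherwise be
    # smeared below threshold by the band-pass
    peak = np.abs(data).max(axis=(1, 2))
    keep = peak <= reject_threshold_uv
    if not keep.any():
        raise ValueError(
            f"all {raw_epochs.n_trials} trials rejected for subject "
            f"{raw_epochs.subject or '<unnamed>'} at {reject_threshold_uv} uV"
        )
    data = signal.sosfiltfilt(sos, data[keep], axis=-1)

    n_pre = min(int(round(0.2 * raw_epochs.fs)), raw_epochs.t0_idx)
    base = data[:, :, raw_epochs.t0_idx - n_pre : raw_epochs.t0_idx]
    if base.shape[-1] > 0:
        data = data - base.mean(axis=-1, keepdims=True)

    return replace(raw_epochs, data=np.ascontiguousarray(data))


def average_erp(epochs: EpochSet) -> np.ndarray:
    """Arithmetic mean over trials -> ``channels x samples`` waveform."""
    if epochs.n_trials < 1:
        raise ValueError("need at least one retained trial")
    return epochs.data.mean(axis=0)


def detect_p50(
    waveform: np.ndarray,
    onset_ms: float,
    fs: float,
    channel_subset: np.ndarray | list[int] | None = None,
    t0_idx: int = 0,
) -> tuple[float, float]:
    """Maximum positive peak in the 30-90 ms window after a click onset.

    Parameters
    ----------
    waveform
        ``channels x samples`` (or 1-D) mean waveform.
    onset_ms
        Click onset in ms relative to the sample at ``t0_idx`` (0 for S1,
        500 for S2).
    channel_subset
        Channel indices averaged before peak picking; ``None`` averages all.

    Returns
    -------
    (amplitude, latency)
        Peak amplitude in microvolts and latency in ms relative to the click
        onset.  Ties break toward the earliest latency.
    """
    w = np.atleast_2d(np.asarray(waveform, dtype=np.float64))
    trace = w.mean(axis=0) if channel_subset is None else w[list(channel_subset)].mean(axis=0)

    lo_ms, hi_ms = P50_WINDOW_MS
    i0 = t0_idx + int(round((onset_ms + lo_ms) * fs / 1000.0))
    i1 = t0_idx + int(round((onset_ms + hi_ms) * fs / 1000.0))
    if i0 < 0 or i1 >= trace.size:
        raise ValueError("P50 window falls outside the waveform")
    window = trace[i0 : i1 + 1]
    peak_idx = int(np.argmax(window))  # argmax returns the first maximum
    amp = float(window[peak_idx])
    latency = lo_ms + peak_idx * 1000.0 / fs
    return amp, latency


def gating_measures(
    s1: tuple[float, float],
    s2: tuple[float, float],
    min_s1_uv: float = 0.5,
) -> P50Measures:
    """Gating difference and ratio from the S1 and S2 peak measures.

    Subjects whose S1 amplitude falls below ``min_s1_uv`` are flagged
    ``valid=False`` (excluded from group statistics but retained).  The
    ratio is undefined (``None``) when the S1 amplitude is not positive.
    """
    s1_amp, s1_lat = s1
    s2_amp, s2_lat = s2
    if not (np.isfinite(s1_amp) and np.isfinite(s2_amp)):
        raise ValueError("amplitudes must be finite")
    ratio = s2_amp / s1_amp if s1_amp > 0 else None
    return P50Measures(
        s1_amp=float(s1_amp),
        s1_latency=float(s1_lat),
        s2_amp=float(s2_amp),
        s2_latency=float(s2_lat),
        diff=float(s1_amp - s2_amp),
        ratio=ratio,
        valid=bool(s1_amp >= min_s1_uv),
    )


def extract_segments(
    avg: np.ndarray,
    fs: float,
    t0_idx: int,
    s2_offset_ms: float = 500.0,
) -> ConditionSegments:
    """Cut the 30-90 ms S1 and S2 windows and form the gating segment.

    Window endpoints are inclusive (61 samples at 1000 Hz).  The gating
    segment is the pointwise difference S1 - S2.
    """
    avg = np.atleast_2d(np.asarray(avg, dtype=np.float64))
    lo_ms, hi_ms = P50_WINDOW_MS

    def cut(onset_ms: float) -> np.ndarray:
        i0 = t0_idx + int(round((onset_ms + lo_ms) * fs / 1000.0))
        i1 = t0_idx + int(round((onset_ms + hi_ms) * fs / 1000.0))
        if i0 < 0 or i1 >= avg.shape[1]:
            raise ValueError("segment window falls outside the waveform")
        return avg[:, i0 : i1 + 1].copy()

    s1_seg = cut(0.0)
    s2_seg = cut(s2_offset_ms)
    if s1_seg.shape != s2_seg.shape:
        raise ValueError("S1 and S2 segments differ in length")
    return ConditionSegments(s1_seg=s1_seg, s2_seg=s2_seg, gating_seg=s1_seg - s2_seg, fs=fs)


def measure_subject(
    epochs: EpochSet,
    band: tuple[float, float] = (1.0, 40.0),
    reject_threshold_uv: float = 100.0,
    channel_subset: list[int] | None = None,
    min_s1_uv: float = 0.5,
) -> tuple[P50Measures, ConditionSegments, np.ndarray]:
    """Full sensor-level ERP stage for one subject.

    Returns the gating measures, the three condition segments and the
    trial-averaged waveform.
    """
    clean = preprocess(epochs, band=band, reject_threshold_uv=reject_threshold_uv)
    if clean.n_trials < epochs.n_trials:
        warnings.warn(
            f"subject {epochs.subject or '<unnamed>'}: rejected "
            f"{epochs.n_trials - clean.n_trials}/{epochs.n_trials} trials",
            stacklevel=2,
        )
    avg = average_erp(clean)
    s1 = detect_p50(avg, 0.0, clean.fs, channel_subset, clean.t0_idx)
    s2 = detect_p50(avg, clean.s2_offset_ms, clean.fs, channel_subset, clean.t0_idx)
    measures = gating_measures(s1, s2, min_s1_uv=min_s1_uv)
    segments = extract_segments(avg, clean.fs, clean.t0_idx, clean.s2_offset_ms)
    return measures, segments, avg
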