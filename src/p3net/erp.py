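"""Task-EEG preprocessing and P3 amplitude/latency extraction.

Processing chain for oddball recordings: average re-reference, 0.5-6 Hz
zero-phase band-pass, segmentation into stimulus-locked epochs
(-200..800 ms), baseline correction (-200..0 ms), amplitude-threshold
artifact rejection (+/-75 uV on all scalp channels), condition-wise
averaging, and peak-centred P3 measurement.

The P3 is measured per channel at the five centro-parietal electrodes
(CPz, CP1, CP2, Cz, Pz): the peak is the maximum of the target ERP in the
300-500 ms post-stimulus search window (earliest sample on exact ties),
latency is the peak time, and amplitude is the mean over peak +/- 50 ms
inclusive (51 samples at 500 Hz).  The subject-level measure is the mean of
the five per-channel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .io import Recording, validate_events

__all__ = [
    "EpochSet",
    "P3Measure",
    "P3_CHANNELS",
    "rereference_average",
    "bandpass",
    "epoch",
    "baseline_correct",
    "reject_artifacts",
    "average_erp",
    "extract_p3",
]

P3_CHANNELS: tuple[str, ...] = ("CPz", "CP1", "CP2", "Cz", "Pz")


@dataclass
class EpochSet:
    """Trial-segmented EEG with condition labels and a rejection mask."""

    epochs: np.ndarray            # (n_trials, n_channels, n_samples) uV
    window_ms: tuple[float, float]
    condition: np.ndarray         # per-trial label
    kept: np.ndarray              # per-trial bool
    fs: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.condition = np.asarray(self.condition)
        self.kept = np.asarray(self.kept, dtype=bool)
        n = self.epochs.shape[0]
        if len(self.condition) != n or len(self.kept) != n:
            raise ValueError("condition/kept length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def times_ms(self) -> np.ndarray:
        """Per-sample time in ms relative to stimulus onset."""
        n = self.epochs.shape[2]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.fs


@dataclass
class P3Measure:
    """Per-subject P3 amplitude (uV) and latency (ms)."""

    amplitude: float
    latency: float
    per_channel: dict[str, tuple[float, float]]


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("average re-referencing needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data=data, fs=rec.fs, labels=list(rec.labels),
                     meta={**rec.meta, "reference": "average"})


def bandpass(rec: Recording, lo_hz: float, hi_hz: float) -> Recording:
    """Zero-phase (forward-backward) 4th-order Butterworth band-pass."""
    if not 0 < lo_hz < hi_hz < rec.fs / 2:
        raise ValueError(
            f"invalid band ({lo_hz}, {hi_hz}) Hz for fs={rec.fs}"
        )
    sos = butter(4, [lo_hz, hi_hz], btype="band", fs=rec.fs, output="sos")
    data = np.ascontiguousarray(rec.data)
    if data.dtype == np.float32:
        sos = sos.astype(np.float32)
    filtered = sosfiltfilt(sos, data, axis=-1)
    return Recording(data=filtered, fs=rec.fs, labels=list(rec.labels),
                     meta={**rec.meta, "band_hz": (lo_hz, hi_hz)})


def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def epoch(rec: Recording, events: pd.DataFrame,
          window_ms: tuple[float, float] = (-200.0, 800.0)) -> EpochSet:
    """Cut stimulus-locked epochs (half-open sample windows).

    Trials whose window would leave the recording are kept in the trial
    count but zero-filled and flagged ``kept=False``.
    """
    validate_events(events)
    lo = _ms_to_samples(window_ms[0], rec.fs)
    hi = _ms_to_samples(window_ms[1], rec.fs)
    n_samp = hi - lo
    onsets = events["onset_sample"].to_numpy()
    n_trials = len(onsets)
    out = np.zeros((n_trials, rec.n_channels, n_samp), dtype=rec.data.dtype)
    kept = np.ones(n_trials, dtype=bool)
    dropped = []
    for t, onset in enumerate(onsets):
        a, b = onset + lo, onset + hi
        if a < 0 or b > rec.n_samples:
            kept[t] = False
            dropped.append(t)
            continue
        out[t] = rec.data[:, a:b]
    meta = {"window_ms": tuple(window_ms)}
    if dropped:
        import warnings

        warnings.warn(
            f"dropped {len(dropped)} trial(s) too close to the recording "
            f"edge: {dropped}", stacklevel=2,
        )
        meta["edge_dropped_trials"] = dropped
    return EpochSet(epochs=out, window_ms=tuple(window_ms),
                    condition=events["label"].to_numpy(), kept=kept,
                    fs=rec.fs, labels=list(rec.labels), meta=meta)


def baseline_correct(eps: EpochSet,
                     base_window_ms: tuple[float, float] = (-200.0, 0.0)
                     ) -> EpochSet:
    """Subtract the per-trial/channel mean over the baseline window."""
    times = eps.times_ms()
    mask = (times >= base_window_ms[0]) & (times < base_window_ms[1])
    if not mask.any():
        raise ValueError(
            f"baseline window {base_window_ms} ms lies outside the epoch "
            f"window {eps.window_ms} ms"
        )
    base = eps.epochs[:, :, mask].mean(axis=-1, keepdims=True)
    return EpochSet(epochs=eps.epochs - base, window_ms=eps.window_ms,
                    condition=eps.condition, kept=eps.kept.copy(),
                    fs=eps.fs, labels=list(eps.labels),
                    meta={**eps.meta, "baseline_ms": tuple(base_window_ms)})


def reject_artifacts(eps: EpochSet, threshold_uv: float = 75.0) -> EpochSet:
    """Flag trials with any sample beyond +/-``threshold_uv`` on any channel."""
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    peak = np.abs(eps.epochs).max(axis=(1, 2))
    kept = eps.kept & (peak <= threshold_uv)
    rejected = sorted(set(np.flatnonzero(~kept)) - set(np.flatnonzero(~eps.kept)))
    import logging

    logging.getLogger(__name__).info(
        "artifact rejection at +/-%g uV: rejected trials %s",
        threshold_uv, rejected,
    )
    return EpochSet(epochs=eps.epochs, window_ms=eps.window_ms,
                    condition=eps.condition, kept=kept, fs=eps.fs,
                    labels=list(eps.labels),
                    meta={**eps.meta, "reject_threshold_uv": threshold_uv,
                          "rejected_trials": [int(t) for t in rejected]})


def average_erp(eps: EpochSet, condition: str) -> np.ndarray:
    """Pointwise mean over kept trials of one condition (channels x samples)."""
    sel = eps.kept & (eps.condition == condition)
    if not sel.any():
        raise ValueError(f"no kept trials with condition {condition!r}")
    return eps.epochs[sel].mean(axis=0)


def extract_p3(erp: np.ndarray, labels, fs: float,
               window_ms: tuple[float, float] = (-200.0, 800.0),
               channels=P3_CHANNELS,
               search_ms: tuple[float, float] = (300.0, 500.0),
               half_width_ms: float = 50.0) -> P3Measure:
    """Peak-centred P3 measurement on an averaged target ERP.

    Per channel the peak is the ERP maximum within ``search_ms``
    post-stimulus (earliest sample on ties); latency is the peak time and
    amplitude the mean over ``peak +/- half_width_ms`` inclusive.  The
    subject-level amplitude/latency are the means across ``channels``.
    """
    erp = np.asarray(erp)
    labels = list(labels)
    missing = [c for c in channels if c not in labels]
    if missing:
        raise KeyError(f"channel(s) {missing} absent from ERP")
    hw = _ms_to_samples(half_width_ms, fs)
    lo_needed = search_ms[0] - half_width_ms
    hi_needed = search_ms[1] + half_width_ms
    if window_ms[0] > lo_needed or window_ms[1] < hi_needed:
        raise ValueError(
            f"epoch window {window_ms} ms cannot cover the measurement "
            f"window [{lo_needed}, {hi_needed}] ms"
        )
    n = erp.shape[1]
    times = window_ms[0] + np.arange(n) * 1000.0 / fs
    search = np.flatnonzero((times >= search_ms[0]) & (times <= search_ms[1]))
    per_channel: dict[str, tuple[float, float]] = {}
    for ch in channels:
        wave = erp[labels.index(ch)]
        peak_rel = int(np.argmax(wave[search]))  # argmax -> earliest tie
        peak = search[peak_rel]
        a, b = peak - hw, peak + hw + 1
        if a < 0 or b > n:
            raise ValueError(
                f"peak +/- {half_width_ms} ms window extends past the epoch"
            )
        per_channel[ch] = (float(wave[a:b].mean()), float(times[peak]))
    amps = [v[0] for v in per_channel.values()]
    lats = [v[1] for v in per_channel.values()]
    return P3Measure(amplitude=float(np.mean(amps)),
                     latency=float(np.mean(lats)),
                     per_channel=per_channel)
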