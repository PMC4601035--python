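"""Synthetic multi-subject EEG cohorts with known ground truth.

Each subject gets an eyes-closed resting recording and an oddball task
recording on a 21-channel 10-20 montage at 500 Hz.  Every channel mixes
*shared* narrowband oscillators (an ~10 Hz alpha and an ~6 Hz theta
component, identical across channels) with *channel-private* 1/f pink
noise; the shared-variance fraction equals the subject's latent efficiency,
so expected pairwise coherence — and with it MFC and the efficiency
indexes — increases monotonically with the latent score.

The task recording follows the oddball trial timeline (250 ms cue, 500 ms
fixation cross, 500 ms stimulus, 1000 ms break); targets are assigned by
exact-count randomization (``round(n_trials * target_prob)`` targets,
shuffled) and carry an added centro-parietal P3 bump (half-cosine, peak
``true_amp`` uV at ``true_lat`` ms post-stimulus, spatial weights maximal
at CPz/Pz).  A configurable fraction of trials / resting 10-s spans gets a
planted high-amplitude artifact burst (2 Hz, 150 uV, 0.5 s, frontal
channels) that reliably crosses the rejection thresholds even after
band-pass filtering.

Across subjects, ``true_amp`` is an affine function of latent efficiency
plus Gaussian noise, calibrated so the population correlation between the
two equals ``coupling_rho`` — the programmable ground-truth coupling the
analysis pipeline is asked to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from .io import DEFAULT_CHANNELS, Recording

__all__ = [
    "CohortSpec",
    "SubjectTruth",
    "P3_SPATIAL_WEIGHTS",
    "p3_template",
    "simulate_resting",
    "simulate_task",
    "simulate_cohort",
    "iter_cohort",
    "truth_table",
]

# oddball trial timeline (ms)
CUE_MS = 250.0
FIX_MS = 500.0
STIM_MS = 500.0
BREAK_MS = 1000.0
TRIAL_MS = CUE_MS + FIX_MS + STIM_MS + BREAK_MS   # 2250 ms
STIM_OFFSET_MS = CUE_MS + FIX_MS                   # stimulus onset in trial
LEAD_S = 1.0                                       # lead-in / tail padding

# fixed P3 scalp profile over the default montage: centro-parietal maximum,
# decaying with 10-20 distance
P3_SPATIAL_WEIGHTS: dict[str, float] = {
    "CPz": 1.0, "Pz": 1.0,
    "CP1": 0.9, "CP2": 0.9, "Cz": 0.9,
    "P3": 0.7, "P4": 0.7,
    "C3": 0.55, "C4": 0.55,
    "Oz": 0.5, "O1": 0.4, "O2": 0.4,
    "Fz": 0.35,
    "T7": 0.25, "T8": 0.25,
    "F3": 0.2, "F4": 0.2,
    "Fp1": 0.1, "Fp2": 0.1, "F7": 0.1, "F8": 0.1,
}

# fixed shared-variance fraction of the task background (see simulate_task)
TASK_SHARED_FRACTION = 0.3

ARTIFACT_AMP_UV = 150.0
ARTIFACT_FREQ_HZ = 2.0
ARTIFACT_DUR_S = 0.5
ARTIFACT_CHANNELS = ("Fp1", "Fp2")


@dataclass
class CohortSpec:
    """Design parameters of a synthetic cohort.

    Defaults mirror the oddball/resting protocol this pipeline targets:
    19 subjects, 500 Hz, four minutes of rest, 150 trials with 20% targets,
    P3 amplitude 4.27 +/- 1.14 uV and latency ~401 +/- 34 ms across
    subjects.
    """

    n_subjects: int = 19
    fs: float = 500.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    rest_duration: float = 240.0
    n_trials: int = 150
    target_prob: float = 0.2
    coupling_rho: float = 0.6
    amp_mean: float = 4.27
    amp_sd: float = 1.14
    lat_mean: float = 401.0
    lat_sd: float = 34.0
    artifact_rate: float = 0.1
    noise_sd: float = 15.0          # background RMS per channel, uV
    p3_width_ms: float = 150.0
    seed: int = 0
    dtype: str = "float64"          # float32 trades precision for speed

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.validate()

    def validate(self) -> None:
        def bad(name, why):
            raise ValueError(f"invalid CohortSpec.{name}: {why}")

        if self.n_subjects < 3:
            bad("n_subjects", f"must be >= 3, got {self.n_subjects}")
        if self.fs <= 0:
            bad("fs", f"must be positive, got {self.fs}")
        if len(self.channels) < 2 or len(set(self.channels)) != len(self.channels):
            bad("channels", "need >= 2 unique channel labels")
        if not 0 < self.target_prob < 1:
            bad("target_prob", f"must lie in (0, 1), got {self.target_prob}")
        if self.rest_duration < 10.0:
            bad("rest_duration",
                f"must cover one 10 s segment, got {self.rest_duration}")
        if self.n_trials < 1:
            bad("n_trials", f"must be >= 1, got {self.n_trials}")
        if not -1 <= self.coupling_rho <= 1:
            bad("coupling_rho", f"must lie in [-1, 1], got {self.coupling_rho}")
        if self.amp_sd < 0:
            bad("amp_sd", f"must be >= 0, got {self.amp_sd}")
        if self.lat_sd < 0:
            bad("lat_sd", f"must be >= 0, got {self.lat_sd}")
        if not 0 <= self.artifact_rate <= 1:
            bad("artifact_rate",
                f"must lie in [0, 1], got {self.artifact_rate}")
        if self.noise_sd < 0:
            bad("noise_sd", f"must be >= 0, got {self.noise_sd}")
        if self.p3_width_ms <= 0:
            bad("p3_width_ms", f"must be positive, got {self.p3_width_ms}")
        if self.dtype not in ("float32", "float64"):
            bad("dtype", f"must be float32 or float64, got {self.dtype}")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CohortSpec field(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject (used by recovery tests)."""

    subject_id: str
    latent_efficiency: float
    true_amp: float
    true_lat: float
    artifact_trial_ids: list[int] = field(default_factory=list)
    artifact_segment_ids: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def p3_template(amp: float, lat_ms: float, width_ms: float = 150.0,
                fs: float = 500.0) -> np.ndarray:
    """Half-cosine P3 bump sampled from stimulus onset.

    Nonnegative and unimodal with peak value ``amp`` at ``lat_ms``
    (rounded to the sample grid) and support ``lat_ms +/- width_ms``:
    ``w(t) = amp * cos(pi * (t - lat) / (2 * width))`` inside the support.
    The returned waveform covers t = 0 .. lat + width.
    """
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    lat_idx = int(round(lat_ms * fs / 1000.0))
    lat_eff = lat_idx * 1000.0 / fs
    n = int(np.ceil((lat_eff + width_ms) * fs / 1000.0)) + 1
    t = np.arange(n) * 1000.0 / fs
    u = (t - lat_eff) / width_ms
    wave = amp * np.cos(0.5 * np.pi * np.clip(u, -1.0, 1.0))
    wave[np.abs(u) > 1] = 0.0
    return wave


def _spectral_noise(rng: np.random.Generator, n_rows: int, n: int,
                    gain: np.ndarray, dtype) -> np.ndarray:
    """Unit-variance noise rows with amplitude spectrum ``gain`` (rfft bins).

    Random draws are restricted to bins where ``gain`` is non-negligible,
    and the inverse FFT runs at a fast composite length, so narrowband and
    band-limited spectra are cheap even for long recordings.
    """
    import scipy.fft

    dt = np.dtype(dtype)
    nf = len(gain)
    n_fft = 2 * (nf - 1)
    gain = gain.astype(dt)
    active = np.flatnonzero(gain > gain.max() * 1e-6)
    hi = int(active[-1]) + 1 if active.size else nf
    spec = np.zeros((n_rows, nf), dtype=np.complex64 if dt == np.float32
                    else np.complex128)
    draws = (rng.standard_normal((n_rows, hi), dtype=dt)
             + 1j * rng.standard_normal((n_rows, hi), dtype=dt))
    draws *= gain[:hi]
    spec[:, :hi] = draws
    x = scipy.fft.irfft(spec, n=n_fft, axis=-1)
    if n != n_fft:
        x = x[:, :n].copy()
    x /= x.std(axis=-1, keepdims=True)
    return x


def _shared_gains(channels) -> tuple[np.ndarray, np.ndarray]:
    """Fixed oscillator topographies: posterior alpha, frontal theta.

    Gains are derived from the montage's anterior-posterior coordinate and
    normalized so the channel-average shared variance is 1; the gradient is
    what lets shared activity survive average re-referencing.
    """
    from .io import MONTAGE_2D

    y = np.array([MONTAGE_2D.get(ch, (0.0, 0.0))[1] for ch in channels])
    g_alpha = 0.5 + 1.0 * np.clip(-y, 0.0, None)
    g_theta = 0.5 + 1.0 * np.clip(y, 0.0, None)
    norm = np.mean(0.6 * g_alpha ** 2 + 0.4 * g_theta ** 2)
    return g_alpha / np.sqrt(norm), g_theta / np.sqrt(norm)


def _background(rng: np.random.Generator, channels, n: int, fs: float,
                latent: float, noise_sd: float, dtype) -> np.ndarray:
    """Shared-oscillator + private-pink background, channels x samples.

    The shared part mixes a ~10 Hz (alpha, posterior-weighted) and a ~6 Hz
    (theta, frontal-weighted) narrowband oscillator, identical waveforms on
    every channel up to the fixed topographic gain; the private part is
    per-channel 1/f pink noise.  The shared-variance fraction equals
    ``latent``.
    """
    import scipy.fft

    n_ch = len(channels)
    dt = np.dtype(dtype)
    if noise_sd == 0:
        return np.zeros((n_ch, n), dtype=dt)
    # synthesize at a fast FFT length >= n, on that length's frequency grid
    n_fft = scipy.fft.next_fast_len(n, real=True)
    while n_fft % 2:
        n_fft = scipy.fft.next_fast_len(n_fft + 1, real=True)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    alpha_gain = np.exp(-0.5 * ((freqs - 10.0) / 1.0) ** 2)
    theta_gain = np.exp(-0.5 * ((freqs - 6.0) / 1.0) ** 2)
    osc_a = _spectral_noise(rng, 1, n, alpha_gain, dt)[0]
    osc_t = _spectral_noise(rng, 1, n, theta_gain, dt)[0]
    # private 1/f noise, band-limited to 45 Hz (all analysis lives <= 30 Hz)
    pink_gain = np.zeros(len(freqs))
    nz = (freqs > 0) & (freqs <= 45.0)
    pink_gain[nz] = freqs[nz] ** -0.5     # amplitude ~ f^(-1/2) => power 1/f
    data = _spectral_noise(rng, n_ch, n, pink_gain, dt)   # becomes output
    m = float(np.clip(latent, 0.0, 1.0))
    g_alpha, g_theta = _shared_gains(channels)
    data *= dt.type(noise_sd * np.sqrt(1.0 - m))
    coef_a = (noise_sd * np.sqrt(m * 0.6) * g_alpha).astype(dt)
    coef_t = (noise_sd * np.sqrt(m * 0.4) * g_theta).astype(dt)
    data += coef_a[:, None] * osc_a[None, :]
    data += coef_t[:, None] * osc_t[None, :]
    return data


def _artifact_burst(fs: float, dtype) -> np.ndarray:
    n = int(round(ARTIFACT_DUR_S * fs))
    t = np.arange(n) / fs
    return (ARTIFACT_AMP_UV
            * np.sin(2 * np.pi * ARTIFACT_FREQ_HZ * t)).astype(dtype)


def _burst_channels(labels) -> list[int]:
    idx = [labels.index(c) for c in ARTIFACT_CHANNELS if c in labels]
    return idx or [0]


def _subject_rng(spec: CohortSpec, subject_index: int, stream: int
                 ) -> np.random.Generator:
    """Documented fan-out: SeedSequence(seed, spawn_key=(subject, stream))."""
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(subject_index, stream))
    )


def _subject_index(truth: SubjectTruth) -> int:
    try:
        return int(truth.subject_id.split("-")[-1])
    except (AttributeError, ValueError):
        return 0


# ---------------------------------------------------------------------------
# per-subject recordings
# ---------------------------------------------------------------------------


def simulate_resting(truth: SubjectTruth, spec: CohortSpec,
                     rng: np.random.Generator | None = None) -> Recording:
    """Eyes-closed resting recording for one subject."""
    if rng is None:
        rng = _subject_rng(spec, _subject_index(truth), 0)
    n = int(round(spec.rest_duration * spec.fs))
    data = _background(rng, spec.channels, n, spec.fs,
                       truth.latent_efficiency, spec.noise_sd, spec.dtype)
    burst = _artifact_burst(spec.fs, data.dtype)
    seg_samples = int(round(10.0 * spec.fs))
    chans = _burst_channels(list(spec.channels))
    for seg_id in truth.artifact_segment_ids:
        start_max = seg_samples - len(burst)
        start = seg_id * seg_samples + rng.integers(0, start_max + 1)
        for c in chans:
            data[c, start:start + len(burst)] += burst
    return Recording(data=data, fs=spec.fs, labels=list(spec.channels),
                     meta={"kind": "resting", "subject_id": truth.subject_id,
                           "reference_note": "amplifier ref FCz, ground AFz"})


def simulate_task(truth: SubjectTruth, spec: CohortSpec,
                  rng: np.random.Generator | None = None
                  ) -> tuple[Recording, pd.DataFrame]:
    """Oddball task recording plus its (onset_sample, label) event table."""
    if rng is None:
        rng = _subject_rng(spec, _subject_index(truth), 1)
    fs = spec.fs
    trial_samples = int(round(TRIAL_MS * fs / 1000.0))
    lead = int(round(LEAD_S * fs))
    import scipy.fft

    n = lead + spec.n_trials * trial_samples + int(round(LEAD_S * fs))
    # pad the tail to an FFT-friendly even length (cheap noise synthesis)
    n = scipy.fft.next_fast_len(n, real=True)
    while n % 2:
        n = scipy.fft.next_fast_len(n + 1, real=True)
    # Task background uses the same generator family as rest but a fixed
    # shared-variance fraction: the latent coupling lives in the resting
    # network, and letting it also modulate task noise would tie the P3
    # measurement error to the latent score (a spurious pathway).
    data = _background(rng, spec.channels, n, fs,
                       TASK_SHARED_FRACTION, spec.noise_sd, spec.dtype)

    # exact-count target assignment, shuffled
    n_targets = int(round(spec.n_trials * spec.target_prob))
    labels_trials = np.array(["standard"] * spec.n_trials, dtype=object)
    labels_trials[:n_targets] = "target"
    labels_trials = rng.permutation(labels_trials)

    onsets = (lead
              + np.arange(spec.n_trials) * trial_samples
              + int(round(STIM_OFFSET_MS * fs / 1000.0)))
    if onsets[-1] + trial_samples > n:
        raise ValueError("trial timeline exceeds recording capacity")

    tmpl = p3_template(truth.true_amp, truth.true_lat, spec.p3_width_ms,
                       fs).astype(data.dtype)
    weights = np.array([P3_SPATIAL_WEIGHTS.get(ch, 0.1)
                        for ch in spec.channels], dtype=data.dtype)
    for t, onset in enumerate(onsets):
        if labels_trials[t] == "target":
            stop = min(onset + len(tmpl), n)
            data[:, onset:stop] += weights[:, None] * tmpl[:stop - onset]

    burst = _artifact_burst(fs, data.dtype)
    chans = _burst_channels(list(spec.channels))
    for t in truth.artifact_trial_ids:
        # burst stays inside the -200..800 ms epoch window of trial t
        start = onsets[t] + rng.integers(0, int(round(0.3 * fs)) + 1)
        for c in chans:
            data[c, start:start + len(burst)] += burst

    events = pd.DataFrame({"onset_sample": onsets.astype(np.int64),
                           "label": labels_trials})
    rec = Recording(data=data, fs=fs, labels=list(spec.channels),
                    meta={"kind": "task", "subject_id": truth.subject_id})
    return rec, events


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _draw_truths(spec: CohortSpec) -> list[SubjectTruth]:
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(2 ** 20,))
    )
    n = spec.n_subjects
    # latent efficiency: uniform on [0.2, 0.8] (extremes excluded so every
    # subject keeps both shared and private signal)
    le = rng.uniform(0.2, 0.8, size=n)
    z = (le - 0.5) / (0.6 / np.sqrt(12.0))
    rho = spec.coupling_rho
    eps = rng.standard_normal(n)
    amp = spec.amp_mean + spec.amp_sd * (rho * z
                                         + np.sqrt(1.0 - rho ** 2) * eps)
    lat = np.clip(rng.normal(spec.lat_mean, spec.lat_sd, size=n),
                  310.0, 490.0)
    # snap latency to the sample grid so noiseless recovery is exact
    lat = np.round(lat * spec.fs / 1000.0) * 1000.0 / spec.fs

    n_seg = int(spec.rest_duration // 10)
    n_art_seg = int(round(spec.artifact_rate * n_seg))
    n_art_trial = int(round(spec.artifact_rate * spec.n_trials))
    truths = []
    for i in range(n):
        seg_ids = sorted(rng.choice(n_seg, size=n_art_seg,
                                    replace=False).tolist()) if n_art_seg else []
        trial_ids = sorted(rng.choice(spec.n_trials, size=n_art_trial,
                                      replace=False).tolist()) if n_art_trial else []
        truths.append(SubjectTruth(
            subject_id=f"sub-{i:03d}",
            latent_efficiency=float(le[i]),
            true_amp=float(amp[i]),
            true_lat=float(lat[i]),
            artifact_trial_ids=[int(t) for t in trial_ids],
            artifact_segment_ids=[int(s) for s in seg_ids],
        ))
    return truths


def iter_cohort(spec: CohortSpec):
    """Lazily yield ``(subject_bundle, truth)`` pairs for one cohort.

    Memory-friendly variant of :func:`simulate_cohort` for large
    simulation studies: each subject's recordings can be analyzed and
    discarded before the next is synthesized.
    """
    spec.validate()
    for i, truth in enumerate(_draw_truths(spec)):
        rest = simulate_resting(truth, spec, rng=_subject_rng(spec, i, 0))
        task, events = simulate_task(truth, spec, rng=_subject_rng(spec, i, 1))
        yield ({"subject_id": truth.subject_id, "rest": rest,
                "task": task, "events": events}, truth)


def simulate_cohort(spec: CohortSpec
                    ) -> tuple[list[dict], list[SubjectTruth]]:
    """Simulate a full cohort: per-subject rest + task bundles and truths.

    Returns ``(subjects, truths)`` where each subject bundle is a dict with
    keys ``subject_id``, ``rest`` (Recording), ``task`` (Recording) and
    ``events`` (DataFrame).  Identical ``(spec, seed)`` reproduce identical
    cohorts.
    """
    pairs = list(iter_cohort(spec))
    return [p[0] for p in pairs], [p[1] for p in pairs]


def truth_table(truths: list[SubjectTruth]) -> pd.DataFrame:
    """Ground-truth manifest as a DataFrame (one row per subject)."""
    return pd.DataFrame({
        "subject_id": [t.subject_id for t in truths],
        "latent_efficiency": [t.latent_efficiency for t in truths],
        "true_amp": [t.true_amp for t in truths],
        "true_lat": [t.true_lat for t in truths],
        "n_artifact_trials": [len(t.artifact_trial_ids) for t in truths],
        "n_artifact_segments": [len(t.artifact_segment_ids) for t in truths],
    })
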