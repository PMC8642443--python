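"""Heart-rate and heart-rate-variability control analysis.

R-peak detection (band-pass + squared-derivative energy with an adaptive
threshold and a 0.2 s refractory period), time-domain RR metrics (heart
rate as the mean of per-beat 60/RR, SDNN with the n-1 denominator, RMSSD),
and the run-exclusion rule: a run is excluded when the segments shorter
than 1.2 s in which no QRS could be located total 30 s or more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .synthetic import RRSeries

REFRACTORY_S = 0.2
MIN_DURATION_S = 10.0
SHORT_SEGMENT_S = 1.2  # unlocatable-QRS segments shorter than this count ...
EXCLUSION_TOTAL_S = 30.0  # ... towards this exclusion total
ANALYSIS_WINDOW_S = 300.0  # 5-min short-term HRV window per run


@dataclass(frozen=True)
class EcgSignal:
    """A single-channel ECG recording."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass(frozen=True)
class HrvMetrics:
    """Time-domain HRV summary of one RR series."""

    mean_rr: float
    sdnn: float
    rmssd: float
    heart_rate: float
    n_beats: int
    defined: bool = True


@dataclass(frozen=True)
class DetectionResult:
    beat_times: np.ndarray  # seconds
    unlocatable_segments: tuple[tuple[float, float], ...]  # (start, stop) s


def detect_r_peaks(ecg: EcgSignal, gap_factor: float = 1.75) -> DetectionResult:
    """Locate R peaks and the segments where no QRS could be found.

    Pan-Tompkins-style: 5-15 Hz band-pass, squared derivative, 150 ms
    moving-window integration, threshold at a multiple of the running
    median of the integrated energy, 0.2 s refractory period.  Peak times
    are refined to the local maximum of the band-passed signal.  Gaps
    between successive detections longer than ``gap_factor`` times the
    median RR are reported as unlocatable segments.
    """
    fs = ecg.sampling_rate
    x = np.asarray(ecg.samples, dtype=float)
    duration = ecg.duration
    if duration < MIN_DURATION_S:
        raise ValueError(f"ECG must be at least {MIN_DURATION_S} s long")

    if np.ptp(x) == 0:
        return DetectionResult(np.array([]), ((0.0, duration),))

    sos = scipy.signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = scipy.signal.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    med = np.median(integ)
    height = max(4.0 * med, 0.1 * integ.max())
    distance = max(1, int(round(REFRACTORY_S * fs)))
    peaks, _ = scipy.signal.find_peaks(integ, height=height, distance=distance)
    if peaks.size == 0:
        return DetectionResult(np.array([]), ((0.0, duration),))

    # refine each detection to the band-passed maximum within +-60 ms
    half = int(round(0.060 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    beat_samples = np.unique(refined)
    # re-impose the refractory period after refinement
    kept = [int(beat_samples[0])]
    for s in beat_samples[1:]:
        if s - kept[-1] >= distance:
            kept.append(int(s))
    beat_times = np.array(kept) / fs

    segments: list[tuple[float, float]] = []
    if len(beat_times) >= 2:
        rr = np.diff(beat_times)
        med_rr = float(np.median(rr))
        for i, gap in enumerate(rr):
            if gap > gap_factor * med_rr:
                segments.append((beat_times[i] + med_rr, beat_times[i + 1]))
        if beat_times[0] > gap_factor * med_rr:
            segments.insert(0, (0.0, beat_times[0]))
        if duration - beat_times[-1] > gap_factor * med_rr:
            segments.append((beat_times[-1] + med_rr, duration))
    return DetectionResult(beat_times, tuple(segments))


def rr_metrics(rr: RRSeries | np.ndarray) -> HrvMetrics:
    """Time-domain metrics of an RR-interval series.

    heart_rate is the mean over beats of 60 / RR_i (beats per minute);
    SDNN is the sample standard deviation (n-1 denominator); RMSSD the
    root mean square of successive differences.  With fewer than two
    intervals the variability metrics are undefined and flagged.
    """
    intervals = rr.intervals if isinstance(rr, RRSeries) else np.asarray(rr, float)
    n = len(intervals)
    if n == 0:
        return HrvMetrics(np.nan, np.nan, np.nan, np.nan, 0, defined=False)
    mean_rr = float(np.mean(intervals))
    heart_rate = float(np.mean(60.0 / intervals))
    if n < 2:
        return HrvMetrics(mean_rr, np.nan, np.nan, heart_rate, n, defined=False)
    sdnn = float(np.std(intervals, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(intervals) ** 2)))
    return HrvMetrics(mean_rr, sdnn, rmssd, heart_rate, n)


def run_exclusion(
    unlocatable_segments: tuple[tuple[float, float], ...],
    run_duration: float,
) -> str:
    """Apply the short-segment exclusion rule to one run.

    Returns ``"exclude"`` iff the total duration of unlocatable segments
    individually shorter than 1.2 s reaches 30 s, else ``"keep"``.
    """
    total = 0.0
    for start, stop in unlocatable_segments:
        if not 0 <= start <= stop <= run_duration + 1e-9:
            raise ValueError(f"segment ({start}, {stop}) outside run bounds")
        d = stop - start
        if d < SHORT_SEGMENT_S:
            total += d
    return "exclude" if total >= EXCLUSION_TOTAL_S else "keep"


def synthetic_ecg(
    beat_times: np.ndarray,
    duration: float,
    sampling_rate: float = 250.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> EcgSignal:
    """Synthetic single-channel ECG with QRS-like wavelets at given beats.

    Each beat is a Mexican-hat (Ricker) wavelet of ~80 ms width and unit
    amplitude over additive Gaussian noise — enough morphology for the
    detector's contract tests, with exactly known ground-truth beat times.
    """
    fs = sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = rng.normal(0.0, noise_sd, size=n)
    width = 0.02  # s, wavelet scale parameter
    for bt in np.asarray(beat_times, dtype=float):
        u = (t - bt) / width
        near = np.abs(u) < 6
        x[near] += (1 - u[near] ** 2) * np.exp(-(u[near] ** 2) / 2)
    return EcgSignal(samples=x, sampling_rate=fs)
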