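"""Sensor-space time-frequency stage.

FIR band-pass design (Hamming window method), single-pass delay-compensated
filtering, Welch power spectral density (512-point Hamming windows, no
overlap), alpha band-power extraction, log transform with planar-gradiometer
combination, and baseline correction of post-exposure runs.

Conventions
-----------
* The -6 dB cut-offs of the band-pass sit at the midpoints of the stated
  transition bands: a 1 Hz lower passband edge with 1 Hz transition
  bandwidth puts the lower -6 dB point at 0.50 Hz, and a 30 Hz upper edge
  with 7.5 Hz transition bandwidth puts the upper one at 33.75 Hz.
* Band power is the *mean* of the PSD over bins whose centre frequency lies
  inside the closed band interval (resolution-independent), not the sum.
* Sensor-space log power uses the natural log; decibels are reserved for
  source space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .layout import SensorLayout

ALPHA_BANDS: dict[str, tuple[float, float]] = {
    "alpha_8_12": (8.0, 12.0),
    "lower_alpha_8_10": (8.0, 10.0),
    "upper_alpha_10_12": (10.0, 12.0),
}

WELCH_WINDOW_LENGTH = 512  # samples per Welch segment


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass FIR specification (Hamming window method)."""

    sampling_rate: float = 1000.0
    l_freq: float = 1.0  # lower passband edge, Hz
    h_freq: float = 30.0  # upper passband edge, Hz
    l_trans_bw: float = 1.0  # lower transition bandwidth, Hz
    h_trans_bw: float = 7.5  # upper transition bandwidth, Hz
    window: str = "hamming"

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2.0
        if not 0 < self.l_freq < self.h_freq < nyq:
            raise ValueError("need 0 < l_freq < h_freq < Nyquist")
        if self.l_trans_bw <= 0 or self.h_trans_bw <= 0:
            raise ValueError("transition bandwidths must be positive")
        if self.l_freq - self.l_trans_bw / 2.0 < 0:
            raise ValueError("lower transition band extends below 0 Hz")
        if self.h_freq + self.h_trans_bw / 2.0 >= nyq:
            raise ValueError("upper transition band extends beyond Nyquist")

    @property
    def l_cutoff(self) -> float:
        """Lower -6 dB frequency (transition-band midpoint)."""
        return self.l_freq - self.l_trans_bw / 2.0

    @property
    def h_cutoff(self) -> float:
        """Upper -6 dB frequency (transition-band midpoint)."""
        return self.h_freq + self.h_trans_bw / 2.0


@dataclass(frozen=True)
class PSDResult:
    """Welch PSD estimate: density per channel on a regular frequency grid."""

    freqs: np.ndarray  # (n_freqs,)
    psd: np.ndarray  # (..., n_freqs), channels leading
    n_segments: int
    window_length: int = WELCH_WINDOW_LENGTH


def design_bandpass_fir(spec: FilterSpec) -> np.ndarray:
    """Design a linear-phase band-pass FIR with the Hamming window method.

    The filter length follows the standard Hamming design rule
    ``N = ceil(3.3 / (df / fs))`` on the narrower transition band, forced
    odd (type-I linear phase).  ``firwin`` places the half-amplitude
    (-6 dB) points at the given cut-offs.
    """
    fs = spec.sampling_rate
    narrow = min(spec.l_trans_bw, spec.h_trans_bw)
    numtaps = int(np.ceil(3.3 / (narrow / fs)))
    if numtaps % 2 == 0:
        numtaps += 1
    coeffs = scipy.signal.firwin(
        numtaps,
        [spec.l_cutoff, spec.h_cutoff],
        window=spec.window,
        pass_zero=False,
        fs=fs,
    )
    # null the residual DC gain exactly so constant offsets are fully removed;
    # the correction is ~5e-3 spread over all taps and moves the -6 dB points
    # by ~1e-3 Hz
    return coeffs - coeffs.sum() / numtaps


def frequency_response(coeffs: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Magnitude response of an FIR filter at arbitrary frequencies."""
    _, h = scipy.signal.freqz(coeffs, worN=2 * np.pi * np.asarray(freqs) / fs)
    return np.abs(h)


def find_cutoff(
    coeffs: np.ndarray,
    fs: float,
    bracket: tuple[float, float],
    level_db: float = -6.0,
) -> float:
    """Locate the frequency where the filter gain crosses ``level_db``.

    Uses bisection on the magnitude response inside ``bracket`` (which must
    straddle the crossing).
    """
    import scipy.optimize

    target = 10.0 ** (level_db / 20.0)

    def gain(f: float) -> float:
        return float(frequency_response(coeffs, np.array([f]), fs)[0]) - target

    lo, hi = bracket
    if gain(lo) * gain(hi) > 0:
        raise ValueError("bracket does not straddle the cut-off")
    return float(scipy.optimize.brentq(gain, lo, hi, xtol=1e-6))


def apply_filter(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Single-pass zero-delay FIR filtering with reflection padding.

    The linear-phase group delay of ``(len(coeffs) - 1) / 2`` samples is
    compensated so the output is aligned with the input and has the same
    length.  Works on 1-D signals or (channels, samples) arrays.
    """
    x = np.asarray(x, dtype=float)
    n_taps = len(coeffs)
    n = x.shape[-1]
    if n <= 3 * n_taps:
        raise ValueError(
            f"signal ({n} samples) must be longer than 3x the filter ({n_taps} taps)"
        )
    pad = n_taps  # reflection padding on both ends
    xp = np.concatenate(
        [x[..., pad:0:-1], x, x[..., -2 : -pad - 2 : -1]], axis=-1
    )
    y = scipy.signal.fftconvolve(xp, np.atleast_2d(coeffs) if x.ndim == 2 else coeffs,
                                 mode="full", axes=-1)
    delay = (n_taps - 1) // 2
    start = pad + delay
    return y[..., start : start + n]


def welch_psd(
    x: np.ndarray,
    sampling_rate: float,
    window_length: int = WELCH_WINDOW_LENGTH,
    window: str = "hamming",
    overlap: int = 0,
) -> PSDResult:
    """Welch PSD: mean of modified periodograms over non-overlapping segments.

    Density normalisation: the integral of the PSD over frequency
    approximates the signal variance.  A trailing partial segment is
    discarded, as is the per-segment mean (detrend by constant).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < window_length:
        raise ValueError(
            f"signal length {n} is shorter than the Welch window ({window_length})"
        )
    freqs, psd = scipy.signal.welch(
        x,
        fs=sampling_rate,
        window=window,
        nperseg=window_length,
        noverlap=overlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    step = window_length - overlap
    n_segments = (n - overlap) // step
    return PSDResult(
        freqs=freqs, psd=psd, n_segments=int(n_segments), window_length=window_length
    )


def band_power(psd: PSDResult, band: tuple[float, float]) -> np.ndarray:
    """Mean PSD over bins whose centre frequency lies in the closed band.

    With a 1000 Hz sampling rate and 512-point windows the grid spacing is
    1.953125 Hz, so the 8-12 Hz band selects exactly the bins at 9.765625
    and 11.71875 Hz.
    """
    f_lo, f_hi = band
    if f_lo > f_hi:
        raise ValueError("band must satisfy f_lo <= f_hi")
    mask = (psd.freqs >= f_lo) & (psd.freqs <= f_hi)
    if not mask.any():
        df = psd.freqs[1] - psd.freqs[0] if len(psd.freqs) > 1 else float("nan")
        raise ValueError(
            f"no PSD bin centre falls inside band [{f_lo}, {f_hi}] Hz "
            f"(grid resolution {df} Hz)"
        )
    return psd.psd[..., mask].mean(axis=-1)


def log_and_combine(power: np.ndarray, layout: SensorLayout) -> dict[str, np.ndarray]:
    """Natural-log transform and planar-gradiometer pair combination.

    Parameters
    ----------
    power : (3 * n_triplets,) array
        Band power per physical channel in triplet-major order
        (magnetometer, gradiometer 1, gradiometer 2).

    Returns
    -------
    dict with keys ``"mag"`` and ``"grad"``
        Each an (n_triplets,) array of log power: the magnetometer log power
        and the arithmetic mean of the two gradiometers' log powers.
    """
    power = np.asarray(power, dtype=float)
    n = layout.n_triplets
    if power.shape[-1] != 3 * n:
        raise ValueError(f"expected {3 * n} channel powers, got {power.shape[-1]}")
    if (power <= 0).any():
        raise ValueError("band power must be strictly positive before log transform")
    by_triplet = power.reshape(*power.shape[:-1], n, 3)
    logp = np.log(by_triplet)
    return {"mag": logp[..., 0], "grad": logp[..., 1:].mean(axis=-1)}


def baseline_correct(
    dataset: pd.DataFrame,
    baseline_runs: tuple[str, ...] = ("Run1", "Run2"),
) -> pd.DataFrame:
    """Subtract the averaged baseline log power from each post-exposure run.

    For every (subject, session, eyes, sensor) cell the mean log power of
    the baseline runs is subtracted from each remaining run's log power.
    Baseline rows are dropped from the output.  EO and EC are corrected
    independently, as are the two sessions.
    """
    runs = dataset["run"].unique()
    missing = [r for r in baseline_runs if r not in runs]
    if missing:
        raise ValueError(f"baseline runs missing from dataset: {missing}")
    keys = ["subject", "session", "eyes", "sensor"]
    is_base = dataset["run"].isin(baseline_runs)
    baseline = (
        dataset[is_base].groupby(keys, sort=False)["log_power"].mean().rename("baseline")
    )
    post = dataset[~is_base]
    if post.empty:
        raise ValueError("dataset has no post-baseline runs to correct")
    merged = post.merge(baseline, on=keys, how="left", validate="many_to_one")
    if merged["baseline"].isna().any():
        bad = merged.loc[merged["baseline"].isna(), keys].iloc[0].to_dict()
        raise ValueError(f"missing baseline cell for {bad}")
    merged["log_power"] = merged["log_power"] - merged["baseline"]
    out = merged.drop(columns="baseline")
    out.attrs["baseline_corrected"] = True
    return out


def band_power_dataset(
    runs: dict[tuple[str, str, str], "object"],
    layout: SensorLayout,
    band: tuple[float, float],
    filter_spec: FilterSpec | None = None,
    window_length: int = WELCH_WINDOW_LENGTH,
) -> pd.DataFrame:
    """Full sensor-space spectral stage on simulated raw runs.

    For every (subject, session, run): band-pass filter, then for each EO/EC
    block compute the Welch PSD, extract band power per channel, log and
    combine triplets.  Returns the long-format dataset (gradiometer values;
    one row per subject x session x run x eyes x sensor) consumed by the
    statistics stage.
    """
    coeffs = design_bandpass_fir(
        filter_spec
        if filter_spec is not None
        else FilterSpec(sampling_rate=next(iter(runs.values())).sampling_rate)
    )
    records = []
    for (subject, session, run), raw in runs.items():
        filtered = apply_filter(raw.data, coeffs)
        fs = raw.sampling_rate
        for start, stop, eyes in raw.blocks:
            seg = filtered[:, int(round(start * fs)) : int(round(stop * fs))]
            psd = welch_psd(seg, fs, window_length=window_length)
            bp = band_power(psd, band)
            combined = log_and_combine(bp, layout)
            records.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "session": session,
                        "run": run,
                        "eyes": eyes,
                        "sensor": np.arange(layout.n_triplets),
                        "log_power": combined["grad"],
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
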