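"""Synthetic generators for a 2x2x2 within-subject MEG crossover experiment.

The emulated study: resting-state MEG recorded in two sessions (real / sham
exposure), each with two baseline runs (Run1, Run2) and four post-exposure
runs (Run9..Run12), every run alternating 3-min eyes-open (EO) and
eyes-closed (EC) blocks.  Generators produce

* factorial per-sensor log band-power datasets with a multiplicative alpha
  power decrease planted on a contiguous sensor patch of the real session's
  post-exposure runs (the ground truth the cluster statistics must recover),
* raw multichannel 1/f + alpha oscillation signals with an EC posterior
  alpha boost,
* stationary AR(1) RR-interval series hitting requested SDNN/RMSSD targets,
* exposure-session metadata (duty-cycle average power).

All generators are pure functions of (parameters, seed); per-subject and
per-run streams are derived from the master seed with
``numpy.random.SeedSequence(seed, *counters)`` so subjects can be generated
independently and in any order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .layout import SensorLayout, build_adjacency

BASELINE_RUNS = ("Run1", "Run2")
POST_RUNS = ("Run9", "Run10", "Run11", "Run12")
SESSIONS = ("real", "sham")
EYES = ("EO", "EC")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial structure of the crossover experiment.

    Defaults reproduce the emulated study: 29 analysed subjects, two
    sessions, two 3-min baseline runs and four post-exposure runs, EO/EC
    alternation, 1000 Hz sampling.
    """

    n_subjects: int = 29
    sessions: tuple[str, ...] = SESSIONS
    baseline_runs: tuple[str, ...] = BASELINE_RUNS
    post_runs: tuple[str, ...] = POST_RUNS
    eyes: tuple[str, ...] = EYES
    block_length: float = 180.0  # seconds per EO or EC block
    sampling_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.block_length <= 0:
            raise ValueError("block_length must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def runs(self) -> tuple[str, ...]:
        return self.baseline_runs + self.post_runs

    @property
    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass(frozen=True)
class EffectSpec:
    """Planted ground truth for the band-power generator.

    Parameters
    ----------
    target_sensors : tuple of int
        Triplet indices carrying the exposure effect; must be spatially
        contiguous under the layout adjacency.
    effect_ratio : float
        Multiplicative change of post-exposure real-session power on the
        target sensors (0.9 = 10 % decrease; 1.0 = global null).
    subject_sd : float
        SD of the subject random intercept on log power.
    noise_sd : float
        Residual log-power SD per design cell.
    eyes_ec_boost : float
        Additive log-power increase for EC cells on posterior sensors
        (emulates the posterior eyes-closed alpha rise).
    """

    target_sensors: tuple[int, ...] = ()
    effect_ratio: float = 0.9
    subject_sd: float = 0.3
    noise_sd: float = 0.2
    eyes_ec_boost: float = 0.7

    def __post_init__(self) -> None:
        if self.effect_ratio <= 0:
            raise ValueError("effect_ratio must be > 0")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class RRSeries:
    """A beat-to-beat interval sequence."""

    intervals: np.ndarray  # seconds, all > 0
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if not np.all(np.isfinite(iv)):
            raise ValueError("RR intervals must be finite")
        if iv.size and iv.min() <= 0:
            raise ValueError("RR intervals must be positive")

    @property
    def beat_times(self) -> np.ndarray:
        return self.origin_time + np.cumsum(self.intervals)


def contiguous_patch(
    layout: SensorLayout,
    adjacency: np.ndarray,
    seed_sensor: int,
    size: int,
) -> tuple[int, ...]:
    """Grow a contiguous sensor patch of ``size`` triplets from a seed by BFS."""
    if size < 1 or size > layout.n_triplets:
        raise ValueError("patch size out of range")
    visited = [seed_sensor]
    frontier = [seed_sensor]
    seen = {seed_sensor}
    while len(visited) < size and frontier:
        nxt = []
        for node in frontier:
            for nb in np.flatnonzero(adjacency[node]):
                if nb not in seen:
                    seen.add(int(nb))
                    visited.append(int(nb))
                    nxt.append(int(nb))
                    if len(visited) == size:
                        return tuple(sorted(visited[:size]))
        frontier = nxt
    if len(visited) < size:
        raise ValueError("adjacency component smaller than requested patch")
    return tuple(sorted(visited[:size]))


def default_effect(
    layout: SensorLayout, adjacency: np.ndarray | None = None, size: int = 10, **kwargs
) -> EffectSpec:
    """EffectSpec with a contiguous posterior target patch of ``size`` triplets."""
    if adjacency is None:
        adjacency = build_adjacency(layout)
    posterior = np.flatnonzero(layout.is_posterior())
    seed_sensor = int(posterior[0]) if posterior.size else 0
    patch = contiguous_patch(layout, adjacency, seed_sensor, size)
    return EffectSpec(target_sensors=patch, **kwargs)


def _check_contiguous(
    target: tuple[int, ...], layout: SensorLayout, adjacency: np.ndarray | None
) -> None:
    if len(target) <= 1:
        return
    if adjacency is None:
        adjacency = build_adjacency(layout)
    idx = np.asarray(sorted(target))
    sub = adjacency[np.ix_(idx, idx)]
    n_comp, _ = connected_components(sub, directed=False)
    if n_comp != 1:
        raise ValueError(
            "EffectSpec.target_sensors must be contiguous under the layout "
            f"adjacency; got {n_comp} components"
        )


def simulate_band_power(
    design: ExperimentDesign,
    layout: SensorLayout,
    effect: EffectSpec,
    seed: int,
    grand_mean: float = 0.0,
    adjacency: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate a factorial per-sensor log band-power dataset.

    The generating model on natural-log power is additive::

        log P = grand_mean
              + subject intercept              ~ Normal(0, subject_sd)
              + eyes_ec_boost                  (EC cells, posterior sensors)
              + log(effect_ratio)              (real session, post runs, target sensors)
              + residual                       ~ Normal(0, noise_sd)

    Returns
    -------
    pandas.DataFrame
        Long format with columns ``subject, session, run, eyes, sensor,
        log_power`` — one row per design cell per sensor triplet.  The
        values represent the already triplet-combined log band power the
        spectral stage would produce.
    """
    n_sens = layout.n_triplets
    if effect.target_sensors and max(effect.target_sensors) >= n_sens:
        raise ValueError("target_sensors outside layout")
    _check_contiguous(effect.target_sensors, layout, adjacency)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subjects = design.subjects
    runs = design.runs
    n_cells = len(design.sessions) * len(runs) * len(design.eyes)

    intercepts = rng.normal(0.0, effect.subject_sd, size=len(subjects))
    posterior = layout.is_posterior()
    target_mask = np.zeros(n_sens, dtype=bool)
    if effect.target_sensors:
        target_mask[list(effect.target_sensors)] = True

    records = []
    for si, subj in enumerate(subjects):
        sub_rng = np.random.default_rng(np.random.SeedSequence([seed, si + 1]))
        noise = sub_rng.normal(0.0, effect.noise_sd, size=(n_cells, n_sens))
        cell = 0
        for session in design.sessions:
            for run in runs:
                is_post_real = session == "real" and run in design.post_runs
                for eyes in design.eyes:
                    vals = grand_mean + intercepts[si] + noise[cell]
                    if eyes == "EC":
                        vals = vals + effect.eyes_ec_boost * posterior
                    if is_post_real:
                        vals = vals + np.log(effect.effect_ratio) * target_mask
                    records.append(
                        pd.DataFrame(
                            {
                                "subject": subj,
                                "session": session,
                                "run": run,
                                "eyes": eyes,
                                "sensor": np.arange(n_sens),
                                "log_power": vals,
                            }
                        )
                    )
                    cell += 1
    out = pd.concat(records, ignore_index=True)
    out.attrs["baseline_corrected"] = False
    return out


@dataclass(frozen=True)
class RawRun:
    """One run of simulated multichannel MEG: EO/EC blocks concatenated."""

    data: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    blocks: tuple[tuple[float, float, str], ...]  # (start_s, stop_s, eyes)
    channel_names: tuple[str, ...] = ()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def block_slice(self, index: int) -> np.ndarray:
        start, stop, _ = self.blocks[index]
        fs = self.sampling_rate
        return self.data[:, int(round(start * fs)) : int(round(stop * fs))]


def _powerlaw_noise(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float,
                    exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, unit variance."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # zero-mean output
    coloured = np.fft.irfft(spec * shaping, n=n_samp, axis=1)
    sd = coloured.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return coloured / sd


def simulate_raw_run(
    design: ExperimentDesign,
    layout: SensorLayout,
    alpha_freq: float = 10.0,
    ec_eo_amplitude_ratio: float = 2.0,
    one_over_f_exponent: float = 1.0,
    alpha_amplitude: float = 1.0,
    amplitude_scale: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
    eyes_order: tuple[str, str] = ("EO", "EC"),
) -> RawRun:
    """Simulate one run: alternating EO/EC blocks of 1/f noise + alpha.

    Each physical channel (three per triplet) carries unit-variance
    1/f-coloured noise plus a narrowband alpha oscillation.  During EC
    blocks the alpha amplitude on posterior channels is multiplied by
    ``ec_eo_amplitude_ratio``.  ``amplitude_scale`` (per triplet) scales
    the alpha amplitude across the whole run — the hook used by the
    pipeline to plant exposure effects in raw space.
    """
    fs = design.sampling_rate
    if not 0 < alpha_freq < fs / 2:
        raise ValueError("alpha_freq must be in (0, Nyquist)")
    if ec_eo_amplitude_ratio < 1:
        raise ValueError("ec_eo_amplitude_ratio must be >= 1")
    n_block = int(round(design.block_length * fs))
    n_ch = layout.n_channels
    rng = np.random.default_rng(seed)

    posterior_trip = layout.is_posterior()
    post_ch = np.repeat(posterior_trip, 3)
    scale_ch = (
        np.repeat(np.asarray(amplitude_scale, dtype=float), 3)
        if amplitude_scale is not None
        else np.ones(n_ch)
    )

    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    segments = []
    blocks = []
    t0 = 0.0
    for bi, eyes in enumerate(eyes_order):
        noise = _powerlaw_noise(rng, n_ch, n_block, fs, one_over_f_exponent)
        t = (np.arange(n_block) + bi * n_block) / fs
        osc = np.sin(2 * np.pi * alpha_freq * t[None, :] + phases[:, None])
        amp = alpha_amplitude * scale_ch.copy()
        if eyes == "EC":
            amp = amp * np.where(post_ch, ec_eo_amplitude_ratio, 1.0)
        segments.append(noise + amp[:, None] * osc)
        blocks.append((t0, t0 + design.block_length, eyes))
        t0 += design.block_length
    data = np.concatenate(segments, axis=1)
    return RawRun(
        data=data,
        sampling_rate=fs,
        blocks=tuple(blocks),
        channel_names=tuple(layout.channel_names()),
    )


def simulate_raw(
    design: ExperimentDesign,
    layout: SensorLayout,
    alpha_freq: float = 10.0,
    ec_eo_amplitude_ratio: float = 2.0,
    one_over_f_exponent: float = 1.0,
    seed: int = 0,
    effect: EffectSpec | None = None,
) -> dict[tuple[str, str, str], RawRun]:
    """Simulate raw signals for every (subject, session, run) of the design.

    When ``effect`` is given, the alpha amplitude of its target triplets is
    scaled by ``sqrt(effect.effect_ratio)`` in the real session's
    post-exposure runs, planting a multiplicative band-power change of
    ``effect_ratio`` at the oscillation peak.

    Per-run random streams derive from ``SeedSequence(seed, subj, sess,
    run)`` so any run can be regenerated in isolation.
    """
    out: dict[tuple[str, str, str], RawRun] = {}
    for si, subj in enumerate(design.subjects):
        for ei, session in enumerate(design.sessions):
            for ri, run in enumerate(design.runs):
                scale = None
                if (
                    effect is not None
                    and effect.target_sensors
                    and session == "real"
                    and run in design.post_runs
                ):
                    scale = np.ones(layout.n_triplets)
                    scale[list(effect.target_sensors)] = np.sqrt(effect.effect_ratio)
                ss = np.random.SeedSequence([seed, si, ei, ri])
                out[(subj, session, run)] = simulate_raw_run(
                    design,
                    layout,
                    alpha_freq=alpha_freq,
                    ec_eo_amplitude_ratio=ec_eo_amplitude_ratio,
                    one_over_f_exponent=one_over_f_exponent,
                    amplitude_scale=scale,
                    seed=ss,
                )
    return out


def simulate_rr(
    n_beats: int,
    mean_rr: float = 0.9,
    sdnn_target: float = 0.05,
    rmssd_target: float = 0.04,
    seed: int = 0,
) -> RRSeries:
    """Stationary AR(1) Gaussian RR intervals with given SDNN and RMSSD.

    For an AR(1) process with coefficient ``phi`` and marginal SD ``s``,
    the population RMSSD is ``s * sqrt(2 * (1 - phi))``; solving gives
    ``phi = 1 - rmssd**2 / (2 * sdnn**2)``, which requires
    ``0 < rmssd < 2 * sdnn`` for stationarity (|phi| < 1).  The degenerate
    ``sdnn_target = 0`` produces constant intervals.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if sdnn_target < 0 or rmssd_target < 0:
        raise ValueError("targets must be >= 0")
    if sdnn_target == 0:
        if rmssd_target != 0:
            raise ValueError("rmssd_target must be 0 when sdnn_target is 0")
        return RRSeries(intervals=np.full(n_beats, mean_rr))
    if not 0 < rmssd_target < 2 * sdnn_target:
        raise ValueError(
            "unachievable (SDNN, RMSSD) pair: need 0 < rmssd < 2*sdnn "
            f"(got sdnn={sdnn_target}, rmssd={rmssd_target})"
        )
    phi = 1.0 - rmssd_target**2 / (2.0 * sdnn_target**2)
    innov_sd = sdnn_target * np.sqrt(1.0 - phi**2)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.empty(n_beats)
    x[0] = rng.normal(0.0, sdnn_target)  # start at stationary distribution
    eps = rng.normal(0.0, innov_sd, size=n_beats - 1)
    for i in range(1, n_beats):
        x[i] = phi * x[i - 1] + eps[i - 1]
    intervals = mean_rr + x
    if (intervals <= 0).any():
        warnings.warn(
            "simulate_rr: Gaussian tail crossed zero; clipping intervals to 1 ms",
            stacklevel=2,
        )
        intervals = np.clip(intervals, 1e-3, None)
    return RRSeries(intervals=intervals)


def gsm_average_power(peak_power: float, duty_cycle: float) -> float:
    """Average emitted power of a pulsed (duty-cycled) transmitter, in watts.

    A GSM handset transmits in 1-of-8 time slots, so a 2 W peak corresponds
    to a 0.25 W average.
    """
    if not 0 < duty_cycle <= 1:
        raise ValueError("duty_cycle must be in (0, 1]")
    if peak_power < 0:
        raise ValueError("peak_power must be >= 0")
    return peak_power * duty_cycle


def write_band_power_tsv(dataset: pd.DataFrame, path) -> None:
    """Write a long-format band-power table as TSV."""
    dataset.to_csv(path, sep="\t", index=False)


def read_band_power_tsv(path) -> pd.DataFrame:
    """Read a long-format band-power table written by :func:`write_band_power_tsv`."""
    return pd.read_csv(path, sep="\t")


def write_raw_h5(runs: dict[tuple[str, str, str], RawRun], path) -> None:
    """Write simulated raw runs to HDF5 as /subject/session/run datasets.

    Each dataset is (channels x samples) float with attributes ``fs`` and
    ``blocks`` (rows of start/stop seconds and the eyes condition).
    """
    import h5py

    with h5py.File(path, "w") as fh:
        for (subject, session, run), raw in runs.items():
            dset = fh.create_dataset(f"{subject}/{session}/{run}", data=raw.data)
            dset.attrs["fs"] = raw.sampling_rate
            dset.attrs["block_starts"] = [b[0] for b in raw.blocks]
            dset.attrs["block_stops"] = [b[1] for b in raw.blocks]
            dset.attrs["block_eyes"] = [b[2] for b in raw.blocks]


def read_raw_h5(path) -> dict[tuple[str, str, str], RawRun]:
    """Read raw runs written by :func:`write_raw_h5`."""
    import h5py

    out: dict[tuple[str, str, str], RawRun] = {}
    with h5py.File(path, "r") as fh:
        for subject in fh:
            for session in fh[subject]:
                for run in fh[subject][session]:
                    dset = fh[subject][session][run]
                    blocks = tuple(
                        (float(a), float(b), str(e))
                        for a, b, e in zip(
                            dset.attrs["block_starts"],
                            dset.attrs["block_stops"],
                            [
                                e.decode() if isinstance(e, bytes) else str(e)
                                for e in dset.attrs["block_eyes"]
                            ],
                        )
                    )
                    out[(subject, session, run)] = RawRun(
                        data=dset[()],
                        sampling_rate=float(dset.attrs["fs"]),
                        blocks=blocks,
                    )
    return out


def write_rr_tsv(rr: RRSeries, path) -> None:
    """Write an RR series as two-column TSV (beat_time_s, rr_s)."""
    pd.DataFrame({"beat_time_s": rr.beat_times, "rr_s": rr.intervals}).to_csv(
        path, sep="\t", index=False
    )
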