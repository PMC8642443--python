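"""End-to-end orchestration of the synthetic crossover experiment.

``run_experiment`` drives every stage from one config and one master seed:

1. sensor layout and neighbouring matrix,
2. factorial band-power datasets with the planted exposure effect,
   one per analysis band (entire alpha 8-12 Hz, lower 8-10, upper 10-12),
3. sensor-space statistics — the 2x2x2 repeated-measures ANOVA cluster
   tests (time x eyes x exposure) and the per-run real-vs-sham one-way
   cluster tests on baseline-corrected power, EO and EC separately,
4. a reduced-scale raw-signal source stage: simulated oscillatory runs,
   FIR filtering, whitening, minimum-norm inversion, per-vertex alpha
   power, baseline correction and source-space cluster tests,
5. HRV control metrics per subject, session and run,
6. exposure-session metadata (duty-cycle average power).

All randomness derives from ``master_seed`` through fixed
``SeedSequence(master_seed, stage, ...)`` counters, so re-running a config
reproduces the report bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cluster_stats as cs
from . import hrv as hrv_mod
from . import source_model as sm
from . import spectral as sp
from . import synthetic as syn
from .layout import SensorLayout, azimuthal_projection, build_adjacency, make_layout

__version__ = "0.1.0"


def _derive_seed(master_seed: int, *counters: int) -> int:
    """A reproducible 31-bit child seed for a pipeline stage."""
    state = np.random.SeedSequence([master_seed, *counters]).generate_state(1)
    return int(state[0] % (2**31))


@dataclass
class SourceStageConfig:
    """Reduced-scale raw-signal source stage settings.

    The raw route is demonstrated at desk scale: fewer subjects, shorter
    blocks and a lower sampling rate than the sensor-space statistics,
    with a depth-3 octahedral grid (258 vertices).
    """

    enabled: bool = True
    n_subjects: int = 8
    block_length: float = 16.0  # s per EO/EC block
    sampling_rate: float = 250.0
    depth: int = 3
    lambda2: float = 1.0 / 9.0
    ridge: float = 0.1
    normal_tilt: float = 1.0
    band: tuple[float, float] = (8.0, 12.0)
    noise_scale: float = 0.05  # sensor noise added before inversion


@dataclass
class HrvStageConfig:
    mean_rr: float = 0.9  # s
    sdnn: float = 0.05  # s
    rmssd: float = 0.04  # s
    window: float = hrv_mod.ANALYSIS_WINDOW_S  # 5-min analysis window


@dataclass
class PipelineConfig:
    """Schema-validated configuration of one synthetic experiment."""

    experiment: syn.ExperimentDesign = field(default_factory=syn.ExperimentDesign)
    n_triplets: int = 102
    cap_half_angle: float = 110.0
    adjacency_method: str = "delaunay"
    effect_ratio: float = 0.9
    subject_sd: float = 0.3
    noise_sd: float = 0.2
    eyes_ec_boost: float = 0.7
    target_size: int = 10
    target_sensors: tuple[int, ...] | None = None  # explicit override
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(sp.ALPHA_BANDS)
    )
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    final_alpha: float = 0.05
    rm_anova_effects: tuple[Any, ...] = (
        "exposure",
        "time",
        "eyes",
        ("time", "exposure"),
    )
    source: SourceStageConfig = field(default_factory=SourceStageConfig)
    hrv: HrvStageConfig = field(default_factory=HrvStageConfig)
    master_seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        if "experiment" in raw:
            kwargs["experiment"] = syn.ExperimentDesign(**raw.pop("experiment"))
        if "source" in raw:
            src = dict(raw.pop("source"))
            if "band" in src:
                src["band"] = tuple(src["band"])
            kwargs["source"] = SourceStageConfig(**src)
        if "hrv" in raw:
            kwargs["hrv"] = HrvStageConfig(**raw.pop("hrv"))
        if "bands" in raw:
            kwargs["bands"] = {k: tuple(v) for k, v in raw.pop("bands").items()}
        if "target_sensors" in raw and raw["target_sensors"] is not None:
            raw["target_sensors"] = tuple(raw["target_sensors"])
        if "rm_anova_effects" in raw:
            raw["rm_anova_effects"] = tuple(
                tuple(e) if isinstance(e, (list, tuple)) else e
                for e in raw.pop("rm_anova_effects")
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(dataclasses.asdict(self))


@dataclass
class RunReport:
    """Aggregated machine-readable result of one pipeline run."""

    provenance: dict[str, Any]
    sensor_clusters: list[dict[str, Any]]
    anova_clusters: list[dict[str, Any]]
    source_clusters: list[dict[str, Any]]
    hrv_table: pd.DataFrame
    exposure: dict[str, float]
    target_sensors: tuple[int, ...]

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "provenance": self.provenance,
            "target_sensors": list(self.target_sensors),
            "anova_clusters": self.anova_clusters,
            "sensor_clusters": self.sensor_clusters,
            "source_clusters": self.source_clusters,
            "hrv": self.hrv_table.to_dict(orient="records"),
            "exposure": self.exposure,
        }


def _cluster_records(
    clusters: list[cs.ClusterResult], **labels: Any
) -> list[dict[str, Any]]:
    return [
        {
            **labels,
            "effect": c.effect,
            "members": list(c.members),
            "size": c.size,
            "mass": round(c.mass, 6),
            "p": c.p_monte_carlo,
            "threshold": round(c.threshold, 6) if c.threshold is not None else None,
        }
        for c in clusters
    ]


def factorial_cell_table(
    dataset: pd.DataFrame, design: syn.ExperimentDesign
) -> tuple[np.ndarray, cs.DesignSpec]:
    """Average runs into the 2x2x2 (time, eyes, exposure) cell array.

    Baseline runs and post-exposure runs are each averaged per subject,
    session and eyes condition, yielding the repeated-measures ANOVA input.
    """
    df = dataset.copy()
    df["time"] = np.where(
        df["run"].isin(design.baseline_runs), "baseline", "post"
    )
    cellmeans = (
        df.groupby(["subject", "time", "eyes", "session", "sensor"], sort=True)[
            "log_power"
        ]
        .mean()
        .reset_index()
    )
    spec = cs.DesignSpec(
        factors=(
            ("time", ("baseline", "post")),
            ("eyes", tuple(sorted(design.eyes))),
            ("exposure", tuple(sorted(design.sessions))),
        )
    )
    arr, _, _ = cs.to_cell_array(
        cellmeans.rename(columns={"session": "exposure"}), spec
    )
    return arr, spec


def real_vs_sham_arrays(
    corrected: pd.DataFrame,
    eyes: str,
    runs: tuple[str, ...] | str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject x sensor matrices of baseline-corrected real and sham power.

    ``runs`` may be one run label or a tuple averaged together.
    """
    if isinstance(runs, str):
        runs = (runs,)
    sel = corrected[(corrected["eyes"] == eyes) & corrected["run"].isin(runs)]
    if sel.empty:
        raise ValueError(f"no rows for eyes={eyes!r}, runs={runs}")
    piv = sel.pivot_table(
        index="subject", columns=["session", "sensor"], values="log_power"
    )
    real = piv["real"].to_numpy()
    sham = piv["sham"].to_numpy()
    return real, sham


def sensor_stats_stage(
    dataset: pd.DataFrame,
    design: syn.ExperimentDesign,
    adjacency: np.ndarray,
    config: PipelineConfig,
    band_name: str,
    seed: int,
) -> tuple[list[dict[str, Any]], list[dict[str, Any]]]:
    """Omnibus ANOVA cluster tests plus per-run real-vs-sham cluster tests."""
    perm = cs.PermutationConfig(
        n_permutations=config.n_permutations,
        cluster_alpha=config.cluster_alpha,
        final_alpha=config.final_alpha,
        seed=seed,
    )
    anova_records: list[dict[str, Any]] = []
    arr, spec = factorial_cell_table(dataset, design)
    for effect in config.rm_anova_effects:
        clusters = cs.cluster_permutation_test(arr, spec, effect, adjacency, perm)
        anova_records += _cluster_records(clusters, band=band_name, test="rm_anova")

    oneway_records: list[dict[str, Any]] = []
    corrected = sp.baseline_correct(dataset, design.baseline_runs)
    for eyes in design.eyes:
        for run in design.post_runs:
            real, sham = real_vs_sham_arrays(corrected, eyes, run)
            clusters = cs.paired_cluster_test(real, sham, adjacency, perm)
            oneway_records += _cluster_records(
                clusters, band=band_name, test="oneway", eyes=eyes, run=run
            )
    return anova_records, oneway_records


def source_stage(
    layout: SensorLayout, config: PipelineConfig, seed: int
) -> list[dict[str, Any]]:
    """Raw-signal route at reduced scale, ending in source-space cluster tests."""
    scfg = config.source
    design = syn.ExperimentDesign(
        n_subjects=scfg.n_subjects,
        block_length=scfg.block_length,
        sampling_rate=scfg.sampling_rate,
    )
    effect = _resolve_effect(layout, config, ratio=config.effect_ratio)
    runs = syn.simulate_raw(design, layout, seed=_derive_seed(seed, 1), effect=effect)

    space = sm.folded_normals(
        sm.octahedral_source_space(scfg.depth), tilt=scfg.normal_tilt
    )
    fwd = sm.sarvas_forward(space, layout)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    # whitening noise: sensor noise floor used to scale mags and grads alike
    scale = np.abs(fwd.lead_field).mean(axis=1, keepdims=True)
    noise = rng.standard_normal((layout.n_channels, 4 * layout.n_channels)) * scale
    whitener = sm.compute_whitener(noise, ridge=scfg.ridge)
    inv = sm.minimum_norm_inverse(fwd, whitener, lambda2=scfg.lambda2)

    filt = sp.design_bandpass_fir(sp.FilterSpec(sampling_rate=scfg.sampling_rate))
    records = []
    for (subject, session, run), raw in runs.items():
        # project the simulated sensor-space signals into source space:
        # sensor signals are treated as field samples scaled to lead-field units
        sensor_data = raw.data * scale
        filtered = sp.apply_filter(sensor_data, filt)
        for start, stop, eyes in raw.blocks:
            fs = raw.sampling_rate
            seg = filtered[:, int(round(start * fs)) : int(round(stop * fs))]
            db = sm.source_band_power(inv, seg, scfg.band, fs)
            records.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "session": session,
                        "run": run,
                        "eyes": eyes,
                        "sensor": np.arange(space.n_vertices),
                        "log_power": db,
                    }
                )
            )
    source_ds = pd.concat(records, ignore_index=True)
    corrected = sp.baseline_correct(source_ds, design.baseline_runs)
    adj = space.adjacency()
    perm = cs.PermutationConfig(
        n_permutations=config.n_permutations,
        cluster_alpha=config.cluster_alpha,
        seed=_derive_seed(seed, 3),
    )
    out: list[dict[str, Any]] = []
    for eyes in design.eyes:
        real, sham = real_vs_sham_arrays(corrected, eyes, design.post_runs)
        clusters = cs.paired_cluster_test(real, sham, adj, perm)
        out += _cluster_records(
            clusters, space="source", eyes=eyes, run="post_mean", test="oneway"
        )
    return out


def hrv_stage(config: PipelineConfig, seed: int) -> pd.DataFrame:
    """Simulate per-run RR series and tabulate HRV control metrics."""
    design = config.experiment
    hcfg = config.hrv
    n_beats = int(round(hcfg.window / hcfg.mean_rr))
    rows = []
    for si, subject in enumerate(design.subjects):
        for ei, session in enumerate(design.sessions):
            for ri, run in enumerate(design.runs):
                rr = syn.simulate_rr(
                    n_beats,
                    mean_rr=hcfg.mean_rr,
                    sdnn_target=hcfg.sdnn,
                    rmssd_target=hcfg.rmssd,
                    seed=_derive_seed(seed, si, ei, ri),
                )
                m = hrv_mod.rr_metrics(rr)
                decision = hrv_mod.run_exclusion((), hcfg.window)
                rows.append(
                    {
                        "subject": subject,
                        "session": session,
                        "run": run,
                        "mean_rr": round(m.mean_rr, 6),
                        "sdnn": round(m.sdnn, 6),
                        "rmssd": round(m.rmssd, 6),
                        "hr": round(m.heart_rate, 6),
                        "excluded_flag": decision == "exclude",
                    }
                )
    return pd.DataFrame(rows)


def _resolve_effect(
    layout: SensorLayout, config: PipelineConfig, ratio: float | None = None
) -> syn.EffectSpec:
    adjacency = build_adjacency(layout, method=config.adjacency_method)
    kwargs = dict(
        effect_ratio=config.effect_ratio if ratio is None else ratio,
        subject_sd=config.subject_sd,
        noise_sd=config.noise_sd,
        eyes_ec_boost=config.eyes_ec_boost,
    )
    if config.target_sensors is not None:
        return syn.EffectSpec(target_sensors=tuple(config.target_sensors), **kwargs)
    return syn.default_effect(layout, adjacency, size=config.target_size, **kwargs)


def run_experiment(config: PipelineConfig | None = None) -> RunReport:
    """Execute the full synthetic experiment and return the aggregated report."""
    config = config or PipelineConfig()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    layout = make_layout(config.n_triplets, config.cap_half_angle)
    adjacency = build_adjacency(layout, method=config.adjacency_method)
    effect = _resolve_effect(layout, config)
    design = config.experiment

    anova_records: list[dict[str, Any]] = []
    oneway_records: list[dict[str, Any]] = []
    for bi, (band_name, band) in enumerate(sorted(config.bands.items())):
        ds_seed = _derive_seed(config.master_seed, 10, bi)
        dataset = syn.simulate_band_power(
            design, layout, effect, seed=ds_seed, adjacency=adjacency
        )
        if out_dir:
            syn.write_band_power_tsv(
                dataset, out_dir / f"band_power_{band_name}.tsv"
            )
        a_rec, o_rec = sensor_stats_stage(
            dataset, design, adjacency, config, band_name,
            seed=_derive_seed(config.master_seed, 20, bi),
        )
        anova_records += a_rec
        oneway_records += o_rec

    source_records: list[dict[str, Any]] = []
    if config.source.enabled:
        source_records = source_stage(
            layout, config, seed=_derive_seed(config.master_seed, 30)
        )

    hrv_table = hrv_stage(config, seed=_derive_seed(config.master_seed, 40))

    exposure = {
        "peak_power_w": 2.0,
        "duty_cycle": 1.0 / 8.0,
        "average_power_w": syn.gsm_average_power(2.0, 1.0 / 8.0),
    }

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    provenance = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": config.master_seed,
        "version": __version__,
    }
    report = RunReport(
        provenance=provenance,
        sensor_clusters=oneway_records,
        anova_clusters=anova_records,
        source_clusters=source_records,
        hrv_table=hrv_table,
        exposure=exposure,
        target_sensors=effect.target_sensors,
    )
    if out_dir:
        hrv_table.to_csv(out_dir / "hrv.tsv", sep="\t", index=False)
        with open(out_dir / "clusters.json", "w") as fh:
            json.dump(
                {
                    "sensor": oneway_records,
                    "anova": anova_records,
                    "source": source_records,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=1, sort_keys=True)
    return report


def export_topography(
    values: np.ndarray,
    layout: SensorLayout,
    path: str | Path,
    image: bool = False,
) -> pd.DataFrame:
    """Write per-sensor values as a flattened topographic map.

    Always writes a TSV of (sensor, x, y, value) using the azimuthal-
    equidistant projection; with ``image=True`` (or a ``.png`` path) also
    renders a scatter topography.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != layout.n_triplets:
        raise ValueError(
            f"{values.shape[0]} values for {layout.n_triplets} sensor triplets"
        )
    path = Path(path)
    xy = azimuthal_projection(layout.positions)
    table = pd.DataFrame(
        {
            "sensor": np.arange(layout.n_triplets),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "value": values,
        }
    )
    tsv_path = path.with_suffix(".tsv") if path.suffix == ".png" else path
    # %.17g guarantees bit-exact float round-trips through the TSV
    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    if image or path.suffix == ".png":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        sc = ax.scatter(table["x"], table["y"], c=table["value"], s=60, cmap="RdBu_r")
        ax.set_aspect("equal")
        ax.set_axis_off()
        fig.colorbar(sc, ax=ax, shrink=0.8)
        fig.savefig(path.with_suffix(".png"), dpi=120, bbox_inches="tight")
        plt.close(fig)
    return table
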