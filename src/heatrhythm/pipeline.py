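"""End-to-end pipeline: simulate -> fit -> timeshift -> exposure -> project.

One global seed fans out deterministically to per-stage child seeds through
``numpy.random.SeedSequence``; a JSON manifest records stages, outputs,
seeds and a hash of the configuration so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import HeatRhythmError
from . import estimator, exposure, io, projection, synth, timeshift

STAGES = ("simulate", "fit", "timeshift", "exposure", "project")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds below 2^31."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    out_dir: str
    seed: int = 0
    synth: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    merge_below: float | None = 0.0
    merge_above: float | None = 35.0
    baseline_group: str = "15-20"
    comparison_group: str = ">30"
    ref_hour: float = 20.0
    exposure_bin: tuple[float, float] = (30.0, 35.0)
    n_models: int = 21
    n_quantiles: int = 25
    scenario: str = "rcp85"
    deltas_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "synth" in data:
            data["synth"] = synth.SyntheticConfig.from_dict(data["synth"])
        if "exposure_bin" in data:
            data["exposure_bin"] = tuple(data["exposure_bin"])
        if data.get("deltas_path") is not None:
            p = Path(data["deltas_path"])
            if not p.exists():
                raise HeatRhythmError(f"deltas_path {p} does not exist")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "synth"}
            | {"synth": self.synth.to_dict()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run all five stages; abort on the first failing stage.

    Returns the manifest (also written to ``manifest.json``).  Partial
    outputs of completed stages are preserved on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def record(stage: str, **files):
        manifest["stages"][stage] = {k: str(v) for k, v in files.items()}
        io.write_json(manifest, out / "manifest.json")

    stage = "simulate"
    try:
        panel, truth = synth.generate_panel(config.synth, seed=seeds[stage])
        p_panel = io.write_panel(panel, out / "panel.csv")
        p_truth = io.write_truth(truth, out / "truth.yaml")
        record(stage, panel=p_panel, truth=p_truth)

        stage = "fit"
        bins = estimator.BinSpec(
            merge_below=config.merge_below, merge_above=config.merge_above
        )
        spec = estimator.ModelSpec(temperature=bins)
        main_fit = estimator.fit(panel, spec)
        try:
            lo, hi = (float(v) for v in config.baseline_group.split("-"))
        except ValueError as exc:
            raise HeatRhythmError(
                f"baseline_group {config.baseline_group!r} must be an interior "
                "bin label like '15-20'"
            ) from exc
        daily_bins = estimator.BinSpec(
            reference=(lo, hi),
            merge_below=config.merge_below,
            merge_above=30.0,
        )
        daily_fit = estimator.fit_daily(
            panel, replace(spec, temperature=daily_bins), stat="mean"
        )
        p_main = io.write_json(main_fit.to_dict(), out / "fit_main.json")
        main_fit.bin_table().to_csv(out / "fit_main_bins.csv")
        p_daily = io.write_json(daily_fit.to_dict(), out / "fit_daily.json")
        record(stage, main=p_main, daily=p_daily,
               bins=out / "fit_main_bins.csv")

        stage = "timeshift"
        profile = estimator.fit_hourly_profile(
            panel, spec, temp_groups=[config.baseline_group, config.comparison_group]
        )
        q_curve = timeshift.daily_quantity_curve(
            daily_fit, baseline=config.baseline_group
        )
        result = timeshift.timeshift_ci(
            profile,
            q_curve,
            comparison_group=config.comparison_group,
            baseline_group=config.baseline_group,
            ref_hour=config.ref_hour,
        )
        p_prof = io.write_profile(profile, out / "profiles.csv")
        p_q = io.write_quantity_curve(q_curve, out / "quantity_curve.json")
        p_shift = io.write_json(result.to_dict(), out / "timeshift.json")
        record(stage, profiles=p_prof, quantity=p_q, timeshift=p_shift)

        stage = "exposure"
        summary = exposure.period_exposure(panel, config.exposure_bin)
        p_exp = io.write_json(summary.to_dict(), out / "exposure.json")
        record(stage, exposure=p_exp)

        stage = "project"
        # the baseline year spans all twelve months regardless of the
        # panel's study window
        year = str(config.synth.start_date)[:4]
        full_year = replace(
            config.synth, start_date=f"{year}-01-01", n_days=365
        )
        climate = synth.generate_climate(full_year, seed=seeds["simulate"])
        baseline = projection.baseline_from_hourly(climate)
        if config.deltas_path:
            deltas = io.read_deltas(config.deltas_path)
        else:
            deltas = synth.make_climate_deltas(
                n_models=config.n_models,
                cells=tuple(sorted(baseline["cell"].unique())),
                seed=seeds[stage],
                scenario=config.scenario,
            )
        spline = projection.fit_spline(main_fit)
        result_p = projection.monte_carlo(
            spline, baseline, deltas, n_quantiles=config.n_quantiles
        )
        result_p.table.to_csv(out / "projection.csv", index=False)
        record(stage, projection=out / "projection.csv")
    except Exception as exc:
        raise HeatRhythmError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["complete"] = True
    io.write_json(manifest, out / "manifest.json")
    return manifest
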