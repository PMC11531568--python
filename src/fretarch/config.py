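"""Schema-validated run configuration and the staged pipeline runner."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .io import write_trace_set
from .photophysics import efficiency_to_distance
from .pipeline import analyze_cohort, derive_seed
from .presets import fluorophore_pair
from .simulate import TraceSimParams, simulate_trace_cohort

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateStage(_Forbid):
    n_traces: int = 200
    donor_only_fraction: float = 0.15
    acceptor_only_fraction: float = 0.15
    true_distance: float = 4.8
    fluorophore_pair_id: str = "cy3b_T"
    frames: int = 800
    mean_donor_photons: float = 300.0
    alpha: float = 0.05
    delta: float = 0.05
    gamma: float = 1.0
    beta: float = 1.0
    donor_bleach_rate: float = 0.002
    acceptor_bleach_rate: float = 0.004
    background_per_channel: float = 10.0


class AnalyzeStage(_Forbid):
    s_window: tuple[float, float] = (0.3, 0.7)
    min_dwell: int = 5
    step_threshold: float = 5.0


class PdaStage(_Forbid):
    bins: int = 40
    n_states: int = 1


class DiscriminateStage(_Forbid):
    forms: dict[str, dict[str, float]] = Field(default_factory=dict)
    sigma_R: float = 0.4
    e_detect: float = 0.1


class RunConfig(_Forbid):
    seed: int = 0
    out_dir: str = "fretarch_run"
    stages: list[str] = Field(
        default_factory=lambda: ["simulate", "analyze"]
    )
    simulate: SimulateStage = Field(default_factory=SimulateStage)
    analyze: AnalyzeStage = Field(default_factory=AnalyzeStage)
    pda: PdaStage = Field(default_factory=PdaStage)
    discriminate: DiscriminateStage = Field(default_factory=DiscriminateStage)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.model_validate(yaml.safe_load(Path(path).read_text()))


_STAGE_ORDER = ["simulate", "analyze", "pda", "discriminate"]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns (and writes) a manifest recording versions, per-stage seeds,
    input digests and outputs.  Any stage failure raises with the stage
    name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(_STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in _STAGE_ORDER if s in config.stages]

    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "global_seed": config.seed,
        "stages": {},
    }
    ts = None
    analysis = None
    for stage in stages:
        seed = derive_seed(config.seed, stage)
        record: dict = {"seed": seed}
        try:
            if stage == "simulate":
                sim = config.simulate
                params = TraceSimParams(
                    true_distance=sim.true_distance,
                    fluorophore_pair_id=sim.fluorophore_pair_id,
                    frames=sim.frames,
                    mean_donor_photons=sim.mean_donor_photons,
                    alpha=sim.alpha,
                    delta=sim.delta,
                    gamma=sim.gamma,
                    beta=sim.beta,
                    donor_bleach_rate=sim.donor_bleach_rate,
                    acceptor_bleach_rate=sim.acceptor_bleach_rate,
                    background_per_channel=sim.background_per_channel,
                    seed=seed,
                )
                ts = simulate_trace_cohort(
                    sim.n_traces,
                    params,
                    sim.donor_only_fraction,
                    sim.acceptor_only_fraction,
                )
                trace_dir = out / "traces"
                paths = write_trace_set(ts, trace_dir)
                digest = hashlib.sha256()
                for p in paths:
                    digest.update(p.read_bytes())
                record["n_traces"] = len(ts)
                record["trace_dir"] = str(trace_dir)
                record["traces_sha256"] = digest.hexdigest()
            elif stage == "analyze":
                if ts is None:
                    raise RuntimeError("analyze requires the simulate stage")
                analysis = analyze_cohort(
                    ts,
                    s_window=tuple(config.analyze.s_window),
                    min_dwell=config.analyze.min_dwell,
                    step_threshold=config.analyze.step_threshold,
                )
                pair = fluorophore_pair(config.simulate.fluorophore_pair_id)
                mean_e = analysis.population.mean_E
                record.update(
                    {
                        "factors": vars(analysis.factors),
                        "mean_E": mean_e,
                        "sigma_E": analysis.population.sigma_E,
                        "n_traces_fit": analysis.population.n_traces,
                        "distance_nm": efficiency_to_distance(
                            np.clip(mean_e, 1e-6, 1 - 1e-6), pair.R0
                        ),
                    }
                )
                (out / "es_population.json").write_text(
                    json.dumps(record, indent=1, default=float)
                )
            elif stage == "pda":
                if analysis is None:
                    raise RuntimeError("pda requires the analyze stage")
                from .pda import pda_fit, windows_from_selected

                pair = fluorophore_pair(config.simulate.fluorophore_pair_id)
                windows = windows_from_selected(analysis.selected)
                fit = pda_fit(
                    windows,
                    R0=pair.R0,
                    factors=analysis.factors,
                    bins=config.pda.bins,
                    n_states=config.pda.n_states,
                )
                record.update(
                    {
                        "distance_nm": fit.distance_nm,
                        "width_nm": fit.width_nm,
                        "chi2_per_dof": fit.chi2_per_dof,
                    }
                )
                (out / "pda_fit.json").write_text(
                    json.dumps(record, indent=1, default=float)
                )
            elif stage == "discriminate":
                if analysis is None:
                    raise RuntimeError("discriminate requires the analyze stage")
                from .discriminate import (
                    MeasuredDistanceSet,
                    MeasuredPair,
                    select_form,
                )

                pair = fluorophore_pair(config.simulate.fluorophore_pair_id)
                mean_e = float(np.clip(analysis.population.mean_E, 1e-6, 1 - 1e-6))
                r = efficiency_to_distance(mean_e, pair.R0)
                measured = MeasuredDistanceSet(
                    entries={
                        "T-T": MeasuredPair(R=r, sigma_R=config.discriminate.sigma_R)
                    }
                )
                report = select_form(measured, config.discriminate.forms)
                record.update(report)
                (out / "discrimination.json").write_text(
                    json.dumps(record, indent=1, default=float)
                )
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = record
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return manifest
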