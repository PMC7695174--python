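"""End-to-end expansion study: build topology -> disordered tails ->
seeded production runs -> translocation analysis -> report bundle.

The default protocol mirrors the production study design: four
randomly selected disordered starting conformations, five independent
simulations from each (20 runs total), production reduced temperature
0.582 with timestep 0.002, tail generation at reduced temperature 1.0.
Every random stream derives from one master seed via seed-sequence
splitting, so a report bundle is a pure function of (config, code).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import (AnalysisParams, QTrace, TranslocationEvent,
                       count_events_by_position, detect_translocation,
                       ensemble_statistics, equilibration_cutoff,
                       event_count_curve, q_probability_distribution, q_trace,
                       rg_trace, tail_contact_subset)
from .contacts import ShadowParams
from .dynamics import (PRODUCTION_TEMPERATURE, TAIL_GENERATION_TEMPERATURE,
                       LangevinParams, SimulationState, generate_disordered_tails,
                       initialize_velocities, run_langevin)
from .structures import MolecularStructure
from .topology import build_topology
from .toyshell import ToyShellPair, ToyShellSpec, make_toy_shell, throat_contact_filter
from .trajectory import Trajectory, write_trajectory

__all__ = ["PipelineConfig", "PipelineReport", "ConfigError", "validate_config",
           "run_pipeline", "simulate_runs", "analyze_runs"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every violation."""


# soft-bonded defaults for the coarse (bead-per-residue) toy topology;
# atomistic structures use the stiffer module-level defaults instead
TOY_BOND_K = 200.0
TOY_ANGLE_K = 20.0


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline settings; see :func:`validate_config`."""

    toy: ToyShellSpec = field(default_factory=ToyShellSpec)
    shadow: ShadowParams = field(default_factory=ShadowParams)
    scale_factor: float = 0.95
    bond_k: float = TOY_BOND_K
    angle_k: float = TOY_ANGLE_K
    n_starting_conformations: int = 4
    runs_per_conformation: int = 5
    production: LangevinParams = field(default_factory=lambda: LangevinParams(
        reduced_temperature=PRODUCTION_TEMPERATURE, timestep=0.002,
        friction=1.0, n_steps=100_000, save_interval=1000))
    tail_generation: LangevinParams = field(default_factory=lambda: LangevinParams(
        reduced_temperature=TAIL_GENERATION_TEMPERATURE, timestep=0.002,
        friction=1.0, n_steps=0, save_interval=500))
    tail_restraint_k: float = 500.0
    tail_equilibration_steps: int = 4000
    tail_stride_steps: int = 4000
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    master_seed: int = 0
    output_dir: str | None = None
    write_trajectories: bool = False

    @property
    def n_runs(self) -> int:
        return self.n_starting_conformations * self.runs_per_conformation


_BLOCK_KEYS = {
    "toy": ToyShellSpec, "shadow": ShadowParams,
    "production": LangevinParams, "tail_generation": LangevinParams,
    "analysis": AnalysisParams,
}
_SCALAR_KEYS = {"scale_factor", "bond_k", "angle_k", "n_starting_conformations",
                "runs_per_conformation", "tail_restraint_k",
                "tail_equilibration_steps", "tail_stride_steps", "master_seed",
                "output_dir", "write_trajectories"}


def validate_config(raw: dict | None = None) -> tuple[PipelineConfig, list[str]]:
    """Normalize a raw (e.g. YAML-loaded) config dict.

    Unknown keys are rejected; every violation is collected and reported
    in a single :class:`ConfigError`.  Returns the validated config and
    a list of notices about defaulted values.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    notices: list[str] = []
    kwargs: dict = {}
    for key in list(raw):
        if key in _BLOCK_KEYS:
            block_cls = _BLOCK_KEYS[key]
            try:
                kwargs[key] = (raw[key] if isinstance(raw[key], block_cls)
                               else block_cls(**raw[key]))
            except (TypeError, ValueError) as exc:
                errors.append(f"{key}: {exc}")
        elif key in _SCALAR_KEYS:
            kwargs[key] = raw[key]
        else:
            errors.append(f"unknown configuration key {key!r}")
    if "production" not in kwargs:
        notices.append(f"production temperature defaulted to "
                       f"{PRODUCTION_TEMPERATURE} (reduced units)")
    if "tail_generation" not in kwargs:
        notices.append(f"tail-generation temperature defaulted to "
                       f"{TAIL_GENERATION_TEMPERATURE} (reduced units)")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    try:
        cfg = PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return cfg, notices


def _derive_seeds(master_seed: int, n: int, stream: str) -> list[int]:
    """n deterministic sub-seeds (< 2**31) for one named stream."""
    import zlib

    tag = zlib.crc32(stream.encode())
    ss = np.random.SeedSequence([int(master_seed), int(tag)])
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


@dataclass
class PipelineReport:
    """Everything the study produces, plus a reproducibility manifest."""

    events: list[TranslocationEvent]
    counts: dict[str, int]
    time_grid: np.ndarray
    ni_curves: dict[str, np.ndarray]        # label -> (n_runs, n_times)
    ni_mean: dict[str, np.ndarray]
    ni_sd: dict[str, np.ndarray]
    q_distributions: dict
    rg_traces: list[np.ndarray]
    q_traces: list[QTrace]
    manifest: dict

    def event_table(self):
        """Events as a pandas DataFrame (chain, position, run, time)."""
        import pandas as pd

        columns = ["run_id", "chain_id", "position_label",
                   "first_passage_time"]
        return pd.DataFrame(
            [{"run_id": e.run_id, "chain_id": e.chain_id,
              "position_label": e.position_label,
              "first_passage_time": e.first_passage_time}
             for e in self.events],
            columns=columns)


def _build_toy_system(cfg: PipelineConfig, seed: int):
    pair = make_toy_shell(cfg.toy, seed=seed)
    topology = build_topology(
        pair.expanded_reference, shadow=cfg.shadow,
        scale_factor=cfg.scale_factor, bonds=pair.bonds,
        bond_k=cfg.bond_k, angle_k=cfg.angle_k,
        contact_filter=throat_contact_filter(pair))
    return pair, topology


def simulate_runs(cfg: PipelineConfig, pair: ToyShellPair, topology,
                  starting_conformations: list[MolecularStructure],
                  run_seeds: list[int]) -> list[Trajectory]:
    """The production stage: one Langevin run per (conformation, repeat)."""
    trajectories = []
    for idx, seed in enumerate(run_seeds):
        conf = starting_conformations[idx % len(starting_conformations)]
        state = SimulationState(
            positions=conf.positions.copy(),
            velocities=initialize_velocities(
                conf.n_atoms, cfg.production.reduced_temperature, seed,
                topology.masses))
        params = replace(cfg.production, seed=seed)
        trajectories.append(run_langevin(topology, state, params))
    return trajectories


def analyze_runs(cfg: PipelineConfig, pair: ToyShellPair, topology,
                 trajectories: list[Trajectory]) -> PipelineReport:
    """The analysis stage; a pure function of its inputs, so it can be
    re-run on stored trajectories and reproduce the report exactly."""
    ap = cfg.analysis
    exp = pair.expanded_reference
    labels = sorted({a.position_label for a in pair.annotations})
    chains_per_label = len(pair.annotations) // len(labels)

    subsets = {ann.chain_id: tail_contact_subset(topology.contacts, exp,
                                                 ann.chain_id, ap)
               for ann in pair.annotations}

    events: list[TranslocationEvent] = []
    q_traces: list[QTrace] = []
    rg_traces_ = []
    q_samples: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    for run_id, traj in enumerate(trajectories):
        rg = rg_trace(traj)
        rg_traces_.append(rg)
        cut = equilibration_cutoff(rg)
        for ann in pair.annotations:
            tr = q_trace(traj, subsets[ann.chain_id], ann.chain_id,
                         ann.position_label, ap)
            q_traces.append(tr)
            ev = detect_translocation(tr, ap.translocation_threshold,
                                      run_id=run_id,
                                      dwell_frames=ap.dwell_frames)
            if ev is not None:
                events.append(ev)
            q_samples[ann.position_label].append(tr.q_values[cut:])

    counts = count_events_by_position(events, labels, chains_per_label,
                                      len(trajectories))
    time_grid = trajectories[0].times
    ni_curves, ni_mean, ni_sd = {}, {}, {}
    for lab in labels:
        curves = np.stack([
            event_count_curve([e for e in events if e.run_id == r], lab,
                              time_grid)
            for r in range(len(trajectories))])
        ni_curves[lab] = curves
        if len(trajectories) >= 2:
            ni_mean[lab], ni_sd[lab] = ensemble_statistics(curves)
        else:
            ni_mean[lab], ni_sd[lab] = curves[0], np.zeros_like(curves[0])

    q_dists = q_probability_distribution(
        {lab: np.concatenate(qs) for lab, qs in q_samples.items()}, ap)

    manifest = {
        "code_version": __version__,
        "master_seed": cfg.master_seed,
        "n_runs": len(trajectories),
        "production": asdict(cfg.production),
        "analysis": asdict(cfg.analysis),
        "toy_spec": asdict(cfg.toy),
        "scale_factor": cfg.scale_factor,
        "labels": labels,
        "chains_per_label": chains_per_label,
    }
    return PipelineReport(events=events, counts=counts, time_grid=time_grid,
                          ni_curves=ni_curves, ni_mean=ni_mean, ni_sd=ni_sd,
                          q_distributions=q_dists, rg_traces=rg_traces_,
                          q_traces=q_traces, manifest=manifest)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run the full study; see module docstring.

    Stages: toy generation, topology, disordered-tail generation,
    ``n_starting_conformations x runs_per_conformation`` production runs,
    analysis.  On failure the offending stage and run id are reported.
    """
    t_start = time.time()
    stage = "toy-generation"
    try:
        toy_seed = _derive_seeds(cfg.master_seed, 1, "toy")[0]
        pair, topology = _build_toy_system(cfg, toy_seed)

        stage = "tail-generation"
        tail_seed = _derive_seeds(cfg.master_seed, 1, "tails")[0]
        tail_params = cfg.tail_generation
        confs, tail_manifest = generate_disordered_tails(
            pair.compact, topology,
            n_samples=cfg.n_starting_conformations,
            high_temperature=tail_params.reduced_temperature,
            restraint_k=cfg.tail_restraint_k,
            seed=tail_seed,
            equilibration_steps=cfg.tail_equilibration_steps,
            stride_steps=cfg.tail_stride_steps,
            timestep=tail_params.timestep)

        stage = "production"
        run_seeds = _derive_seeds(cfg.master_seed, cfg.n_runs, "production")
        trajectories = simulate_runs(cfg, pair, topology, confs, run_seeds)

        stage = "analysis"
        report = analyze_runs(cfg, pair, topology, trajectories)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    report.manifest.update({
        "toy_seed": toy_seed, "tail_seed": tail_seed, "run_seeds": run_seeds,
        "tail_generation": tail_manifest,
        "wall_time_s": round(time.time() - t_start, 2),
    })
    if cfg.output_dir is not None:
        _write_report(cfg, pair, trajectories, report)
    return report


def _write_report(cfg: PipelineConfig, pair: ToyShellPair,
                  trajectories: list[Trajectory], report: PipelineReport) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.event_table().to_csv(out / "events.tsv", sep="\t", index=False)
    with open(out / "counts.tsv", "w") as fh:
        fh.write("position_label\tevents\n")
        for lab, n in sorted(report.counts.items()):
            fh.write(f"{lab}\t{n}\n")
    with open(out / "ni_curves.tsv", "w") as fh:
        fh.write("position_label\ttime\tmean\tsd\n")
        for lab in sorted(report.ni_mean):
            for t, mu, sd in zip(report.time_grid, report.ni_mean[lab],
                                 report.ni_sd[lab]):
                fh.write(f"{lab}\t{t:.4f}\t{mu:.4f}\t{sd:.4f}\n")
    dists = {lab: {"bin_edges": d.bin_edges.tolist(),
                   "probabilities": d.probabilities.tolist(),
                   "peaks": d.peaks}
             for lab, d in report.q_distributions.items()}
    with open(out / "q_distributions.json", "w") as fh:
        json.dump(dists, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=1, default=str)
    if cfg.write_trajectories:
        for i, traj in enumerate(trajectories):
            write_trajectory(traj, out / f"run_{i:03d}.xyz")
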