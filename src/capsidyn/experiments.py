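"""Canned desk-scale study presets.

These functions wrap the pipeline into the two ensemble experiments the
toy shell was designed for:

* :func:`steric_hierarchy_experiment` -- replicate shells whose cavity
  half-widths are strictly ordered across position classes; per-class
  translocation counts at the end of a fixed production window should
  rank-correlate with the widths (the desk-scale analogue of the
  position-dependent kinetic hierarchy of the real capsid).
* :func:`intermediate_detection_experiment` -- small shells whose exit
  routes carry a deliberate mid-path constriction ("kinked" cavities)
  versus straight controls; the constriction produces a long-lived
  intermediate, visible as a peak at intermediate Q in the Q probability
  distribution.

Problem sizes are chosen so each experiment completes in minutes on a
single CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import spearmanr

from .analysis import (AnalysisParams, detect_translocation, equilibration_cutoff,
                       q_probability_distribution, q_trace, rg_trace,
                       tail_contact_subset)
from .dynamics import LangevinParams, SimulationState, initialize_velocities, run_langevin
from .pipeline import TOY_ANGLE_K, TOY_BOND_K
from .topology import build_topology
from .toyshell import (ORDERED_CAVITY_WIDTHS, ToyShellSpec, make_toy_shell,
                       throat_contact_filter)

__all__ = ["steric_hierarchy_experiment", "intermediate_detection_experiment"]


def _run_shell(spec: ToyShellSpec, seed: int, n_steps: int,
               params: AnalysisParams, save_interval: int = 1000):
    """One seeded production run on one toy shell; returns the shell,
    topology, trajectory."""
    pair = make_toy_shell(spec, seed=seed)
    exp = pair.expanded_reference
    topology = build_topology(exp, bonds=pair.bonds,
                              bond_k=TOY_BOND_K, angle_k=TOY_ANGLE_K,
                              contact_filter=throat_contact_filter(pair))
    state = SimulationState(
        positions=pair.compact.positions.copy(),
        velocities=initialize_velocities(exp.n_atoms, 0.582, seed,
                                         topology.masses))
    traj = run_langevin(topology, state,
                        LangevinParams(n_steps=n_steps, seed=seed,
                                       save_interval=save_interval))
    return pair, topology, traj


def steric_hierarchy_experiment(n_seeds: int = 10, n_steps: int = 130_000,
                                base_seed: int = 0,
                                widths: dict | None = None,
                                params: AnalysisParams | None = None) -> dict:
    """Ensemble of seeded runs on shells with strictly ordered cavity widths.

    Returns per-class event counts, their Spearman rank correlation with
    the widths, and the fraction of seeds in which the narrowest class
    had the fewest events (ties counting as fewest).
    """
    widths = dict(widths or ORDERED_CAVITY_WIDTHS)
    params = params or AnalysisParams()
    spec = ToyShellSpec(cavity_half_widths=widths)
    labels = spec.labels
    counts = {lab: 0 for lab in labels}
    per_seed = []
    narrowest = min(widths, key=widths.get)
    narrowest_fewest = 0
    for s in range(n_seeds):
        seed = base_seed + s
        pair, topology, traj = _run_shell(spec, seed, n_steps, params)
        seed_counts = {lab: 0 for lab in labels}
        for ann in pair.annotations:
            subset = tail_contact_subset(topology.contacts,
                                         pair.expanded_reference,
                                         ann.chain_id, params)
            trace = q_trace(traj, subset, ann.chain_id, ann.position_label,
                            params)
            if detect_translocation(trace, params.translocation_threshold,
                                    run_id=seed) is not None:
                seed_counts[ann.position_label] += 1
        for lab, n in seed_counts.items():
            counts[lab] += n
        if seed_counts[narrowest] == min(seed_counts.values()):
            narrowest_fewest += 1
        per_seed.append(seed_counts)
    rho, pval = spearmanr([widths[lab] for lab in labels],
                          [counts[lab] for lab in labels])
    return {
        "widths": widths,
        "counts": counts,
        "per_seed": per_seed,
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "narrowest_class": narrowest,
        "narrowest_fewest_seeds": narrowest_fewest,
        "n_seeds": n_seeds,
        "n_steps": n_steps,
    }


#: small two-class shell used for the intermediate-detection contrast
_KINK_SPEC = dict(n_position_classes=2, chains_per_class=2,
                  residues_per_chain=60, tail_length=6,
                  compact_radius=1.23, expanded_radius=1.40,
                  cavity_half_widths={"A": 0.46, "B": 0.46})


def intermediate_detection_experiment(n_seeds: int = 4, n_steps: int = 120_000,
                                      base_seed: int = 500) -> dict:
    """Kinked-cavity vs straight-cavity Q-distribution contrast.

    Pools post-expansion Q samples over all tails and seeds for each
    condition and detects histogram peaks.  The kinked condition is
    expected to show at least one intermediate peak; the straight
    control none.
    """
    # Q takes ~n_contacts+1 discrete values per chain, so the histogram
    # uses coarse bins to stay below that granularity
    params = AnalysisParams(histogram_bins=8)
    out: dict = {}
    for tag, kinked in (("straight", ()), ("kinked", ("A", "B"))):
        spec = ToyShellSpec(kinked_classes=kinked, **_KINK_SPEC)
        samples = []
        for s in range(n_seeds):
            pair, topology, traj = _run_shell(spec, base_seed + s, n_steps,
                                              params, save_interval=400)
            cut = equilibration_cutoff(rg_trace(traj))
            for ann in pair.annotations:
                subset = tail_contact_subset(topology.contacts,
                                             pair.expanded_reference,
                                             ann.chain_id, params)
                trace = q_trace(traj, subset, ann.chain_id,
                                ann.position_label, params)
                samples.append(trace.q_values[cut:])
        dist = q_probability_distribution(
            {tag: np.concatenate(samples)}, params)[tag]
        out[tag] = {
            "distribution": dist,
            "intermediate_peaks": dist.intermediate_peaks,
        }
    out["n_seeds"] = n_seeds
    out["n_steps"] = n_steps
    return out
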