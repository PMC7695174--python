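# capsidyn

Structure-based simulation and analysis of viral capsid expansion and
trans-shell tail translocation.

## The problem

During maturation of tailed bacteriophages such as T7, DNA packaging is
accompanied by a ~14% expansion of the icosahedral protein shell (radius
of gyration ~25 nm → ~28.5 nm) and by a striking disorder–order
transition: the N-terminal tails of the 420 major capsid-protein chains,
disordered on the *inner* surface of the compact shell, thread through
cavities in the shell wall and become ordered on the *outer* surface.
Which tails translocate quickly and which stall is governed not by
energetics (the mature state is downhill for every tail) but by
molecular *sterics*: the width and shape of the trans-shell cavity at
each monomer position (A–F in the hexons, G in the pentons).

`capsidyn` implements the full modelling workflow for studying this
process with a single-basin structure-based (Gō-like) model, plus a
synthetic *toy shell* generator so the entire pipeline runs at desk
scale without the 10⁶-atom production system.

## The model

All stabilizing interactions are defined from one reference ("native")
conformation — the expanded, mature shell — making it the potential
energy minimum:

- native contacts from the **Shadow map**: atom pairs within 0.6 nm of
  each other in the reference, unless a third atom (sphere of radius
  0.1 nm) occludes the line of sight; each contact is a 6–12
  Lennard-Jones well of depth ε with its minimum at σ = 0.95 · r_native
  (the 5% compression keeps the free-energy minimum in R_g at the
  mature value);
- harmonic bonds and angles with Amber-ff03-valued equilibria
  (reference-geometry fallback, logged);
- rigid dihedrals (planar/sp² central bonds): k(1 − cos 2φ), minima at
  0° and 180°; flexible dihedrals: minima at the reference torsion;
- r⁻¹² excluded volume (radius 0.25 nm) between all remaining pairs —
  the steric term the model exists to probe.

Dynamics are Langevin (BAOAB splitting) in reduced units: production
temperature 0.582, timestep 0.002, all atoms unit mass.  Disordered
starting tails are generated by a restrained simulation at reduced
temperature 1.0.  The observables follow the standard native-contact
formalism: per-chain fraction Q_i of mature-specific intermolecular
tail contacts (a contact is *formed* when r < 1.5 · r_native), a chain
has *translocated* at the first time Q_i ≥ 0.8 (inclusive), counts
N_i(t) are accumulated per monomer position over an ensemble of
seeded runs (default 4 starting conformations × 5 runs).

## Worked example

```python
from capsidyn import validate_config, run_pipeline

cfg, _ = validate_config({
    "toy": {"n_position_classes": 2, "chains_per_class": 2,
            "residues_per_chain": 60, "tail_length": 6,
            "compact_radius": 1.23, "expanded_radius": 1.40,
            "cavity_half_widths": {"A": 0.40, "B": 0.45}},
    "n_starting_conformations": 2, "runs_per_conformation": 2,
    "production": {"n_steps": 60000, "save_interval": 1000},
    "master_seed": 7,
})
report = run_pipeline(cfg)
print(report.counts)
```

```
{'A': 0, 'B': 1}
```

This tiny study builds a 4-chain toy shell whose class-B cavities are
0.05 nm wider than class A, runs four seeded expansion simulations of
60 000 steps from two disordered starting conformations, and counts
translocation events per position class: one of the four class-B tails
(the wider cavities) reaches the exterior within this short window while
no class-A tail does.  Resolving the full seven-class hierarchy takes
the ensemble experiment in `capsidyn.experiments`.  `report` also carries the first-passage event
table, N_i(t) mean ± SD curves, R_g traces and the Q_i probability
distributions.

The same study runs from the shell:

```bash
capsidyn all --seed 7 --outdir out/           # full default study
capsidyn toy --seed 1 --outdir shell/         # just the synthetic shell
capsidyn build-top --reference shell/expanded.tsv --out top.json
```

Real structures are supported through the same interfaces: PDB files
are parsed (Å → nm) with `read_structure`, 420-chain assemblies are
built from an asymmetric unit with `expand_assembly`, and
`build_topology` accepts any heavy-atom reference conformation.

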