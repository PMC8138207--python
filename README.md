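# graphdock

Pose prediction and virtual screening for **graphene-based drug delivery
systems (GDDS)** — non-covalent complexes of a drug molecule adsorbed on a
graphene or graphene-oxide (GO) carrier — using a **quantum genetic
algorithm (QGA)** and a multi-fidelity **cascade protocol**.

It is written for computational chemists and nanomaterials researchers who
want to estimate, before any experiment, how stably a drug-like molecule
binds to a graphitic carrier and which carrier functionalization keeps
that binding intact.

## What it does

- **Carrier generation.** Circular or rectangular pristine graphene sheets
  are cut from an ideal honeycomb lattice (C–C 1.42 Å, sheet in z = 0),
  hydrogen-terminated at the edges.  Sheets are decorated with hydroxyl
  and epoxy groups on the basal plane and carboxyl groups at the edge to
  form GO ensembles; each model's aromatic system is inspected for π
  connectivity and the Hückel 4n+2 electron count, and ensembles are
  deduplicated by a 2048-bit radius-5 extended-connectivity fingerprint.
- **Energy model.** A native Tripos-style molecular-mechanics force field
  (harmonic bonds/angles, cosine torsions, 6-12 van der Waals, Coulomb
  with distance-dependent dielectric) with Gasteiger charges, plus Powell
  minimization and a generic command-template adapter for external
  semi-empirical / ab-initio programs.
- **Pose search.** The ligand's pose — one torsion per rotatable bond, a
  translation, and a quaternion — is quantized to a bit string whose bits
  are *qubits* (α, β) = (cos θ, sin θ).  The population evolves by a
  quantum rotation gate toward the best chromosome, a quantum NOT gate as
  mutation, single-point crossover, and a catastrophe operator that
  re-initializes the population when the average fitness stagnates.
  Fitness is −E_GDDS (total potential energy) or −E_Δ, where

      E_Δ = E_GDDS − E_G − E_lig

  is the binding energy (more negative = more stable complex).
- **Cascade protocol.** A cheap, fine-grained QGA/force-field layer feeds
  its best chromosomes into the initial population of a coarse,
  higher-accuracy layer (e.g. QGA over an external tight-binding code).
- **Screening.** A ligand library is filtered (computed logP above a
  threshold; longest intramolecular distance within the carrier
  diameter), docked repeatedly, and ranked by average binding energy.

## Worked example

Dock rigid benzene onto a coronene-like 24-carbon graphene patch with the
internal force field:

```python
import graphdock as gd
from graphdock.cascade import InternalFFEngine
from graphdock.qga import QGAConfig, run_qga

carrier = gd.make_fixture("coronene_patch")
ligand = gd.make_fixture("benzene")
config = QGAConfig(population_size=60, max_generations=800, seed=1,
                   convergence_enabled=False)
result = run_qga(carrier, ligand, config, InternalFFEngine())

report = result.reports[0]
height = abs(result.poses[0].ligand.coords[:, 2].mean())
print(f"E_GDDS              {report.e_gdds:8.3f} kcal/mol")
print(f"E_Delta (binding)   {report.e_delta:8.3f} kcal/mol")
print(f"stacking height     {height:8.2f} Å")
```

prints

```
E_GDDS                38.912 kcal/mol
E_Delta (binding)    -11.372 kcal/mol
stacking height         3.31 Å
```

The optimizer recovers the parallel π-stacked pose: the benzene plane sits
3.3 Å above the sheet — the graphitic interlayer spacing — and binds by
about −11 kcal/mol of dispersion energy.  (E_GDDS is positive here because
the idealized 1.42 Å lattice carries constant internal strain relative to
the force field's 1.395 Å aromatic reference length; constants shift every
pose equally and cancel exactly in E_Δ.)

The same workflow is available from the shell:

```sh
graphdock build --shape circular --diameter 21.76 --out g.mol2
# graphene_circ_21.76: 168 atoms, π electrons 138, 4n+2 ok -> g.mol2
graphdock functionalize g.mol2 --oh 3 --epoxy 3 --cooh 3 --max-models 20 --seed 1
graphdock dock --carrier g.mol2 --ligand ligand.mol2 --seed 1 --out poses.mol2
graphdock screen --library ligands/ --carrier g.mol2 --logp-min 5.0 --repeats 3
```

## Layout

- `src/graphdock/structures.py` — molecular data model, Mol2/XYZ/SDF/SMILES I/O
- `src/graphdock/builder.py` — graphene/GO generation, aromaticity checks, dedup
- `src/graphdock/forcefield.py` — Tripos-style force field, charges, Powell minimizer
- `src/graphdock/qga.py` — pose encoding and the quantum genetic algorithm
- `src/graphdock/cascade.py` — engines (internal / external / mock) and the cascade
- `src/graphdock/screen.py` — library filtering, repeated docking, ranking
- `src/graphdock/fixtures.py` — deterministic test molecules and mini-carriers
- `docs/methods.md` — model details, parameter choices, and limitations
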