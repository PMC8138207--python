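"""Multi-fidelity cascade protocol and pluggable energy engines.

A cascade chains QGA layers of increasing energy-model accuracy: a cheap
layer (internal force field, fine search parameters) runs first and its
best chromosomes are migrated to seed the initial population of the next,
more expensive layer (typically an external semi-empirical or ab initio
program, coarse parameters).  Migrated bit strings become qubit
populations through a seeding bias ε: a seeded qubit re-measures its
source bit with probability 1 − ε, so ε = 0 reproduces the bits exactly
and ε = 0.5 is indistinguishable from a fresh π/4 qubit.
"""

from __future__ import annotations

import dataclasses
import math
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .forcefield import EnergyReport, TriposForceField
from .qga import PoseLayout, QGAConfig, QGAResult, QubitChromosome, run_qga
from .structures import ComplexPose, MolecularStructure, total_formal_charge, write_mol2, write_xyz

__all__ = [
    "EngineSpec",
    "CascadeConfig",
    "CascadeResult",
    "InternalFFEngine",
    "MockEngine",
    "ExternalCommandEngine",
    "build_engine",
    "seed_population",
    "run_cascade",
    "external_engine_energy",
    "default_cascade",
]

_UNIT_TO_KCAL = {
    "kcal": 1.0,
    "kcal/mol": 1.0,
    "hartree": 627.509474,
    "ev": 23.060548,
    "kj": 0.239005736,
    "kj/mol": 0.239005736,
}


# ---------------------------------------------------------------------------
# engines


class InternalFFEngine:
    """Fitness backend over the internal molecular-mechanics force field.

    The carrier is rigid, so its internal energy is computed once and
    cached; the ligand's internal energy is re-evaluated at each pose
    (torsions change it), and the binding energy is the intermolecular
    nonbonded sum, making E_Delta = E_GDDS − E_G − E_lig exact.
    """

    def __init__(self, forcefield: TriposForceField | None = None) -> None:
        self.ff = forcefield or TriposForceField()
        self._carrier_energy: dict[int, float] = {}

    def evaluate_pose(
        self, carrier: MolecularStructure, ligand: MolecularStructure, lig_xyz: np.ndarray
    ) -> EnergyReport:
        key = id(carrier)
        e_g = self._carrier_energy.get(key)
        if e_g is None:
            e_g = self.ff.structure_energy(carrier)
            self._carrier_energy[key] = e_g
        e_lig = self.ff.structure_energy(ligand, lig_xyz)
        inter = self.ff.intermolecular_energy(carrier, ligand, xyz_b=lig_xyz)
        e_inter = inter["inter_vdw"] + inter["inter_electrostatic"]
        e_gdds = e_g + e_lig + e_inter
        return EnergyReport(
            e_gdds=e_gdds, e_g=e_g, e_lig=e_lig, e_delta=e_gdds - e_g - e_lig, terms=inter
        )

    def evaluate(self, pose: ComplexPose) -> EnergyReport:
        return self.evaluate_pose(pose.carrier, pose.ligand, pose.ligand.coords)


class MockEngine:
    """Deterministic analytic engine for tests and protocol studies.

    ``fn(carrier, ligand, lig_xyz)`` may return a float (taken as E_GDDS
    with zero fragment energies), a (E_GDDS, E_G, E_lig) triple, or a full
    :class:`EnergyReport`.
    """

    def __init__(self, fn: Callable) -> None:
        self.fn = fn

    def evaluate_pose(self, carrier, ligand, lig_xyz) -> EnergyReport:
        out = self.fn(carrier, ligand, np.asarray(lig_xyz))
        if isinstance(out, EnergyReport):
            return out
        if isinstance(out, (tuple, list)):
            e_gdds, e_g, e_lig = (float(v) for v in out)
        else:
            e_gdds, e_g, e_lig = float(out), 0.0, 0.0
        return EnergyReport(e_gdds=e_gdds, e_g=e_g, e_lig=e_lig, e_delta=e_gdds - e_g - e_lig)

    def evaluate(self, pose: ComplexPose) -> EnergyReport:
        return self.evaluate_pose(pose.carrier, pose.ligand, pose.ligand.coords)


@dataclass
class EngineSpec:
    """Declarative engine choice for one cascade layer.

    ``external_command`` templates must contain ``{input}`` and ``{output}``
    placeholders; ``energy_pattern`` is a regex whose first group captures
    the total energy in ``unit``.
    """

    kind: str = "internal_ff"  # internal_ff | external_command | mock
    command_template: str = ""
    energy_pattern: str = r"TOTAL ENERGY\s+=?\s*(-?\d+\.?\d*)"
    unit: str = "hartree"
    mock_fn: Callable | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("internal_ff", "external_command", "mock"):
            raise ValueError(f"unknown engine kind {self.kind!r}")
        if self.kind == "external_command" and not self.command_template:
            raise ValueError("external_command engines require a command template")
        if self.kind == "mock" and self.mock_fn is None:
            raise ValueError("mock engines require a deterministic energy function")
        if self.unit.lower() not in _UNIT_TO_KCAL:
            raise ValueError(f"unknown energy unit {self.unit!r}")


class ExternalCommandEngine:
    """Adapter that evaluates poses by invoking an external program.

    Each evaluation writes the complex and both isolated fragments to XYZ
    (with total formal charge and multiplicity 1 in the comment line), runs
    the templated command, parses the energy, and converts to kcal/mol.
    """

    def __init__(self, spec: EngineSpec, workdir: str | Path = ".") -> None:
        self.spec = spec
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self._counter = 0

    def _run_one(self, structure: MolecularStructure, tag: str) -> float:
        self._counter += 1
        inp = self.workdir / f"{tag}_{self._counter:06d}.xyz"
        out = self.workdir / f"{tag}_{self._counter:06d}.out"
        comment = f"charge={total_formal_charge(structure)} multiplicity=1"
        write_xyz(structure, inp, comment=comment)
        cmd = self.spec.command_template.format(input=inp, output=out)
        exe = cmd.split()[0]
        if shutil.which(exe) is None:
            raise RuntimeError(f"external engine executable not found: {exe!r}")
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"external engine failed (exit {proc.returncode}):\n{proc.stdout}\n{proc.stderr}"
            )
        text = out.read_text() if out.exists() else proc.stdout
        return parse_energy(text, self.spec.energy_pattern, self.spec.unit)

    def evaluate_pose(self, carrier, ligand, lig_xyz) -> EnergyReport:
        posed = ligand.copy()
        posed.set_coords(np.asarray(lig_xyz))
        return self.evaluate(ComplexPose(carrier=carrier, ligand=posed))

    def evaluate(self, pose: ComplexPose) -> EnergyReport:
        merged = _merge(pose.carrier, pose.ligand)
        e_gdds = self._run_one(merged, "complex")
        e_g = self._run_one(pose.carrier, "carrier")
        e_lig = self._run_one(pose.ligand, "ligand")
        return EnergyReport(
            e_gdds=e_gdds, e_g=e_g, e_lig=e_lig, e_delta=e_gdds - e_g - e_lig
        )


def parse_energy(text: str, pattern: str, unit: str) -> float:
    m = re.search(pattern, text)
    if not m:
        raise RuntimeError(f"energy pattern {pattern!r} not found in engine output:\n{text[:500]}")
    return float(m.group(1)) * _UNIT_TO_KCAL[unit.lower()]


def _merge(a: MolecularStructure, b: MolecularStructure) -> MolecularStructure:
    from .structures import Bond

    merged = a.copy()
    offset = merged.n_atoms
    bcopy = b.copy()
    merged.atoms.extend(bcopy.atoms)
    merged.bonds.extend(Bond(x.i + offset, x.j + offset, x.order) for x in bcopy.bonds)
    merged.name = f"{a.name}+{b.name}"
    merged.validate()
    return merged


def build_engine(spec: EngineSpec, workdir: str | Path = ".") -> object:
    if spec.kind == "internal_ff":
        return InternalFFEngine()
    if spec.kind == "mock":
        return MockEngine(spec.mock_fn)
    return ExternalCommandEngine(spec, workdir)


def external_engine_energy(
    pose: ComplexPose, spec: EngineSpec, workdir: str | Path
) -> EnergyReport:
    """One-shot external evaluation of a pose (complex and both fragments)."""
    return ExternalCommandEngine(spec, workdir).evaluate(pose)


# ---------------------------------------------------------------------------
# seeding and the cascade loop


def seed_population(
    bits_list: list[str],
    config: QGAConfig,
    epsilon: float = 0.05,
    n_bits: int | None = None,
) -> list[QubitChromosome]:
    """Initial population with ``bits_list`` imprinted on the first
    chromosomes: a seeded qubit re-measures its source bit with probability
    1 − ε.  Remaining slots are fresh π/4 chromosomes."""
    if len(bits_list) > config.population_size:
        raise ValueError(
            f"{len(bits_list)} migrated chromosomes exceed population size {config.population_size}"
        )
    if bits_list:
        n_bits = len(bits_list[0])
    if n_bits is None:
        raise ValueError("n_bits required when no strings are migrated")
    theta_one = math.acos(math.sqrt(1.0 - epsilon))  # P(bit 1) = 1 − ε
    theta_zero = math.acos(math.sqrt(epsilon))  # P(bit 1) = ε
    out: list[QubitChromosome] = []
    for bits in bits_list:
        if len(bits) != n_bits:
            raise ValueError("migrated bit strings have inconsistent lengths")
        thetas = np.array([theta_one if c == "1" else theta_zero for c in bits])
        out.append(QubitChromosome(thetas))
    while len(out) < config.population_size:
        out.append(QubitChromosome(np.full(n_bits, math.pi / 4.0)))
    return out


@dataclass
class CascadeConfig:
    """Ordered (engine, QGA parameters) layers plus migration settings."""

    layers: list[tuple[EngineSpec, QGAConfig]]
    migration_count: int = 10
    seeding_bias: float = 0.05

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a cascade needs at least one layer")
        if not 0.0 <= self.seeding_bias <= 0.5:
            raise ValueError("seeding bias must lie in [0, 0.5]")


def default_cascade(seed: int = 0, engine2: EngineSpec | None = None) -> CascadeConfig:
    """The standard two-layer protocol: a fine force-field layer
    (5000 generations, population 100, catastrophe on, convergence off)
    feeding ten chromosomes into a coarse high-accuracy layer
    (500 generations, population 20, catastrophe off, convergence on)."""
    layer1 = QGAConfig(
        population_size=100,
        max_generations=5000,
        seed=seed,
        catastrophe_enabled=True,
        convergence_enabled=False,
    )
    layer2 = QGAConfig(
        population_size=20,
        max_generations=500,
        seed=seed + 1,
        catastrophe_enabled=False,
        convergence_enabled=True,
    )
    return CascadeConfig(
        layers=[
            (EngineSpec(kind="internal_ff"), layer1),
            (engine2 or EngineSpec(kind="internal_ff"), layer2),
        ]
    )


@dataclass
class CascadeResult:
    layer_results: list[QGAResult]
    best_pose: ComplexPose | None
    best_report: EnergyReport | None
    engines: list = field(default_factory=list)


def run_cascade(
    carrier: MolecularStructure,
    ligand: MolecularStructure,
    cascade: CascadeConfig,
    workdir: str | Path | None = None,
) -> CascadeResult:
    """Run the layers in order, migrating the best chromosomes forward.

    Layer 1 starts from scratch; each later layer's initial population is
    seeded with the previous layer's ``migration_count`` best bit strings
    (re-encoded if the quantization differs).  Traces and best poses are
    persisted under ``workdir/layer_<k>/`` when a work directory is given.
    """
    results: list[QGAResult] = []
    engines: list = []
    prev_bits: list[str] | None = None
    prev_layout: PoseLayout | None = None

    for k, (espec, qcfg) in enumerate(cascade.layers, start=1):
        layer_dir = None
        if workdir is not None:
            layer_dir = Path(workdir) / f"layer_{k}"
            layer_dir.mkdir(parents=True, exist_ok=True)
        engine = build_engine(espec, layer_dir or ".")
        layout = PoseLayout(carrier, ligand, bits_per_variable=qcfg.bits_per_variable)

        initial_bits = None
        if prev_bits is not None:
            if cascade.migration_count > len(prev_bits):
                raise ValueError(
                    f"migration_count {cascade.migration_count} exceeds the previous "
                    f"layer's archive size {len(prev_bits)}"
                )
            migrated = prev_bits[: cascade.migration_count]
            if prev_layout is not None and prev_layout.n_bits != layout.n_bits:
                migrated = [
                    layout.encode_values(
                        np.clip(
                            prev_layout.decode_values(b),
                            layout.bounds[:, 0],
                            layout.bounds[:, 1],
                        )
                    )
                    for b in migrated
                ]
            initial_bits = migrated

        if initial_bits is not None:
            seeded = seed_population(
                initial_bits, qcfg, epsilon=cascade.seeding_bias, n_bits=layout.n_bits
            )
            from .qga import QGAOptimizer

            def fitness_fn(bits: str, _engine=engine, _layout=layout, _cfg=qcfg) -> float:
                xyz = _layout.apply(_layout.decode_values(bits))
                report = _engine.evaluate_pose(carrier, ligand, xyz)
                return -report.e_delta if _cfg.fitness_mode == "binding" else -report.e_gdds

            opt = QGAOptimizer(layout.n_bits, fitness_fn, qcfg)
            result = opt.run(seeded)
            for bits in result.best_bits:
                pose = layout.decode_pose(bits)
                result.poses.append(pose)
                result.reports.append(engine.evaluate_pose(carrier, ligand, pose.ligand.coords))
        else:
            result = run_qga(carrier, ligand, qcfg, engine, layout=layout)

        results.append(result)
        engines.append(engine)
        prev_bits = result.best_bits
        prev_layout = layout

        if layer_dir is not None:
            _persist_layer(layer_dir, result)

    last = results[-1]
    best_pose = last.poses[0] if last.poses else None
    best_report = last.reports[0] if last.reports else None
    return CascadeResult(
        layer_results=results, best_pose=best_pose, best_report=best_report, engines=engines
    )


def _persist_layer(layer_dir: Path, result: QGAResult) -> None:
    lines = ["generation\tavg_fitness\tbest_fitness\tcatastrophe"]
    cat = set(result.catastrophe_generations)
    for g, (a, b) in enumerate(zip(result.avg_fitness_trace, result.best_fitness_trace), start=1):
        lines.append(f"{g}\t{a:.6f}\t{b:.6f}\t{int(g in cat)}")
    (layer_dir / "gen_trace.tsv").write_text("\n".join(lines) + "\n")
    for i, (pose, report) in enumerate(zip(result.poses, result.reports)):
        merged = _merge(pose.carrier, pose.ligand)
        write_mol2(merged, layer_dir / f"best_{i}.mol2", energies=report.as_dict())
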