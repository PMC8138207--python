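"""Quantum genetic algorithm for ligand pose search.

A ligand pose is encoded as a real vector — one torsion per freely
rotatable bond, a translation (x, y, z) inside the search box, and a
quaternion (q1..q4, normalized on decode) — quantized to a binary string
with a fixed number of bits per variable.  Each bit is represented by a
qubit angle θ (α = cos θ, β = sin θ, so α² + β² = 1 holds identically);
measurement collapses a qubit to "1" with probability |cos θ|².  The
population evolves by a quantum rotation gate toward the best chromosome
(Δθ from an editable schedule), a quantum NOT gate as mutation
(α, β) → (β, α), single-point crossover of θ segments, and a catastrophe
operator that re-initializes every qubit to π/4 when the average fitness
stagnates.  Fitness is −E_GDDS (total potential energy of the complex) by
default, or −E_Delta (binding energy) in ``binding`` mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .structures import AROMATIC, ComplexPose, MolecularStructure

__all__ = [
    "PoseGenome",
    "PoseLayout",
    "QubitChromosome",
    "QGAConfig",
    "QGAResult",
    "DeltaThetaSchedule",
    "detect_rotatable_bonds",
    "encode_pose",
    "decode_chromosome",
    "initialize_population",
    "measure_chromosome",
    "apply_qrgo",
    "apply_qngo",
    "crossover",
    "catastrophe",
    "compute_fitness",
    "QGAOptimizer",
    "run_qga",
]


# ---------------------------------------------------------------------------
# rotatable bonds


def _terminal_side(structure: MolecularStructure, pivot: int, other: int) -> bool:
    """True if rotating about (other→pivot) only permutes equivalent leaves:
    every substituent of `pivot` besides `other` is a degree-1 atom and they
    are all the same element (methyl, CF3, OH, primary amine...)."""
    adj = structure.neighbours()
    subs = [k for k in adj[pivot] if k != other]
    if not subs:
        return True
    if any(len(adj[k]) != 1 for k in subs):
        return False
    elements = {structure.atoms[k].element for k in subs}
    return len(elements) == 1


def detect_rotatable_bonds(ligand: MolecularStructure) -> list[int]:
    """Indices (into ``ligand.bonds``) of freely rotatable bonds: single,
    acyclic, between heavy atoms, excluding amide C–N and bonds whose
    rotation only permutes equivalent terminal atoms."""
    g = nx.Graph()
    g.add_nodes_from(range(ligand.n_atoms))
    for b in ligand.bonds:
        g.add_edge(b.i, b.j)
    bridges = set(frozenset(e) for e in nx.bridges(g)) if ligand.n_atoms > 1 else set()
    adj = ligand.neighbours()
    order_map: dict[frozenset, object] = {frozenset((b.i, b.j)): b.order for b in ligand.bonds}

    def is_amide(i: int, j: int) -> bool:
        for c, n in ((i, j), (j, i)):
            if ligand.atoms[c].element == "C" and ligand.atoms[n].element == "N":
                if any(
                    ligand.atoms[k].element == "O" and order_map.get(frozenset((c, k))) == 2
                    for k in adj[c]
                ):
                    return True
        return False

    out = []
    for idx, b in enumerate(ligand.bonds):
        if b.order != 1:
            continue
        if frozenset((b.i, b.j)) not in bridges:
            continue  # ring bond
        ai, aj = ligand.atoms[b.i], ligand.atoms[b.j]
        if ai.element == "H" or aj.element == "H":
            continue
        if is_amide(b.i, b.j):
            continue
        if _terminal_side(ligand, b.i, b.j) or _terminal_side(ligand, b.j, b.i):
            continue
        out.append(idx)
    return out


# ---------------------------------------------------------------------------
# genome, layout, encode/decode


@dataclass
class PoseGenome:
    """Real-valued pose variables with per-variable bounds."""

    torsions: np.ndarray  # radians
    translation: np.ndarray  # Å, displacement of the ligand centroid
    quaternion: np.ndarray  # raw components; normalized on application
    bounds: np.ndarray  # (n_vars, 2)

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.torsions, self.translation, self.quaternion])


class PoseLayout:
    """Fixed variable order (torsions, tx, ty, tz, q1..q4), quantization and
    pose application for one carrier/ligand pair."""

    def __init__(
        self,
        carrier: MolecularStructure,
        ligand: MolecularStructure,
        bits_per_variable: int = 16,
        xy_margin: float = 10.0,
        z_extent: float = 8.0,
    ) -> None:
        self.carrier = carrier
        self.ligand = ligand
        self.bits_per_variable = int(bits_per_variable)
        self.rotatable = detect_rotatable_bonds(ligand)
        self._moving_sets = [self._moving_side(ligand.bonds[i]) for i in self.rotatable]
        self.ref_coords = ligand.coords
        self.ref_centroid = self.ref_coords.mean(axis=0)

        cxyz = carrier.coords
        lo = cxyz.min(axis=0)
        hi = cxyz.max(axis=0)
        c = self.ref_centroid
        bounds = []
        bounds.extend([(-math.pi, math.pi)] * len(self.rotatable))
        bounds.append((lo[0] - xy_margin - c[0], hi[0] + xy_margin - c[0]))
        bounds.append((lo[1] - xy_margin - c[1], hi[1] + xy_margin - c[1]))
        bounds.append((-z_extent - c[2], z_extent - c[2]))
        bounds.extend([(-1.0, 1.0)] * 4)
        self.bounds = np.array(bounds)
        self.n_vars = len(bounds)
        self.n_bits = self.n_vars * self.bits_per_variable

    def _moving_side(self, bond) -> np.ndarray:
        """Atoms on the smaller side of an acyclic bond (the side rotated)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.ligand.n_atoms))
        for b in self.ligand.bonds:
            if b.key() != bond.key():
                g.add_edge(b.i, b.j)
        side_j = nx.node_connected_component(g, bond.j)
        side_i = nx.node_connected_component(g, bond.i)
        if len(side_j) <= len(side_i):
            return np.array(sorted(side_j)), bond.i, bond.j
        return np.array(sorted(side_i)), bond.j, bond.i

    # -- quantization -----------------------------------------------------
    def encode_values(self, values: np.ndarray) -> str:
        b = self.bits_per_variable
        levels = (1 << b) - 1
        chunks = []
        for v, (lo, hi) in zip(values, self.bounds):
            if v < lo - 1e-9 or v > hi + 1e-9:
                raise ValueError(f"variable value {v} outside bounds [{lo}, {hi}]")
            level = int(round((v - lo) / (hi - lo) * levels))
            level = min(max(level, 0), levels)
            chunks.append(format(level, f"0{b}b"))
        return "".join(chunks)

    def decode_values(self, bits: str) -> np.ndarray:
        b = self.bits_per_variable
        if len(bits) != self.n_bits:
            raise ValueError(f"bit string length {len(bits)} != layout size {self.n_bits}")
        levels = (1 << b) - 1
        vals = np.empty(self.n_vars)
        for k in range(self.n_vars):
            level = int(bits[k * b : (k + 1) * b], 2)
            lo, hi = self.bounds[k]
            vals[k] = lo + level * (hi - lo) / levels
        return vals

    def genome_from_values(self, values: np.ndarray) -> PoseGenome:
        nt = len(self.rotatable)
        return PoseGenome(
            torsions=np.asarray(values[:nt], dtype=float),
            translation=np.asarray(values[nt : nt + 3], dtype=float),
            quaternion=np.asarray(values[nt + 3 : nt + 7], dtype=float),
            bounds=self.bounds,
        )

    # -- pose application -------------------------------------------------
    def apply(self, values: np.ndarray) -> np.ndarray:
        """Posed ligand coordinates: torsions about each rotatable bond
        (smaller fragment moves), quaternion about the centroid, then the
        translation.  Bond lengths and angles are preserved exactly."""
        nt = len(self.rotatable)
        xyz = self.ref_coords.copy()
        for t_idx in range(nt):
            angle = values[t_idx]
            moving, anchor, piv = self._moving_sets[t_idx]
            axis = xyz[piv] - xyz[anchor]
            norm = np.linalg.norm(axis)
            if norm < 1e-12:
                continue
            rot = Rotation.from_rotvec(axis / norm * angle)
            xyz[moving] = rot.apply(xyz[moving] - xyz[anchor]) + xyz[anchor]
        q = np.asarray(values[nt + 3 : nt + 7], dtype=float)
        qn = np.linalg.norm(q)
        centroid = xyz.mean(axis=0)
        if qn > 1e-12:  # all-zero quaternion decodes to the identity rotation
            rot = Rotation.from_quat(q / qn)
            xyz = rot.apply(xyz - centroid) + centroid
        xyz = xyz + values[nt : nt + 3]
        return xyz

    def decode_pose(self, bits: str) -> ComplexPose:
        values = self.decode_values(bits)
        posed = self.ligand.copy()
        posed.set_coords(self.apply(values))
        return ComplexPose(carrier=self.carrier, ligand=posed, genome=self.genome_from_values(values))


def encode_pose(genome: PoseGenome, bits_per_variable: int = 16) -> str:
    """Quantize a genome onto its bounds with 2^bits levels per variable
    (big-endian bits, fixed variable order)."""
    b = int(bits_per_variable)
    levels = (1 << b) - 1
    chunks = []
    for v, (lo, hi) in zip(genome.values, genome.bounds):
        if v < lo - 1e-9 or v > hi + 1e-9:
            raise ValueError(f"variable value {v} outside bounds [{lo}, {hi}]")
        level = min(max(int(round((v - lo) / (hi - lo) * levels)), 0), levels)
        chunks.append(format(level, f"0{b}b"))
    return "".join(chunks)


def decode_chromosome(bits: str, ligand: MolecularStructure, layout: PoseLayout) -> ComplexPose:
    """Decode a measured bit string to a posed carrier/ligand complex."""
    if ligand is not layout.ligand:
        raise ValueError("layout was built for a different ligand")
    return layout.decode_pose(bits)


# ---------------------------------------------------------------------------
# qubits and operators


@dataclass
class QubitChromosome:
    thetas: np.ndarray
    measured_bits: str | None = None
    fitness: float | None = None

    @property
    def alpha(self) -> np.ndarray:
        return np.cos(self.thetas)

    @property
    def beta(self) -> np.ndarray:
        return np.sin(self.thetas)

    def copy(self) -> "QubitChromosome":
        return QubitChromosome(self.thetas.copy(), self.measured_bits, self.fitness)


class DeltaThetaSchedule:
    """(bit, best_bit, fitness≥best) → (|Δθ|, target bit) lookup."""

    def __init__(self, rows: list[dict] | None = None) -> None:
        if rows is None:
            with resources.files("graphdock.data").joinpath("delta_theta.yaml").open() as fh:
                rows = yaml.safe_load(fh)["rows"]
        self.table: dict[tuple[int, int, bool], tuple[float, str]] = {}
        for r in rows:
            key = (int(r["bit"]), int(r["best"]), bool(r["better"]))
            self.table[key] = (float(r["magnitude"]) * math.pi, str(r["target"]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeltaThetaSchedule":
        return cls(yaml.safe_load(Path(path).read_text())["rows"])

    def lookup(self, bit: int, best_bit: int, better: bool) -> tuple[float, str]:
        try:
            return self.table[(bit, best_bit, better)]
        except KeyError:
            raise KeyError(f"Δθ schedule has no entry for (bit={bit}, best={best_bit}, better={better})") from None


@dataclass
class QGAConfig:
    """QGA control parameters (defaults follow the platform's standard
    settings: operator probabilities 0.5 / 0.1 / 0.7, stagnation window 50
    generations at an average-fitness change below 0.001)."""

    population_size: int = 100
    max_generations: int = 5000
    p_qrgo: float = 0.5
    p_qngo: float = 0.1
    p_crossover: float = 0.7
    stagnation_window: int = 50
    convergence_threshold: float = 0.001
    bits_per_variable: int = 16
    seed: int = 0
    fitness_mode: str = "potential"  # potential (−E_GDDS) | binding (−E_Delta)
    catastrophe_enabled: bool = True
    convergence_enabled: bool = True
    convergence_window: int = 100
    archive_size: int = 10
    measurement_polarity: str = "alpha_one"  # u < |α|² → bit 1 ("alpha_zero" flips it)
    delta_theta_schedule: DeltaThetaSchedule | None = None

    def __post_init__(self) -> None:
        for p in (self.p_qrgo, self.p_qngo, self.p_crossover):
            if not 0.0 <= p <= 1.0:
                raise ValueError("operator probabilities must lie in [0, 1]")
        if self.population_size < 1 or self.max_generations < 1:
            raise ValueError("population size and generations must be positive")
        if self.fitness_mode not in ("potential", "binding"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.measurement_polarity not in ("alpha_one", "alpha_zero"):
            raise ValueError(f"unknown measurement_polarity {self.measurement_polarity!r}")

    def schedule(self) -> DeltaThetaSchedule:
        if self.delta_theta_schedule is None:
            self.delta_theta_schedule = DeltaThetaSchedule()
        return self.delta_theta_schedule


def initialize_population(config: QGAConfig, n_bits: int | None = None) -> list[QubitChromosome]:
    """Fresh population: every θ = π/4, so each qubit collapses to either
    state with probability 1/2."""
    if n_bits is None:
        n_bits = config.bits_per_variable
    return [
        QubitChromosome(np.full(n_bits, math.pi / 4.0)) for _ in range(config.population_size)
    ]


def measure_chromosome(
    chromosome: QubitChromosome, rng: np.random.Generator, polarity: str = "alpha_one"
) -> str:
    """Collapse each qubit: draw u ∈ [0,1); with the default polarity the
    bit is "1" iff u < |cos θ|²."""
    p_alpha = np.cos(chromosome.thetas) ** 2
    u = rng.random(len(chromosome.thetas))
    if polarity == "alpha_one":
        bits = u < p_alpha
    else:
        bits = u >= p_alpha
    s = "".join("1" if b else "0" for b in bits)
    chromosome.measured_bits = s
    return s


def _signed_delta(theta: float, magnitude: float, target_bit: int, rng: np.random.Generator) -> float:
    """Δθ moving the measurement probability toward ``target_bit``.

    P(1) = cos²θ has derivative −sin 2θ; the sign follows.  At the
    stationary points (θ ≡ 0 mod π/2) the direction is drawn at random so a
    fully collapsed qubit can still escape."""
    s2 = math.sin(2.0 * theta)
    if abs(s2) < 1e-12:
        direction = 1.0 if rng.random() < 0.5 else -1.0
        # already saturated toward the target → no rotation needed
        p1 = math.cos(theta) ** 2
        if (target_bit == 1 and p1 > 0.5) or (target_bit == 0 and p1 < 0.5):
            return 0.0
        return direction * magnitude
    direction = -math.copysign(1.0, s2) if target_bit == 1 else math.copysign(1.0, s2)
    return direction * magnitude


def apply_qrgo(
    chromosome: QubitChromosome,
    best: QubitChromosome,
    schedule: DeltaThetaSchedule,
    rng: np.random.Generator,
    p_qrgo: float = 0.5,
) -> QubitChromosome:
    """Quantum rotation gate: with probability ``p_qrgo`` per chromosome,
    rotate each qubit by the scheduled Δθ given (own bit, best bit, own
    fitness ≥ best fitness); (α', β') = (cos(θ+Δθ), sin(θ+Δθ))."""
    if chromosome.measured_bits is None or best.measured_bits is None:
        raise ValueError("both chromosomes must be measured before QRGO")
    if rng.random() >= p_qrgo:
        return chromosome
    better = (chromosome.fitness or 0.0) >= (best.fitness or 0.0)
    for i, (bc, bb) in enumerate(zip(chromosome.measured_bits, best.measured_bits)):
        mag, target = schedule.lookup(int(bc), int(bb), better)
        if mag == 0.0 or target == "none":
            continue
        target_bit = int(bb) if target == "best" else int(bc)
        chromosome.thetas[i] += _signed_delta(chromosome.thetas[i], mag, target_bit, rng)
    return chromosome


def apply_qngo(
    chromosome: QubitChromosome, rng: np.random.Generator, p_qngo: float = 0.1
) -> QubitChromosome:
    """Quantum NOT gate (mutation): per qubit with probability ``p_qngo``,
    (α, β) → (β, α), i.e. θ → π/2 − θ.  An involution; θ = π/4 is fixed."""
    mask = rng.random(len(chromosome.thetas)) < p_qngo
    chromosome.thetas[mask] = math.pi / 2.0 - chromosome.thetas[mask]
    return chromosome


def crossover(
    c1: QubitChromosome,
    c2: QubitChromosome,
    rng: np.random.Generator,
    p_crossover: float = 0.7,
) -> tuple[QubitChromosome, QubitChromosome]:
    """Single-point exchange of θ segments after a uniformly drawn cut."""
    if len(c1.thetas) != len(c2.thetas):
        raise ValueError("chromosome length mismatch in crossover")
    a, b = c1.copy(), c2.copy()
    if rng.random() < p_crossover:
        cut = int(rng.integers(0, len(a.thetas) + 1))
        tail = a.thetas[cut:].copy()
        a.thetas[cut:] = b.thetas[cut:]
        b.thetas[cut:] = tail
    return a, b


def catastrophe(population: list[QubitChromosome]) -> list[QubitChromosome]:
    """Reinitialize every qubit of every chromosome to π/4.  The best
    chromosome survives only in the external archive."""
    n_bits = len(population[0].thetas)
    return [QubitChromosome(np.full(n_bits, math.pi / 4.0)) for _ in population]


def compute_fitness(pose: ComplexPose, engine, mode: str = "potential") -> float:
    """Fitness = −E_GDDS (``potential``) or −E_Delta (``binding``)."""
    report = engine.evaluate(pose)
    if mode == "potential":
        return -1.0 * report.e_gdds
    if mode == "binding":
        if report.e_delta is None:
            raise ValueError("engine did not report a binding energy")
        return -1.0 * report.e_delta
    raise ValueError(f"unknown fitness mode {mode!r}")


# ---------------------------------------------------------------------------
# the evolutionary loop


@dataclass
class _ArchiveEntry:
    bits: str
    fitness: float
    generation: int
    index: int


@dataclass
class QGAResult:
    best_bits: list[str]
    best_fitnesses: list[float]
    avg_fitness_trace: list[float]
    best_fitness_trace: list[float]
    catastrophe_generations: list[int]
    n_generations: int
    converged: bool
    poses: list[ComplexPose] = field(default_factory=list)
    reports: list = field(default_factory=list)


class QGAOptimizer:
    """Generic QGA loop over bit strings with an arbitrary fitness function.

    The chemistry-aware entry point :func:`run_qga` builds the fitness from
    a pose layout and an energy engine; toy objectives can drive this class
    directly.
    """

    def __init__(
        self,
        n_bits: int,
        fitness_fn: Callable[[str], float],
        config: QGAConfig,
        memoize: bool = True,
    ) -> None:
        self.n_bits = n_bits
        self.fitness_fn = fitness_fn
        self.config = config
        self.memoize = memoize
        self._cache: dict[str, float] = {}

    def _fitness(self, bits: str) -> float:
        if not self.memoize:
            return self.fitness_fn(bits)
        val = self._cache.get(bits)
        if val is None:
            val = self.fitness_fn(bits)
            self._cache[bits] = val
        return val

    def run(self, initial_population: list[QubitChromosome] | None = None) -> QGAResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        schedule = cfg.schedule()
        if initial_population is not None:
            if len(initial_population) != cfg.population_size:
                raise ValueError("initial population size does not match the configuration")
            population = [c.copy() for c in initial_population]
        else:
            population = initialize_population(cfg, self.n_bits)

        archive: list[_ArchiveEntry] = []
        avg_trace: list[float] = []
        best_trace: list[float] = []
        catastrophes: list[int] = []
        avg_prev: float | None = None
        stagnant = 0
        converged_for = 0
        converged = False
        gen = 0

        for gen in range(1, cfg.max_generations + 1):
            fits = []
            for idx, ch in enumerate(population):
                bits = measure_chromosome(ch, rng, cfg.measurement_polarity)
                ch.fitness = self._fitness(bits)
                fits.append(ch.fitness)
                self._update_archive(archive, bits, ch.fitness, gen, idx)
            avg = float(np.mean(fits))
            avg_trace.append(avg)
            best_trace.append(archive[0].fitness)

            if avg_prev is not None and abs(avg - avg_prev) < cfg.convergence_threshold:
                stagnant += 1
                converged_for += 1
            else:
                stagnant = 0
                converged_for = 0
            avg_prev = avg

            if cfg.convergence_enabled and converged_for >= cfg.convergence_window:
                converged = True
                break
            if gen == cfg.max_generations:
                break
            if cfg.catastrophe_enabled and stagnant >= cfg.stagnation_window:
                population = catastrophe(population)
                catastrophes.append(gen)
                stagnant = 0
                continue

            best_entry = archive[0]
            best_ch = QubitChromosome(
                np.full(self.n_bits, math.pi / 4.0), best_entry.bits, best_entry.fitness
            )
            for ch in population:
                apply_qrgo(ch, best_ch, schedule, rng, cfg.p_qrgo)
            for ch in population:
                apply_qngo(ch, rng, cfg.p_qngo)
            next_pop: list[QubitChromosome] = []
            for k in range(0, len(population) - 1, 2):
                a, b = crossover(population[k], population[k + 1], rng, cfg.p_crossover)
                next_pop.extend((a, b))
            if len(population) % 2 == 1:
                next_pop.append(population[-1].copy())
            population = next_pop

        return QGAResult(
            best_bits=[e.bits for e in archive],
            best_fitnesses=[e.fitness for e in archive],
            avg_fitness_trace=avg_trace,
            best_fitness_trace=best_trace,
            catastrophe_generations=catastrophes,
            n_generations=gen,
            converged=converged,
        )

    def _update_archive(
        self, archive: list[_ArchiveEntry], bits: str, fitness: float, gen: int, idx: int
    ) -> None:
        for e in archive:
            if e.bits == bits:
                return  # already archived; earliest sighting kept
        archive.append(_ArchiveEntry(bits, fitness, gen, idx))
        archive.sort(key=lambda e: (-e.fitness, e.generation, e.index))
        del archive[self.config.archive_size :]


def run_qga(
    carrier: MolecularStructure,
    ligand: MolecularStructure,
    config: QGAConfig,
    engine,
    initial_bits: Sequence[str] | None = None,
    layout: PoseLayout | None = None,
) -> QGAResult:
    """Global pose search of a ligand against a rigid carrier.

    ``engine`` must expose ``evaluate_pose(carrier, ligand, lig_xyz) ->
    EnergyReport``.  ``initial_bits`` seeds part of the starting population
    (used by the cascade protocol); remaining slots start fresh at θ = π/4.
    """
    layout = layout or PoseLayout(carrier, ligand, bits_per_variable=config.bits_per_variable)

    def fitness_fn(bits: str) -> float:
        xyz = layout.apply(layout.decode_values(bits))
        report = engine.evaluate_pose(carrier, ligand, xyz)
        if config.fitness_mode == "binding":
            return -1.0 * report.e_delta
        return -1.0 * report.e_gdds

    opt = QGAOptimizer(layout.n_bits, fitness_fn, config)
    initial_population = None
    if initial_bits is not None:
        from .cascade import seed_population

        initial_population = seed_population(list(initial_bits), config, n_bits=layout.n_bits)
    result = opt.run(initial_population)

    for bits in result.best_bits:
        pose = layout.decode_pose(bits)
        result.poses.append(pose)
        result.reports.append(engine.evaluate_pose(carrier, ligand, pose.ligand.coords))
    return result
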